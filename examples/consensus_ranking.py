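"""Borda-count consensus over several goodness-of-fit scores.

Each score ranks the ensemble; rank r earns N - r points, and fits are
re-ranked by total points.  Combining CCC, MI and NV-S overrules the
occasional score that prefers a decoy.
"""

from emscore import borda_rank, make_benchmark_case, score_ensemble

target, model, fits = make_benchmark_case(resolution=20.0, n_fits=30, seed=11)
table = score_ensemble(fits, model, target, resolution=20.0,
                       which=["ccc", "mi", "nv_s"])
df = borda_rank(table, ["CCC", "MI", "NV-S"])

cols = ["fit_id", "rank_CCC", "rank_MI", "rank_NV-S", "borda_points", "borda_rank"]
print(df.sort_values("borda_rank")[cols].head(5).to_string(index=False))
print("\nThe consensus best fit earned the most Borda points across all "
      "three scores; per-score ranks show how much the scores agree.")
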