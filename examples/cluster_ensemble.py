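"""Cluster the top-scoring fits of an ensemble by Cα-RMSD.

The 20 best fits under MI are clustered agglomeratively (complete
linkage), cut at the mean pairwise Cα-RMSD of those fits, and the
best-scoring non-singleton cluster is selected.  A good fit surrounded by
near-identical alternatives is more trustworthy than an isolated one.
"""

from emscore import (
    apply_transform,
    cluster_fits,
    cluster_summary,
    make_benchmark_case,
    rmsd_matrix,
    score_ensemble,
)

target, model, fits = make_benchmark_case(resolution=10.0, n_fits=30, seed=7)
table = score_ensemble(fits, model, target, resolution=10.0, which=["mi"])
members = [apply_transform(model, f) for f in fits]
matrix = rmsd_matrix(members)

result = cluster_fits(matrix, table, "MI", cutoff="mean-top20", top_k=20)
fit_index = {f: i for i, f in enumerate(table.fit_ids)}
print(f"cutoff = {result.cutoff:.2f} A (mean pairwise Ca-RMSD of the top 20)")
print(cluster_summary(result, matrix, fit_index))
print(f"top non-singleton cluster: {result.top_cluster} "
      f"with members {result.top_cluster_members()}")
print("model_0 sitting in the top cluster means nearby perturbations score "
      "almost as well - the placement is precise, not a scoring accident.")
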