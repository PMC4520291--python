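"""Borda-count consensus ranking across multiple goodness-of-fit scores.

Each score ranks the N fits of an ensemble; under the Borda count a fit
ranked r by a score earns N - r points from that score, and the consensus
orders fits by their total points over all S scores (S > 1).  Combining
scores with different strengths this way damps the idiosyncrasies of any
single score.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .scores import ScoreTable, canonical_score_name

#: Points awarded to rank r in an ensemble of N fits: N - r + BORDA_OFFSET.
BORDA_OFFSET = 0


def borda_points(ranks: np.ndarray, n: int, offset: int = BORDA_OFFSET) -> np.ndarray:
    """Points for a vector of (possibly fractional, tied) ranks."""
    return n - np.asarray(ranks, dtype=float) + offset


def borda_rank(
    table: ScoreTable,
    scores: list[str],
    offset: int = BORDA_OFFSET,
) -> pd.DataFrame:
    """Consensus-rank an ensemble over >= 2 scores.

    Returns the score table as a DataFrame augmented with ``borda_points``
    (total points; higher is better) and ``borda_rank`` (1 = consensus
    best).  Ties in a score column contribute mean fractional points; ties
    in total points are broken by lexicographic fit id.
    """
    names = [canonical_score_name(s) for s in scores]
    if len(names) < 2:
        raise ValueError("Borda consensus requires at least two scores (S > 1)")
    for n in names:
        if n not in table.scores:
            raise ValueError(f"score {n!r} not present in the table")

    n_fits = len(table)
    totals = np.zeros(n_fits)
    for n in names:
        totals += borda_points(table.ranks[n], n_fits, offset)

    df = table.to_dataframe()
    df["borda_points"] = totals
    # descending points; ties broken by fit_id
    order = sorted(range(n_fits), key=lambda i: (-totals[i], table.fit_ids[i]))
    rank = np.empty(n_fits, dtype=int)
    for position, i in enumerate(order, start=1):
        rank[i] = position
    df["borda_rank"] = rank
    return df


def consensus_report(df: pd.DataFrame, out_prefix: str | os.PathLike) -> tuple[str, str]:
    """Write ``<prefix>_consensus.tsv`` (sorted by Borda rank) and
    ``<prefix>_rank_heatmap.png`` (fits x scores, color-coded rank)."""
    if "borda_rank" not in df.columns:
        raise ValueError("run borda_rank first: borda columns missing")
    out_prefix = os.fspath(out_prefix)
    tsv_path = f"{out_prefix}_consensus.tsv"
    png_path = f"{out_prefix}_rank_heatmap.png"

    ordered = df.sort_values("borda_rank")
    ordered.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rank_cols = [c for c in df.columns if c.startswith("rank_")]
    mat = ordered[rank_cols].to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * len(rank_cols), 1 + 0.25 * len(ordered))
    )
    im = ax.imshow(mat, aspect="auto", cmap="Blues_r")
    ax.set_xticks(range(len(rank_cols)))
    ax.set_xticklabels([c[len("rank_"):] for c in rank_cols], rotation=45)
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels(ordered["fit_id"], fontsize=6)
    fig.colorbar(im, ax=ax, label="rank (1 = best)")
    ax.set_title("per-score ranks, rows sorted by Borda consensus", fontsize=9)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return tsv_path, png_path
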