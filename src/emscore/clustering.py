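"""Hierarchical Cα-RMSD clustering of fit ensembles.

Alternative placements of the same model are compared by Cα-RMSD in the
shared map frame and clustered agglomeratively (complete linkage by
default, so the cutoff bounds the intra-cluster diameter).  The flat cut
uses either an explicit cutoff in Å or the "mean-top20" rule: the mean
pairwise Cα-RMSD of the k best fits under a chosen score.  The cluster of
interest is the best-scoring *non-singleton* cluster — a good fit that no
alternative placement comes close to reproducing is treated with suspicion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .scores import ScoreTable
from .structure_core import AtomicStructure, calpha_rmsd

MEAN_TOPK_RULE = "mean-top20"


@dataclass
class ClusterResult:
    """Linkage, flat labels and top-cluster selection for a fit ensemble."""

    fit_ids: list[str]
    linkage: np.ndarray
    labels: dict[str, int]
    cutoff: float
    top_cluster: int | None
    score_name: str | None = None

    def members(self, cluster_id: int) -> list[str]:
        return [f for f, c in self.labels.items() if c == cluster_id]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def top_cluster_members(self) -> list[str]:
        if self.top_cluster is None:
            return []
        return self.members(self.top_cluster)


def rmsd_matrix(fits: list[AtomicStructure]) -> np.ndarray:
    """Symmetric matrix of pairwise Cα-RMSDs (Å), zero diagonal."""
    if len(fits) < 2:
        raise ValueError("need at least two fits")
    n = len(fits)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = calpha_rmsd(fits[i], fits[j])
    return m


def cluster_fits(
    matrix: np.ndarray,
    score_table: ScoreTable,
    score: str,
    cutoff: float | str = MEAN_TOPK_RULE,
    top_k: int = 20,
    linkage_method: str = "complete",
    cluster_all: bool = False,
) -> ClusterResult:
    """Agglomerative clustering of the top fits under one score.

    By default the ``top_k`` best fits under ``score`` are clustered; with
    ``cluster_all`` the whole ensemble is clustered while the cutoff is
    still derived from the top-k fits.  ``cutoff`` is either a height in Å
    or the rule ``"mean-top20"`` (mean pairwise Cα-RMSD of the top-k fits).
    The top cluster is the non-singleton cluster containing the best-ranked
    fit that belongs to any non-singleton cluster; ``top_cluster`` is None
    (flagged, not an error) when every cluster is a singleton.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or n != len(score_table):
        raise ValueError("matrix must be square and cover every fit in the table")

    top_ids = score_table.top_fits(score, min(top_k, n))
    top_idx = [score_table.fit_ids.index(f) for f in top_ids]
    sub = matrix[np.ix_(top_idx, top_idx)]
    if isinstance(cutoff, str):
        if not cutoff.startswith("mean-top"):
            raise ValueError(f"unknown cutoff rule {cutoff!r}")
        k = len(top_idx)
        cutoff_value = float(sub[np.triu_indices(k, 1)].mean())
    else:
        cutoff_value = float(cutoff)

    if cluster_all:
        use_idx = list(range(n))
        use_matrix = matrix
    else:
        use_idx = top_idx
        use_matrix = sub

    Z = hierarchy.linkage(squareform(use_matrix, checks=False), method=linkage_method)
    flat = hierarchy.fcluster(Z, t=cutoff_value, criterion="distance")
    fit_ids = [score_table.fit_ids[i] for i in use_idx]
    labels = {f: int(c) for f, c in zip(fit_ids, flat)}

    sizes: dict[int, int] = {}
    for c in flat:
        sizes[int(c)] = sizes.get(int(c), 0) + 1
    ranks = score_table.ranks[_canon(score_table, score)]
    top_cluster = None
    best_rank = np.inf
    for f, c in labels.items():
        if sizes[c] < 2:
            continue
        r = ranks[score_table.fit_ids.index(f)]
        if r < best_rank:
            best_rank, top_cluster = r, c
    return ClusterResult(
        fit_ids=fit_ids,
        linkage=Z,
        labels=labels,
        cutoff=cutoff_value,
        top_cluster=top_cluster,
        score_name=_canon(score_table, score),
    )


def _canon(table: ScoreTable, score: str) -> str:
    from .scores import canonical_score_name

    name = canonical_score_name(score)
    if name not in table.scores:
        raise ValueError(f"score {name!r} not present in the table")
    return name


def cluster_summary(result: ClusterResult, matrix: np.ndarray,
                    fit_index: dict[str, int]) -> str:
    """Deterministic tab-separated cluster summary.

    Columns: cluster id, size, whether it is the top cluster, mean
    intra-cluster Cα-RMSD (0 for singletons) and the member fit ids.
    """
    lines = ["cluster\tsize\ttop\tmean_intra_rmsd\tmembers"]
    for cid in sorted(set(result.labels.values())):
        members = result.members(cid)
        idx = [fit_index[f] for f in members]
        if len(idx) > 1:
            sub = np.asarray(matrix)[np.ix_(idx, idx)]
            mean_rmsd = float(sub[np.triu_indices(len(idx), 1)].mean())
        else:
            mean_rmsd = 0.0
        top = "yes" if cid == result.top_cluster else "no"
        lines.append(
            f"{cid}\t{len(members)}\t{top}\t{mean_rmsd:.4f}\t{','.join(members)}"
        )
    return "\n".join(lines) + "\n"


def dendrogram_report(
    result: ClusterResult,
    score_table: ScoreTable,
    matrix: np.ndarray,
    out_prefix: str | os.PathLike,
) -> tuple[str, str]:
    """Write ``<prefix>_dendrogram.png`` and ``<prefix>_clusters.tsv``.

    The dendrogram carries a per-fit color bar for the clustering score,
    shaded from white (worst) to saturated blue (best).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import Normalize

    out_prefix = os.fspath(out_prefix)
    png_path = f"{out_prefix}_dendrogram.png"
    tsv_path = f"{out_prefix}_clusters.tsv"

    fig, (ax_d, ax_c) = plt.subplots(
        2, 1, figsize=(max(6, 0.5 * len(result.fit_ids)), 6),
        gridspec_kw={"height_ratios": [5, 1]},
    )
    dd = hierarchy.dendrogram(
        result.linkage, labels=result.fit_ids, ax=ax_d,
        color_threshold=result.cutoff,
    )
    ax_d.axhline(result.cutoff, ls="--", c="grey", lw=0.8)
    ax_d.set_ylabel("C$\\alpha$-RMSD (Å)")

    name = result.score_name or next(iter(score_table.scores))
    vals = np.array(
        [score_table.scores[name][score_table.fit_ids.index(f)] for f in dd["ivl"]]
    )
    from .scores import HIGHER_BETTER

    if name not in HIGHER_BETTER:
        vals = -vals  # saturate the best (lowest) values
    norm = Normalize(vmin=vals.min(), vmax=vals.max()) if np.ptp(vals) else Normalize(0, 1)
    ax_c.imshow(norm(vals)[None, :], aspect="auto", cmap="Blues", vmin=0, vmax=1)
    ax_c.set_yticks([])
    ax_c.set_xticks(range(len(dd["ivl"])))
    ax_c.set_xticklabels(dd["ivl"], rotation=90, fontsize=6)
    ax_c.set_title(f"{name} per fit (white = lowest, blue = best)", fontsize=8)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)

    fit_index = {f: i for i, f in enumerate(score_table.fit_ids)}
    with open(tsv_path, "w") as fh:
        fh.write(cluster_summary(result, matrix, fit_index))
    return png_path, tsv_path
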