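"""Goodness-of-fit scores between a target density map and a fitted model.

Global scores compare two maps on a common grid (the probe map is simulated
from the fitted model by Gaussian blurring): cross-correlation (CCC) and its
Laplacian-filtered variant (LAP), mutual information (MI), the envelope
score (ENV), the surface normal-vector score with and without Sobel edge
detection (NV, NV-S), and the Chamfer surface distance (CD).  Segment-based
variants (SCCC, SMI) restrict CCC/MI to the map region occupied by one
structural segment, which localizes fit quality to domains or
secondary-structure elements.

Score polarity: CCC/LAP/MI/ENV/SCCC/SMI are higher-better; NV/NV-S/CD are
lower-better (0 is a perfect surface match).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .blurrer import DEFAULT_SIGMA_FACTOR, simulate_on_grid
from .map_core import (
    DensityMap,
    extract_surface,
    laplacian_filter,
    volume_threshold,
)
from .structure_core import (
    AtomicStructure,
    FitTransform,
    SegmentSelection,
    apply_transform,
)

logger = logging.getLogger(__name__)

#: Å³ of molecular volume per Dalton (protein partial specific volume),
#: used to derive envelope thresholds from a structure's mass.
VOLUME_PER_DALTON = 1.21

#: Default number of intensity bins for mutual information.
DEFAULT_MI_BINS = 20

HIGHER_BETTER = frozenset({"CCC", "LAP", "MI", "ENV", "SCCC", "SMI"})
LOWER_BETTER = frozenset({"NV", "NV-S", "CD"})
GLOBAL_SCORES = ("CCC", "LAP", "MI", "ENV", "NV", "NV-S", "CD")

_ALIASES = {
    "ccc": "CCC", "lap": "LAP", "mi": "MI", "env": "ENV",
    "nv": "NV", "nv-s": "NV-S", "nv_s": "NV-S", "nvs": "NV-S",
    "cd": "CD", "sccc": "SCCC", "smi": "SMI",
}


def canonical_score_name(name: str) -> str:
    key = name.strip()
    canon = _ALIASES.get(key.lower(), key.upper())
    if canon not in HIGHER_BETTER | LOWER_BETTER:
        raise ValueError(
            f"unknown score {name!r}; supported: {sorted(HIGHER_BETTER | LOWER_BETTER)}"
        )
    return canon


# -- score table ------------------------------------------------------------


@dataclass
class ScoreTable:
    """Per-fit values and ranks of one or more named scores.

    Rank 1 is the best fit under each score's polarity; ties receive
    average (fractional) ranks.
    """

    fit_ids: list[str]
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    ranks: dict[str, np.ndarray] = field(default_factory=dict)

    def add_score(self, name: str, values) -> None:
        name = canonical_score_name(name)
        values = np.asarray(values, dtype=float)
        if len(values) != len(self.fit_ids):
            raise ValueError("one value per fit required")
        self.scores[name] = values
        signed = -values if name in HIGHER_BETTER else values
        self.ranks[name] = rankdata(signed, method="average")

    def rank_of(self, name: str, fit_id: str) -> float:
        name = canonical_score_name(name)
        return float(self.ranks[name][self.fit_ids.index(fit_id)])

    def best_fit(self, name: str) -> str:
        name = canonical_score_name(name)
        return self.fit_ids[int(np.argmin(self.ranks[name]))]

    def top_fits(self, name: str, k: int) -> list[str]:
        """The k best fit ids under a score, best first (ties by fit order)."""
        name = canonical_score_name(name)
        order = np.argsort(self.ranks[name], kind="stable")
        return [self.fit_ids[i] for i in order[:k]]

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, object] = {"fit_id": self.fit_ids}
        for name, vals in self.scores.items():
            data[name] = vals
        for name in self.scores:
            data[f"rank_{name}"] = self.ranks[name]
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", dtype={"fit_id": str})
        table = cls(fit_ids=list(df["fit_id"]))
        for col in df.columns:
            if col == "fit_id" or col.startswith(("rank_", "borda")):
                continue
            table.add_score(col, df[col].to_numpy())
        return table

    def __len__(self) -> int:
        return len(self.fit_ids)


# -- map-vs-map scores ------------------------------------------------------


def _check_common_grid(probe: DensityMap, target: DensityMap) -> None:
    if probe.shape != target.shape:
        raise ValueError(
            f"maps must share a grid (shapes {probe.shape} vs {target.shape}); "
            "resample first"
        )


def ccc(probe: DensityMap, target: DensityMap, mask: np.ndarray | None = None) -> float:
    """Cross-correlation coefficient of voxel intensities, in [-1, 1].

    Pearson correlation over all voxels of the shared grid (or over
    ``mask``): sum of products of mean-centred intensities, normalized by
    the two standard deviations.
    """
    _check_common_grid(probe, target)
    p = np.asarray(probe.grid, dtype=float)
    t = np.asarray(target.grid, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != p.shape:
            raise ValueError("mask must match the grid shape")
        if not mask.any():
            raise ValueError("empty mask")
        p, t = p[mask], t[mask]
    p = p - p.mean()
    t = t - t.mean()
    denom = np.sqrt((p * p).sum() * (t * t).sum())
    if denom == 0.0:
        raise ValueError("undefined CCC: zero intensity variance over the evaluated voxels")
    return float(np.clip((p * t).sum() / denom, -1.0, 1.0))


def lap_ccc(probe: DensityMap, target: DensityMap) -> float:
    """CCC of the Laplacian-filtered maps (edge-weighted correlation)."""
    return ccc(laplacian_filter(probe), laplacian_filter(target))


@dataclass
class JointHistogram:
    """Joint intensity distribution of two maps on a shared grid."""

    bins: int
    edges_x: np.ndarray
    edges_y: np.ndarray
    joint: np.ndarray
    marginal_x: np.ndarray
    marginal_y: np.ndarray


def joint_histogram(
    probe: DensityMap,
    target: DensityMap,
    bins: int = DEFAULT_MI_BINS,
    mask: np.ndarray | None = None,
) -> JointHistogram:
    """Equal-width joint histogram over each map's own intensity range."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    _check_common_grid(probe, target)
    x = np.asarray(probe.grid, dtype=float).ravel()
    y = np.asarray(target.grid, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if not m.any():
            raise ValueError("empty mask")
        x, y = x[m], y[m]

    def _range(v):
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:  # constant map: single occupied bin
            hi = lo + 1.0
        return lo, hi

    counts, ex, ey = np.histogram2d(x, y, bins=bins, range=[_range(x), _range(y)])
    joint = counts / counts.sum()
    return JointHistogram(
        bins=bins,
        edges_x=ex,
        edges_y=ey,
        joint=joint,
        marginal_x=joint.sum(axis=1),
        marginal_y=joint.sum(axis=0),
    )


def mutual_information(
    probe: DensityMap,
    target: DensityMap,
    bins: int = DEFAULT_MI_BINS,
    mask: np.ndarray | None = None,
) -> float:
    """Mutual information in bits between binned probe and target intensities.

    MI = sum over occupied histogram cells of p(x,y) log2[p(x,y)/(p(x)p(y))];
    always >= 0, and equal to the binned entropy when probe == target.
    """
    h = joint_histogram(probe, target, bins=bins, mask=mask)
    pj = h.joint
    occupied = pj > 0
    px = h.marginal_x[:, None]
    py = h.marginal_y[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj[occupied] * np.log2(pj[occupied] / (px * py)[occupied])
    return float(max(terms.sum(), 0.0))


# -- envelope score ---------------------------------------------------------


def envelope_score(
    model: AtomicStructure,
    target: DensityMap,
    threshold: float,
    weights: tuple[int, int, int] = (1, -2, -1),
) -> int:
    """Integer occupancy score of a model inside the map envelope.

    The target is binarized at ``threshold``.  Each atom contributes
    ``weights[0]`` (+1) when its voxel is inside the envelope and
    ``weights[1]`` (-2, a protrusion penalty) when below threshold or
    outside the grid.  Every envelope voxel with no atom within one voxel
    (3x3x3 neighbourhood) contributes ``weights[2]`` (-1, an empty-space
    penalty).  Larger values denote better fits.
    """
    inside_w, protrusion_w, empty_w = weights
    above = np.asarray(target.grid, dtype=float) >= threshold
    nz, ny, nx = target.shape
    score = 0
    occupied = np.zeros_like(above, dtype=bool)
    n_outside = 0
    for coord in model.coords:
        k, j, i = target.voxel_of(coord)
        if 0 <= k < nz and 0 <= j < ny and 0 <= i < nx:
            score += inside_w if above[k, j, i] else protrusion_w
            occupied[k, j, i] = True
        else:
            n_outside += 1
            score += protrusion_w
    if n_outside:
        logger.warning(
            "%d atom(s) of %r fall outside the map grid; counted as protrusions",
            n_outside, model.label,
        )
    near_atom = ndimage.binary_dilation(occupied, structure=np.ones((3, 3, 3), bool))
    score += empty_w * int(np.count_nonzero(above & ~near_atom))
    return int(score)


# -- surface scores ---------------------------------------------------------


def normal_vector_score(
    probe: DensityMap,
    target: DensityMap,
    threshold_t: float,
    threshold_p: float,
    use_sobel: bool = False,
) -> float:
    """Mean angle (radians, in [0, pi]) between target and probe surface normals.

    For each surface voxel of the target envelope, the probe normal is taken
    at the nearest probe surface voxel; the score is the mean arccos of the
    normal dot products.  0 means the two surfaces are locally parallel
    everywhere (best); pi means everywhere opposed.  With ``use_sobel`` the
    normals derive from Sobel-filtered gradients masked above the threshold.
    """
    _check_common_grid(probe, target)
    surf_t = extract_surface(target, threshold_t, use_sobel=use_sobel)
    surf_p = extract_surface(probe, threshold_p, use_sobel=use_sobel)
    probe_coords = surf_p.coordinates()
    tree = cKDTree(probe_coords)
    target_coords = surf_t.coordinates()
    dists, nearest = tree.query(target_coords, k=1)
    # ties at equal distance resolve to the lowest probe point index
    for m, (p, d) in enumerate(zip(target_coords, dists)):
        candidates = tree.query_ball_point(p, r=d * (1.0 + 1e-9) + 1e-12)
        nearest[m] = min(candidates)
    dots = np.einsum("ij,ij->i", surf_t.normals, surf_p.normals[nearest])
    angles = np.arccos(np.clip(dots, -1.0, 1.0))
    return float(angles.mean())


def chamfer_distance(
    probe: DensityMap,
    target: DensityMap,
    threshold_t: float,
    threshold_p: float,
) -> float:
    """Mean distance (Å) from each probe surface point to the nearest
    target surface point.

    0 when every probe surface voxel lies on a target surface voxel; not
    symmetric in its arguments.
    """
    _check_common_grid(probe, target)
    x = extract_surface(probe, threshold_p, with_normals=False).coordinates()
    y = extract_surface(target, threshold_t, with_normals=False).coordinates()
    dists, _ = cKDTree(y).query(x, k=1)
    return float(dists.mean())


# -- segment-based scores ---------------------------------------------------


def segment_mask(
    model: AtomicStructure,
    segment: SegmentSelection,
    target: DensityMap,
    resolution: float,
    sigma_factor: float = DEFAULT_SIGMA_FACTOR,
) -> np.ndarray:
    """Boolean voxel mask of the map region occupied by one segment.

    The segment is blurred alone at the working resolution and thresholded
    at its own volume-based cutoff (1.21 Å³ per Dalton of segment mass).
    """
    seg = model.select(segment)
    seg_map = simulate_on_grid(seg, resolution, target, sigma_factor=sigma_factor)
    thr = volume_threshold(seg_map, VOLUME_PER_DALTON * seg.total_mass)
    mask = seg_map.grid >= thr
    if not mask.any():
        raise ValueError(f"segment {segment.label!r} produced an empty mask")
    return mask


def sccc(
    model: AtomicStructure,
    segment: SegmentSelection,
    target: DensityMap,
    resolution: float,
    sigma_factor: float = DEFAULT_SIGMA_FACTOR,
) -> float:
    """Segment-based CCC: whole-model probe map correlated with the target
    over the segment's own envelope only."""
    probe = simulate_on_grid(model, resolution, target, sigma_factor=sigma_factor)
    mask = segment_mask(model, segment, target, resolution, sigma_factor)
    return ccc(probe, target, mask=mask)


def smi(
    model: AtomicStructure,
    segment: SegmentSelection,
    target: DensityMap,
    resolution: float,
    bins: int = DEFAULT_MI_BINS,
    sigma_factor: float = DEFAULT_SIGMA_FACTOR,
) -> float:
    """Segment-based mutual information over the segment's envelope."""
    probe = simulate_on_grid(model, resolution, target, sigma_factor=sigma_factor)
    mask = segment_mask(model, segment, target, resolution, sigma_factor)
    return mutual_information(probe, target, bins=bins, mask=mask)


# -- ensemble scoring -------------------------------------------------------


def score_ensemble(
    fits: list[FitTransform],
    model: AtomicStructure,
    target: DensityMap,
    resolution: float,
    which: list[str],
    sigma_factor: float = DEFAULT_SIGMA_FACTOR,
    bins: int = DEFAULT_MI_BINS,
) -> ScoreTable:
    """Score every rigid fit of a model against a target map.

    For each fit the model is transformed, blurred onto the target grid and
    evaluated with each requested global score.  The target-side envelope
    threshold (from the model's molecular volume) and filtered/surface
    representations are computed once, so all fits are compared on equal
    footing.  Ranks follow each score's polarity.
    """
    if not which:
        raise ValueError("at least one score name is required")
    names = [canonical_score_name(n) for n in which]
    for n in names:
        if n not in GLOBAL_SCORES:
            raise ValueError(
                f"{n} is segment-based; use sccc()/smi() with a segment selection"
            )

    target_thr = volume_threshold(target, VOLUME_PER_DALTON * model.total_mass)
    lap_target = laplacian_filter(target) if "LAP" in names else None

    values: dict[str, list[float]] = {n: [] for n in names}
    for fit in fits:
        moved = apply_transform(model, fit)
        probe = simulate_on_grid(moved, resolution, target, sigma_factor=sigma_factor)
        probe_thr = None
        if {"NV", "NV-S", "CD"} & set(names):
            probe_thr = volume_threshold(probe, VOLUME_PER_DALTON * model.total_mass)
        for n in names:
            if n == "CCC":
                v = ccc(probe, target)
            elif n == "LAP":
                v = ccc(laplacian_filter(probe), lap_target)
            elif n == "MI":
                v = mutual_information(probe, target, bins=bins)
            elif n == "ENV":
                v = envelope_score(moved, target, target_thr)
            elif n == "NV":
                v = normal_vector_score(probe, target, target_thr, probe_thr, use_sobel=False)
            elif n == "NV-S":
                v = normal_vector_score(probe, target, target_thr, probe_thr, use_sobel=True)
            elif n == "CD":
                v = chamfer_distance(probe, target, target_thr, probe_thr)
            values[n].append(v)

    table = ScoreTable(fit_ids=[f.fit_id for f in fits])
    for n in names:
        table.add_score(n, values[n])
    return table
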