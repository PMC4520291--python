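"""Synthetic structures and simulated benchmark cases.

Every pipeline stage is testable without downloading coordinates or maps:
poly-alanine toy structures (an ideal alpha-helix, or two helical domains
on a hinge) stand in for crystal structures, and a map simulated from the
toy model plus a bounded random local ensemble recapitulates the
self-fit-recovery study design at desk scale.
"""

from __future__ import annotations

import numpy as np

from .blurrer import MAX_APIX, simulate_map
from .ensemble import generate_local_ensemble
from .map_core import DensityMap
from .structure_core import AtomRecord, AtomicStructure, FitTransform

_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Å, C-alpha helix radius

_MASS = {"N": 14.007, "C": 12.011, "O": 15.999}


def _helix_calphas(n_residues: int, start_index: int = 0) -> np.ndarray:
    i = np.arange(start_index, start_index + n_residues)
    theta = np.deg2rad(_HELIX_TWIST * i)
    return np.stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i],
        axis=1,
    )


def _backbone_from_calphas(ca: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Five heavy atoms per residue placed around each C-alpha.

    Backbone N/C sit along the chain direction, O on the carbonyl carbon
    and C-beta radially outward — plausible bond lengths, not refined
    stereochemistry; sufficient for blurring and mass bookkeeping.
    """
    n_res = len(ca)
    atoms = []
    axis_xy = ca.copy()
    axis_xy[:, 2] = 0.0
    for i in range(n_res):
        prev_dir = ca[i - 1] - ca[i] if i > 0 else ca[i] - ca[i + 1]
        next_dir = ca[i + 1] - ca[i] if i < n_res - 1 else ca[i] - ca[i - 1]
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        radial = axis_xy[i]
        nrm = np.linalg.norm(radial)
        radial = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        n_at = ca[i] + 1.46 * prev_dir
        c_at = ca[i] + 1.52 * next_dir
        o_at = c_at + 1.23 * radial
        cb_at = ca[i] + 1.53 * radial
        atoms.append(("N", "N", n_at))
        atoms.append(("CA", "C", ca[i]))
        atoms.append(("C", "C", c_at))
        atoms.append(("O", "O", o_at))
        atoms.append(("CB", "C", cb_at))
    return atoms


def _build_structure(ca: np.ndarray, label: str) -> AtomicStructure:
    records = []
    serial = 0
    placed = _backbone_from_calphas(ca)
    for res_i in range(len(ca)):
        for name, element, coord in placed[res_i * 5 : res_i * 5 + 5]:
            serial += 1
            records.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    res_name="ALA",
                    chain="A",
                    res_seq=res_i + 1,
                    coord=tuple(coord),
                    mass=_MASS[element],
                )
            )
    return AtomicStructure(atoms=records, label=label)


def make_toy_structure(
    n_residues: int,
    motif: str = "helix",
    seed: int = 0,
    hinge_angle: float | None = None,
) -> AtomicStructure:
    """Poly-alanine toy structure with 5 heavy atoms per residue.

    ``motif="helix"``: one ideal alpha-helix (rise 1.5 Å, 100 degrees per
    residue).  ``motif="two-domain"``: two helical domains joined at the
    midpoint with an inter-domain hinge rotation; the hinge angle is
    ``hinge_angle`` degrees if given, otherwise drawn uniformly from
    [10, 50) degrees under ``seed``.
    """
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    if motif == "helix":
        ca = _helix_calphas(n_residues)
    elif motif == "two-domain":
        ca = _helix_calphas(n_residues)
        half = n_residues // 2
        if hinge_angle is None:
            hinge_angle = float(np.random.default_rng(seed).uniform(10.0, 50.0))
        angle = np.deg2rad(hinge_angle)
        # rotate the second domain about the x axis through the junction Ca
        pivot = ca[half]
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        ca[half:] = (ca[half:] - pivot) @ rot.T + pivot
    else:
        raise ValueError(f"unknown motif {motif!r}")
    return _build_structure(ca, label=f"toy-{motif}-{n_residues}")


def make_benchmark_case(
    resolution: float,
    n_fits: int,
    seed: int,
    n_residues: int = 40,
    max_trans: float = 10.0,
    max_rot: float = 60.0,
) -> tuple[DensityMap, AtomicStructure, list[FitTransform]]:
    """Self-fit recovery benchmark: a simulated target map plus a local
    random ensemble around the generating placement.

    The target map is blurred from a toy helix at the requested resolution
    (sigma factor 0.225, grid spacing capped at 3.5 Å); the ensemble holds
    ``n_fits`` bounded perturbations plus the identity "model 0".
    """
    if not (3.0 <= resolution <= 30.0):
        raise ValueError("resolution must be within [3, 30] Å")
    model = make_toy_structure(n_residues, "helix", seed=seed)
    apix = min(MAX_APIX, resolution / 3.0)
    target = simulate_map(model, resolution, apix=apix)
    fits = generate_local_ensemble(
        model, n_fits, max_trans=max_trans, max_rot=max_rot, seed=seed
    )
    return target, model, fits
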