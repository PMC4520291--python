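"""Atomic-structure model, PDB I/O, rigid transforms, Cα-RMSD and segments.

Structures are flat, ordered lists of atom records — enough to place a model
in a map, blur it into a density, and compare alternative placements.  No
bond perception, hierarchy or sequence handling is attempted.

Cα-RMSD here is computed *without* superposition: alternative fits live in
the same map coordinate frame, so the raw deviation is exactly the quantity
that distinguishes placements.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np


class StructureFormatError(ValueError):
    """Raised when a coordinate or segment file cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    chain: str
    res_seq: int
    coord: tuple[float, float, float]
    mass: float
    icode: str = ""
    het: bool = False

    def __post_init__(self):
        if not all(np.isfinite(self.coord)):
            raise ValueError("atom coordinates must be finite")
        if not self.mass > 0:
            raise ValueError("atom mass must be positive")


@dataclass
class AtomicStructure:
    """Ordered collection of atoms with cached coordinate/mass arrays."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) coordinates in Å."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "AtomicStructure":
        coords = np.asarray(coords, dtype=float)
        atoms = [
            replace(a, coord=tuple(c)) for a, c in zip(self.atoms, coords)
        ]
        return AtomicStructure(atoms=atoms, label=self.label if label is None else label)

    def calpha_index(self) -> dict[tuple[str, str], int]:
        """Map (chain, residue key) -> atom index for Cα atoms."""
        out: dict[tuple[str, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.name.strip() == "CA" and not a.het:
                out[(a.chain, f"{a.res_seq}{a.icode}")] = i
        return out

    def select(self, selection: "SegmentSelection") -> "AtomicStructure":
        """Atoms whose (chain, res_seq) falls in any of the selection's ranges."""
        picked = [
            a
            for a in self.atoms
            if any(
                a.chain == ch and lo <= a.res_seq <= hi
                for ch, lo, hi in selection.ranges
            )
        ]
        if not picked:
            raise ValueError(
                f"segment {selection.label!r} matches no residue of {self.label!r}"
            )
        return AtomicStructure(atoms=picked, label=selection.label)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class SegmentSelection:
    """Inclusive residue ranges, e.g. a rigid body or secondary-structure element."""

    ranges: tuple[tuple[str, int, int], ...]
    label: str = ""

    def __post_init__(self):
        for ch, lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(
                    f"segment {self.label!r}: range {ch}:{lo}-{hi} has start > end"
                )


@dataclass(frozen=True)
class FitTransform:
    """A rigid placement: rotate about ``pivot``, then translate."""

    rotation: np.ndarray
    translation: np.ndarray
    pivot: np.ndarray
    fit_id: str

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        object.__setattr__(self, "pivot", np.asarray(self.pivot, dtype=float).reshape(3))
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls, pivot=(0.0, 0.0, 0.0), fit_id: str = "model_0") -> "FitTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(pivot, dtype=float), fit_id)

    def inverse(self, fit_id: str | None = None) -> "FitTransform":
        Rinv = self.rotation.T
        return FitTransform(
            rotation=Rinv,
            translation=-(Rinv @ self.translation),
            pivot=self.pivot,
            fit_id=fit_id or f"{self.fit_id}_inv",
        )


# -- PDB I/O ---------------------------------------------------------------

_CARBON_MASS = gemmi.Element("C").weight


def _atom_mass(element: str, atom_name: str) -> float:
    el = gemmi.Element(element) if element else None
    if el is not None and el.name not in ("X", "") and el.weight > 0:
        return float(el.weight)
    warnings.warn(
        f"unknown element for atom {atom_name!r}; assigning carbon mass",
        stacklevel=3,
    )
    return float(_CARBON_MASS)


def read_pdb(path: str | os.PathLike, skip_het: bool = False,
             model_index: int = 0) -> AtomicStructure:
    """Read a PDB (or mmCIF) file into an :class:`AtomicStructure`.

    Altlocs keep the highest-occupancy conformer (ties: first seen); waters
    and other heteroatoms are kept unless ``skip_het``.  ``model_index``
    selects a model from a multi-model file.
    """
    path = os.fspath(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")
    atoms = _model_to_atoms(st[model_index], skip_het=skip_het)
    if not atoms:
        raise StructureFormatError(f"{path}: no atoms selected")
    return AtomicStructure(atoms=atoms, label=os.path.basename(path))


def read_pdb_models(path: str | os.PathLike, skip_het: bool = False) -> list[AtomicStructure]:
    """All MODEL/ENDMDL members of a multi-model PDB file."""
    path = os.fspath(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    out = []
    for model in st:
        num = getattr(model, "num", None) or getattr(model, "name", "?")
        atoms = _model_to_atoms(model, skip_het=skip_het)
        if not atoms:
            raise StructureFormatError(f"{path}: model {num} has no atoms")
        out.append(
            AtomicStructure(atoms=atoms, label=f"{os.path.basename(path)}#{num}")
        )
    if not out:
        raise StructureFormatError(f"{path}: no models found")
    return out


def _model_to_atoms(model: gemmi.Model, skip_het: bool) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            if skip_het and het:
                continue
            # altloc resolution: highest occupancy wins, first seen on ties
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res:  # preserve file order
                if best.get(at.name) is not at:
                    continue
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        res_name=res.name,
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        mass=_atom_mass(at.element.name, at.name),
                        het=het,
                    )
                )
    return atoms


def _format_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: 1-2 char element symbols right-justify to col 14."""
    name = name.strip()
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_pdb(structure: AtomicStructure, path: str | os.PathLike) -> None:
    """Write fixed-width ATOM/HETATM records (3-decimal coordinates)."""
    with open(os.fspath(path), "w") as fh:
        fh.write(_pdb_records(structure))
        fh.write("END\n")


def write_pdb_models(structures: list[AtomicStructure], path: str | os.PathLike) -> None:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB file."""
    with open(os.fspath(path), "w") as fh:
        for i, s in enumerate(structures, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            fh.write(_pdb_records(s))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _pdb_records(structure: AtomicStructure) -> str:
    lines = []
    for a in structure.atoms:
        if any(abs(c) >= 10000 for c in a.coord):
            raise ValueError(
                f"coordinate {a.coord} outside the PDB fixed-width range (|x| < 10000 Å)"
            )
        record = "HETATM" if a.het else "ATOM  "
        x, y, z = a.coord
        lines.append(
            f"{record}{a.serial % 100000:5d} {_format_atom_name(a.name, a.element)}"
            f" {a.res_name:<3s} {a.chain[:1]}{a.res_seq:4d}{a.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}\n"
        )
    return "".join(lines)


# -- segment files ----------------------------------------------------------


def read_segments(path: str | os.PathLike) -> list[SegmentSelection]:
    """Parse a rigid-body/segment text file, one selection per line.

    Grammar per line: ``label chain:start-end[,chain:start-end...]``.
    Blank lines and ``#`` comments are ignored.
    """
    selections = []
    with open(os.fspath(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                label, spec = line.split(None, 1)
                ranges = []
                for token in spec.replace(" ", "").split(","):
                    chain, span = token.split(":")
                    lo_s, _, hi_s = span.partition("-")
                    lo, hi = int(lo_s), int(hi_s or lo_s)
                    ranges.append((chain, lo, hi))
                selections.append(SegmentSelection(tuple(ranges), label=label))
            except (ValueError, TypeError) as exc:
                raise StructureFormatError(
                    f"{path}:{lineno}: cannot parse segment line {line!r} ({exc})"
                ) from exc
    if not selections:
        raise StructureFormatError(f"{path}: no segment definitions found")
    return selections


def write_segments(selections: list[SegmentSelection], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        for sel in selections:
            spec = ",".join(f"{ch}:{lo}-{hi}" for ch, lo, hi in sel.ranges)
            fh.write(f"{sel.label} {spec}\n")


# -- geometry ---------------------------------------------------------------


def apply_transform(structure: AtomicStructure, t: FitTransform) -> AtomicStructure:
    """Rigidly move a structure: ``x -> R (x - pivot) + pivot + translation``."""
    coords = structure.coords
    moved = (coords - t.pivot) @ t.rotation.T + t.pivot + t.translation
    return structure.with_coords(moved, label=t.fit_id or structure.label)


def calpha_rmsd(a: AtomicStructure, b: AtomicStructure) -> float:
    """Cα-RMSD in Å between two placements of the same molecule.

    Atoms are paired by (chain, residue); no superposition is performed,
    because fits are compared in the shared map frame.
    """
    ia, ib = a.calpha_index(), b.calpha_index()
    if not ia:
        raise ValueError(f"{a.label!r} has no C-alpha atoms")
    if set(ia) != set(ib):
        missing = sorted(set(ia).symmetric_difference(ib))[0]
        raise ValueError(
            f"C-alpha sets differ between {a.label!r} and {b.label!r}; "
            f"first mismatch: chain {missing[0]!r} residue {missing[1]}"
        )
    keys = sorted(ia)
    ca, cb = a.coords, b.coords
    da = ca[[ia[k] for k in keys]]
    db = cb[[ib[k] for k in keys]]
    return float(np.sqrt(np.mean(np.sum((da - db) ** 2, axis=1))))


def center_of_mass(structure: AtomicStructure) -> np.ndarray:
    """Mass-weighted mean coordinate (x, y, z) in Å."""
    m = structure.masses
    return (structure.coords * m[:, None]).sum(axis=0) / m.sum()
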