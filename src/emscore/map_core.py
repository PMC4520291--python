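"""Density-map data model, CCP4/MRC I/O, thresholding, surfaces and filters.

A :class:`DensityMap` is a 3D scalar field on a regular cubic voxel grid.
The internal axis order is ``(z, y, x)`` regardless of how the file on disk
orders its sections/rows/columns; the MRC axis-correspondence words are
honoured on read and written canonically (MAPC, MAPR, MAPS = 1, 2, 3).

Coordinate convention: ``origin`` is the real-space position (x, y, z, in Å)
of the *center* of voxel ``(0, 0, 0)``; the center of voxel ``(k, j, i)``
(z, y, x indexing) is ``origin + apix * (i, j, k)``.  The voxel containing
an arbitrary point is found by rounding to the nearest voxel center.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage


class MapFormatError(ValueError):
    """Raised when a CCP4/MRC file cannot be interpreted."""


@dataclass
class DensityMap:
    """A 3D density grid with isotropic voxel spacing.

    Parameters
    ----------
    grid:
        3D array of intensities, indexed ``(z, y, x)``.
    apix:
        Voxel edge length in Å (isotropic).
    origin:
        Real-space (x, y, z) coordinate in Å of the center of voxel (0,0,0).
    label:
        Free-text description.
    """

    grid: np.ndarray
    apix: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3D with every axis of length >= 2")
        if not (self.apix > 0):
            raise ValueError("apix must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid intensities must be finite")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # (nz, ny, nx)

    def voxel_volume(self) -> float:
        return float(self.apix) ** 3

    def voxel_of(self, coord: np.ndarray) -> tuple[int, int, int]:
        """Nearest voxel index ``(k, j, i)`` for a real-space (x,y,z) point.

        The index may lie outside the grid; callers decide how to treat that.
        """
        xyz = (np.asarray(coord, dtype=float) - self.origin) / self.apix
        i, j, k = np.rint(xyz).astype(int)
        return int(k), int(j), int(i)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Real-space (x,y,z) centers for an ``(n, 3)`` array of (k,j,i) indices."""
        idx = np.asarray(indices, dtype=float)
        return self.origin + self.apix * idx[:, ::-1]

    def copy(self, grid: np.ndarray | None = None, label: str | None = None) -> "DensityMap":
        return DensityMap(
            grid=self.grid.copy() if grid is None else grid,
            apix=self.apix,
            origin=self.origin.copy(),
            label=self.label if label is None else label,
        )


@dataclass
class SurfacePointSet:
    """Surface voxels of a thresholded envelope with outward unit normals.

    ``points`` are ``(k, j, i)`` voxel indices; ``normals`` are unit 3-vectors
    in (x, y, z) order pointing down the density gradient (outward).
    """

    points: np.ndarray
    normals: np.ndarray
    threshold: float
    apix: float
    origin: np.ndarray

    def coordinates(self) -> np.ndarray:
        """Real-space (x,y,z) coordinates of the surface voxel centers."""
        pts = np.asarray(self.points, dtype=float)
        return self.origin + self.apix * pts[:, ::-1]

    def __len__(self) -> int:
        return len(self.points)


# -- CCP4/MRC I/O -----------------------------------------------------------

_ISOTROPY_RTOL = 1e-3


def read_mrc(path: str | os.PathLike) -> DensityMap:
    """Read a CCP4/MRC map (modes 0/1/2) into internal (z, y, x) order.

    Axis-correspondence header words (MAPC/MAPR/MAPS) are honoured: the
    returned grid always has z as the slowest axis, whatever the file's
    section order.  The origin is taken from the ORIGIN header words or,
    when those are all zero, from NxSTART * apix.
    """
    path = os.fspath(path)
    if os.path.getsize(path) < 1024:
        raise MapFormatError(
            f"{path}: file shorter than the 1024-byte CCP4/MRC header"
        )
    try:
        m = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    try:
        m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except RuntimeError as exc:
        raise MapFormatError(f"{path}: bad MAPC/MAPR/MAPS words ({exc})") from exc

    nstart = [m.header_i32(i) for i in (5, 6, 7)]  # pre-setup values consumed below
    arr = np.array(m.grid, copy=True)  # (nx, ny, nz) after reordering
    if not np.all(np.isfinite(arr)):
        raise MapFormatError(f"{path}: map contains non-finite intensities")
    grid = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)

    cell = m.grid.unit_cell
    nx, ny, nz = arr.shape
    spacings = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if not np.allclose(spacings, spacings[0], rtol=_ISOTROPY_RTOL):
        raise MapFormatError(
            f"{path}: anisotropic voxels {spacings} Å are not supported"
        )
    apix = float(spacings.mean())

    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if np.all(origin == 0.0) and any(nstart):
        origin = apix * np.array(nstart, dtype=float)
    return DensityMap(grid=grid, apix=apix, origin=origin, label=os.path.basename(path))


def write_mrc(density_map: DensityMap, path: str | os.PathLike) -> None:
    """Write a mode-2 (32-bit float) CCP4/MRC 2014 file, canonical axis order."""
    path = os.fspath(path)
    data_xyz = np.ascontiguousarray(
        density_map.grid.transpose(2, 1, 0).astype(np.float32)
    )
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data_xyz)
    nz, ny, nx = density_map.shape
    a = density_map.apix
    m.grid.set_unit_cell(gemmi.UnitCell(nx * a, ny * a, nz * a, 90, 90, 90))
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), density_map.origin):
        m.set_header_float(word, float(value))
    try:
        m.write_ccp4_map(path)
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map to {path}: {exc}") from exc


# -- thresholding and surfaces ----------------------------------------------


def volume_threshold(density_map: DensityMap, target_volume: float) -> float:
    """Density cutoff enclosing at least ``target_volume`` Å³.

    Returns the largest density value ``t`` such that the voxels with density
    ``>= t`` occupy at least ``target_volume``.  Used to define the molecular
    envelope from an expected molecular volume (e.g. 1.21 Å³ per Dalton).
    """
    total = density_map.grid.size * density_map.voxel_volume()
    if not (0 < target_volume <= total):
        raise ValueError(
            f"target_volume must be in (0, {total:.6g}] Å³, got {target_volume!r}"
        )
    n_needed = int(math.ceil(target_volume / density_map.voxel_volume()))
    flat = np.sort(density_map.grid, axis=None)  # ascending
    return float(flat[-n_needed])


def extract_surface(density_map: DensityMap, threshold: float,
                    use_sobel: bool = False,
                    with_normals: bool = True) -> SurfacePointSet:
    """Surface voxels of the envelope at ``threshold`` with outward normals.

    A voxel belongs to the surface when its density is >= threshold and at
    least one of its 6 face-neighbours is below threshold (voxels outside
    the grid count as below).  Normals point down the density gradient
    (outward from the envelope): by default the gradient is a central
    difference; with ``use_sobel`` it comes from the Sobel responses masked
    above the threshold.  Surface voxels with zero gradient are dropped —
    only when normals are requested; with ``with_normals=False`` the full
    point set is kept and ``normals`` is empty (pure point-set consumers
    such as the Chamfer distance use this).
    """
    grid = np.asarray(density_map.grid, dtype=float)
    above = grid >= threshold
    if not above.any():
        raise ValueError("no voxels above threshold")

    # Face-neighbour erosion with out-of-grid treated as below threshold.
    interior = ndimage.binary_erosion(above, structure=_FACE_STRUCT, border_value=0)
    surface = above & ~interior
    points = np.argwhere(surface)

    if not with_normals:
        return SurfacePointSet(
            points=points,
            normals=np.empty((0, 3)),
            threshold=float(threshold),
            apix=density_map.apix,
            origin=density_map.origin.copy(),
        )

    if use_sobel:
        masked = np.where(above, grid, 0.0)
        grads = [ndimage.sobel(masked, axis=ax, mode="reflect") for ax in range(3)]
    else:
        grads = np.gradient(grid)  # central differences, one-sided at edges
    # grads are d/dz, d/dy, d/dx on (z,y,x); normals stored (x,y,z).
    gvec = np.stack(
        [g[surface] for g in grads[::-1]], axis=1
    )
    normals = -gvec
    norms = np.linalg.norm(normals, axis=1)
    keep = norms > 0
    points, normals, norms = points[keep], normals[keep], norms[keep]
    if len(points) == 0:
        raise ValueError("no surface voxels with a defined normal")
    normals /= norms[:, None]
    return SurfacePointSet(
        points=points,
        normals=normals,
        threshold=float(threshold),
        apix=density_map.apix,
        origin=density_map.origin.copy(),
    )


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


# -- filters ----------------------------------------------------------------


def sobel_filter(density_map: DensityMap, mask_above: float | None = None) -> DensityMap:
    """Gradient-magnitude map from separable 3D Sobel kernels.

    Per axis the kernel is the differentiation stencil [1, 0, -1] combined
    with smoothing [1, 2, 1] along the two other axes; the three responses
    are combined as the Euclidean magnitude.  Reflective padding at the
    edges.  With ``mask_above``, the output is zeroed wherever the *input*
    is below that density (edge detection restricted to the envelope).
    """
    grid = np.asarray(density_map.grid, dtype=float)
    responses = [ndimage.sobel(grid, axis=ax, mode="reflect") for ax in range(3)]
    mag = np.sqrt(sum(r * r for r in responses))
    if mask_above is not None:
        mag[grid < mask_above] = 0.0
    return density_map.copy(grid=mag, label=f"sobel({density_map.label})")


def laplacian_filter(density_map: DensityMap) -> DensityMap:
    """Discrete 6-neighbour Laplacian (reflective padding at the edges)."""
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 1] = -6.0
    for off in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
        kernel[off] = 1.0
    out = ndimage.correlate(
        np.asarray(density_map.grid, dtype=float), kernel, mode="reflect"
    )
    return density_map.copy(grid=out, label=f"laplacian({density_map.label})")
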