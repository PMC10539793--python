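"""Localisation-space grid engine.

Evaluates the PCS RMSD field on a regular cubic grid, integrates the
localisation volume V_RMSD (the total volume of grid points whose RMSD falls
strictly below a threshold), adapts thresholds to a target volume, and counts
disconnected solution regions.

Conventions: the grid is a cube of a given volume (ų) centred on a point of
interest, with a point density in points/Å; each grid point carries a volume
ΔV = spacing³.  The sub-threshold mask uses a strict ``<`` so a threshold of
zero always yields an empty localisation space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tensor import ChiTensor, pcs_basis

__all__ = [
    "Grid",
    "LocalisationSpace",
    "build_grid",
    "rmsd_field",
    "rmsd_volume",
    "threshold_for_volume",
    "connected_components",
    "export_space",
]

# grid points per evaluation chunk; bounds transient memory for large grids
_CHUNK = 200_000


@dataclass(frozen=True)
class Grid:
    """Regular cubic grid: cube of ``volume`` ų centred at ``center``."""

    center: np.ndarray
    points_per_angstrom: float
    volume: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if self.volume <= 0 or self.points_per_angstrom <= 0:
            raise ValueError("grid volume and point density must be positive")

    @property
    def side(self) -> float:
        return float(self.volume ** (1.0 / 3.0))

    @property
    def n(self) -> int:
        """Points per axis: round(side × density)."""
        return int(round(self.side * self.points_per_angstrom))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n, self.n, self.n)

    @property
    def n_points(self) -> int:
        return self.n**3

    @property
    def spacing(self) -> float:
        return 1.0 / self.points_per_angstrom

    @property
    def dv(self) -> float:
        """ΔV, the volume occupied by a single grid point (ų)."""
        return self.spacing**3

    @property
    def origin(self) -> np.ndarray:
        """Coordinates of grid index (0, 0, 0)."""
        return self.center - (self.n - 1) / 2.0 * self.spacing

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinate vectors (x, y, z)."""
        idx = np.arange(self.n)
        return tuple(self.origin[k] + idx * self.spacing for k in range(3))

    def points(self) -> np.ndarray:
        """All grid points as an (n³, 3) array, z fastest (C order of (i,j,k))."""
        ax, ay, az = self.axes()
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def build_grid(volume: float, density: float, center=(0.0, 0.0, 0.0)) -> Grid:
    """Cubic grid of ``volume`` ų at ``density`` points/Å centred at ``center``."""
    return Grid(center=center, points_per_angstrom=density, volume=volume)


@dataclass(frozen=True)
class LocalisationSpace:
    """δRMSD field with a threshold, its sub-threshold mask and volume."""

    grid: Grid
    rmsd_field: np.ndarray  # ppm, shape grid.shape
    threshold: float  # ppm
    mask: np.ndarray  # bool, rmsd_field < threshold
    volume: float  # ų
    boundary_truncated: bool

    @property
    def n_points(self) -> int:
        return int(self.mask.sum())


def _check_inputs(tensors, observed):
    observed = np.asarray(observed, dtype=float)
    if len(tensors) == 0 or observed.size != len(tensors):
        raise ValueError("need one observation per tensor, at least one tensor")
    return observed


def rmsd_field(tensors: list[ChiTensor], observed, grid: Grid) -> np.ndarray:
    """δRMSD (ppm) at every grid point, shape ``grid.shape``.

    A grid point coinciding with a metal position is set to +inf so it can
    never enter a localisation space.
    """
    observed = _check_inputs(tensors, observed)
    pts = grid.points()
    ssq = np.zeros(len(pts))
    for start in range(0, len(pts), _CHUNK):
        sl = slice(start, min(start + _CHUNK, len(pts)))
        acc = np.zeros(sl.stop - sl.start)
        for t, obs in zip(tensors, observed):
            calc = pcs_basis(t.position, pts[sl]) @ t.comps
            acc += (obs - calc) ** 2
        ssq[sl] = acc
    field = np.sqrt(ssq / len(tensors))
    field[~np.isfinite(field)] = np.inf
    return field.reshape(grid.shape)


def rmsd_volume(
    tensors: list[ChiTensor], observed, grid: Grid, threshold: float, *, field=None
) -> LocalisationSpace:
    """Localisation space: grid points with δRMSD strictly below ``threshold``.

    ``field`` may carry a precomputed δRMSD field to avoid re-evaluation.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if field is None:
        field = rmsd_field(tensors, observed, grid)
    mask = field < threshold
    truncated = bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    return LocalisationSpace(
        grid=grid,
        rmsd_field=field,
        threshold=float(threshold),
        mask=mask,
        volume=float(mask.sum()) * grid.dv,
        boundary_truncated=truncated,
    )


def threshold_for_volume(
    tensors: list[ChiTensor], observed, grid: Grid, target_volume: float, *, field=None
) -> float:
    """Smallest threshold (ppm) whose localisation volume reaches ``target_volume``.

    The volume is a step function of the threshold, so the threshold is found
    by order statistics: with k = round(target/ΔV) points wanted, any value
    just above the k-th smallest field value yields a volume within ΔV of the
    target (exactly, barring ties in the field).
    """
    if not 0 < target_volume <= grid.volume:
        raise ValueError("target volume must be in (0, grid volume]")
    if field is None:
        field = rmsd_field(tensors, observed, grid)
    flat = field.ravel()
    k = max(1, int(round(target_volume / grid.dv)))
    finite = np.isfinite(flat)
    if k > finite.sum():
        raise ValueError("target volume unreachable: too few finite field values")
    kth = np.partition(flat, k - 1)[k - 1]
    return float(np.nextafter(kth, np.inf))


def connected_components(space: LocalisationSpace) -> tuple[int, np.ndarray]:
    """Count 26-connected components of the mask; volumes (ų) sorted descending."""
    labels, n = ndimage.label(space.mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return 0, np.array([])
    counts = np.bincount(labels.ravel())[1:]
    vols = np.sort(counts)[::-1] * space.grid.dv
    return int(n), vols


def export_space(space: LocalisationSpace, path, format: str = "pdb") -> None:
    """Write a localisation space to disk.

    ``format="pdb"``: pseudo-atoms at sub-threshold grid points, occupancy
    1 − δRMSD/threshold.  ``format="dx"``: OpenDX scalar map of the full field.
    """
    from . import io as _io

    if format == "pdb":
        pts = space.grid.points().reshape(*space.grid.shape, 3)[space.mask]
        vals = space.rmsd_field[space.mask]
        occ = 1.0 - vals / space.threshold if space.threshold > 0 else np.zeros(len(vals))
        _io.write_pseudoatom_pdb(path, pts, occ)
    elif format == "dx":
        _io.write_dx(path, space.grid, space.rmsd_field)
    else:
        raise ValueError(f"unknown export format: {format!r} (use 'pdb' or 'dx')")
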