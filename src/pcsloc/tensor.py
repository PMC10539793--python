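"""Magnetic susceptibility anisotropy (Δχ) tensors and pseudocontact shifts.

The pseudocontact shift (PCS) of a nuclear spin at position ``p`` caused by a
paramagnetic centre at position ``m`` with anisotropy tensor ``Δχ`` is

    δ = k / (4 π r⁵) · [x²−z², y²−z², 2xy, 2xz, 2yz] · (Δχxx, Δχyy, Δχxy, Δχxz, Δχyz)

with ``(x, y, z) = p − m`` and ``r = |p − m|``.  Because the tensor is traceless
the bracket contraction equals the full quadratic form ``rᵀ·Δχ·r``.

Unit convention (fixed throughout the package): coordinates in Å, Δχ in
10⁻³² m³ and PCS in ppm, which makes the prefactor ``k = 10⁴``.  This is the
convention common to paramagnetic-NMR fitting software; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ChiTensor",
    "DegeneratePositionError",
    "InvalidRotationError",
    "pcs",
    "pcs_gradient",
    "from_axial_rhombic",
    "rotate",
    "UNIT_PREFACTOR",
]

#: ppm · Å³ per 10⁻³² m³ — fixes the PCS formula's units (Å, 10⁻³² m³ → ppm).
UNIT_PREFACTOR = 1.0e4

#: Electron-nucleus distances below this (Å) are treated as degenerate.
R_MIN_DEFAULT = 1.0e-6


class DegeneratePositionError(ValueError):
    """Evaluation point coincides with the paramagnetic centre."""


class InvalidRotationError(ValueError):
    """Rotation input is not a proper orthonormal rotation."""


def _as_rotation_matrix(rotation) -> np.ndarray:
    """Coerce a scipy Rotation or 3×3 matrix into a validated proper rotation."""
    if isinstance(rotation, Rotation):
        return rotation.as_matrix()
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"rotation must be 3x3, got shape {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
        raise InvalidRotationError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise InvalidRotationError("rotation matrix has determinant -1 (improper)")
    return R


@dataclass(frozen=True)
class ChiTensor:
    """A Δχ tensor: metal position plus the 5 independent traceless components.

    Parameters
    ----------
    position
        Paramagnetic-centre coordinates, Å.
    comps
        ``(Δχxx, Δχyy, Δχxy, Δχxz, Δχyz)`` in 10⁻³² m³; ``Δχzz`` follows from
        tracelessness.
    """

    position: np.ndarray
    comps: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(self, "comps", np.asarray(self.comps, dtype=float).reshape(5))
        if not np.all(np.isfinite(self.position)) or not np.all(np.isfinite(self.comps)):
            raise ValueError("tensor position and components must be finite")

    @property
    def matrix(self) -> np.ndarray:
        """Full symmetric traceless 3×3 matrix, 10⁻³² m³."""
        xx, yy, xy, xz, yz = self.comps
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, -xx - yy]])

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, position) -> "ChiTensor":
        """Build from a symmetric traceless 3×3 matrix (validated)."""
        X = np.asarray(matrix, dtype=float)
        if X.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if not np.allclose(X, X.T, atol=1e-10 * max(1.0, np.abs(X).max())):
            raise ValueError("matrix must be symmetric")
        scale = max(1.0, np.abs(X).max())
        if abs(np.trace(X)) > 1e-10 * scale:
            raise ValueError("matrix must be traceless")
        return cls(position=position, comps=[X[0, 0], X[1, 1], X[0, 1], X[0, 2], X[1, 2]])

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (λx, λy, λz) and principal axes in the unique tensor
        representation, |λz| ≥ |λy| ≥ |λx|, axes right-handed.

        Returns ``(eigenvalues, R)`` with columns of ``R`` the x/y/z axes.
        """
        vals, vecs = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(vals))  # |λx| ≤ |λy| ≤ |λz|
        vals = vals[order]
        vecs = vecs[:, order]
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        return vals, vecs

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.eig()[0]

    @property
    def ax(self) -> float:
        """Axial anisotropy Δχax = λz − (λx + λy)/2 = 3λz/2."""
        lx, ly, lz = self.eig()[0]
        return float(lz - (lx + ly) / 2.0)

    @property
    def rh(self) -> float:
        """Rhombic anisotropy Δχrh = λx − λy."""
        lx, ly, _ = self.eig()[0]
        return float(lx - ly)


def _displacements(tensor: ChiTensor, points: np.ndarray, r_min: float):
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    d = pts - tensor.position
    r = np.linalg.norm(d, axis=1)
    if np.any(r < r_min):
        raise DegeneratePositionError(
            f"evaluation point within {r_min} Å of the paramagnetic centre"
        )
    return d, r, single


def pcs(tensor: ChiTensor, points, *, r_min: float = R_MIN_DEFAULT):
    """Pseudocontact shift (ppm) at one point or an (N, 3) array of points (Å)."""
    d, r, single = _displacements(tensor, points, r_min)
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    basis = np.stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z], axis=1)
    out = UNIT_PREFACTOR * (basis @ tensor.comps) / (4.0 * np.pi * r**5)
    return float(out[0]) if single else out


def pcs_basis(position: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Design matrix B with ``pcs = B @ comps`` for points (N, 3) around a metal.

    Rows for points coinciding with the metal position are set to NaN; callers
    decide how to treat the singularity.  This is the linear backbone shared by
    field evaluation and tensor fitting.
    """
    d = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(position, dtype=float)
    r = np.linalg.norm(d, axis=1)
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    B = np.stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        B = UNIT_PREFACTOR * B / (4.0 * np.pi * r[:, None] ** 5)
    B[r == 0.0] = np.nan
    return B


def pcs_gradient(tensor: ChiTensor, points, *, r_min: float = R_MIN_DEFAULT):
    """Analytic PCS gradient ∇δ (ppm/Å) at one point or an (N, 3) array.

    Two-term form: contraction ``2·Δχ·r / 4πr⁵`` minus the quadratic form times
    ``5·r / 4πr⁷``, scaled by the same unit prefactor as :func:`pcs`.  The
    direction is the local isosurface normal.
    """
    d, r, single = _displacements(tensor, points, r_min)
    X = tensor.matrix
    q = np.einsum("ni,ij,nj->n", d, X, d)  # rᵀ·Δχ·r
    term1 = 2.0 * (d @ X.T) / (4.0 * np.pi * r[:, None] ** 5)
    term2 = 5.0 * q[:, None] * d / (4.0 * np.pi * r[:, None] ** 7)
    out = UNIT_PREFACTOR * (term1 - term2)
    return out[0] if single else out


def from_axial_rhombic(ax: float, rh: float, rotation=None, position=(0.0, 0.0, 0.0)) -> ChiTensor:
    """Build a tensor from axial/rhombic anisotropy, orientation and position.

    Principal-frame eigenvalues are ``(−ax/3 + rh/2, −ax/3 − rh/2, 2·ax/3)``
    so that Δχax = λz − (λx+λy)/2 and Δχrh = λx − λy; the frame is rotated into
    the laboratory by ``rotation`` (scipy Rotation or 3×3 matrix; identity if
    None).  |rh| > (2/3)|ax| violates the unique-representation ordering and
    triggers a warning, not an error.
    """
    import warnings

    if abs(rh) > (2.0 / 3.0) * abs(ax) + 1e-15:
        warnings.warn(
            "|rh| > (2/3)|ax|: tensor is not in the unique representation; "
            "derived (ax, rh) of the result will differ",
            stacklevel=2,
        )
    R = np.eye(3) if rotation is None else _as_rotation_matrix(rotation)
    D = np.diag([-ax / 3.0 + rh / 2.0, -ax / 3.0 - rh / 2.0, 2.0 * ax / 3.0])
    return ChiTensor.from_matrix(R @ D @ R.T, position)


def rotate(tensor: ChiTensor, rotation) -> ChiTensor:
    """Rotate the tensor (R·Δχ·Rᵀ); the metal position is unchanged."""
    R = _as_rotation_matrix(rotation)
    return ChiTensor.from_matrix(R @ tensor.matrix @ R.T, tensor.position)


def pcs_polar(ax: float, rh: float, r: float, theta: float, phi: float) -> float:
    """Principal-frame closed form of the PCS (ppm) in polar coordinates.

    δ = k/(12πr³) · [Δχax (3cos²θ − 1) + (3/2) Δχrh sin²θ cos 2φ]; used as an
    independent cross-check of the matrix contraction.
    """
    return (
        UNIT_PREFACTOR
        / (12.0 * np.pi * r**3)
        * (ax * (3.0 * np.cos(theta) ** 2 - 1.0) + 1.5 * rh * np.sin(theta) ** 2 * np.cos(2.0 * phi))
    )
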