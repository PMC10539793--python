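"""Precision metrics for PCS localisation.

Given several Δχ tensors, how precisely can a spin at the site of interest be
localised?  Two single-number predictors are computed from the PCS gradient
vectors of the tensors evaluated at that site:

* the parallel metric δ∥ — mean absolute cosine between gradient directions
  over unordered tensor pairs, normalised by (n − 1); small when the
  isosurfaces intersect steeply,
* the perpendicular metric δ⟂ — matching sum of cross-product magnitudes,
  which keeps the gradient magnitudes and therefore also rewards proximity to
  the paramagnetic centre; large values predict tight localisation.

Also here: the per-point PCS RMSD (the scalar the grid engine integrates),
pairwise isosurface intersection angles, and the angle between tensor z axes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .tensor import ChiTensor, pcs

__all__ = [
    "pcs_rmsd",
    "parallel_metric",
    "perpendicular_metric",
    "intersection_angles",
    "z_axis_angle",
    "gradient_set",
]


def gradient_set(tensors: list[ChiTensor], point) -> np.ndarray:
    """PCS gradient of each tensor at one point, stacked (n, 3), ppm/Å."""
    from .tensor import pcs_gradient

    return np.stack([pcs_gradient(t, point) for t in tensors])


def pcs_rmsd(tensors: list[ChiTensor], observed, point) -> float:
    """RMSD (ppm) between measured PCSs and the values back-calculated at ``point``.

    sqrt( (1/n) Σᵢ (δexp,i − δcal,i)² ) over the n tensors.
    """
    observed = np.asarray(observed, dtype=float)
    if len(tensors) == 0:
        raise ValueError("at least one tensor is required")
    if len(tensors) != observed.size:
        raise ValueError(f"{len(tensors)} tensors but {observed.size} observations")
    calc = np.array([pcs(t, point) for t in tensors])
    return float(np.sqrt(np.mean((observed - calc) ** 2)))


def _vectors(g) -> np.ndarray:
    v = np.asarray(g, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise ValueError("need an (n, 3) array of gradient vectors with n >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("gradient vectors must be finite")
    return v


def parallel_metric(g) -> float:
    """δ∥ = 1/(n−1) · Σ_{i<j} |cos θij| over unordered pairs (unitless).

    Scale-invariant.  Zero requires mutually orthogonal gradients, which is
    only possible for n ≤ 3; lies in [0, 1] for n = 2.
    """
    v = _vectors(g)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-magnitude gradient vector has no direction")
    u = v / norms[:, None]
    n = len(v)
    total = sum(abs(float(u[i] @ u[j])) for i, j in combinations(range(n), 2))
    return total / (n - 1)


def perpendicular_metric(g) -> float:
    """δ⟂ = 1/(n−1) · Σ_{i<j} |vᵢ ∧ vⱼ| over unordered pairs, (ppm/Å)².

    Preserves gradient magnitudes; ≥ 0 with no upper bound.  Zero vectors are
    allowed and contribute nothing.
    """
    v = _vectors(g)
    n = len(v)
    total = sum(
        float(np.linalg.norm(np.cross(v[i], v[j]))) for i, j in combinations(range(n), 2)
    )
    return total / (n - 1)


def intersection_angles(g) -> np.ndarray:
    """Pairwise isosurface intersection angles, degrees in [0, 90].

    The angle between two isosurface normals folded by min(θ, 180° − θ); the
    pairs are ordered (0,1), (0,2), …, (n−2, n−1).  Shallow intersections give
    small angles.
    """
    v = _vectors(g)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-magnitude gradient vector has no direction")
    u = v / norms[:, None]
    n = len(v)
    cosines = [abs(np.clip(u[i] @ u[j], -1.0, 1.0)) for i, j in combinations(range(n), 2)]
    return np.degrees(np.arccos(cosines))


def z_axis_angle(a: ChiTensor, b: ChiTensor, *, degeneracy_rtol: float = 1e-8) -> float:
    """Angle (degrees, in [0, 90]) between the unique-representation z axes.

    Eigenvector signs are arbitrary, so the angle is folded into [0°, 90°].
    Raises if either tensor has |λz| not strictly largest (ambiguous frame).
    """
    angle_axes = []
    for t in (a, b):
        vals, vecs = t.eig()
        if abs(abs(vals[2]) - abs(vals[1])) <= degeneracy_rtol * max(abs(vals[2]), 1e-300):
            raise ValueError("degenerate eigenvalues: tensor z axis is ambiguous")
        angle_axes.append(vecs[:, 2])
    c = abs(np.clip(angle_axes[0] @ angle_axes[1], -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))
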