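"""Fit an effective Δχ tensor (metal position + 5 components) to measured PCSs.

The PCS is linear in the five tensor components at a fixed metal position, so
the eight-parameter least-squares problem is solved by variable projection:
for any trial position the optimal components come from a linear solve, and a
nonlinear optimiser refines only the three position coordinates.  Multi-start
jittered initial positions guard against local minima of the projected
objective.

The fit quality factor is Q = ‖δobs − δcal‖ / ‖δobs‖.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tensor import ChiTensor, pcs_basis

__all__ = ["FitResult", "fit_tensor", "quality_factor", "fit_uncertainty_by_omission"]

MIN_MEASUREMENTS = 8  # 8 tensor parameters


@dataclass(frozen=True)
class FitResult:
    tensor: ChiTensor
    q_factor: float
    residuals: np.ndarray  # ppm, observed − calculated
    n_used: int
    converged: bool
    restarts_used: int


def quality_factor(observed, calculated) -> float:
    """Q = sqrt(Σ(δobs−δcal)²) / sqrt(Σδobs²)."""
    obs = np.asarray(observed, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if obs.shape != cal.shape:
        raise ValueError("observed and calculated PCS lists differ in length")
    norm = np.linalg.norm(obs)
    if norm == 0.0:
        raise ValueError("quality factor undefined: observed PCSs have zero norm")
    return float(np.linalg.norm(obs - cal) / norm)


def _spin_positions(spins) -> np.ndarray:
    if hasattr(spins[0], "position"):
        return np.stack([s.position for s in spins])
    return np.atleast_2d(np.asarray(spins, dtype=float))


def _solve_components(position, positions, observed, weights) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 5 components at a fixed metal position; returns (comps, residuals)."""
    B = pcs_basis(position, positions)
    if not np.all(np.isfinite(B)):  # metal on top of a spin: reject this position
        return np.zeros(5), np.full(len(observed), np.inf)
    A = B * weights[:, None]
    comps, *_ = np.linalg.lstsq(A, observed * weights, rcond=None)
    return comps, observed - B @ comps


def fit_tensor(
    spins,
    observed,
    init_position,
    n_restarts: int = 10,
    *,
    jitter: float = 5.0,
    errors=None,
    weighted: bool = False,
    seed: int = 0,
) -> FitResult:
    """Least-squares Δχ tensor fit to PCSs at known spin positions.

    Parameters
    ----------
    spins
        (n, 3) coordinates in Å, or objects with a ``.position`` attribute.
    observed
        Measured PCSs, ppm (one per spin).
    init_position
        Starting metal position, Å; restarts jitter around it (sd ``jitter`` Å).
    n_restarts
        Total optimiser starts (the first is un-jittered); best result wins.
    errors, weighted
        With ``weighted=True``, residuals are weighted by 1/error; by default
        measurement errors are ignored in the objective.
    """
    positions = _spin_positions(spins)
    observed = np.asarray(observed, dtype=float)
    n = len(observed)
    if len(positions) != n:
        raise ValueError("one observation per spin position required")
    if n < MIN_MEASUREMENTS:
        raise ValueError(f"need at least {MIN_MEASUREMENTS} measurements, got {n}")
    if n == MIN_MEASUREMENTS:
        warnings.warn("exactly 8 measurements: fit has zero degrees of freedom", stacklevel=2)
    if np.linalg.norm(observed) == 0.0:
        raise ValueError("all observed PCSs are zero: tensor and Q are undefined")
    rank = np.linalg.matrix_rank(positions - positions.mean(axis=0))
    if rank < 2:
        raise ValueError("degenerate geometry: spin positions are collinear")

    if weighted:
        err = np.asarray(errors, dtype=float)
        if np.any(err <= 0):
            raise ValueError("weighted fit requires strictly positive errors")
        weights = 1.0 / err
    else:
        weights = np.ones(n)

    init_position = np.asarray(init_position, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)

    def residual_vec(p):
        _, resid = _solve_components(p, positions, observed, weights)
        return resid * weights

    best = None
    for restart in range(max(1, n_restarts)):
        p0 = init_position if restart == 0 else init_position + rng.normal(0.0, jitter, 3)
        sol = least_squares(residual_vec, p0, method="lm", xtol=1e-12, ftol=1e-12)
        cost = float(sol.cost)
        if best is None or cost < best[0]:
            best = (cost, sol, restart)
    cost, sol, _ = best

    comps, resid = _solve_components(sol.x, positions, observed, weights)
    tensor = ChiTensor(position=sol.x, comps=comps)
    calc = observed - resid
    return FitResult(
        tensor=tensor,
        q_factor=quality_factor(observed, calc),
        residuals=resid,
        n_used=n,
        converged=bool(sol.success),
        restarts_used=max(1, n_restarts),
    )


def fit_uncertainty_by_omission(
    spins,
    observed,
    omit_fraction: float,
    n_repeats: int,
    seed: int,
    init_position,
    n_restarts: int = 5,
    **fit_kwargs,
) -> list[FitResult]:
    """Repeat the fit on random measurement subsets to probe its stability.

    Each repeat keeps ``ceil((1 − omit_fraction)·n)`` measurements chosen
    uniformly without replacement; the spread of the resulting tensors (e.g.
    metal-position scatter) estimates the fit uncertainty.
    """
    if not 0.0 < omit_fraction < 1.0:
        raise ValueError("omit_fraction must be in (0, 1)")
    positions = _spin_positions(spins)
    observed = np.asarray(observed, dtype=float)
    n = len(observed)
    n_keep = int(np.ceil((1.0 - omit_fraction) * n))
    if n_keep < MIN_MEASUREMENTS:
        raise ValueError(
            f"omission leaves {n_keep} measurements; at least {MIN_MEASUREMENTS} required"
        )
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(n_repeats):
        keep = rng.choice(n, size=n_keep, replace=False)
        results.append(
            fit_tensor(
                positions[keep],
                observed[keep],
                init_position,
                n_restarts,
                seed=int(rng.integers(2**31)),
                **fit_kwargs,
            )
        )
    return results
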