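"""Monte Carlo comparison of paramagnetic tagging strategies.

Model: a globular macromolecule is a sphere of radius R (default 25 Å) with
tagging sites — each identical to a paramagnetic-centre position — on its
surface.  Sites sit at even divisions of a circle on the sphere, all at the
same distance d (default 20 Å) from the nucleus of interest, which lies at the
centre of that circle, in its plane.  Tags are distributed over the sites as
evenly as possible (round-robin).

For each Monte Carlo sample every tag receives an independent, uniformly
random orientation of a Δχ tensor with fixed anisotropy; the "observed" PCSs
are the exact values at the site of interest, and the localisation volume
V_RMSD below an RMSD threshold is integrated on a grid centred there.
Repeating over many samples yields the distribution of localisation volumes a
given (n_tags, n_sites) strategy can be expected to deliver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .localisation import Grid
from .tensor import from_axial_rhombic, pcs_basis

__all__ = [
    "TagGeometry",
    "MCDistribution",
    "build_geometry",
    "sample_localisation_volumes",
    "summarize",
]

DEFAULT_SPHERE_RADIUS = 25.0  # Å
DEFAULT_SOI_DISTANCE = 20.0  # Å
#: Default anisotropy for simulated tags, 10⁻³² m³ (thulium-tag scale).
DEFAULT_AX = 20.0
DEFAULT_RH = 4.0


@dataclass(frozen=True)
class TagGeometry:
    """Sites on a sphere, a site of interest, and a tag→site assignment."""

    sphere_radius: float
    soi_distance: float
    n_sites: int
    n_tags: int
    site_positions: np.ndarray  # (n_sites, 3), Å
    tag_site_assignment: np.ndarray  # (n_tags,), site indices
    soi_position: np.ndarray  # (3,), Å

    @property
    def tag_positions(self) -> np.ndarray:
        return self.site_positions[self.tag_site_assignment]


def build_geometry(
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
    d: float = DEFAULT_SOI_DISTANCE,
    n_sites: int = 1,
    n_tags: int = 1,
) -> TagGeometry:
    """Place ``n_sites`` tagging sites evenly on a circle of the sphere.

    The site of interest sits at the circle centre, in the circle plane, at
    height h = sqrt(R² − d²) on the z axis; each site is then both on the
    sphere (|site| = R) and at distance d from the site of interest.  Tags are
    assigned to sites round-robin, so per-site counts differ by at most one.
    """
    if sphere_radius <= 0 or d <= 0:
        raise ValueError("sphere radius and spin-metal distance must be positive")
    if d > sphere_radius:
        raise ValueError(
            "soi distance d may not exceed the sphere radius in the circle-centre "
            "geometry (the site circle has radius d on the sphere)"
        )
    if n_sites < 1 or n_tags < 1:
        raise ValueError("need at least one site and one tag")
    h = float(np.sqrt(sphere_radius**2 - d**2))
    phi = 2.0 * np.pi * np.arange(n_sites) / n_sites
    sites = np.stack([d * np.cos(phi), d * np.sin(phi), np.full(n_sites, h)], axis=1)
    assignment = np.arange(n_tags) % n_sites
    return TagGeometry(
        sphere_radius=float(sphere_radius),
        soi_distance=float(d),
        n_sites=int(n_sites),
        n_tags=int(n_tags),
        site_positions=sites,
        tag_site_assignment=assignment,
        soi_position=np.array([0.0, 0.0, h]),
    )


@dataclass(frozen=True)
class MCDistribution:
    """Sampled localisation volumes with percentile summary and provenance."""

    samples: np.ndarray  # ų
    truncated_fraction: float
    summary: dict
    config: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def summarize(samples) -> dict:
    """Median, quartiles and 95th percentile (linear interpolation), ų."""
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("cannot summarise an empty sample list")
    q25, med, q75, p95 = np.percentile(s, [25.0, 50.0, 75.0, 95.0])
    return {"median": float(med), "q25": float(q25), "q75": float(q75), "p95": float(p95)}


def random_rotations(n: int, rng: np.random.Generator) -> Rotation:
    """n orientations uniform on SO(3), via unit quaternions from the rng."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q)


def sample_localisation_volumes(
    geom: TagGeometry,
    ax: float = DEFAULT_AX,
    rh: float = DEFAULT_RH,
    threshold: float = 0.03,
    grid: Grid | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
    keep_samples: bool = True,
) -> MCDistribution:
    """Distribution of V_RMSD over random tag orientations.

    Each sample draws an independent uniform rotation per tag; the tensor keeps
    its site position and (ax, rh) anisotropy.  Observed PCSs are the exact
    values at the site of interest (no measurement noise) so all localisation
    uncertainty enters through ``threshold``.  Fully reproducible from ``seed``.
    """
    if grid is None:
        grid = Grid(center=geom.soi_position, points_per_angstrom=5.0, volume=1000.0)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rng = np.random.default_rng(seed)

    pts = grid.points()
    n_grid = len(pts)
    # the PCS is linear in the 5 tensor components, so the grid design matrix per
    # *site* is orientation-independent and can be shared across all samples.
    site_basis = [pcs_basis(site, pts) for site in geom.site_positions]
    soi_basis = [
        pcs_basis(site, geom.soi_position[None, :])[0] for site in geom.site_positions
    ]
    for b in site_basis:
        b[~np.isfinite(b)] = np.inf  # metal on a grid point: exclude that point

    face = np.zeros(grid.shape, dtype=bool)
    face[0] = face[-1] = True
    face[:, 0] = face[:, -1] = True
    face[:, :, 0] = face[:, :, -1] = True
    face = face.ravel()

    thr_sq = threshold**2 * geom.n_tags  # compare Σ residual² directly
    volumes = np.empty(n_samples)
    truncated = 0
    for i in range(n_samples):
        rots = random_rotations(geom.n_tags, rng)
        ssq = np.zeros(n_grid)
        for t in range(geom.n_tags):
            s = geom.tag_site_assignment[t]
            comps = from_axial_rhombic(ax, rh, rots[t], geom.site_positions[s]).comps
            with np.errstate(invalid="ignore"):
                resid = soi_basis[s] @ comps - site_basis[s] @ comps
            ssq += resid**2
        mask = ssq < thr_sq
        volumes[i] = mask.sum() * grid.dv
        if mask[face].any():
            truncated += 1

    return MCDistribution(
        samples=volumes if keep_samples else np.array([]),
        truncated_fraction=truncated / n_samples,
        summary=summarize(volumes),
        config={
            "sphere_radius": geom.sphere_radius,
            "soi_distance": geom.soi_distance,
            "n_sites": geom.n_sites,
            "n_tags": geom.n_tags,
            "ax": ax,
            "rh": rh,
            "threshold_ppm": threshold,
            "grid_volume_A3": grid.volume,
            "grid_density_per_A": grid.points_per_angstrom,
            "n_samples": n_samples,
            "seed": seed,
        },
    )
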