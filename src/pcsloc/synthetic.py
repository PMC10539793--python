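"""Synthetic scenes: protein-like spin clouds, ground-truth tensors, noisy PCSs.

Every stage of the package is testable offline against scenes generated here:
amide-proton-like point clouds in a spherical shell around the tag region,
Δχ tensors of realistic anisotropy at surface-like positions, and PCS datasets
with Gaussian measurement noise.  The default scene mirrors the scale of a
small-protein, four-thulium-tag experiment: ~70 protons 8–35 Å from the
metals, tensor anisotropies bracketing small and large cyclen-based tags
(ax 8–35, rh 1–8, 10⁻³² m³), and 0.01 ppm noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import PCSMeasurement, SpinSite, write_npc, write_pdb, write_tensor
from .montecarlo import random_rotations
from .tensor import ChiTensor, from_axial_rhombic, pcs

__all__ = ["SyntheticScene", "make_spin_cloud", "make_pcs_dataset", "make_scene", "write_fixture"]

DEFAULT_N_SPINS = 70
DEFAULT_SHELL = (8.0, 35.0)  # Å from the metal region
DEFAULT_NOISE_SD = 0.01  # ppm
DEFAULT_AX_RANGE = (8.0, 35.0)  # 10⁻³² m³
DEFAULT_RH_RANGE = (1.0, 8.0)


@dataclass(frozen=True)
class SyntheticScene:
    spins: list[SpinSite]
    tensors: list[ChiTensor]
    measurements: list[list[PCSMeasurement]]  # one list per tensor
    noise_sd: float
    seed: int

    @property
    def spin_positions(self) -> np.ndarray:
        return np.stack([s.position for s in self.spins])


def make_spin_cloud(n: int, rmin: float, rmax: float, seed: int) -> list[SpinSite]:
    """n points uniform in the spherical shell [rmin, rmax] around the origin.

    Labelled as sequential residues with atom H, mimicking backbone amide
    protons of a globular protein.
    """
    if n < 1:
        raise ValueError("need at least one spin")
    if not 0 < rmin < rmax:
        raise ValueError("shell radii must satisfy 0 < rmin < rmax")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    # radius CDF ∝ r³ between the shell bounds
    r = (rng.uniform(rmin**3, rmax**3, size=n)) ** (1.0 / 3.0)
    return [
        SpinSite(chain="A", residue_number=i + 1, residue_name="GLY", atom_name="H",
                 position=u[i] * r[i])
        for i in range(n)
    ]


def make_pcs_dataset(
    tensor: ChiTensor, spins: list[SpinSite], noise_sd: float, seed: int
) -> list[PCSMeasurement]:
    """Exact PCSs at the spin sites plus Gaussian noise of sd ``noise_sd`` ppm."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(spins)) if noise_sd > 0 else np.zeros(len(spins))
    return [
        PCSMeasurement(s.residue_number, s.atom_name,
                       float(pcs(tensor, s.position) + noise[i]), noise_sd)
        for i, s in enumerate(spins)
    ]


def make_scene(
    seed: int,
    n_spins: int = DEFAULT_N_SPINS,
    n_tensors: int = 4,
    shell: tuple[float, float] = DEFAULT_SHELL,
    noise_sd: float = DEFAULT_NOISE_SD,
    ax_range: tuple[float, float] = DEFAULT_AX_RANGE,
    rh_range: tuple[float, float] = DEFAULT_RH_RANGE,
) -> SyntheticScene:
    """Full scene: spin cloud, ground-truth tensors nearby, noisy datasets.

    The tensors sit in a single-site-like cluster (metal positions uniform in
    a 3 Å ball, so pairwise metal separations span roughly 0–6 Å, as observed
    for different tags attached to one residue), with anisotropies drawn
    uniformly from the stated ranges and independent uniform orientations.
    Spins are resampled until every spin is at least ``shell[0]`` Å from every
    metal, so the shell bounds hold relative to the metals, not just the
    origin.  All randomness derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    rots = random_rotations(n_tensors, rng)
    tensors = []
    for t in range(n_tensors):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = direction * 3.0 * rng.uniform() ** (1.0 / 3.0)
        ax = rng.uniform(*ax_range)
        rh = min(rng.uniform(*rh_range), (2.0 / 3.0) * ax)
        tensors.append(from_axial_rhombic(ax, rh, rots[t], pos))
    metal_positions = np.stack([t.position for t in tensors])
    spins = make_spin_cloud(n_spins, shell[0], shell[1], int(rng.integers(2**31)))
    for i, s in enumerate(spins):
        while np.min(np.linalg.norm(metal_positions - s.position, axis=1)) < shell[0]:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(shell[0] ** 3, shell[1] ** 3) ** (1.0 / 3.0)
            s = SpinSite(chain=s.chain, residue_number=s.residue_number,
                         residue_name=s.residue_name, atom_name=s.atom_name, position=u * r)
            spins[i] = s
    measurements = [
        make_pcs_dataset(tensors[t], spins, noise_sd, int(rng.integers(2**31)))
        for t in range(n_tensors)
    ]
    return SyntheticScene(spins=spins, tensors=tensors, measurements=measurements,
                          noise_sd=noise_sd, seed=seed)


def write_fixture(directory, scene: SyntheticScene) -> dict[str, list[str]]:
    """Write the scene as PDB + per-tensor npc and tensor files; returns paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pdb = d / "scene.pdb"
    write_pdb(pdb, scene.spins)
    npc_paths, tensor_paths = [], []
    for i, (tensor, meas) in enumerate(zip(scene.tensors, scene.measurements), start=1):
        npc = d / f"tag{i}.npc"
        tf = d / f"tag{i}.tensor"
        write_npc(npc, meas)
        write_tensor(tf, tensor)
        npc_paths.append(str(npc))
        tensor_paths.append(str(tf))
    return {"pdb": [str(pdb)], "npc": npc_paths, "tensor": tensor_paths}
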