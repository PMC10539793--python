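"""File formats: PDB structures, PCS measurement lists, tensor files, DX maps.

PCS measurements use the whitespace ``.npc`` dialect: one line per shift,
``residue_number atom_name value_ppm error_ppm``, with ``#`` comments.  Tensor
files are key–value text with a metal position and either the five matrix
components or an (ax, rh, ZYZ Euler angles) parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .tensor import ChiTensor, from_axial_rhombic

__all__ = [
    "SpinSite",
    "PCSMeasurement",
    "read_pdb",
    "write_pdb",
    "read_npc",
    "write_npc",
    "match",
    "read_tensor",
    "write_tensor",
    "write_dx",
    "read_dx",
    "write_pseudoatom_pdb",
]


@dataclass(frozen=True)
class SpinSite:
    """One atom of the reference structure."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray  # Å

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom coordinates must be finite")

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_number, self.atom_name)


@dataclass(frozen=True)
class PCSMeasurement:
    """One experimental PCS: (residue, atom) key, value and error in ppm."""

    residue_number: int
    atom_name: str
    value: float  # ppm
    error: float  # ppm

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("PCS value must be finite")
        if self.error < 0:
            raise ValueError("PCS error must be >= 0")

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_number, self.atom_name)


def _normalise_atom_name(name: str) -> str:
    # amide-proton aliases: HN and H denote the same proton
    return "H" if name.upper() == "HN" else name


def read_pdb(path) -> list[SpinSite]:
    """All ATOM/HETATM sites of the first model; highest-occupancy altloc kept."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    st.remove_empty_chains()
    model = st[0]
    sites: list[SpinSite] = []
    for chain in model:
        for residue in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                sites.append(
                    SpinSite(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=_normalise_atom_name(atom.name),
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
    if not sites:
        raise ValueError(f"{path}: no ATOM records found")
    return sites


def write_pdb(path, sites: list[SpinSite]) -> None:
    """Minimal fixed-width PDB writer (single model, occupancy 1, B = 0)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            name = s.atom_name if len(s.atom_name) >= 4 else f" {s.atom_name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:<4s}{s.residue_name:>4s} {s.chain[:1]}"
                f"{s.residue_number:4d}    "
                f"{s.position[0]:8.3f}{s.position[1]:8.3f}{s.position[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {s.atom_name[:1]:>2s}\n"
            )
        fh.write("TER\nEND\n")


def write_pseudoatom_pdb(path, points: np.ndarray, occupancies: np.ndarray) -> None:
    """Grid pseudo-atoms (element O, residue LOC) for visualising a space."""
    points = np.atleast_2d(points)
    with open(path, "w") as fh:
        for i, (p, occ) in enumerate(zip(points, occupancies), start=1):
            serial = i % 100000
            fh.write(
                f"HETATM{serial:5d}  O   LOC A   1    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{occ:6.2f}{0.0:6.2f}           O\n"
            )
        fh.write("END\n")


def read_npc(path) -> list[PCSMeasurement]:
    """Parse a whitespace PCS file: ``residue atom value error`` per line."""
    out: list[PCSMeasurement] = []
    seen: set[tuple[int, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'residue atom value error'")
            try:
                res = int(parts[0])
                value = float(parts[2])
                error = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            atom = _normalise_atom_name(parts[1])
            if (res, atom) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate measurement for ({res}, {atom})")
            seen.add((res, atom))
            out.append(PCSMeasurement(res, atom, value, error))
    if not out:
        raise ValueError(f"{path}: no PCS data lines")
    return out


def write_npc(path, measurements: list[PCSMeasurement]) -> None:
    with open(path, "w") as fh:
        fh.write("# residue atom pcs_ppm error_ppm\n")
        for m in measurements:
            fh.write(f"{m.residue_number:4d} {m.atom_name:<4s} {m.value:12.6f} {m.error:10.6f}\n")


def match(
    sites: list[SpinSite], measurements: list[PCSMeasurement]
) -> tuple[list[tuple[SpinSite, PCSMeasurement]], list[PCSMeasurement]]:
    """Inner join on (residue_number, atom_name).

    Returns (pairs, unmatched_measurements); unmatched entries are reported,
    never silently dropped.  Raises if nothing matches.
    """
    by_key = {s.key: s for s in sites}
    pairs, unmatched = [], []
    for m in measurements:
        site = by_key.get(m.key)
        if site is None:
            unmatched.append(m)
        else:
            pairs.append((site, m))
    if not pairs:
        raise ValueError("no measurement matches any atom in the structure")
    return pairs, unmatched


# -- tensor files -------------------------------------------------------------

_FMT = "%.17g"  # full double precision: round-trips exceed 12 significant digits


def write_tensor(path, tensor: ChiTensor) -> None:
    """Key–value tensor file: position, five components, derived ax/rh."""
    vals, vecs = tensor.eig()
    eul = Rotation.from_matrix(vecs).as_euler("ZYZ", degrees=True)
    with open(path, "w") as fh:
        fh.write("# Δχ tensor: position in Å, components in 1e-32 m^3\n")
        fh.write("position " + " ".join(_FMT % v for v in tensor.position) + "\n")
        fh.write("comps " + " ".join(_FMT % v for v in tensor.comps) + "\n")
        fh.write(f"# derived: ax {_FMT % tensor.ax}  rh {_FMT % tensor.rh}"
                 f"  euler_zyz_deg " + " ".join(_FMT % v for v in eul) + "\n")


def read_tensor(path) -> ChiTensor:
    """Read a tensor file with either ``comps`` or (ax, rh, euler_zyz_deg)."""
    fields: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, *rest = line.split()
            try:
                fields[key.lower()] = [float(v) for v in rest]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value for {key!r}") from None
    if "position" not in fields or len(fields["position"]) != 3:
        raise ValueError(f"{path}: missing 3-component 'position'")
    pos = fields["position"]
    if "comps" in fields:
        if len(fields["comps"]) != 5:
            raise ValueError(f"{path}: 'comps' needs 5 values")
        return ChiTensor(position=pos, comps=fields["comps"])
    if {"ax", "rh"} <= fields.keys():
        eul = fields.get("euler_zyz_deg", [0.0, 0.0, 0.0])
        rot = Rotation.from_euler("ZYZ", eul, degrees=True)
        return from_axial_rhombic(fields["ax"][0], fields["rh"][0], rot, pos)
    raise ValueError(f"{path}: need either 'comps' or 'ax'+'rh' (+'euler_zyz_deg')")


# -- OpenDX scalar maps -------------------------------------------------------


def write_dx(path, grid, field: np.ndarray) -> None:
    """OpenDX regular scalar map of a grid field (C order, z fastest)."""
    n = grid.n
    o = grid.origin
    d = grid.spacing
    vals = np.asarray(field, dtype=float).ravel()
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {n} {n} {n}\n")
        fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"delta {d:.6f} 0 0\ndelta 0 {d:.6f} 0\ndelta 0 0 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {n} {n} {n}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} data follows\n")
        for start in range(0, vals.size, 3):
            fh.write(" ".join("%.6e" % v for v in vals[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def read_dx(path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read an OpenDX map; returns (field n×n×n, spacing, origin)."""
    counts = None
    origin = None
    delta = []
    data: list[float] = []
    in_data = False
    n_items = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if in_data:
                if s.startswith("attribute") or s.startswith("object"):
                    in_data = False
                    continue
                data.extend(float(v) for v in s.split())
                if len(data) >= n_items:
                    in_data = False
                continue
            if s.startswith("object 1"):
                counts = [int(v) for v in s.split()[-3:]]
            elif s.startswith("origin"):
                origin = np.array([float(v) for v in s.split()[1:4]])
            elif s.startswith("delta"):
                delta.append([float(v) for v in s.split()[1:4]])
            elif "data follows" in s:
                n_items = int(s.split()[-3])
                in_data = True
    if counts is None or origin is None or not delta:
        raise ValueError(f"{path}: not a regular OpenDX scalar map")
    spacing = float(delta[0][0])
    return np.array(data).reshape(counts), spacing, origin
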