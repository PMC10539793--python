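"""Localise a nuclear spin from four PCSs measured with four co-located tags.

Four Δχ tensors with random orientations share one tagging site 20 Å from the
spin.  The PCS RMSD between 'measured' and back-calculated shifts is
integrated on a 1000 ų grid; the volume below a 0.03 ppm threshold is the
localisation space of the spin.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from pcsloc import (
    build_geometry, build_grid, connected_components, from_axial_rhombic,
    pcs, rmsd_volume, threshold_for_volume,
)

geom = build_geometry(sphere_radius=25.0, d=20.0, n_sites=1, n_tags=4)
rots = Rotation.random(4, rng=np.random.default_rng(11))
tensors = [from_axial_rhombic(20.0, 4.0, rots[i], geom.tag_positions[i]) for i in range(4)]
observed = [pcs(t, geom.soi_position) for t in tensors]

grid = build_grid(volume=1000.0, density=5.0, center=geom.soi_position)
space = rmsd_volume(tensors, observed, grid, threshold=0.03)
n_comp, vols = connected_components(space)

print(f"grid: {grid.n_points} points, ΔV = {grid.dv:.3f} ų")
print(f"localisation volume at 0.03 ppm: {space.volume:.2f} ų "
      f"in {n_comp} connected region(s); truncated at grid edge: {space.boundary_truncated}")

thr = threshold_for_volume(tensors, observed, grid, target_volume=5.0)
print(f"threshold producing a ~5 ų space: {thr:.4f} ppm")
print("A volume of a few ų means the spin is pinned to within ~1-2 Å;")
print("the adaptive threshold is how spaces of comparable size are displayed.")
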