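"""Evaluate pseudocontact shifts and their gradients for a Δχ tensor.

An axial tensor (Δχax = 3, Δχrh = 0, units 10⁻³² m³) sits at the origin; we
evaluate the PCS along its z axis, confirm the point symmetry about the metal,
and look at the gradient (the isosurface normal).
"""

import numpy as np

from pcsloc import from_axial_rhombic, pcs, pcs_gradient

tensor = from_axial_rhombic(ax=3.0, rh=0.0)

for z in (5.0, 10.0, 20.0):
    print(f"PCS at (0, 0, {z:4.0f} Å): {pcs(tensor, [0, 0, z]):+8.4f} ppm")
print(f"PCS at (0, 0, -10 Å): {pcs(tensor, [0, 0, -10.0]):+8.4f} ppm  "
      "(same as +10 Å: isosurfaces are point-symmetric about the metal)")

g = pcs_gradient(tensor, [0.0, 0.0, 10.0])
print(f"gradient at (0, 0, 10 Å): ({g[0]:+.4f}, {g[1]:+.4f}, {g[2]:+.4f}) ppm/Å")
print("The PCS falls off as 1/r³, so the gradient points back toward the metal;")
print("its magnitude sets how sharply a measured PCS pins the spin position.")
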