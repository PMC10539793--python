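"""Predict localisation precision from PCS gradient geometry at the spin.

For each spin of a synthetic four-tag scene we evaluate the parallel metric
δ∥ (mean |cos| between gradient directions — small is good) and the
perpendicular metric δ⟂ (cross-product magnitudes — large is good), then
check how δ⟂ ranks against the actual localisation volume.
"""

import numpy as np
from scipy import stats

from pcsloc import (
    build_grid, gradient_set, make_scene, parallel_metric, pcs,
    perpendicular_metric, rmsd_volume,
)

scene = make_scene(seed=21, n_spins=15, noise_sd=0.0)

print("spin   δ∥      δ⟂ (ppm/Å)²   V_RMSD @0.03ppm (ų)")
perp, vols = [], []
for i, spin in enumerate(scene.spins):
    g = gradient_set(scene.tensors, spin.position)
    observed = [pcs(t, spin.position) for t in scene.tensors]
    grid = build_grid(1000.0, 5.0, spin.position)
    v = rmsd_volume(scene.tensors, observed, grid, 0.03).volume
    perp.append(perpendicular_metric(g))
    vols.append(v)
    print(f"{i+1:4d}  {parallel_metric(g):.3f}   {perp[-1]:10.4f}   {v:12.3f}")

rho = stats.spearmanr(perp, vols).statistic
print(f"\nSpearman rank correlation δ⟂ vs V_RMSD: {rho:+.2f}")
print("Large δ⟂ (strong, mutually inclined gradients) predicts a small,")
print("well-confined localisation space; the correlation is negative.")
print("A volume of 0 means the space fell below what the 0.2 Å grid resolves:")
print("near the metals the PCS gradient is so steep that no grid point stays")
print("within the threshold — the spin is localised more tightly than ΔV.")
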