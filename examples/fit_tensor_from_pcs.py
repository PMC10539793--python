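"""Fit a Δχ tensor to noisy PCSs and probe its stability by random omission.

A synthetic scene provides 70 amide-proton-like spins with PCSs from a known
ground-truth tensor plus 0.01 ppm Gaussian noise; the eight-parameter fit
(3 position + 5 tensor components) should recover the metal position to a
fraction of an Å.
"""

import numpy as np

from pcsloc import fit_tensor, fit_uncertainty_by_omission, make_scene

scene = make_scene(seed=5)
truth = scene.tensors[0]
positions = scene.spin_positions
observed = np.array([m.value for m in scene.measurements[0]])

result = fit_tensor(positions, observed, init_position=positions.mean(axis=0),
                    n_restarts=10, seed=0)
err = np.linalg.norm(result.tensor.position - truth.position)
print(f"fitted metal position: {np.round(result.tensor.position, 2)} Å "
      f"(error {err:.3f} Å from ground truth)")
print(f"quality factor Q = {result.q_factor:.4f}  "
      "(‖residual‖/‖observed‖; experimental fits are typically 0.01-0.05)")
print(f"anisotropy: ax = {result.tensor.ax:.2f}, rh = {result.tensor.rh:.2f} ×10⁻³² m³")

repeats = fit_uncertainty_by_omission(positions, observed, omit_fraction=0.1,
                                      n_repeats=10, seed=1,
                                      init_position=result.tensor.position)
metals = np.stack([r.tensor.position for r in repeats])
scatter = np.linalg.norm(metals - metals.mean(axis=0), axis=1)
print(f"metal-position scatter over 10 fits with 10% of PCSs omitted: "
      f"max {scatter.max():.3f} Å")
print("A small scatter means the fit is not dominated by any single PCS.")
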