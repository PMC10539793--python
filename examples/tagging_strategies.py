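"""Compare tagging strategies: many tags at one site vs tags spread over sites.

Monte Carlo over random tensor orientations (fixed anisotropy ax = 20,
rh = 4 in 10⁻³² m³) on a 25 Å sphere with the spin of interest 20 Å from each
site; localisation volumes are integrated at a 0.03 ppm RMSD threshold.
Reduced to 200 samples per scenario so it runs in seconds.
"""

from pcsloc import build_geometry, build_grid, sample_localisation_volumes

print("n_tags  n_sites  median V_RMSD (ų)   IQR (ų)")
for n_tags, n_sites in [(2, 1), (3, 1), (4, 1), (4, 4)]:
    geom = build_geometry(25.0, 20.0, n_sites, n_tags)
    grid = build_grid(1000.0, 5.0, geom.soi_position)
    d = sample_localisation_volumes(geom, ax=20.0, rh=4.0, threshold=0.03,
                                    grid=grid, n_samples=200, seed=42 + n_tags + n_sites)
    s = d.summary
    print(f"{n_tags:6d}  {n_sites:7d}  {s['median']:12.2f}   "
          f"[{s['q25']:.2f}, {s['q75']:.2f}]")
print()
print("Adding tags shrinks the expected localisation volume sharply;")
print("spreading the same four tags over four sites helps only marginally —")
print("the number of tags matters more than the number of tagging sites.")
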