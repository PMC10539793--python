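# pcsloc

Localising nuclear spins in macromolecules from **pseudocontact shifts**
(PCSs) generated by paramagnetic lanthanoid tags.

Attaching a tag carrying a paramagnetic metal ion (e.g. Tm³⁺) to a protein
shifts the NMR resonances of nuclei tens of Å away. Each measured PCS confines
the nucleus to an isosurface of the tag's magnetic susceptibility anisotropy
(Δχ) tensor; several tensors together confine it to a small 3D *localisation
space*. `pcsloc` is a library (plus a thin CLI) for the computational side of
this experiment-design and analysis problem, aimed at paramagnetic-NMR
spectroscopists deciding **how many tags and how many tagging sites** they
need, and at analysts turning measured PCSs into fitted tensors and
localisation volumes.

## The model

With the metal at the origin and nuclear coordinates (x, y, z),
r = |(x, y, z)|, the PCS in ppm is

    δ = k/(4πr⁵) · [x²−z², y²−z², 2xy, 2xz, 2yz] · (Δχxx, Δχyy, Δχxy, Δχxz, Δχyz)

with k = 10⁴ for coordinates in Å and Δχ in 10⁻³² m³. Everything else builds
on this linear form:

- **δRMSD / V_RMSD** — the RMSD between measured and back-calculated PCSs,
  evaluated on a regular grid; the volume with δRMSD below a threshold
  (strict `<`) is the localisation space of the spin.
- **∇δ** — the analytic PCS gradient; its direction is the isosurface normal
  and its magnitude the localisation precision along that normal.
- **δ∥ and δ⟂** — orthogonality metrics over the gradients of n tensors at
  one spin: δ∥ = Σᵢ<ⱼ|cos θᵢⱼ|/(n−1) (small is good),
  δ⟂ = Σᵢ<ⱼ|vᵢ∧vⱼ|/(n−1) (large is good, and it rewards proximity to the
  metal by keeping the gradient magnitudes).
- **Tensor fitting** — the eight-parameter (position + 5 components)
  least-squares fit of an effective Δχ tensor to PCSs against a reference
  structure, solved by variable projection (the components enter linearly),
  with quality factor Q = ‖δobs−δcal‖/‖δobs‖ and uncertainty estimation by
  random omission of a fraction of the PCSs.
- **Monte Carlo strategy comparison** — tagging sites on a 25 Å sphere, the
  spin of interest 20 Å from every site, random uniform tensor orientations:
  the distribution of V_RMSD tells you what a given (tags × sites) strategy
  buys you.

## Worked example

`python examples/tagging_strategies.py` (200 Monte Carlo samples per
scenario, 1000 ų grid at 5 points/Å, 0.03 ppm threshold) prints:

```
n_tags  n_sites  median V_RMSD (ų)   IQR (ų)
     2        1          8.73   [5.73, 12.59]
     3        1          1.61   [0.84, 4.71]
     4        1          0.98   [0.62, 1.57]
     4        4          0.87   [0.55, 1.43]
```

Going from 2 to 4 tags shrinks the median localisation volume from ~9 ų to
~1 ų, i.e. from a diffuse region to a near-atomic pinpoint — while spreading
the same four tags over four sites (last row) improves the median only
marginally. That is the practical message: the *number of tags* matters much
more than the *number of tagging sites*, so a single well-chosen cysteine
mutant carrying several different tags is usually enough.

The other examples each run in seconds:

- `examples/compute_pcs.py` — PCS and gradient evaluation, point symmetry.
- `examples/localise_spin.py` — grid localisation of one spin, adaptive
  thresholds, connected solution regions.
- `examples/fit_tensor_from_pcs.py` — tensor fit on noisy synthetic PCSs
  (recovers the metal position to ~0.02 Å; Q ≈ 0.008) and omission-based
  stability.
- `examples/orthogonality_metrics.py` — δ∥/δ⟂ per spin and their rank
  correlation with the actual localisation volume (strongly negative).

## Command line

The same operations are exposed as `pcsloc fit | metrics | localise |
simulate | make-fixture`; `pcsloc <cmd> --help` documents each. Outputs are
TSV/JSON with the resolved configuration embedded, and identical arguments
plus `--seed` reproduce outputs byte for byte. `pcsloc make-fixture` writes a
fully synthetic PDB + PCS (.npc) + tensor file set for trying the tools
without any external data.

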