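# Methods

## PCS model and units

The pseudocontact shift of a nucleus at displacement (x, y, z) from a
paramagnetic centre with traceless symmetric anisotropy tensor Δχ is computed
as the contraction

δ = k/(4πr⁵) · [x²−z², y²−z², 2xy, 2xz, 2yz] · (Δχxx, Δχyy, Δχxy, Δχxz, Δχyz),

which, by tracelessness, equals k·rᵀΔχr/(4πr⁵). The package fixes one unit
convention throughout: **coordinates in Å, Δχ in 10⁻³² m³, PCS in ppm**,
which makes the prefactor k = 10⁴. This is the convention of the common
paramagnetic-NMR fitting tools; any other consistent choice rescales δ⟂ (and
nothing else) because that metric keeps the gradient magnitudes.

Tensors are stored as the five independent components, so PCS evaluation is a
dot product and the fit below is partially linear. Conversions to the
axial/rhombic parameterisation use the principal-frame eigenvalues
(−ax/3 + rh/2, −ax/3 − rh/2, 2ax/3) and the unique-representation ordering
|λz| ≥ |λy| ≥ |λx| with a right-handed eigenvector frame; the z-axis angle
between two tensors is folded into [0°, 90°] because eigenvector signs are
arbitrary. |rh| > (2/3)|ax| is accepted with a warning (the result simply is
not in the unique representation).

The analytic gradient is the two-term expression
∇δ = k·[2Δχ·r/(4πr⁵) − 5(rᵀΔχr)·r/(4πr⁷)]. Points closer than 10⁻⁶ Å to the
metal raise a degenerate-position error in scalar evaluation; in grid
evaluation such points are set to +∞ so they can never enter a localisation
space.

## Localisation spaces

δRMSD(p) = sqrt(mean over tensors of (δexp − δcal(p))²) is evaluated over a
cubic grid described by its total volume (ų), point density (points/Å) and
centre; each grid point carries ΔV = spacing³, and a 1000 ų grid at
5 points/Å has exactly 50³ = 125 000 points with ΔV = 0.008 ų. Field
evaluation is vectorised through the shared design matrix and chunked over
~200 000-point slabs to bound transient memory (≈ 100 MB on a 10⁶-point
grid).

The localisation space is the set of grid points with δRMSD **strictly
below** the threshold; a zero threshold is therefore always empty. The volume
is count·ΔV. Two reported diagnostics matter in practice:

- **boundary truncation** — if any sub-threshold point lies on a grid face,
  the true space extends beyond the grid and the volume is a lower bound; the
  flag is surfaced rather than silently under-reporting.
- **connected components** — 26-connectivity labelling of the mask. Three
  PCS isosurfaces generically intersect in two separate points, so
  three-tensor spaces frequently split into two regions; a fourth tensor
  collapses them to one.

Threshold adaptation to a target volume uses order statistics rather than
iteration: the volume is a right-continuous step function of the threshold,
so the smallest admissible threshold is the value just above the k-th
smallest field value, k = round(target/ΔV). Ties in the field (measure-zero
for generic inputs) can only enlarge the result by their own ΔV multiple.

Export formats: pseudo-atom PDB (occupancy 1 − δRMSD/threshold) for quick
visualisation, and OpenDX scalar maps that round-trip the field to 10⁻⁶.

## Tensor fitting

The eight-parameter fit minimises Σ(δexp − δcal)² over metal position and the
five components by variable projection: at fixed position the optimal
components are a linear least-squares solve, leaving a 3D nonlinear problem
solved with Levenberg–Marquardt; multi-start (default 10 starts, Gaussian
position jitter of sd 5 Å) guards against the multiple local minima the
1/r³ geometry can produce. Q = ‖δobs − δcal‖/‖δobs‖. Measurement errors are
ignored by default (Q is then the plain normalised residual); an optional
weighted mode uses 1/σ residual weighting. Degenerate inputs are rejected
early: fewer than 8 measurements, all-zero observations, collinear spin
positions; exactly 8 measurements warns (zero degrees of freedom).

Fit uncertainty is probed by refitting on random subsets that keep
⌈(1−f)·n⌉ measurements; the scatter of the refitted metal positions is the
headline stability number.

## Monte Carlo tagging-strategy simulation

The protein is a 25 Å sphere; tagging sites (= metal positions) lie on a
circle on the sphere, evenly spaced in azimuth, each at d = 20 Å from the
spin of interest, which sits at the circle centre in its plane (height
h = √(R²−d²) on the symmetry axis; with two sites this degenerates to the
collinear tag–spin–tag arrangement). This requires d ≤ R; larger d has no
circle-centre solution and is rejected. Tags are assigned to sites
round-robin, so per-site counts differ by at most one.

Each sample draws an independent uniform SO(3) orientation per tag
(unit-quaternion sampling from one seeded `numpy` Generator), keeps a fixed
anisotropy (defaults ax = 20, rh = 4 ×10⁻³² m³ — a thulium-tag scale; the
comparisons depend only weakly on the absolute magnitude since all scenarios
share it), sets the observed PCSs to their exact values at the spin of
interest, and integrates V_RMSD at a 0.03 ppm threshold — a typical
experimental PCS uncertainty. All uncertainty thus enters through the
threshold; measurement noise is deliberately absent. Because the grid design
matrix per site is orientation-independent, it is shared across samples,
making 10⁴ samples on the 125 000-point grid a minutes-scale computation;
tests and examples use 50–200 samples, which already resolve the ordering of
the scenario medians, and the acceptance script uses 200.

Summaries report median, quartiles and the 95th percentile (linear
interpolation) plus the fraction of samples whose space touched the grid
boundary (volume under-reported for those).

## Synthetic scenes

`make_scene` emulates the scale of a small-protein experiment with several
tags on one site: four tensors whose metal positions cluster in a 3 Å ball
(pairwise metal separations 0–6 Å, matching what different tag chemistries
attached to one residue produce), anisotropies uniform in ax ∈ [8, 35],
rh ∈ [1, 8] ×10⁻³² m³ (bracketing small and large cyclen-based tags), and 70
amide-proton-like spins uniform in a shell 8–35 Å from the origin, resampled
so that no spin comes within 8 Å of any metal. PCS noise is Gaussian with sd
0.01 ppm by default. What the generator does **not** emulate: real backbone
geometry, tag flexibility (each dataset really is produced by its single
ground-truth tensor), correlated errors, or missing assignments — so passing
tests demonstrate the correctness of the machinery and its statistical
behaviour under the stated model, not robustness to structural noise or
effective-tensor approximation error in real data.

The end-to-end check (fit four tensors on a scene with one spin held out,
then ask whether the held-out spin lies inside its own 0.03 ppm localisation
space) passes in ≥ 95 % of seeded replicates; the occasional failure is the
physically expected one — a spin near the 8 Å standoff limit where the
fitted-tensor error is amplified.

## Numerical and design choices

- Strict `<` in the mask; ties at the threshold are excluded.
- The δ∥ normalisation sums each unordered pair once with prefactor 1/(n−1);
  its [0, 1] range statement holds only at n = 2 (an orthonormal triple gives
  0, four or more vectors cannot reach 0).
- Grids may be centred on the spin of interest (simulations) or on a
  reference atom (structure-based localisation); the CLI centres on the
  selected atom.
- Tensor text files store full double precision (`%.17g`), so read/write
  round-trips are value-stable beyond 12 significant digits.
- All stochastic code takes an explicit integer seed and uses
  `numpy.random.default_rng`; no global RNG state is touched.

## Known limitations

- RDCs, contact shifts, residual anisotropic chemical shifts, Curie-spin
  cross-correlation and temperature dependence of Δχ are out of scope.
- Only cubic regular grids (no octree/adaptive refinement, no marching-cubes
  surfaces).
- Single-model PDB reading (first model, highest-occupancy altloc); no mmCIF
  or ensemble handling.
- The simulation's absolute volumes depend on the chosen anisotropy and
  threshold; only the comparisons between scenarios at shared settings are
  meaningful.
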