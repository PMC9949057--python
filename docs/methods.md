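# Methods

This note documents the models implemented in `rndflux`, the conventions
and numerical choices that decide edge cases, what the synthetic
generators do and do not emulate, and the package's known limitations.
Units throughout: energies kJ/mol, lengths nm, times ps, potentials volts,
concentrations mM.  Thermal energies are provided as named constants,
kT(310 K) = 2.5773 and kT(323 K) = 2.6854 kJ/mol (310 K is the
physiological/atomistic temperature, 323 K the coarse-grained one).

## Umbrella sampling and WHAM (`rndflux.pmf`)

Each window *i* biases the 1D reaction coordinate with
w_i(ξ) = ½k(ξ−ξ₀ᵢ)².  Retained samples (after an equilibration discard,
expressed either as a leading fraction < 1 or as an absolute time) are
histogrammed on shared bins and the coupled WHAM equations are solved for
the unbiased bin probabilities p(ξ_b) and window normalisations f_i.  The
profile is ΔG(ξ_b) = −kT ln p(ξ_b), shifted so its minimum is zero.

**Solver.**  Direct self-consistent iteration, accelerated by damped
Newton steps on the equivalent convex objective
F(g) = Σ_b M_b ln Σ_i N_i exp(g_i − w_i(ξ_b)/kT) − Σ_i N_i g_i
(g_i = f_i/kT, M_b total counts in bin b), whose stationary point is the
WHAM fixed point.  Newton steps are accepted only when they reduce the
fixed-point residual, so the solver can never do worse than plain
iteration.  This matters because plain iteration propagates information
one window-overlap per sweep and needs O(K²) sweeps across a chain of K
windows, which would make thousands of bootstrap re-solves impractical.
Convergence: max|Δg_i| < 10⁻⁷ kT, max 10⁵ iterations; non-convergence and
histogram-disconnected window sets are hard errors (the disconnection
error names the gap between window centers).  The gauge is fixed by
g₀ = 0; profiles are invariant to any constant shift of the initial g.

**Bins.**  Default width 0.05 nm (equal to the default window spacing),
configurable.  Empty interior bins are dropped with a warning, never
interpolated.  Note a systematic floor: with bins comparable in width to
the biased-sample distribution (σ ≈ √(kT/k) ≈ 0.05 nm at
k = 1000 kJ/mol/nm²), finite-bin discretisation produces inter-window
disagreement of order 0.1 kJ/mol that does not shrink with more samples.
Narrower bins push the floor down at the cost of noisier bins.

**Error band.**  Bayesian bootstrap over complete window histograms: per
replicate, the K windows receive Dirichlet(1, …, 1) weights (scaled to
mean 1) applied to their histogram counts, WHAM is re-solved warm-started
from the central solution, each replicate profile is aligned to the
central one by its mean offset (the additive gauge between re-zeroed
profiles), and the band is the per-bin standard deviation over
replicates.  Default 2000 replicates, seeded and reproducible.  Complete
histograms, rather than individual points, are the resampling unit — the
point-level alternative exists in the literature and would give a
somewhat different band; the histogram-level choice treats each window as
one exchangeable observation of the profile.

**Leg extraction.**  A leg is mean ΔG over the stated reference interval
minus the minimum ΔG in the bound interval, direction recorded
bound → reference.  A region mean, not a single bin, defines the
reference ("bulk") level because single-bin values carry bin noise.  The
leg error combines the band at the bound minimum and the mean band over
the reference region in quadrature.

**Peaks.**  Local maxima above a prominence threshold (scipy's
prominence definition), reported relative to the profile minimum;
equal-height adjacent bins (a plateau) report the leftmost ξ.

## Alchemical estimators (`rndflux.alchemical`)

Inputs are reduced energies u[k][j][n] = U_j(x_kn)/kT: sample n drawn in
state k, evaluated in every state j of the λ schedule.  Everything is
computed in kT units internally; kJ/mol appears only at reporting.

**MBAR.**  Self-consistent warm-up followed by damped Newton on the
convex MBAR objective, gradient tolerance 10⁻⁸ (gauge f₀ = 0).
Uncertainties come from the asymptotic covariance Θ computed via the SVD
form Θ = V S (I − S Vᵀ diag(N) V S)⁺ S Vᵀ of the weight matrix;
var(f_j − f_i) = Θ_ii + Θ_jj − 2Θ_ij.  The overlap matrix
O_ij = Σ_n W_ni N_j W_nj is the diagnostic: adjacent-state overlap below
0.03 warns, essentially-zero overlap anywhere in the chain is an error.

**Cross-checks.**  BAR is run as the two-state special case of MBAR on
each adjacent pair and chained with quadrature errors.  Exponential
averaging is computed forward (samples of the lower state) and reverse
(samples of the upper state) per pair; by Jensen's inequality the forward
estimate is biased high and the reverse low at finite n, so the two
bracket the converged value — a deliberate property test, not a defect.
TI integrates per-state ⟨du/dλ⟩ with the trapezoid rule when du/dλ
samples are present; its quadrature (discretisation) error is *not*
included in the reported statistical error and dominates on coarse
schedules, so TI rows are expected to flag against MBAR unless the λ
grid is dense.  `cross_check` flags any method deviating from MBAR by
more than 2 combined standard errors.

**Repeats.**  Independent repeats are analysed separately and reported as
mean ± standard deviation between repeats; the equilibration discard
(fraction or absolute per-state sample count) is applied per repeat
*before* any pooling, because a single discard on concatenated repeats
would retain the unequilibrated head of every repeat but the first.
Pooled analysis is available behind a flag.  No restraint or
standard-state volume correction is applied to decoupling legs; an
externally computed correction can be added as an ordinary leg in a
cycle.  λ windows that barely contribute (e.g. pure mass perturbation)
are treated as ordinary states.

## Thermodynamic cycles (`rndflux.cycles`)

Legs are directed (from_state → to_state) with one-sigma errors.
Composition requires the oriented legs to chain head-to-tail and the set
to be declared independent; the composed value is the signed sum and the
error the root sum of squares.  Correlated legs are refused unless
explicitly overridden, because quadrature is invalid for them.  ΔΔG of
two legs of the same transformation is a − b with quadrature error.
Closure between two independent routes with the same endpoints reports
discrepancy, combined error and z = |Δ|/σ, passing at |z| ≤ 2 by default.
Paper-style summaries round value and error to integer kJ/mol; full
precision is retained internally.  Sign conventions are always explicit:
a leg is reversed by negating its value and swapping its labels, never
inferred from magnitude.

## Electrochemical coupling (`rndflux.ions`)

ΔG_influx = RT ln(c_in/c_out) + zFΔV for one mole moved outside → inside
at membrane potential ΔV (inside minus outside); efflux is the negation;
R = 8.314 J/mol/K, F = 96 485 C/mol.  The reversal (Nernst) potential
solves ΔG = 0.  Stoichiometry: with an export cost ΔG_exp > 0 and an ion
moving spontaneously (ΔG_ion < 0) in its declared direction, the
continuous ion number is ΔG_exp/|ΔG_ion| and the ceiling is the minimal
whole-ion count.  Direction is always an explicit parameter (Na⁺
coupling uses influx, K⁺ coupling efflux, under standard cellular
gradients Na⁺ 12/145 mM and K⁺ 150/4 mM); grid points where the gradient
opposes export carry a distinguished `not_drivable` marker in curve
tables rather than NaN.  Default temperature 310 K; the documented
ceiling counts are stable across 298–323 K.  Both continuous and ceiling
modes are provided since either may be the quantity of interest.

## Trajectory geometry (`rndflux.trajectory`)

Ensembles are ordered frames of labelled coordinates with constant atom
labelling; an optional orthorhombic box enables the minimum-image
convention (applied only when a box is present).  Conventions that decide
boundary cases, fixed and tested:

* the membrane normal is +z toward the extracellular side; a cylinder
  (default length 4 nm, radius 1.3 nm) is centred on the midpoint of two
  single-atom anchors, and its halves split at the midpoint plane with
  boundary points assigned to the extracellular half;
* cylinder containment is closed (axial |s| ≤ L/2, radial ≤ r);
* contact cutoffs are strict (< cutoff), matching "within X nm";
  defaults 0.3 nm for ion coordination and 0.6 nm for sterol contacts,
  with rows under 1% occupancy dropped;
* contact tables sort by occupancy descending with ties broken by
  ascending residue number, and top-k selection inherits that order;
* ion displacement is measured against the first frame or a supplied
  reference, optionally after a rigid Kabsch superposition of a protein
  Cα selection, which makes the measure invariant to whole-system rigid
  motion;
* water selections default to oxygen atoms (the `name=OW`-style selector
  is explicit, never guessed);
* trailing-window statistics ("final 10 ns") take a window in ps; across
  repeats, per-repeat means combine as mean ± sd between repeats.

Density grids are mean per-frame counts per voxel divided by voxel
volume, so the grid integrates to the mean in-region particle count; they
are written as OpenDX text.

## Synthetic generators (`rndflux.synthetic`)

The generators emulate the *statistical structure* of the real inputs at
the documented protocol — 0.05 nm window spacing, 1000 kJ/mol/nm²
umbrella constant, multi-microsecond-style per-window sample counts
(10⁴–10⁵), λ schedules of two to dozens of states — with exactly known
answers:

* **Umbrella windows** are Metropolis random walks on
  exp(−[U(ξ) + bias]/kT) for analytic U (flat, harmonic, quartic double
  well with planted well positions and barrier height, signed Gaussian
  wells/barriers).  Step sizes are pilot-tuned per window to 30–50%
  acceptance and the first 10% of each chain is discarded as burn-in.
  Chains are serially correlated over a few steps — harmless for WHAM
  point estimates, but distribution-level tests (e.g. KS against the
  analytic density) use the sampler's `thin` parameter for
  near-independent draws.
* **Alchemical states** are 1D harmonic oscillators with per-state spring
  constants; samples are exact iid Gaussians and the exact free energy is
  f_j = (kT/2) ln(k_j/k₀), independent of the state centers.  The
  generator attaches du/dλ samples for the TI cross-check.
* **Scripted trajectories** reproduce per-frame coordinate scripts
  exactly, with optional seeded Gaussian jitter.

What the generators do *not* emulate: force-field physics, slow
orthogonal degrees of freedom (the samplers equilibrate within each
window by construction), soft-core λ paths, finite-box electrostatics,
and real water/lipid structure.  Passing tests therefore demonstrate
estimator correctness — that WHAM/MBAR/geometry recover known answers at
realistic data shapes and noise levels — not that any particular
molecular system is converged.

**Reproducibility.**  Every generator takes one global seed; per-window
and per-state streams derive from it by fixed offsets
(`default_rng([seed, stream])`) and are recorded in run manifests.  Two
runs with identical parameters and seed are byte-identical.

## Known limitations

* 1D, non-periodic reaction coordinates only; no MBAR-based profile
  estimator (binned WHAM only) and no autocorrelation-based statistical
  inefficiency weighting — error bands assume the histogram counts are
  what they are.
* No soft-core potentials, dual-topology bookkeeping, or standard-state
  corrections; decoupling results are raw.
* PDB is the only trajectory format in core; binary formats (XTC/TRR/DCD)
  should be converted upstream (e.g. `mdtraj` or `gmx trjconv` write
  multi-model PDB).
* The binned-WHAM discretisation floor described above bounds how far the
  bootstrap band can shrink at very large sample counts with wide bins.
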