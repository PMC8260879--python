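# Methods

This note records the models implemented in oligomerkit, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Mass-action equilibrium (`oligomerkit.equilibrium`)

The package models a single association step, n·M ⇌ Mₙ, with a 2-D
dissociation constant K_diss = [M]ⁿ/[Mₙ] in (receptors/μm²)^(n−1).
Intermediate species (e.g. dimers on the way to trimers) are deliberately
absent: the two-state model is what the FRET fitting procedure assumes,
and the oligomer order n is itself a fit parameter selected by MSE
comparison.

* **Root finding.** [M] solves M + n·Mⁿ/K = R_total. The residual is
  strictly increasing on [0, R_total], so bisection with a guaranteed
  bracket is used (relative tolerance 10⁻¹², 200 iteration cap,
  vectorized over totals). For n = 2 the quadratic closed form
  (K/4)(√(1+8R/K) − 1) is exposed separately and used as a cross-check in
  tests, not as the implementation path.
* **Conventions.** The oligomeric fraction counts molecules, not
  particles, and is defined as 0 at R_total = 0 (the continuous dilute
  limit) rather than an error. The apparent dissociation constant of an
  n-mer is the half-saturation density R_half = 2(K/n)^(1/(n−1)), the
  natural reading of "the concentration at which half the receptors are
  oligomeric"; its inverse K = n(R_half/2)^(n−1) converts reported
  apparent constants into model parameters.
* **Free energy.** ΔG = RT·ln(K_diss/10⁶) with R = 1.9872×10⁻³
  kcal/(mol·K) and the 2-D standard state of 1 receptor/nm². The
  temperature is fixed at T = 298.15 K as this package's own convention;
  it reproduces all six published dimer ΔG values to the printed decimal,
  but no temperature is claimed on behalf of the original measurements.
  ΔG is only defined here for dimers, where K_diss carries concentration
  units; apparent constants of higher oligomers are not converted.

## FRET model and fitting (`oligomerkit.fret`)

Inputs are per-region records (donor density, acceptor density, apparent
FRET efficiency); no image-level calibration is performed.

* **Forward model.** Donors and acceptors are assumed to label oligomers
  at random with the region's acceptor fraction x_A, so a donor in an
  n-mer has k acceptor partners with probability Binom(k; n−1, x_A). The
  per-donor efficiency with k acceptors is taken as kẼ/(kẼ + 1 − Ẽ) —
  k parallel transfer channels of pairwise efficiency Ẽ competing with
  one radiative channel. The apparent FRET is f_n·Ē. This is an explicit
  modeling interpretation for n ≥ 3 (published treatments differ in
  detail and are not fully reproducible from the available text); the
  per-donor efficiency function is a pluggable argument, and the n = 2
  case reduces exactly to f_D·x_A·Ẽ whatever the choice. A consequence:
  the apparent FRET is bounded by the saturated-oligomer per-donor
  efficiency (n−1)Ẽ/((n−1)Ẽ+1−Ẽ), which exceeds Ẽ for n ≥ 3.
* **Proximity FRET.** Nonspecific transfer from random 2-D crowding is
  modeled with the Wolber–Hudson two-exponential approximation in the
  reduced acceptor density c = σ_A·π(R0² − r_e²), with Förster radius
  R0 = 5.7 nm and exclusion radius 1 nm by default (an mTurquoise/EYFP-
  scale pair). Measured FRET is corrected as (E − E_prox)/(1 − E_prox),
  clipped to [0, 1]. The synthetic generator composes proximity through
  the exact inverse of this correction, so the round trip is exact by
  construction and the correction itself is fully testable. The proximity
  function is pluggable for users with a calibrated alternative.
* **Fitting.** MSE is (1/N)·Σ(corrected FRET − model)² — on FRET, not
  FRET/x_A, and unweighted; x_A is taken per record because transfection
  ratios vary cell to cell. Optimization is a coarse grid
  (K_diss log-spaced over 10⁻¹..10⁷, 49 points × Ẽ ∈ [0.05, 1],
  20 points) followed by Nelder–Mead refinement (parameter tolerance
  10⁻⁸), which is deterministic given the data. Records with zero total
  are dropped with a warning; a single distinct concentration is flagged
  ill-conditioned (K and Ẽ are not jointly identifiable); all-zero
  corrected FRET pins Ẽ at the lower search bound with a warning.
* **Order selection.** Orders n = 1..6 are fitted and the minimal-MSE
  order selected, ties broken toward smaller n (parsimony). The n = 1
  "fit" has no free parameters (MSE of a zero-FRET model). On noiseless
  proximity-only data the monomer model wins exactly; with clipped
  Gaussian noise on truly zero-signal data, higher orders can fit the
  small positive mean created by clipping at 0, so monomer recovery from
  noisy null data is not guaranteed — a known limitation of MSE-only
  selection without a complexity penalty.
* **Fraction curves.** Per-record oligomeric fraction is inferred as
  corrected FRET divided by the record's own composition factor
  Ē(n, x_A, Ẽ), clipped to [0, 1], then binned into 12 log-spaced bins
  (mean ± SD/√m; bins with fewer than 2 records omitted). The bin scheme
  is this package's choice.

## Molecular brightness (`oligomerkit.fif`)

Segments (default 15×15 pixels; border remainders dropped, never padded)
are the unit of estimation: ε is computed from the variance and mean of
the pixels within one segment.

* Photon-counting mode: ε = σ²/⟨I⟩ − 1, which removes the shot-noise
  floor analytically. Analog mode: ε = (σ² − σ_D²)/⟨I⟩ with a
  user-supplied detector variance (no calibration procedure is modeled).
  Note the convention: if σ_D² covers only additive detector noise, the
  analog estimate retains the +1 shot-noise unit; supplying
  σ_D² = ⟨I⟩ (pure shot noise) makes the two estimators agree exactly.
* With Poisson particle numbers per pixel and Poisson photon emission,
  ε converges to λ·⟨s²⟩/⟨s⟩ — the particle-weighted mean oligomer size
  in units of the monomer brightness λ. A half-saturated monomer/trimer
  mixture therefore reads ε = 2λ, not 3λ; only oligomer-dominated data
  (e.g. above ~3000 receptors/μm² for the constants studied here) read
  out the oligomer size directly.
* Segment concentration is ⟨I⟩/(λ·pixel_area); λ is a required
  calibration input for concentration-filtered analyses. Histograms use
  uniform bins (default 0.1 monomeric units) from the data minimum; the
  mode is the maximal bin's center, ties toward the lowest bin; negative
  brightness values (dim segments) are kept in histograms but excluded
  from modal estimation.

## Synthetic data (`oligomerkit.synthetic`)

All generators are pure functions of (truth, seed) — byte-identical
across runs.

* **FRET.** Totals log-uniform over 50–10,000 receptors/μm² (the wide
  expression range of transient transfection); x_A Beta-jittered around
  the nominal labeling ratio (concentration parameter 50, a realistic
  cell-to-cell spread); Gaussian FRET noise (default sd 0.03) added and
  clipped to [0, 1]. Defaults plant a dimer with K = 1050 receptors/μm²
  and Ẽ = 0.55, matching the scale of the measured constants; proximity
  is off by default since the analyses consume corrected efficiencies,
  and enabling it composes the exact inverse of the corrector.
* **FIF.** Per segment: total density log-uniform; species split from the
  equilibrium model (or a pure n-mer); per pixel, independent Poisson
  particle counts per species and Poisson photons given particles; analog
  mode adds Gaussian detector noise. Pixel area defaults to 0.01 μm²
  (100 nm pixels), giving tens of photons per pixel at the densities of
  interest.
* **Trajectories.** A toy Cα chain: each planted community is a ring of
  radius 2 Å (all intra-ring Cα pairs within 4.5 Å), centers 8 Å apart so
  adjacent rings share exactly one bridging contact near 4.0 Å — the
  graph stays connected and community detection has genuine work to do.
  Same-community residues share a latent 3-D factor giving displacement
  correlation ≈ coupling (default 0.9); community latents can be coupled
  across communities; fluctuation sd defaults to 0.3 Å per coordinate.
  Not emulated anywhere: photophysics (bleaching, blinking), diffusion,
  spectral crosstalk, real protein geometry, anharmonic dynamics, or
  solvent. Passing tests therefore demonstrate estimator correctness
  under the stated statistical assumptions, not robustness to the many
  ways real data violate them.

## Trajectory post-processing (`oligomerkit.trajnet`)

* **Superposition.** Kabsch least-squares rotation via the SVD of the
  cross-covariance, with a determinant check to exclude reflections;
  collinear selections raise a degeneracy error. RMSF superposes each
  post-burn-in frame to the reference on backbone atoms (falling back to
  all atoms for Cα-only models) and averages over replicates; burn-in
  defaults to 1/6 of the frames (e.g. 50 ns of a 300 ns run). Because
  superposition absorbs six rigid degrees of freedom, RMSF on small
  systems is biased slightly low (≈ √(1 − 2/N) for N isotropic residues).
* **SASA.** Shrake–Rupley with a deterministic Fibonacci sphere lattice
  (960 points default, probe 1.4 Å) and the radii table C 1.70, N 1.55,
  O 1.52, S 1.80, H 1.20 Å; unknown elements get a configurable default
  with a warning. Neighbor search uses a k-d tree. Implemented in-package
  because the radii table, point count, and fallback behavior are part of
  the contract; an independent library implementation serves as a test
  oracle.
* **Networks.** The contact criterion defaults to Cα–Cα distance ≤ 4.5 Å
  in ≥ 75% (inclusive) of pooled post-burn-in frames across replicates,
  with a heavy-atom option (`contact_atoms="heavy"`); consecutive
  residues within a chain never form edges. Correlations are
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) on Cα displacements about the
  pooled mean (pooling across replicates rather than averaging
  per-replicate correlations — the simpler estimator, flagged as a
  choice). Path weights are −log|C_ij|, capped at 10 for |C| ≤ e⁻¹⁰.
* **Communities.** Girvan–Newman edge removal by maximal weighted
  betweenness (ties broken toward the lexicographically smallest edge,
  making the procedure deterministic), scanning the dendrogram — the
  initial connected components included — for maximal modularity computed
  with |C_ij| as the affinity weight. A fixed community count is
  available via `k` for users who want a prescribed partition size
  instead of the modularity cut.
* **Interfaces.** Residue pairs across two chains with any interatomic
  distance ≤ 4.0 Å (inclusive), sorted.

## Numerical and degenerate-input conventions

Invalid physics (negative densities, FRET outside [0, 1], nonpositive
K_diss) raises `InvalidInputError`; undefined quantities (half-saturation
of a monomer model) raise `UndefinedOperationError`; too little data
raises `InsufficientDataError`. Estimates that can legitimately be
negative (brightness in dim segments) are returned as-is with a warning
rather than clipped. All file outputs have deterministic field ordering.

## Problem sizes

The test suite and drivers use 300-record FRET datasets (50 replicate
datasets for recovery statistics), 2000–3000 FIF segments of 15×15 pixels
(100×100 for estimator-bias checks), and toy trajectories of 500–5000
frames over 12–30 residues — sizes at which every estimator's sampling
error is well below the tolerances being asserted while the full suite
completes in minutes.
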