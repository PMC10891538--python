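# Methods

## Model

The system is a single "bottle-brush" polymer — a linear backbone of
`n_backbone` beads, each carrying one side loop of `loop_size` beads
closed as a ring through its backbone bead — confined to a cylinder
(axis z, radius R, length L).  All quantities are in reduced units:
σ = 1 (bead diameter and equilibrium bond length), ε = 1 (energy),
k_BT = 1.  The reference model is 200 × 40 (8,200 beads) in a cylinder
of R = 14.75 σ, L = 50.75 σ, a bead volume fraction of 12.4%.

Interactions:

* bonds, either FENE about σ, U = −½KR₀² ln[1 − ((d−σ)/R₀)²] with
  K = 30 ε/σ², R₀ = 1.5 σ, or harmonic U = ½ k_bond (d−σ)² with
  k_bond = 100 ε/σ².  A FENE bond reaching |d−σ| = R₀ aborts the run
  with the bond index (clamping would silently corrupt the ensemble);
* WCA repulsion between all non-bonded pairs, cut at 2^{1/6} σ (1–2
  exclusion only: the printed bond potentials are complete as written,
  so no extra excluded-volume term is added between bonded beads);
* a 10–4 wall potential U(r) = 2πε[⅖(σ/r)¹⁰ − (σ/r)⁴ + ⅗] within σ of
  each surface.  The cylindrical side surface and the two flat caps are
  treated as separate walls whose contributions add; a bead within σ of
  both a cap and the side wall feels both.  Edge curvature at the rim is
  not modelled.

## Dynamics

Overdamped position updates,

    r(n+1) = r(n) + (Δt/ζ) F(n) + sqrt(2 k_BT Δt/ζ) ξ(n),

with ζ = 6πη a_bead, a_bead = σ/2 and η = 200/(3πσ), so ζ = 200 in
reduced units, the free diffusion coefficient D = k_BT/ζ = 0.005 σ²/τ,
and at the default Δt = 0.01 the per-axis noise displacement is exactly
0.01 σ per step.  The viscosity is a configuration field; its default is
the reading of the cytoplasm viscosity under which the reduced units
close neatly (ζ = 200 exactly).  Inertia is absent by construction.

ξ(n) has three components per bead, each an independent standardized fGn
stream: E[X(n)] = 0, autocovariance γ(k) = ½(|k−1|^{2H} − 2|k|^{2H} +
|k+1|^{2H}).  Cross-bead and cross-axis correlations are zero — the
"independent media" simplification; spatially correlated noise between
nearby beads is a known crudeness of the model and out of scope.

### Noise generation

Streams are pre-generated before the production phase.  The primary
sampler is Davies–Harte circulant embedding: the n-point Toeplitz
covariance is embedded in an M-point circulant (M the smallest even
FFT-friendly length ≥ 2n; the padding lags use the true γ), whose
eigenvalues are the real FFT of its first row.  One inverse real FFT of
a spectrally weighted complex white-noise vector yields an *exactly*
distributed sample.  Eigenvalues below −10⁻⁸·λmax invalidate the
embedding and trigger the O(n²) Hosking (Durbin–Levinson) recursion —
also exact — rather than any clamping; magnitudes inside that tolerance
are floating-point zeros of the spectrum.  Requesting the embedding
method explicitly turns fallback into a hard error.

Each (bead, axis) stream is seeded as `SeedSequence(seed,
spawn_key=(bead, axis))`, so streams are independent, and any single
stream is reproducible without generating the others.  Tensors above
~6.7×10⁷ values are stored in single precision (the increments enter the
update at scale 0.01 σ; 10⁻⁷ relative rounding is negligible against
every statistical error in play), with all FFT arithmetic still in
double precision.  An optional chunked mode generates independent blocks
of configurable length for runs too long to hold in memory; covariance
is exact within blocks but long-range correlation across block
boundaries is truncated, which is documented and off by default.
Equilibration noise is drawn per step from a dedicated seeded stream of
i.i.d. standard normals — at H = ½ the fGn covariance is the identity,
so this is the same process as a pre-generated H = ½ tensor without the
memory.

### Protocol

Runs equilibrate with standard Brownian dynamics (H = ½) for `n_equil`
steps from a constructed initial state, then switch to the target H for
`n_steps` of production.  Only the last 80% of production is
analysis-eligible (configurable).  All randomness derives from the
single run seed through fixed spawn-key domains, so trajectories are
bit-reproducible.

Initial states lay the backbone on a helix about the cylinder axis with
each loop as a planar ring through its backbone bead (the model's own
equilibrium density is helical, so this start is unbiased and fast to
equilibrate), then remove residual overlaps with a capped
steepest-descent relaxation under soft-core repulsion.  The construction
contract — bonds within 10% of σ, no non-bonded pair closer than 0.9 σ,
every bead strictly inside — is verified and enforced with bounded
retries before a run may start.

Forces use a linked-cell pair search with a 0.3 σ Verlet skin, rebuilt
when any bead has moved half a skin.  Explicit-Euler stability is
comfortable at the defaults: Δt·k_bond/ζ = 0.005.

## Estimators

* **MSD.** Time-origin averaged (and bead-averaged for ensemble curves)
  squared displacement of the x,z components at log-spaced lags, fitted
  as log MSD vs log t; α is the slope, D_xz = exp(intercept)/4, with the
  slope's standard error reported.  The default fit window is
  [10 sampling intervals, T/10]: the first ten lags of any series are
  dominated by sampling discreteness and the fastest local relaxations
  (for frame-recorded polymer curves the lower edge, 10 t.u., sits well
  above the monomer relaxation time ζ/k_bond = 2 t.u., so the fit
  measures polymer-dressed motion rather than the free-noise crossover),
  and lags beyond a tenth of the series have too few independent
  origins.  The window is a parameter; stderr makes window sensitivity
  visible.
* **VACF.** C_v(τ) = ⟨[r(t+Δt)−r(t)]·[r(t+τ+Δt)−r(t+τ)]⟩/Δt² averaged
  over all origins in the analysis window (stationarity assumed),
  normalized by C_v(0); standard errors from 20 non-overlapping block
  means.  Requires the bead to be recorded every step (`track_beads`).
  For a free bead the normalized VACF *is* γ(k) — the cross-module
  oracle tying the integrator to the noise module.
* **Displacement distributions.** Standardized Δz/δ histograms at a set
  of lags (interpreted in simulation-time units; τ = 1 is 100 steps at
  Δt = 0.01).  The Kolmogorov–Smirnov distance to N(0,1) is compared to
  the 1% critical value at the number of *non-overlapping* windows,
  since overlapping origins are strongly correlated.
* **Projected density.** 2D histogram of bead positions on the xz plane
  (counts sum to beads × frames) plus the per-frame center-of-mass axial
  offset.
* **Energy trace.** Plateau detection fits a line to 8 block means of
  the last half of the energy series; a plateau is declared when the
  95% CI of the slope contains zero.  Block means absorb the strong
  autocorrelation of the energy series that a naive OLS CI ignores.

fGn validation uses theoretical bands: the sample mean of fGn has exact
standard deviation n^{H−1}; variance and lag bands use the Bartlett
approximation with the theoretical covariance; the normality band scales
as n^{H−1} because long-range dependence slows empirical-CDF convergence
below the i.i.d. n^{−1/2} rate.

## Scaled study systems

Full-protocol runs at 8,200 beads × 10⁷ steps are not desk-scale.  The
quantitative checks therefore use, as the package's reference reduced
system, a 30 × 40 brush (1,230 beads) in a cylinder of the same radius
and proportionally shortened length (7.6125 σ), preserving the 12.4%
volume fraction and the local brush environment (loop size, grafting
density, crowding) every bead sees; protocols are 2×10⁴ equilibration +
10⁵ production steps, three replicate seeds.  Free-bead oracles use
10⁵-step runs with 20 replicates.

What transfers at this scale: exact noise statistics, α = 2H for free
beads, the VACF ↔ γ(k) identity, the H = ½ VACF null for polymer beads,
the per-bead exponents (side-loop bead α ≈ 0.5, mid-backbone bead
α ≈ 0.30–0.35 for H ≤ 0.5), Gaussian displacement distributions, the
FENE > harmonic energy ordering, the growth of plateau energy with H,
and the center-of-mass displacement toward a cap for H > ½.

What does not: the *ensemble-averaged* exponent.  In long runs the
ensemble fit is dominated by lag decades 10²–10⁴ t.u. where the
bead-averaged MSD has bent down to slopes near 0.4; a 10³-t.u. scaled
run ends where that regime begins, so its default-window fit
(≈ 0.54 at H = 0.45) sits above the long-run value even though the
measured local slope falls to ≈ 0.4 at the longest accessible lags.
Equally, 2×10⁴ equilibration steps relax the potential energy but not
the slowest conformational modes of the brush (≈ 2.5×10³ t.u.), another
genuinely scale-bound limitation.  These are reported as measured, not
recalibrated.

## Numerical choices and edge cases

* Overstretched FENE bonds, hard-core overlaps (< 10⁻⁶ σ) and escaped
  beads abort with indices and flush the partial trajectory onto the
  raised exception; positions are checked finite every step through the
  update kernel's displacement accumulator.
* Hurst values outside [0.35, 0.65] warn (generation cost and statistics
  degrade) but are not refused; H must lie in (0, 1).
* The wall force at ρ → 0 (a bead exactly on the axis, radial direction
  undefined) applies no radial component; the configuration set never
  reaches it in practice since the wall cutoff is σ ≪ R.
* Degenerate inputs (zero-variance displacement series, non-positive MSD
  in a fit window, too-short series) raise typed errors naming the
  requirement rather than returning NaN.

## Known limitations

Independent noise across beads ignores the spatial correlation of a real
viscoelastic medium; hydrodynamics, bending stiffness, electrostatics,
crowder particles, heterogeneous (diffusing) diffusivity and the
non-Gaussian (Laplace) displacement tails observed experimentally are
all outside the model.  Chunked noise truncates cross-block correlation.
The synthetic study systems probe the model's own statistics; agreement
there shows the method is implemented exactly, not that the model
captures any particular organism's chromosome.
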