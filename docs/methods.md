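# Methods

This note records the model equations as implemented, the numerical
choices behind them, the defaults and their rationale, and what the test
suite's synthetic conditions do and do not demonstrate about real
membranes.

## Membrane phase field

The composition field c(**r**, t) lives on a periodic L×L grid
(default L = 256 cells at Δx = 1, i.e. a 256 nm × 256 nm patch at the
physical calibration) and evolves by

    ∂c/∂t = −(c − c_r)/τ_r + M ∇²(δF/δc) + η,
    δF/δc = −∇·(W²[1 − αρ(r)] ∇c) + Λc + c³.

* **Variational derivative.** With a spatially varying gradient
  coefficient the functional derivative of F is the divergence form
  −∇·(k∇c), k = W²(1 − αρ); we discretize it in flux form with
  face-averaged coefficients, which reduces exactly to the 5-point
  Laplacian when α = 0 and conserves mass together with the outer
  Laplacian.
* **Immobile-protein density (pinning).** ρ is a sum of normalized
  Gaussians, prefactor (πσ_IMP²)⁻¹, width σ_IMP = 1/2, truncated at 6σ
  (relative error < 2·10⁻⁸), minimum-image periodic. The normalized
  prefactor is the only self-consistent reading: an un-normalized
  π/σ_IMP² prefactor would push αρ above 1 at protein centers with the
  reference values α = 1/π, σ_IMP = 1/2, flipping the sign of the
  gradient coefficient and making the PDE unconditionally unstable.
* **Recycling noise.** η is white Gaussian noise filtered in wavevector
  space by A(q) = (H·Δt/Δx)·l|q|/(1 + q²l²), q = 2π·(integer
  frequency)/L per axis. The Δt factor is part of the amplitude itself,
  so η is added once per Euler step with no further Δt multiplication;
  we do not replace HΔt by √(HΔt) (a variant that appears in related
  work) — the amplitude above is the defining form. A(0) = 0, hence every
  noise sample has exactly zero spatial mean and never changes the total
  composition.
* **Integrator.** Explicit Euler, centered second-order periodic
  differences, Δx = 1, Δt = 0.005. The biharmonic stability bound is
  Δt < Δx⁴/(8MW²) = 0.125, so the reference step is 25× inside it; the
  stiffest extra terms (Λ, reservoir) are mild at the reference values.
  `step_field` is the readable per-step reference; `advance_field` runs
  the same discrete operators through a compiled loop with the noise
  generated and filtered in batches, consuming the random stream in
  identical order (they agree to rounding, ~10⁻¹⁶ per step).
* **Blow-up guard.** |c| > 10³ or non-finite values abort with the step
  index; physical fields stay within ~1.1 of the binodal.

Reference models (shared c_r = 0.3, M = 1, W = 1, σ_IMP = 1/2):

| model | τ_r | Λ | l | H | α | N_imp | steps (256²) |
|-------|-----|---|---|---|---|-------|--------------|
| 1 | ∞ | −0.001 | 0.1 | 0.0283 | 0 | 0 | 24 000 |
| 2 | ∞ | −1 | 1 | 0.85 | 1/π | 1500 | 1 500 000 |
| 3 | ∞ | 10 | 1280 | 0.85 | 0 | 0 | 180 |
| 4 | ∞ | −1 | 1280 | 0.85 | 0 | 0 | 24 000 |
| 5 | 500 | −1 | 0.1 | 2.12 | 0 | 0 | 720 000 |

When the grid is reduced from 256 cells the default equilibration step
count shrinks with the grid area (diffusive scaling) and, for model 2,
the immobile-protein count shrinks likewise so the pinning density is
preserved.

**Normalization.** c̄ = (c − min c)/(max c − min c), computed over the
equilibrated field and then frozen as an affine map; later fields pushed
through the same map are clipped to [0, 1]. The freeze prevents the
diffusivity scale from drifting when the field keeps evolving (two-way
coupling). c̄ < 0.5 is labelled Lo, c̄ ≥ 0.5 Ld (ties to Ld).

**Phase regimes.** From the Landau density f = Λc²/2 + c⁴/4: "Mixed"
outside the binodal (Λ ≥ 0 or |c₀| ≥ √(−Λ)), "Spinodal Decomposition"
where f''(c₀) = Λ + 3c₀² < 0, "Nucleation" otherwise.

## Tracer dynamics

Euler–Maruyama with Δt = 10⁻³ (1 ns at D₀ = 1 ↔ 1 µm²/s; one internal
time unit is 1 µs):

    Δr = −(D/k_BT) ∇U Δt + √(2DΔt) ξ,  D = (c_b + c̄(r)) D₀.

* **Itô without drift correction, deliberately.** The governing equation
  carries no drift term, and we follow it literally, evaluating D at the
  pre-move position. This is *not* the thermodynamically consistent
  (isothermal) convention: its stationary density is ∝ 1/D(r), so
  force-free tracers accumulate in the slow Lo phase. That accumulation
  is part of the model's intended phenomenology (spontaneous raft
  partitioning without any explicit affinity), not an artifact to be
  corrected.
* **Field sampling.** Bilinear interpolation of c̄ at the tracer
  position (nearest-cell lookup available for sensitivity checks).
* **Interactions.** Truncated, unshifted Lennard-Jones with σ = 3 nm,
  r_cut = 2.5σ (community default; |force| there is ~10⁻² ε), linked-cell
  neighbor search with minimum-image distances, all-pairs fallback when
  the box is too small for 3×3 cells. Pair distances below 10⁻⁶σ abort.
  Single-molecule convention c_b = 1 (D ∈ [1, 2]); crowded systems use
  c_b = 0.1.
* **Domain preference.** "Loχ" rejects a move whose start is Lo and
  whose end is Ld with probability χ/100; entering the preferred domain
  is always accepted (one-way wall); "Ldχ" is the mirror image.
  Reflection is implemented as move rejection (stay in place), the
  minimal reading of probabilistic reflection; membership is tested at
  the old and new positions with the c̄ < 0.5 rule. Forces are computed
  before the filter; the filter acts on the net proposed displacement.
* **Initialization.** Uniform random positions; interacting systems use
  a hard-core rejection pass at 0.9σ (relaxed by 10% steps if insertion
  stalls) because a literally uniform draw can place particles deep
  inside the r⁻¹² core where the first Euler step would be unphysical.
* **Bookkeeping.** Wrapped and unwrapped coordinates are carried
  separately; a per-step displacement above half the box aborts.
* **Engines.** `step_particles` is the NumPy reference step (with a
  noise-override hook for force-only tests); `run_simulation` runs a
  compiled single-threaded loop seeded from one integer. The long-run
  engine uses its own in-kernel generator, the coupled integrator is
  driven block-wise by one NumPy generator; both are bit-reproducible
  from their seed.

## Two-way coupling

Field update (W = 1, no pinning, no reservoir):

    ∂c/∂t = ∇·{M ∇[−∇²c + Λc + c³ + g(r, t)]} + η,
    g(r) = α_g (r ≤ σ);  α_g e^−(r−σ)/r_g (r > σ),

g summed over particle positions (tail truncated at 10⁻⁶α_g, i.e.
σ + 13.8 r_g). Defaults α_g = 0.5, r_g = 2. One field step of
Δt = 0.005 is applied after every 10 Langevin steps of Δt = 10⁻³; the
two time steps originate in different unit systems and are kept as
separate dimensionless clocks rather than unified. Before the field has
developed contrast the normalization is a running min-max of the current
field; once max − min ≥ 1 the affine map freezes. All randomness (field
init, particle insertion, block noise, field noise) flows from one
seeded generator in a fixed documented order, so a run with α_g = 0
reproduces the uncoupled primitives exactly. Diffusivity during
coupling uses the crowded convention c_b = 0.1.

## Statistics

* **TAMSD** uses all overlapping windows (stride 1) — the discrete
  estimator whose continuum limit is the time-averaged integral.
  Ensemble curves default to ~40 log-spaced lags up to a tenth of the
  measurement time.
* **RSD** recomputes the fixed-lag TAMSD for every truncated measurement
  time via cumulative sums and uses the population variance convention
  (divide by n), matching the ensemble-moment definition.
* **α(Δ)** is the centered-difference slope of ln⟨TAMSD⟩ vs ln Δ,
  optionally smoothed with a short moving average (default 3 points,
  edge-reflected); there is no canonical choice of
  smoothing for such curves, so the window is a reported parameter. Single-exponent fits are
  log-log least squares over a stated lag window.
* **Residence times** are run-length encodings of the per-sample Lo/Ld
  labels; the first and last run of every trajectory are censored and
  excluded from fits; durations are multiples of the sampling interval
  (no sub-sample boundary interpolation). Pooled multi-trajectory
  analyses never merge runs across trajectory boundaries.
* **Truncated power law** P(t) ∝ t^−β e^(−t/τ) is fitted by maximum
  likelihood on [t_min, ∞), t_min defaulting to five sampling intervals
  to drop resolution-limited durations; the normalization uses the
  generalized upper incomplete gamma (computed by downward recurrence
  for non-positive argument), Nelder–Mead in (β, ln τ), seeded bootstrap
  for standard errors. MLE is preferred over log-binned least squares
  because it is unbiased for heavy tails; the log-binned histogram is
  kept for plotting and tail-slope readouts. Fits report β positive
  (the t^−β convention); signed slopes are reported where a slope is
  the quantity of interest.
* **First-passage oracle.** P_x(t) = |x|e^(−x²/4Dt)/√(4πDt³) with CDF
  erfc(|x|/√(4Dt)). The companion simulator uses Euler steps with a
  Brownian-bridge crossing test (crossing probability
  e^(−(x−a)(x−b)/(DΔt)) per step), which removes the O(√Δt) detection
  bias; walkers are capped at t_max and comparisons condition on
  T ≤ t_max. Note the density's local log-log slope is
  −1.5 + x²/(4Dt): tail-slope fits must start well beyond the mode
  x²/6D (we fit from t ≈ 10·x²/4D).
* **Confinement ratio** is the Lo fraction of particles per recorded
  frame, including the t = 0 (random-initialization) frame.

All estimators are pure functions: identical inputs give bit-identical
outputs.

## Desk-scale replicas and what they show

Full-scale runs (256² grid, 720 000 field steps, 10⁷ Langevin steps,
100 repeat trajectories) are hours-scale on one core. The package's
reproduction runs therefore use a 128² grid with the field step count
reduced in proportion to the grid area, and particle counts reduced in
proportion so the *area occupancy* of the tracers is preserved (the
collision physics is local); e.g. 512 particles on 128² replicate the
occupancy of 2048 on 256². Single-tracer statistics are pooled over a
small ensemble of independent tracers on the same frozen field, which
is statistically equivalent to one long trajectory and mirrors the
standard many-repeat single-particle-tracking protocol. The scale factor is stamped into every
scenario manifest so reduced and full-scale outputs cannot be conflated.

The synthetic fixture fields (stripe, uniform, smoothed bimodal) exercise
the estimators with known Lo geometry without running the PDE. They
reproduce the *structure* of a phase-separated membrane (two diffusivity
levels, smooth boundaries) but none of its dynamics: passing estimator
tests on fixtures shows the statistics are computed correctly, not that
the membrane model is realistic. Conversely, the equilibrated-model
tests probe the joint field+tracer phenomenology (bimodal composition
histograms, t^−1.5 residence tails, crowding subdiffusion to α ≈ 0.85,
preference-controlled partitioning) at reduced scale; residual
finite-size effects shift non-universal quantities (cutoff times,
plateau levels) relative to the full-scale system, which is why those
comparisons carry the wider, scaled-down tolerances.

Real membranes differ from all of this in ways the model does not
attempt to capture: no hydrodynamic coupling through the solvent or
leaflet, no curvature, no lipid chemistry beyond one order parameter, a
field frozen on tracer timescales (justified by raft lifetimes far
exceeding the simulated window), and thermal noise taken as the recycling
spectrum above rather than a fluctuation–dissipation pair.

## Known limitations

* The Itô-no-correction convention means tracer steady states depend on
  the chosen stochastic calculus; this is documented, intended model
  behavior, and switching to a corrected (isothermal) convention would
  remove the spontaneous Lo accumulation of force-free tracers.
* Explicit Euler limits the field step; a semi-implicit spectral stepper
  would allow larger steps but is not the reference scheme.
* Residence durations are quantized at the sampling interval; fits start
  at 5 intervals to suppress the resulting bias, and β recovers to
  ±0.1 under that choice in the parameter-recovery tests.
* The two-clock convention (field vs Langevin time) is inherited from
  the source parameterization and deliberately not unified; physical
  labels (ns, ms) are presentation only.
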