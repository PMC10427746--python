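# ldpf — Langevin dynamics coupled with the phase-field method

Mesoscale simulation of protein diffusion and partitioning in
heterogeneous, phase-separating cell membranes.

Cell membranes demix into liquid-ordered (Lo, raft-like, slow) and
liquid-disordered (Ld, fluid, fast) domains. A protein diffusing across
this pattern experiences a *fluctuating diffusivity*: it slows down in
rafts and speeds up outside them, which shapes its long-time transport
statistics and its steady-state localization. `ldpf` lets you build the
membrane pattern, diffuse tracers on it (or let them remodel it), and
measure the anomalous-diffusion observables used in single-particle
tracking, all on a desk-scale CPU budget.

## Model

**Membrane field.** The composition order parameter c(**r**, t)
(c < 0: Lo, c > 0: Ld) evolves by a modified Cahn–Hilliard equation

    ∂c/∂t = −(c − c_r)/τ_r + M ∇² (δF/δc) + η(r, t),
    F = ∫ { W²/2 [1 − αρ(r)] |∇c|² + Λc²/2 + c⁴/4 } dr,

with reduced temperature Λ, line tension W, optional coupling to a lipid
reservoir (τ_r, c_r), optional pinning by immobile proteins ρ(**r**), and
spectrally colored lipid-recycling noise η with amplitude
A(q) = (HΔt/Δx)·l|q|/(1 + q²l²). Five canonical parameter sets
(models 1–5) produce raft patterns by critical fluctuations, interface
pinning, miscible/immiscible mixing and reservoir exchange.

**Tracers.** Each tracer obeys an overdamped Langevin equation with
field-dependent diffusivity (Itô convention, no spurious-drift
correction),

    dr/dt = −(D(r)/k_BT) dU/dl + √(2 D(r)) w(t),
    D(r) = (c_b + c̄(r)) D₀,

where c̄ ∈ [0, 1] is the min-max-normalized field (c̄ < 0.5 is Lo), U is
a truncated Lennard-Jones pair potential (crowding), and domain
preference is a probabilistic one-way reflection: a move leaving the
preferred domain is rejected with probability χ%.

**Two-way coupling.** Optionally the particles feed back on the field
through a short-ranged kernel g(r) = α_g (r ≤ σ),
α_g·exp(−(r−σ)/r_g) (r > σ) added to the chemical potential, so protein
clusters nucleate and extend Lo nanodomains.

**Statistics.** Time-averaged MSD (TAMSD), its ensemble relative
standard deviation (RSD, the ergodicity probe), local power-law
exponents α(Δ), Lo/Ld residence times with censoring-aware truncated
power-law MLE (P(t) ∝ t^−β e^(−t/τ)), confinement ratios, and the exact
1-D first-passage-time density |x|e^(−x²/4Dt)/√(4πDt³) as an analytic
reference.

## Worked example

Equilibrate the reservoir-coupled membrane (model 5) on a reduced
128×128 grid, diffuse one free tracer ensemble on it, and fit the
residence-time distribution:

```python
import ldpf

state = ldpf.equilibrate_model(5, L=128, seed=1)       # ~2.5 min
field = ldpf.normalize_field(state)
print(f"Lo area fraction: {field.lo_area_fraction():.3f}")

sys_ = ldpf.ParticleSystem(Np=24, epsilon=0.0, cb=1.0, D0=1.0)
traj = ldpf.run_simulation(field, sys_, n_steps=250_000,
                           n_discard=50_000, sample_every=1, seed=5)
res = ldpf.residence_times(traj, field)
fit = ldpf.fit_truncated_powerlaw(res.durations(),
                                  sampling_interval=traj.sampling_interval)
print(f"uncensored samples: {len(res.durations())}")
print(f"tail exponent beta = {fit.beta:.2f}, cutoff tau = {fit.tau:.3g}")
```

Output:

```
Lo area fraction: 0.368
uncensored samples: 16945
tail exponent beta = 1.51, cutoff tau = 85.1
```

The tail exponent ≈ 1.5 is the signature of first-passage-controlled
domain escape (compare the 1-D closed form, slope −1.5); the exponential
cutoff reflects the finite raft size. Time is in Langevin units
(1 unit = 1 µs at the physical calibration dt = 10⁻³ ↔ 1 ns), so
τ ≈ 85 corresponds to ≈ 0.085 ms.

The same pipeline is scriptable from the shell:

```bash
ldpf field --model 5 --grid-l 128 --seed 1 --out field.h5
ldpf run --field field.h5 --np 512 --eps 2.0 --pref Lo40 \
         --steps 1e6 --discard 2e5 --sample-every 50 --seed 7 --out traj.h5
ldpf analyze alpha --traj traj.h5 --out alpha.csv
```

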