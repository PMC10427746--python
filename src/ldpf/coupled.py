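"""Two-way coupling: diffusing particles reshape the membrane field.

Extends the frozen-field tracer dynamics to the regime where proteins
modify the composition around them.  The field obeys the conservative
Cahn–Hilliard form

    dc/dt = div{ M grad[ -lap(c) + Lambda*c + c^3 + g(r, t) ] } + eta(r, t)

where the short-ranged protein–lipid interaction kernel

    g(r) = alpha_g                       for r <= sigma,
           alpha_g * exp(-(r - sigma)/r_g)  for r > sigma,

is summed over the instantaneous particle positions.  A positive
``alpha_g`` raises the local chemical potential under a particle, which
drives composition out of the particle neighborhood and nucleates an
ordered (Lo, c < 0) patch there: clustered proteins create and extend
raft-like nanodomains even above the spontaneous-demixing point
(Lambda close to 0-).

Clock convention: the field advances by one Cahn–Hilliard step of
``field_dt`` after every ``update_stride`` Langevin steps (default 10).
The two time steps (0.005 field units vs 1e-3 Langevin units) come from
different unit systems and are deliberately kept as separate dimensionless
clocks.

Normalization while the field develops: before the field has contrast,
cbar is a running min-max of the current field; once max - min exceeds
1.0 the affine map is frozen (further excursions clip), so the
diffusivity scale does not drift during the production phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .phasefield import (FieldState, ModelParams, NormalizedField,
                         chemical_potential, laplacian, recycling_noise)
from .tracers import (OverlapError, ParticleSystem, StepSizeError,
                      TrajectorySet, insert_positions)

__all__ = [
    "CouplingParams",
    "protein_field_source",
    "step_coupled_field",
    "run_coupled",
]

#: Relative level at which the exponential tail of g is truncated.
_G_TRUNC = 1.0e-6

#: Field contrast (max - min of c) at which the normalization freezes.
_FREEZE_CONTRAST = 1.0


@dataclass(frozen=True)
class CouplingParams:
    """Parameters of the particle-to-field coupling.

    ``alpha_g`` is the field-modification intensity, ``r_g`` the
    relaxation length of the kernel tail; the field is stepped once per
    ``update_stride`` Langevin steps with time step ``field_dt``.
    """

    alpha_g: float = 0.5
    r_g: float = 2.0
    update_stride: int = 10
    field_dt: float = 0.005

    def __post_init__(self):
        if self.r_g <= 0:
            raise ValueError("r_g must be positive")
        if self.update_stride < 1:
            raise ValueError("update_stride must be >= 1")


def truncation_radius(coupling: CouplingParams, sigma: float) -> float:
    """Radius where the kernel tail falls below 1e-6 of alpha_g."""
    return sigma + coupling.r_g * np.log(1.0 / _G_TRUNC)


def protein_field_source(positions, coupling: CouplingParams, sigma: float,
                         L: int, dx: float = 1.0) -> np.ndarray:
    """Sum of the piecewise protein kernel g over particles, on the grid.

    Distances are periodic minimum-image; the exponential tail is
    truncated where it falls below ``1e-6 * alpha_g``.  Falls back to a
    dense minimum-image evaluation when the truncation window does not
    fit in the box.
    """
    grid = np.zeros((L, L))
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0 or coupling.alpha_g == 0.0:
        return grid
    positions = np.atleast_2d(positions)
    r_t = truncation_radius(coupling, sigma)
    box = L * dx
    if 2 * (int(np.ceil(r_t / dx)) + 1) + 1 < L:
        _kernels.deposit_source(positions, grid, coupling.alpha_g,
                                coupling.r_g, sigma, dx, box, r_t)
        return grid
    coords = np.arange(L) * dx
    for px, py in positions:
        ddx = coords - px
        ddx -= box * np.round(ddx / box)
        ddy = coords - py
        ddy -= box * np.round(ddy / box)
        r = np.sqrt(ddx[:, None]**2 + ddy[None, :]**2)
        g = np.where(r <= sigma, coupling.alpha_g,
                     coupling.alpha_g * np.exp(-(r - sigma) / coupling.r_g))
        grid += np.where(r <= r_t, g, 0.0)
    return grid


def step_coupled_field(state: FieldState, g: np.ndarray, params: ModelParams,
                       coupling: CouplingParams | None = None) -> FieldState:
    """One Cahn–Hilliard step with the particle source in the potential.

    mu = -lap(c) + Lambda*c + c^3 + g  (W = 1, no pinning, no reservoir),
    advanced in conservative form c += dt * div(M grad mu) + eta.  The
    spatial mean of c is exactly conserved when H = 0 (and the recycling
    noise itself carries no zero mode).  Uses ``coupling.field_dt`` when
    given, else ``params.dt_field``.
    """
    if params.alpha != 0:
        raise ValueError("coupled stepping assumes no immobile-protein pinning")
    if g.shape != state.c.shape:
        raise ValueError("source grid g must match the field grid")
    dt = params.dt_field if coupling is None else coupling.field_dt
    mu = chemical_potential(state.c, params) + g
    c_new = state.c + dt * params.M * laplacian(mu, params.dx)
    if params.H > 0:
        c_new += recycling_noise(params, state.rng)
    return FieldState(c=c_new, t=state.t + dt, rng=state.rng,
                      imp_positions=state.imp_positions)


def _normalizer(c: np.ndarray, frozen: NormalizedField | None,
                dx: float) -> tuple[NormalizedField, NormalizedField | None]:
    """Running min-max before freeze, frozen affine map after."""
    if frozen is not None:
        return frozen.renormalize(c), frozen
    c_min, c_max = float(np.min(c)), float(np.max(c))
    if c_max - c_min <= 0:
        # pathological flat start; map everything to mid-range
        nf = NormalizedField(cbar=np.full_like(c, 0.5), c_min=c_min,
                             c_max=c_min + 1.0, dx=dx)
        return nf, None
    nf = NormalizedField.from_raw(c, dx=dx)
    if c_max - c_min >= _FREEZE_CONTRAST:
        return nf, nf
    return nf, None


def run_coupled(params: ModelParams, coupling: CouplingParams,
                sys: ParticleSystem, n_steps: int, seed: int = 0,
                n_discard: int = 0, sample_every: int | None = None,
                snapshot_every: int | None = None, init_mean: float = 0.0,
                ) -> tuple[TrajectorySet, list[tuple[float, np.ndarray]]]:
    """Interleaved Langevin / Cahn–Hilliard run with two-way coupling.

    Starts from a homogeneous Gaussian field c ~ N(init_mean, 1) and
    particle positions drawn uniformly (hard-core adjusted when
    interacting).  Every ``update_stride`` Langevin steps the particle
    source g is recomputed and one field step applied; particles then
    diffuse on the re-normalized field.  ``sample_every`` (trajectory
    recording) and ``snapshot_every`` (field snapshots) are in Langevin
    steps and must be multiples of the stride; ``n_discard`` shifts the
    start of trajectory recording.  A single NumPy generator seeded with
    ``seed`` drives the initial field, the particle insertion, the
    per-block Langevin noise and the field noise, in that fixed order, so
    runs are exactly reproducible.

    Returns the trajectory set and a list of (Langevin time, c-field copy)
    snapshots (always including the final field).
    """
    stride = coupling.update_stride
    if n_steps % stride != 0:
        raise ValueError("n_steps must be a multiple of the update stride")
    if sample_every is None:
        sample_every = stride
    for name, val in (("sample_every", sample_every),
                      ("snapshot_every", snapshot_every or stride)):
        if val % stride != 0:
            raise ValueError(f"{name} must be a multiple of the update stride")
    if n_discard % stride != 0:
        raise ValueError("n_discard must be a multiple of the update stride")

    rng = np.random.default_rng(seed)
    L, dx = params.L, params.dx
    box = L * dx
    c = init_mean + rng.standard_normal((L, L))
    state = FieldState(c=c, t=0.0, rng=rng)

    if sys.positions is None:
        if sys.epsilon > 0:
            sys.positions = insert_positions(sys.Np, box, 0.9 * sys.sigma, rng)
        else:
            sys.positions = rng.uniform(0.0, box, size=(sys.Np, 2))
        sys.unwrapped = sys.positions.copy()

    frozen: NormalizedField | None = None
    nf, frozen = _normalizer(state.c, frozen, dx)

    n_samples = (n_steps - n_discard) // sample_every + 1
    out = np.empty((n_samples, sys.Np, 2))
    rec = 0
    snapshots: list[tuple[float, np.ndarray]] = []
    chi = sys.preference.chi / 100.0

    def maybe_record(step):
        nonlocal rec
        if step >= n_discard and (step - n_discard) % sample_every == 0 and rec < n_samples:
            out[rec] = sys.unwrapped
            rec += 1
        if snapshot_every is not None and step % snapshot_every == 0:
            snapshots.append((step * sys.dt, state.c.copy()))

    maybe_record(0)
    n_blocks = n_steps // stride
    for b in range(n_blocks):
        xi = rng.standard_normal((stride, sys.Np, 2))
        u = rng.random((stride, sys.Np))
        err = _kernels.langevin_block(
            sys.positions, sys.unwrapped, np.ascontiguousarray(nf.cbar),
            dx, box, sys.cb, sys.D0, sys.kBT, sys.dt,
            sys.epsilon, sys.sigma, sys.r_cut, sys.preference.code, chi, xi, u)
        if err == _kernels.ERR_OVERLAP:
            raise OverlapError("particle overlap below hard floor during coupled run")
        if err == _kernels.ERR_STEP_TOO_LARGE:
            raise StepSizeError("single-step displacement exceeded half the box")
        g = protein_field_source(sys.positions, coupling, sys.sigma, L, dx)
        state = step_coupled_field(state, g, params, coupling)
        nf, frozen = _normalizer(state.c, frozen, dx)
        maybe_record((b + 1) * stride)

    if not snapshots or snapshots[-1][1] is not state.c:
        snapshots.append((n_steps * sys.dt, state.c.copy()))
    times = np.arange(n_samples) * sample_every * sys.dt
    meta = dict(seed=seed, n_steps=n_steps, n_discard=n_discard,
                sample_every=sample_every, alpha_g=coupling.alpha_g,
                r_g=coupling.r_g, stride=stride, Lambda=params.Lambda,
                init_mean=init_mean)
    traj = TrajectorySet(times=times, positions=out,
                         sampling_interval=sample_every * sys.dt, box=box,
                         metadata=meta)
    return traj, snapshots
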