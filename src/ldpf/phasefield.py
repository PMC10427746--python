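"""Cahn–Hilliard dynamics of phase-separating membrane composition fields.

The membrane is described by an order parameter ``c(r, t)`` — the local
deviation of the lipid composition from the critical composition — evolved
on a periodic square grid by a modified Cahn–Hilliard equation

    dc/dt = -(c - c_r)/tau_r + M * lap(dF/dc) + eta(r, t)

with the Ginzburg–Landau free energy

    F = integral{ W^2/2 * [1 - alpha*rho(r)] * |grad c|^2
                  + Lambda*c^2/2 + c^4/4 } dr.

``Lambda`` is the reduced temperature (negative below the demixing critical
point), ``W`` sets the line tension, the ``tau_r`` term couples the leaflet
to a lipid reservoir of composition ``c_r``, ``rho(r)`` is the density of
immobile membrane proteins that locally soften the line tension (pinning),
and ``eta`` is a spectrally colored "recycling" noise representing lipid
turnover on a length scale ``l``.  Five canonical parameter sets (models
1–5) cover raft formation by critical fluctuations, interface pinning,
miscible and immiscible mixtures, and reservoir coupling.

Regions with ``c < 0`` are the ordered, raft-like Lo phase; ``c > 0`` is
the disordered Ld phase.  Tracer dynamics (see :mod:`ldpf.tracers`) read
the field through its min-max normalization ``cbar`` in [0, 1].

Numerics: explicit Euler with a centered 5-point periodic Laplacian,
``dx = 1``, ``dt = 0.005`` (stable: dt < dx^4 / (8*M*W^2)).  The gradient
term with spatially varying coefficient is discretized in divergence
(flux) form, which is the exact functional derivative of F and conserves
mass together with the outer Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "ModelParams",
    "FieldState",
    "NormalizedField",
    "FieldInstabilityError",
    "MODEL_TABLE",
    "model_params",
    "chemical_potential",
    "immobile_protein_density",
    "recycling_noise",
    "step_field",
    "equilibrate",
    "equilibrate_model",
    "normalize_field",
    "classify_phase_regime",
]

#: Absolute bound on |c| beyond which the explicit integrator is declared
#: unstable.  Physical fields stay within a few units of the binodal (~1).
BLOWUP_BOUND = 1.0e3

#: Default grid side (cells) — a 256 nm x 256 nm membrane patch at 1 nm
#: lattice spacing.
DEFAULT_L = 256

#: Reference per-model parameters: tau_r, Lambda, recycling length l,
#: noise amplitude H, pinning strength alpha, number of immobile proteins,
#: equilibration step count (at the reference 256^2 grid).
MODEL_TABLE = {
    1: dict(tau_r=np.inf, Lambda=-0.001, l_rec=0.1, H=0.0283, alpha=0.0,
            N_imp=0, n_steps=24_000),
    2: dict(tau_r=np.inf, Lambda=-1.0, l_rec=1.0, H=0.85, alpha=1.0 / np.pi,
            N_imp=1500, n_steps=1_500_000),
    3: dict(tau_r=np.inf, Lambda=10.0, l_rec=1280.0, H=0.85, alpha=0.0,
            N_imp=0, n_steps=180),
    4: dict(tau_r=np.inf, Lambda=-1.0, l_rec=1280.0, H=0.85, alpha=0.0,
            N_imp=0, n_steps=24_000),
    5: dict(tau_r=500.0, Lambda=-1.0, l_rec=0.1, H=2.12, alpha=0.0,
            N_imp=0, n_steps=720_000),
}


class FieldInstabilityError(RuntimeError):
    """Raised when the field develops non-finite or runaway values."""


@dataclass(frozen=True)
class ModelParams:
    """All parameters of one membrane phase-field model.

    Shared constants across the five reference models: ``c_r = 0.3``,
    ``M = 1``, ``sigma_imp = 1/2``, ``W = 1``.  ``tau_r = inf`` disables
    the reservoir term.
    """

    tau_r: float = np.inf      # reservoir relaxation time
    c_r: float = 0.3           # reservoir composition
    M: float = 1.0             # mobility
    Lambda: float = -1.0       # reduced temperature
    W: float = 1.0             # line-tension coefficient
    alpha: float = 0.0         # pinning strength
    N_imp: int = 0             # number of immobile proteins
    sigma_imp: float = 0.5     # immobile-protein width
    l_rec: float = 0.1         # lipid recycling length
    H: float = 0.0             # recycling-noise amplitude
    n_steps: int = 0           # reference equilibration step count
    dt_field: float = 0.005    # field time step
    dx: float = 1.0            # lattice spacing
    L: int = DEFAULT_L         # grid side length in cells

    def __post_init__(self):
        if self.M <= 0:
            raise ValueError(f"mobility M must be positive, got {self.M}")
        if self.W < 0:
            raise ValueError(f"line-tension coefficient W must be >= 0, got {self.W}")
        if self.dx <= 0 or self.dt_field <= 0:
            raise ValueError("dx and dt_field must be positive")
        if self.L < 2 or (self.L & (self.L - 1)) != 0:
            raise ValueError(f"grid side L must be a power of two, got {self.L}")
        if self.H < 0:
            raise ValueError(f"noise amplitude H must be >= 0, got {self.H}")
        if self.alpha != 0 and self.N_imp <= 0:
            raise ValueError("pinning (alpha != 0) requires N_imp > 0")


@dataclass
class FieldState:
    """A composition field ``c`` with its clock and random generator.

    ``rng`` is advanced in place by :func:`step_field`; two states obtained
    from the same seed and parameter set evolve bit-identically.  ``rho``
    caches the immobile-protein density grid (model 2), derived from
    ``imp_positions`` on first use.
    """

    c: np.ndarray
    t: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    imp_positions: np.ndarray | None = None
    rho: np.ndarray | None = None


def model_params(model_id: int, L: int = DEFAULT_L, n_steps: int | None = None,
                 **overrides) -> ModelParams:
    """Build :class:`ModelParams` for one of the reference models 1–5.

    When the grid is reduced from the reference 256 cells, the default
    equilibration step count shrinks with the grid area (diffusive
    scaling); pass ``n_steps`` to override.
    """
    if model_id not in MODEL_TABLE:
        raise KeyError(f"model_id must be one of {sorted(MODEL_TABLE)}, got {model_id}")
    base = dict(MODEL_TABLE[model_id])
    if n_steps is None:
        n_steps = max(1, round(base["n_steps"] * (L / DEFAULT_L) ** 2))
    base["n_steps"] = n_steps
    if model_id == 2 and L != DEFAULT_L and "N_imp" not in overrides:
        base["N_imp"] = max(1, round(base["N_imp"] * (L / DEFAULT_L) ** 2))
    base.update(overrides)
    return ModelParams(L=L, **base)


# ----------------------------------------------------------------------
# Spatial operators
# ----------------------------------------------------------------------

def laplacian(a: np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Centered 5-point periodic Laplacian."""
    return (np.roll(a, 1, 0) + np.roll(a, -1, 0)
            + np.roll(a, 1, 1) + np.roll(a, -1, 1) - 4.0 * a) / dx**2


def _div_k_grad(c: np.ndarray, k: np.ndarray, dx: float) -> np.ndarray:
    """div(k grad c) in flux form with face-averaged coefficients."""
    out = np.zeros_like(c)
    for axis in (0, 1):
        cp = np.roll(c, -1, axis)
        cm = np.roll(c, 1, axis)
        kp = 0.5 * (k + np.roll(k, -1, axis))
        km = 0.5 * (k + np.roll(k, 1, axis))
        out += (kp * (cp - c) - km * (c - cm)) / dx**2
    return out


def chemical_potential(c: np.ndarray, params: ModelParams,
                       rho: np.ndarray | None = None) -> np.ndarray:
    """Functional derivative dF/dc of the Ginzburg–Landau free energy.

    Returns ``-div(W^2 [1 - alpha*rho] grad c) + Lambda*c + c^3``.  ``rho``
    is required exactly when ``params.alpha != 0``.
    """
    if not np.all(np.isfinite(c)):
        raise FieldInstabilityError(
            "non-finite values in c: the field has blown up "
            f"(max |finite c| = {np.nanmax(np.abs(c[np.isfinite(c)]), initial=0.0):g})")
    if params.alpha != 0:
        if rho is None:
            raise ValueError("rho grid required when alpha != 0")
        k = params.W**2 * (1.0 - params.alpha * rho)
        grad_term = -_div_k_grad(c, k, params.dx)
    else:
        if rho is not None:
            raise ValueError("rho given but alpha == 0")
        grad_term = -params.W**2 * laplacian(c, params.dx)
    return grad_term + params.Lambda * c + c**3


def immobile_protein_density(positions, sigma_imp: float, L: int,
                             dx: float = 1.0) -> np.ndarray:
    """Gaussian density of immobile membrane proteins on the grid.

    rho(r) = (pi sigma_imp^2)^(-1) * sum_i exp(-|r - r_i|^2 / 2 sigma_imp^2)

    with periodic minimum-image distances.  Each Gaussian is truncated at
    6 sigma (relative error < 2e-8).  An empty position list yields the
    zero grid.
    """
    rho = np.zeros((L, L))
    positions = np.atleast_2d(np.asarray(positions, dtype=float)) if len(positions) else None
    if positions is None:
        return rho
    pref = 1.0 / (np.pi * sigma_imp**2)
    w = int(np.ceil(6.0 * sigma_imp / dx)) + 1
    if 2 * w + 1 >= L:
        coords = np.arange(L) * dx
        box = L * dx
        for px, py in positions:
            ddx = coords - px
            ddx -= box * np.round(ddx / box)
            ddy = coords - py
            ddy -= box * np.round(ddy / box)
            r2 = ddx[:, None]**2 + ddy[None, :]**2
            rho += pref * np.where(r2 <= (6 * sigma_imp)**2,
                                   np.exp(-r2 / (2 * sigma_imp**2)), 0.0)
        return rho
    offs = np.arange(-w, w + 1)
    for px, py in positions:
        i0 = int(np.floor(px / dx))
        j0 = int(np.floor(py / dx))
        ddx = (i0 + offs) * dx - px
        ddy = (j0 + offs) * dx - py
        r2 = ddx[:, None]**2 + ddy[None, :]**2
        block = pref * np.where(r2 <= (6 * sigma_imp)**2,
                                np.exp(-r2 / (2 * sigma_imp**2)), 0.0)
        ii = (i0 + offs) % L
        jj = (j0 + offs) % L
        rho[np.ix_(ii, jj)] += block
    return rho


@lru_cache(maxsize=8)
def _noise_amplitude(params: ModelParams) -> np.ndarray:
    """Spectral amplitude A(q) = (H dt/dx) * l|q| / (1 + q^2 l^2), rfft layout."""
    qx = 2.0 * np.pi * np.fft.fftfreq(params.L, d=params.dx)
    qy = 2.0 * np.pi * np.fft.rfftfreq(params.L, d=params.dx)
    q = np.sqrt(qx[:, None]**2 + qy[None, :]**2)
    lq = params.l_rec * q
    return (params.H * params.dt_field / params.dx) * lq / (1.0 + lq**2)


def recycling_noise(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """One grid of spectrally colored lipid-recycling noise.

    White unit Gaussian noise is drawn per cell, filtered in wavevector
    space by ``A(q) = (H dt/dx) l|q|/(1 + q^2 l^2)`` and transformed back.
    A(0) = 0, so every sample has exactly zero spatial mean and the noise
    never changes the total composition.  The dt factor of the amplitude is
    the full per-step magnitude: callers add the returned grid once per
    Euler step without another dt multiplication.
    """
    if params.H < 0:
        raise ValueError("noise amplitude H must be >= 0")
    if params.H == 0:
        return np.zeros((params.L, params.L))
    xi = rng.standard_normal((params.L, params.L))
    return np.fft.irfft2(_noise_amplitude(params) * np.fft.rfft2(xi),
                         s=(params.L, params.L))


# ----------------------------------------------------------------------
# Time stepping
# ----------------------------------------------------------------------

def step_field(state: FieldState, params: ModelParams) -> FieldState:
    """One explicit-Euler Cahn–Hilliard step.

    c <- c + dt * [-(c - c_r)/tau_r + M lap(mu)] + eta,

    with ``mu`` from :func:`chemical_potential` and ``eta`` from
    :func:`recycling_noise` (already carrying its dt factor).  The
    reservoir term vanishes for ``tau_r = inf``.  Returns a new state with
    the clock advanced by ``dt_field``; ``state.rng`` is shared and
    advanced in place.
    """
    c = state.c
    peak = np.max(np.abs(c))
    if not np.isfinite(peak) or peak > BLOWUP_BOUND:
        raise FieldInstabilityError(
            f"field instability at t = {state.t:g} (step {round(state.t / params.dt_field)}): "
            f"max |c| = {peak:g} exceeds {BLOWUP_BOUND:g}")
    rho = state.rho
    if params.alpha != 0 and rho is None:
        if state.imp_positions is None:
            raise ValueError("alpha != 0 requires immobile protein positions")
        rho = immobile_protein_density(state.imp_positions, params.sigma_imp,
                                       params.L, params.dx)
    mu = chemical_potential(c, params, rho)
    dcdt = params.M * laplacian(mu, params.dx)
    if np.isfinite(params.tau_r):
        dcdt -= (c - params.c_r) / params.tau_r
    c_new = c + params.dt_field * dcdt
    if params.H > 0:
        c_new += recycling_noise(params, state.rng)
    return FieldState(c=c_new, t=state.t + params.dt_field, rng=state.rng,
                      imp_positions=state.imp_positions, rho=rho)


def advance_field(state: FieldState, params: ModelParams, n_steps: int,
                  noise_batch: int = 256) -> FieldState:
    """Advance the field ``n_steps`` Euler steps with the compiled stepper.

    Applies the same discrete operators as :func:`step_field` (which is
    the readable per-step reference) through a compiled double loop, with
    the spectral noise generated and filtered in batches.  The random
    stream is consumed in exactly the per-step order, so results agree
    with repeated :func:`step_field` calls to rounding accuracy.
    """
    from . import _kernels

    L, dx, dt = params.L, params.dx, params.dt_field
    rho = state.rho
    uniform_k = params.alpha == 0
    if not uniform_k:
        if rho is None:
            if state.imp_positions is None:
                raise ValueError("alpha != 0 requires immobile protein positions")
            rho = immobile_protein_density(state.imp_positions, params.sigma_imp,
                                           L, dx)
        k = np.ascontiguousarray(params.W**2 * (1.0 - params.alpha * rho))
    else:
        k = np.zeros((1, 1))
    inv_tau = 1.0 / params.tau_r if np.isfinite(params.tau_r) else 0.0
    use_eta = params.H > 0
    A = _noise_amplitude(params) if use_eta else None
    c = np.ascontiguousarray(state.c, dtype=np.float64)
    buf = np.empty_like(c)
    mu = np.empty_like(c)
    eta0 = np.zeros((L, L))
    done = 0
    t = state.t
    while done < n_steps:
        m = min(noise_batch, n_steps - done)
        if use_eta:
            xi = state.rng.standard_normal((m, L, L))
            eta = np.fft.irfft2(A[None] * np.fft.rfft2(xi, axes=(1, 2)),
                                s=(L, L), axes=(1, 2))
        for j in range(m):
            peak = _kernels.euler_ch_step(
                c, k, uniform_k, params.W**2, params.Lambda, params.M,
                inv_tau, params.c_r, dt, 1.0 / dx**2,
                eta[j] if use_eta else eta0, use_eta, mu, buf)
            c, buf = buf, c
            t += dt
            if not np.isfinite(peak) or peak > BLOWUP_BOUND:
                raise FieldInstabilityError(
                    f"field instability at t = {t:g} (step {round(t / dt)}): "
                    f"max |c| = {peak:g} exceeds {BLOWUP_BOUND:g}")
        done += m
    return FieldState(c=c, t=t, rng=state.rng,
                      imp_positions=state.imp_positions, rho=rho)


def equilibrate(params: ModelParams, seed: int = 0,
                n_steps: int | None = None) -> FieldState:
    """Run a model from a homogeneous Gaussian start to its reference time.

    The initial field is i.i.d. Gaussian(0, 1) per cell; immobile proteins
    (if any) are placed uniformly at random once and stay fixed.
    """
    rng = np.random.default_rng(seed)
    c0 = rng.standard_normal((params.L, params.L))
    imp = None
    if params.N_imp > 0:
        imp = rng.uniform(0.0, params.L * params.dx, size=(params.N_imp, 2))
    state = FieldState(c=c0, t=0.0, rng=rng, imp_positions=imp)
    steps = params.n_steps if n_steps is None else n_steps
    return advance_field(state, params, steps)


def equilibrate_model(model_id: int, L: int = DEFAULT_L, seed: int = 0,
                      n_steps: int | None = None, **overrides) -> FieldState:
    """Equilibrate one of the five reference membrane models."""
    params = model_params(model_id, L=L, n_steps=n_steps, **overrides)
    return equilibrate(params, seed=seed)


# ----------------------------------------------------------------------
# Normalization and phase classification
# ----------------------------------------------------------------------

@dataclass
class NormalizedField:
    """Min-max normalized order parameter field, frozen as an affine map.

    ``cbar = clip((c - c_min) / (c_max - c_min), 0, 1)``.  The map is fixed
    at normalization time; applying it to a later field (two-way coupling)
    reuses the same coefficients, clipping any excursions.  ``cbar < 0.5``
    is Lo, ``cbar >= 0.5`` is Ld.
    """

    cbar: np.ndarray
    c_min: float
    c_max: float
    dx: float = 1.0
    threshold: float = 0.5

    @property
    def L(self) -> int:
        return self.cbar.shape[0]

    @property
    def box(self) -> float:
        return self.L * self.dx

    @classmethod
    def from_raw(cls, c: np.ndarray, dx: float = 1.0) -> "NormalizedField":
        c_min = float(np.min(c))
        c_max = float(np.max(c))
        if c_max - c_min <= 0:
            raise ValueError("degenerate normalization: field is constant")
        cbar = (c - c_min) / (c_max - c_min)
        return cls(cbar=cbar, c_min=c_min, c_max=c_max, dx=dx)

    def renormalize(self, c: np.ndarray) -> "NormalizedField":
        """Apply the frozen affine map to a new raw field (with clipping)."""
        cbar = np.clip((c - self.c_min) / (self.c_max - self.c_min), 0.0, 1.0)
        return replace(self, cbar=cbar)

    def interpolate(self, points, method: str = "bilinear") -> np.ndarray:
        """Evaluate cbar at continuous positions (periodic).

        ``method`` is "bilinear" (default) or "nearest".
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = pts / self.dx
        L = self.L
        if method == "nearest":
            idx = np.rint(g).astype(np.int64) % L
            out = self.cbar[idx[:, 0], idx[:, 1]]
        elif method == "bilinear":
            i0 = np.floor(g).astype(np.int64)
            f = g - np.floor(g)
            i0 %= L
            i1 = (i0 + 1) % L
            fx = f[:, 0]
            fy = f[:, 1]
            cb = self.cbar
            out = (cb[i0[:, 0], i0[:, 1]] * (1 - fx) * (1 - fy)
                   + cb[i1[:, 0], i0[:, 1]] * fx * (1 - fy)
                   + cb[i0[:, 0], i1[:, 1]] * (1 - fx) * fy
                   + cb[i1[:, 0], i1[:, 1]] * fx * fy)
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def lo_mask(self) -> np.ndarray:
        return self.cbar < self.threshold

    def lo_area_fraction(self) -> float:
        return float(np.mean(self.lo_mask()))


def normalize_field(state: FieldState, dx: float | None = None) -> NormalizedField:
    """Min-max normalize an equilibrated field to [0, 1] and freeze the map."""
    return NormalizedField.from_raw(state.c, dx=1.0 if dx is None else dx)


def classify_phase_regime(Lambda: float, c0: float) -> str:
    """Mean-field phase-separation regime of a uniform mixture.

    From the Landau free-energy density f = Lambda c^2/2 + c^4/4 (no
    pinning): outside the binodal |c0| >= sqrt(-Lambda) (or Lambda >= 0)
    the mixture is 'Mixed'; inside, it is linearly unstable ('Spinodal
    Decomposition') when f''(c0) = Lambda + 3 c0^2 < 0 and metastable
    ('Nucleation') otherwise.
    """
    if Lambda >= 0 or abs(c0) >= np.sqrt(-Lambda):
        return "Mixed"
    if Lambda + 3.0 * c0**2 < 0:
        return "Spinodal Decomposition"
    return "Nucleation"
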