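"""Langevin dynamics of tracer particles on a frozen membrane field.

A tracer at position r obeys the overdamped Langevin equation with
field-dependent fluctuating diffusivity

    dr/dt = -(D(r)/kBT) dU/dl + sqrt(2 D(r)) w(t),
    D(r)  = (cb + cbar(r)) * D0,

where ``cbar`` is the normalized composition of the membrane (0 in the
deepest Lo region, 1 in the deepest Ld region), so diffusion is slow in
ordered (raft) domains and fast in disordered ones.  With ``cb = 1``,
``D0 = 1`` (single-molecule convention) D fluctuates in [1, 2]; crowded
multi-particle systems use ``cb = 0.1``.  Pairwise interactions are
truncated Lennard-Jones; domain preference is a probabilistic one-way
reflection at the Lo/Ld boundary: a move that exits the preferred domain
is rejected with probability chi percent, moves into it always pass.

Integration is Euler–Maruyama in the Ito convention with the diffusivity
evaluated at the pre-move position and no spurious-drift correction.
This is deliberate and has a physical consequence: the stationary density
of a force-free tracer is proportional to 1/D(r), i.e. tracers accumulate
in the slow Lo phase even without any domain preference.

Internal units: length in nm (lattice spacing 1 nm), the Langevin time
step ``dt = 1e-3`` corresponds to 1 ns and ``D0 = 1`` to 1 um^2/s, so one
internal time unit is 1 microsecond.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernels
from .phasefield import NormalizedField

__all__ = [
    "PreferenceSpec",
    "ParticleSystem",
    "TrajectorySet",
    "OverlapError",
    "StepSizeError",
    "local_diffusivity",
    "lj_potential",
    "lj_pair_force",
    "apply_preference",
    "step_particles",
    "insert_positions",
    "run_simulation",
]

_PREF_CODE = {"none": 0, "Lo": 1, "Ld": 2}


class OverlapError(RuntimeError):
    """Two particles closer than the hard floor 1e-6 * sigma."""


class StepSizeError(RuntimeError):
    """A single-step displacement exceeded half the box."""


@dataclass(frozen=True)
class PreferenceSpec:
    """Domain preference: reject moves leaving ``domain`` with chi percent.

    ``domain`` is "none", "Lo" or "Ld"; ``chi`` in [0, 100].  "Lo40" style
    strings parse via :meth:`from_string`.  chi = 0 is identical to no
    preference.
    """

    domain: str = "none"
    chi: float = 0.0

    def __post_init__(self):
        if self.domain not in _PREF_CODE:
            raise ValueError(f"domain must be one of {list(_PREF_CODE)}, got {self.domain!r}")
        if not 0.0 <= self.chi <= 100.0:
            raise ValueError(f"chi must be in [0, 100] percent, got {self.chi}")

    @classmethod
    def from_string(cls, spec: str) -> "PreferenceSpec":
        """Parse "Lo40", "Ld80", "none" or "Lo0"."""
        if spec in (None, "", "none"):
            return cls()
        for dom in ("Lo", "Ld"):
            if spec.startswith(dom):
                return cls(domain=dom, chi=float(spec[len(dom):] or 0))
        raise ValueError(f"cannot parse preference spec {spec!r}")

    @property
    def code(self) -> int:
        return 0 if self.chi == 0 else _PREF_CODE[self.domain]


@dataclass
class ParticleSystem:
    """State and parameters of the interacting tracer ensemble.

    ``positions`` may be None, in which case :func:`run_simulation` draws
    initial positions itself (uniform, with a hard-core rejection pass for
    interacting particles).  ``r_cut`` defaults to 2.5 sigma, the
    conventional LJ truncation; the force there is ~1e-2 epsilon.
    """

    Np: int = 1
    positions: Optional[np.ndarray] = None
    epsilon: float = 0.0
    sigma: float = 3.0
    r_cut: Optional[float] = None
    cb: float = 1.0
    D0: float = 1.0
    kBT: float = 1.0
    dt: float = 1.0e-3
    preference: PreferenceSpec = dc_field(default_factory=PreferenceSpec)
    unwrapped: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.Np < 1:
            raise ValueError("Np must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.r_cut is None:
            self.r_cut = 2.5 * self.sigma
        if self.positions is not None:
            self.positions = np.array(self.positions, dtype=float)
            if self.positions.shape != (self.Np, 2):
                raise ValueError("positions must have shape (Np, 2)")
            if self.unwrapped is None:
                self.unwrapped = self.positions.copy()


@dataclass
class TrajectorySet:
    """Uniformly sampled, unwrapped tracer trajectories.

    ``positions`` has shape (n_times, Np, 2) and is continuous across the
    periodic boundary (no box jumps); wrap with ``wrapped()`` to recover
    box coordinates.  ``times`` starts at zero at the first recorded frame.
    """

    times: np.ndarray
    positions: np.ndarray
    sampling_interval: float
    box: float
    metadata: dict = dc_field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def n_times(self) -> int:
        return self.positions.shape[0]

    @property
    def measurement_time(self) -> float:
        return float(self.times[-1])

    def particle(self, i: int) -> np.ndarray:
        """(n_times, 2) unwrapped track of particle i."""
        return self.positions[:, i, :]

    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.box)


# ----------------------------------------------------------------------
# Elementary operations
# ----------------------------------------------------------------------

def local_diffusivity(pos, field: NormalizedField, cb: float, D0: float):
    """D = (cb + cbar(pos)) * D0, with cbar bilinearly interpolated."""
    c_here = field.interpolate(pos)
    D = (cb + np.asarray(c_here)) * D0
    if np.any(D <= 0):
        raise ValueError(
            f"nonpositive diffusivity: cb + cbar = {np.min(cb + np.asarray(c_here)):g} <= 0")
    return D if np.ndim(pos) > 1 else float(D)


def lj_potential(l, epsilon: float, sigma: float, r_cut: float | None = None):
    """Truncated (unshifted) Lennard-Jones pair potential U(l)."""
    l = np.asarray(l, dtype=float)
    s6 = (sigma / l) ** 6
    u = 4.0 * epsilon * (s6**2 - s6)
    if r_cut is not None:
        u = np.where(l > r_cut, 0.0, u)
    return u if u.ndim else float(u)


def lj_pair_force(l, epsilon: float, sigma: float, r_cut: float | None = None):
    """Signed radial force -dU/dl; positive = repulsive.

    Zero beyond ``r_cut`` (potential truncated, unshifted).  Distances
    below 1e-6 sigma raise :class:`OverlapError`.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 1.0e-6 * sigma):
        raise OverlapError(f"pair distance below hard floor 1e-6*sigma = {1e-6 * sigma:g}")
    s6 = (sigma / l) ** 6
    f = 24.0 * epsilon * (2.0 * s6**2 - s6) / l
    if r_cut is not None:
        f = np.where(l > r_cut, 0.0, f)
    return f if f.ndim else float(f)


def _pair_forces(pos: np.ndarray, box: float, epsilon: float, sigma: float,
                 r_cut: float) -> np.ndarray:
    """All-pairs minimum-image LJ forces (NumPy reference path)."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    r2 = np.sum(d**2, axis=-1)
    np.fill_diagonal(r2, np.inf)
    if np.any(r2 < (1.0e-6 * sigma) ** 2):
        raise OverlapError("particle overlap below hard floor 1e-6*sigma")
    mask = r2 < r_cut**2
    s2 = np.where(mask, sigma**2 / r2, 0.0)
    s6 = s2**3
    f_over_r2 = np.where(mask, 24.0 * epsilon * (2.0 * s6**2 - s6) / np.where(mask, r2, 1.0), 0.0)
    return np.sum(f_over_r2[:, :, None] * d, axis=1)


def apply_preference(old_pos, new_pos, field: NormalizedField,
                     pref: PreferenceSpec, rng: np.random.Generator):
    """Accept or reject proposed moves under the domain-preference rule.

    A move whose start lies in the preferred domain and whose end lies
    outside it is rejected (particle keeps ``old_pos``) with probability
    chi/100; every other move — including entry into the preferred domain —
    is always accepted (one-way wall).  Works on single positions or
    (N, 2) arrays; returns accepted positions of the same shape.
    """
    single = np.ndim(old_pos) == 1
    old = np.atleast_2d(np.asarray(old_pos, dtype=float))
    new = np.atleast_2d(np.asarray(new_pos, dtype=float))
    if pref.code == 0:
        out = new
    else:
        old_lo = field.interpolate(old) < field.threshold
        new_lo = field.interpolate(new) < field.threshold
        if pref.domain == "Lo":
            exits = old_lo & ~new_lo
        else:
            exits = ~old_lo & new_lo
        reject = exits & (rng.random(old.shape[0]) < pref.chi / 100.0)
        out = np.where(reject[:, None], old, new)
    return out[0] if single else out


def step_particles(sys: ParticleSystem, field: NormalizedField,
                   rng: np.random.Generator, noise: np.ndarray | None = None) -> ParticleSystem:
    """One Euler–Maruyama step (NumPy reference path); mutates ``sys``.

    delta_r = -(D/kBT) grad U dt + sqrt(2 D dt) xi, with D evaluated at the
    pre-move position, followed by the preference filter on the net
    proposed displacement.  ``noise`` overrides the Gaussian draw (testing
    hook, e.g. all-zero noise to probe force fixed points).  The production
    path for long runs is the compiled loop inside :func:`run_simulation`;
    this step is its readable, drop-in equivalent.
    """
    if sys.positions is None:
        raise ValueError("sys.positions must be set before stepping")
    box = field.box
    pos = sys.positions
    D = local_diffusivity(pos, field, sys.cb, sys.D0)
    if noise is None:
        noise = rng.standard_normal((sys.Np, 2))
    disp = np.sqrt(2.0 * D * sys.dt)[:, None] * noise
    if sys.epsilon > 0:
        F = _pair_forces(pos, box, sys.epsilon, sys.sigma, sys.r_cut)
        disp += (D / sys.kBT * sys.dt)[:, None] * F
    if np.any(np.abs(disp) > 0.5 * box):
        raise StepSizeError("single-step displacement exceeds half the box")
    proposed = np.mod(pos + disp, box)
    accepted = apply_preference(pos, proposed, field, sys.preference, rng)
    moved = np.any(accepted != pos, axis=1)
    sys.unwrapped = sys.unwrapped + np.where(moved[:, None], disp, 0.0)
    sys.positions = np.where(moved[:, None], accepted, pos)
    return sys


def insert_positions(n: int, box: float, d_min: float,
                     rng: np.random.Generator, max_tries: int = 2000) -> np.ndarray:
    """Uniform random positions with a minimum-image hard-core distance.

    Used to avoid unphysical overlap forces at t = 0 for interacting
    particles.  If a particle cannot be placed, ``d_min`` is relaxed by 10%
    and the insertion retried (dense systems).
    """
    pos = np.empty((n, 2))
    k = 0
    tries = 0
    while k < n:
        p = rng.uniform(0.0, box, size=2)
        if k > 0:
            d = pos[:k] - p
            d -= box * np.round(d / box)
            if np.min(np.sum(d**2, axis=1)) < d_min**2:
                tries += 1
                if tries > max_tries:
                    d_min *= 0.9
                    tries = 0
                continue
        pos[k] = p
        k += 1
        tries = 0
    return pos


def run_simulation(field: NormalizedField, sys: ParticleSystem, n_steps: int,
                   n_discard: int = 0, sample_every: int = 1, seed: int = 0,
                   engine: str = "numba") -> TrajectorySet:
    """Propagate the particle system and record unwrapped trajectories.

    If ``sys.positions`` is None, initial positions are drawn uniformly
    over the box (with hard-core rejection at 0.9 sigma for interacting
    particles).  The first ``n_discard`` steps are treated as relaxation:
    recording starts there, every ``sample_every`` steps, including the
    frame at the start of the recording window.  Fully reproducible from
    ``seed``; ``engine`` picks the compiled loop ("numba", default) or the
    per-step NumPy reference ("numpy").
    """
    if n_discard >= n_steps and n_steps > 0:
        raise ValueError("n_discard must be smaller than n_steps")
    box = field.box
    rng = np.random.default_rng(seed)
    if sys.positions is None:
        if sys.epsilon > 0:
            pos = insert_positions(sys.Np, box, 0.9 * sys.sigma, rng)
        else:
            pos = rng.uniform(0.0, box, size=(sys.Np, 2))
        sys.positions = pos
        sys.unwrapped = pos.copy()
    if sys.positions.shape != (sys.Np, 2):
        raise ValueError("positions shape does not match Np")
    n_samples = (n_steps - n_discard) // sample_every + 1
    if n_samples < 2:
        import warnings
        warnings.warn("trajectory has fewer than two samples; most statistics "
                      "will be undefined", stacklevel=2)
    out = np.empty((n_samples, sys.Np, 2))
    cbar = np.ascontiguousarray(field.cbar, dtype=np.float64)
    if np.any(sys.cb + cbar <= 0):
        raise ValueError("cb + cbar <= 0 somewhere on the grid: nonpositive diffusivity")
    chi = sys.preference.chi / 100.0
    if engine == "numba":
        kernel_seed = int(rng.integers(2**31 - 1))
        err = _kernels.run_langevin(
            sys.positions, sys.unwrapped, cbar, field.dx, box,
            sys.cb, sys.D0, sys.kBT, sys.dt, sys.epsilon, sys.sigma, sys.r_cut,
            sys.preference.code, chi, n_steps, n_discard, sample_every,
            kernel_seed, out)
        if err == _kernels.ERR_OVERLAP:
            raise OverlapError("particle overlap below hard floor during run")
        if err == _kernels.ERR_STEP_TOO_LARGE:
            raise StepSizeError("single-step displacement exceeded half the box")
    elif engine == "numpy":
        rec = 0
        for s in range(n_steps + 1):
            if s >= n_discard and (s - n_discard) % sample_every == 0 and rec < n_samples:
                out[rec] = sys.unwrapped
                rec += 1
            if s < n_steps:
                step_particles(sys, field, rng)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    times = np.arange(n_samples) * sample_every * sys.dt
    meta = dict(seed=seed, n_steps=n_steps, n_discard=n_discard,
                sample_every=sample_every, engine=engine,
                epsilon=sys.epsilon, sigma=sys.sigma, cb=sys.cb, D0=sys.D0,
                preference=f"{sys.preference.domain}{sys.preference.chi:g}")
    return TrajectorySet(times=times, positions=out,
                         sampling_interval=sample_every * sys.dt,
                         box=box, metadata=meta)
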