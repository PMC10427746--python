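"""Trajectory and field observables for heterogeneous-diffusion analysis.

Implements the full analysis suite used on tracer trajectories:

* TAMSD — the time-averaged mean squared displacement of one track,
  ``tamsd(D; t) = 1/(t - D) * integral_0^{t-D} |r(t' + D) - r(t')|^2 dt'``,
  estimated with all overlapping windows (stride 1).
* RSD — the relative standard deviation of TAMSDs across an ensemble at
  fixed lag, as a function of measurement time; the standard ergodicity
  probe (Brownian motion decays as t^-0.5, fluctuating-diffusivity models
  show a plateau before the decay).
* alpha(lag) — the local log-log slope of the ensemble-averaged TAMSD;
  values below 1 signal subdiffusion.
* Residence times in the Lo / Ld domains (cbar < 0.5 is Lo) via run-length
  encoding, with boundary runs flagged as censored, plus a maximum-
  likelihood fit of the truncated power law P(t) ~ t^-beta exp(-t/tau).
* The closed-form first-passage-time density of 1-D Brownian motion,
  P_x(t) = |x| exp(-x^2 / 4Dt) / sqrt(4 pi D t^3), whose t^-1.5 tail is
  the analytic reference for the residence-time statistics, together with
  a direct first-passage simulator.
* Confinement ratio — the fraction of particles inside the Lo domain per
  recorded frame.

All estimators are pure functions of their inputs (bootstrap resampling
is explicitly seeded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats as sp_stats

from . import _kernels
from .phasefield import NormalizedField
from .tracers import TrajectorySet

__all__ = [
    "TamsdCurve",
    "RsdCurve",
    "ResidenceSamples",
    "PowerLawFit",
    "tamsd",
    "ensemble_tamsd",
    "rsd",
    "local_alpha",
    "fit_alpha",
    "domain_label",
    "residence_times",
    "fit_truncated_powerlaw",
    "fpt_density_oracle",
    "fpt_cdf_oracle",
    "simulate_fpt",
    "confinement_ratio",
    "log_binned_density",
    "fit_tail_slope",
]


@dataclass
class TamsdCurve:
    """TAMSD values on a lag grid; ``values`` is (n_lags,) for a single
    trajectory or the ensemble mean (with ``n`` > 1)."""

    lags: np.ndarray
    values: np.ndarray
    measurement_time: float
    n: int = 1


@dataclass
class RsdCurve:
    """RSD of TAMSDs at fixed lag versus measurement time."""

    times: np.ndarray
    values: np.ndarray
    lag: float
    n: int


@dataclass
class ResidenceSamples:
    """Run-length-encoded domain visits of one trajectory.

    ``lo`` marks Lo-domain runs, ``duration`` is in time units
    (sample count times sampling interval) and ``censored`` flags the
    first and last runs, which touch the trajectory boundary and whose
    true length is unknown.
    """

    lo: np.ndarray
    duration: np.ndarray
    censored: np.ndarray

    def durations(self, domain: str | None = None, censored: bool = False) -> np.ndarray:
        """Durations filtered by domain ("Lo"/"Ld"/None) and censoring."""
        keep = np.ones(len(self.duration), dtype=bool)
        if not censored:
            keep &= ~self.censored
        if domain == "Lo":
            keep &= self.lo
        elif domain == "Ld":
            keep &= ~self.lo
        elif domain is not None:
            raise ValueError(f"domain must be 'Lo', 'Ld' or None, got {domain!r}")
        return self.duration[keep]

    @classmethod
    def concatenate(cls, parts) -> "ResidenceSamples":
        return cls(lo=np.concatenate([p.lo for p in parts]),
                   duration=np.concatenate([p.duration for p in parts]),
                   censored=np.concatenate([p.censored for p in parts]))


@dataclass
class PowerLawFit:
    """MLE of P(t) ~ t^-beta * exp(-t/tau) on [t_min, inf)."""

    beta: float
    tau: float
    t_min: float
    n: int
    beta_se: float = np.nan
    tau_se: float = np.nan


# ----------------------------------------------------------------------
# TAMSD / RSD / alpha
# ----------------------------------------------------------------------

def _as_positions(traj) -> tuple[np.ndarray, float]:
    """Normalize input to (n_times, n_particles, dim) plus sampling interval."""
    if isinstance(traj, TrajectorySet):
        return traj.positions, traj.sampling_interval
    arr = np.asarray(traj, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None, None]
    elif arr.ndim == 2:
        arr = arr[:, None, :]
    return arr, 1.0


def _lags_to_samples(lags, interval: float, n_times: int) -> np.ndarray:
    d = np.rint(np.asarray(lags, dtype=float) / interval).astype(np.int64)
    if np.any(d < 1) or np.any(d >= n_times):
        raise ValueError("each lag must be a positive multiple of the sampling "
                         "interval and smaller than the measurement time")
    return d


def _tamsd_matrix(pos: np.ndarray, d_samples: np.ndarray) -> np.ndarray:
    """(n_lags, n_particles) TAMSD over all overlapping windows."""
    out = np.empty((len(d_samples), pos.shape[1]))
    for k, d in enumerate(d_samples):
        diff = pos[d:] - pos[:-d]
        out[k] = np.mean(np.sum(diff**2, axis=-1), axis=0)
    return out


def tamsd(traj, lags, sampling_interval: float | None = None) -> TamsdCurve:
    """TAMSD of one trajectory at the requested lags (time units).

    ``traj`` is a (n, 2) / (n,) array or a single-particle
    :class:`~ldpf.tracers.TrajectorySet`; lags must be multiples of the
    sampling interval and smaller than the measurement time.
    """
    pos, interval = _as_positions(traj)
    if sampling_interval is not None:
        interval = sampling_interval
    if pos.shape[1] != 1:
        raise ValueError("tamsd() takes a single trajectory; "
                         "use ensemble_tamsd() for ensembles")
    d = _lags_to_samples(lags, interval, pos.shape[0])
    vals = _tamsd_matrix(pos, d)[:, 0]
    return TamsdCurve(lags=d * interval, values=vals,
                      measurement_time=(pos.shape[0] - 1) * interval, n=1)


def ensemble_tamsd(traj, lags=None, n_lags: int = 40) -> TamsdCurve:
    """Ensemble-averaged TAMSD over all particles of a trajectory set.

    Default lags: ``n_lags`` log-spaced multiples of the sampling interval
    up to a tenth of the measurement time.
    """
    pos, interval = _as_positions(traj)
    n = pos.shape[0]
    if lags is None:
        d_max = max(2, (n - 1) // 10)
        d = np.unique(np.rint(np.geomspace(1, d_max, n_lags)).astype(np.int64))
    else:
        d = _lags_to_samples(lags, interval, n)
    vals = _tamsd_matrix(pos, d).mean(axis=1)
    return TamsdCurve(lags=d * interval, values=vals,
                      measurement_time=(n - 1) * interval, n=pos.shape[1])


def rsd(traj, lag: float, times=None) -> RsdCurve:
    """RSD of TAMSDs at fixed lag versus measurement time.

    For every measurement time t the TAMSD of each trajectory truncated at
    t is recomputed at the given lag; the RSD is the population standard
    deviation over the ensemble divided by the ensemble mean.  ``times``
    defaults to every attainable measurement time; pass an array to
    subsample (e.g. log-spaced).
    """
    pos, interval = _as_positions(traj)
    n, n_traj = pos.shape[0], pos.shape[1]
    if n_traj < 2:
        raise ValueError("RSD needs at least 2 trajectories")
    d = int(_lags_to_samples([lag], interval, n)[0])
    sq = np.sum((pos[d:] - pos[:-d])**2, axis=-1)          # (n-d, n_traj)
    csum = np.cumsum(sq, axis=0)
    counts = np.arange(1, n - d + 1)[:, None]
    tamsds = csum / counts                                  # TAMSD at t=(k+d)*dt
    t_all = (np.arange(d + 1, n + 1) - 1) * interval
    if times is not None:
        idx = np.unique(np.clip(np.searchsorted(t_all, np.asarray(times)),
                                0, len(t_all) - 1))
    else:
        idx = np.arange(len(t_all))
    mean = tamsds[idx].mean(axis=1)
    std = tamsds[idx].std(axis=1)                           # population convention
    return RsdCurve(times=t_all[idx], values=std / mean, lag=d * interval, n=n_traj)


def local_alpha(lags, mean_tamsd, smooth_window: int = 3) -> np.ndarray:
    """Local power-law exponent alpha(lag) = d ln TAMSD / d ln lag.

    Centered differences on a (log-spaced) lag grid, then a short moving
    average (``smooth_window`` points, edge-reflected).  Requires at least
    3 lags and strictly positive TAMSD values.
    """
    lags = np.asarray(lags, dtype=float)
    m = np.asarray(mean_tamsd, dtype=float)
    if len(lags) < 3:
        raise ValueError("need at least 3 lags for a local slope")
    if np.any(m <= 0):
        raise ValueError("mean TAMSD must be strictly positive")
    a = np.gradient(np.log(m), np.log(lags))
    if smooth_window and smooth_window > 1:
        w = int(smooth_window)
        pad = np.pad(a, w // 2, mode="reflect")
        kern = np.ones(w) / w
        a = np.convolve(pad, kern, mode="valid")[: len(lags)]
    return a


def fit_alpha(lags, mean_tamsd, lag_min: float | None = None,
              lag_max: float | None = None) -> float:
    """Single power-law exponent by log-log least squares over a window."""
    lags = np.asarray(lags, dtype=float)
    m = np.asarray(mean_tamsd, dtype=float)
    keep = m > 0
    if lag_min is not None:
        keep &= lags >= lag_min
    if lag_max is not None:
        keep &= lags <= lag_max
    if np.count_nonzero(keep) < 2:
        raise ValueError("fit window contains fewer than 2 lags")
    slope, _ = np.polyfit(np.log(lags[keep]), np.log(m[keep]), 1)
    return float(slope)


# ----------------------------------------------------------------------
# Domains, residence times, heavy-tail fits
# ----------------------------------------------------------------------

def domain_label(pos, field: NormalizedField):
    """"Lo" where interpolated cbar < 0.5, "Ld" otherwise (ties to Ld)."""
    c = field.interpolate(pos)
    lab = np.where(np.atleast_1d(c) < field.threshold, "Lo", "Ld")
    return lab if np.ndim(pos) > 1 else str(lab[0])


def residence_times(traj, field: NormalizedField,
                    particle: int | None = None) -> ResidenceSamples:
    """Domain visit durations of trajectories via run-length encoding.

    Labels each frame Lo/Ld from the interpolated cbar at the wrapped
    position, encodes runs, and flags the first and last run of every
    trajectory as censored (their true duration extends beyond the
    observation window).  Durations are run length (sample count) times
    the sampling interval.  For multi-particle sets all tracks are pooled
    (runs never span track boundaries); pass ``particle`` to restrict.
    """
    if isinstance(traj, TrajectorySet):
        pos = traj.wrapped()
        interval = traj.sampling_interval
    else:
        pos, interval = _as_positions(traj)
        pos = np.mod(pos, field.box)
    idxs = range(pos.shape[1]) if particle is None else [particle]
    parts = []
    for i in idxs:
        lo = field.interpolate(pos[:, i, :]) < field.threshold
        change = np.flatnonzero(lo[1:] != lo[:-1])
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change, [len(lo) - 1]))
        dur = (ends - starts + 1).astype(float) * interval
        cens = np.zeros(len(dur), dtype=bool)
        cens[0] = True
        cens[-1] = True
        parts.append(ResidenceSamples(lo=lo[starts], duration=dur, censored=cens))
    return ResidenceSamples.concatenate(parts)


def _upper_gamma(s: float, x: float) -> float:
    """Generalized upper incomplete gamma Gamma(s, x), any real s, x > 0.

    Uses the downward recurrence Gamma(s, x) = (Gamma(s+1, x) -
    x^s e^-x) / s to reach positive s where scipy applies.
    """
    if s > 0:
        return float(special.gammaincc(s, x) * special.gamma(s))
    return (_upper_gamma(s + 1.0, x) - x**s * np.exp(-x)) / s


def fit_truncated_powerlaw(samples, t_min: float | None = None,
                           sampling_interval: float | None = None,
                           n_bootstrap: int = 0, seed: int = 0,
                           min_samples: int = 200) -> PowerLawFit:
    """Maximum-likelihood fit of P(t) ~ t^-beta exp(-t/tau) on [t_min, inf).

    ``t_min`` defaults to five sampling intervals (pass either one),
    discarding the resolution-limited shortest durations.  Bootstrap
    standard errors (seeded) are computed when ``n_bootstrap > 0``.
    beta ~ 1.5 is the hallmark of first-passage-controlled domain escape;
    beta -> 0 recovers a pure exponential.
    """
    t = np.sort(np.asarray(samples, dtype=float))
    if t_min is None:
        if sampling_interval is None:
            raise ValueError("give t_min or sampling_interval")
        t_min = 5.0 * sampling_interval
    t = t[t >= t_min]
    if len(t) < min_samples:
        raise ValueError(f"need at least {min_samples} samples above t_min "
                         f"for a stable heavy-tail fit, got {len(t)}")

    log_t_sum = np.sum(np.log(t))
    t_sum = np.sum(t)
    n = len(t)

    def nll(theta):
        beta, log_tau = theta
        tau = np.exp(log_tau)
        a = t_min / tau
        if a <= 0 or a > 700:
            return 1e300
        try:
            z = _upper_gamma(1.0 - beta, a)
        except (OverflowError, FloatingPointError):
            return 1e300
        if not np.isfinite(z) or z <= 0:
            return 1e300
        log_z = (1.0 - beta) * log_tau + np.log(z)
        return n * log_z + beta * log_t_sum + t_sum / tau

    def _fit(tvals):
        nonlocal log_t_sum, t_sum, n
        log_t_sum = np.sum(np.log(tvals))
        t_sum = np.sum(tvals)
        n = len(tvals)
        x0 = np.array([1.2, np.log(3.0 * np.mean(tvals))])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-5, fatol=1e-8, maxiter=2000))
        return res.x[0], np.exp(res.x[1])

    beta, tau = _fit(t)
    beta_se = tau_se = np.nan
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        bb, tt = [], []
        for _ in range(n_bootstrap):
            b, ta = _fit(rng.choice(t, size=len(t), replace=True))
            bb.append(b)
            tt.append(ta)
        beta_se = float(np.std(bb))
        tau_se = float(np.std(tt))
        beta, tau = _fit(t)  # restore sums and point estimate
    return PowerLawFit(beta=float(beta), tau=float(tau), t_min=float(t_min),
                       n=len(t), beta_se=beta_se, tau_se=tau_se)


# ----------------------------------------------------------------------
# First-passage oracle and simulator
# ----------------------------------------------------------------------

def fpt_density_oracle(x: float, D: float, t):
    """Closed-form FPT density of 1-D Brownian motion from 0 to level x.

    P_x(t) = |x| exp(-x^2 / 4Dt) / sqrt(4 pi D t^3); proportional to
    t^-1.5 for large t.  Normalized to 1 over t in (0, inf).
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if x == 0:
        raise ValueError("x must be nonzero")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    out = np.abs(x) * np.exp(-x**2 / (4.0 * D * t)) / np.sqrt(4.0 * np.pi * D * t**3)
    return out if out.ndim else float(out)


def fpt_cdf_oracle(x: float, D: float, t):
    """P(T <= t) = erfc(|x| / sqrt(4 D t)) for the 1-D Brownian FPT."""
    if D <= 0:
        raise ValueError("D must be positive")
    t = np.asarray(t, dtype=float)
    out = special.erfc(np.abs(x) / np.sqrt(4.0 * D * t))
    return out if out.ndim else float(out)


def simulate_fpt(n: int, x: float, D: float = 1.0, dt: float = 1.0e-3,
                 t_max: float = 1.0e3, seed: int = 0) -> np.ndarray:
    """Simulated first-passage times of ``n`` 1-D Brownian walkers.

    Euler steps with a Brownian-bridge crossing correction; walkers that
    have not passed level x by ``t_max`` are dropped from the returned
    array (the caller knows ``n`` for censoring-aware comparisons).
    """
    out = np.empty(n)
    _kernels.fpt_1d(n, float(abs(x)), float(D), float(dt), float(t_max),
                    int(seed) % (2**31 - 1), out)
    return out[out > 0]


# ----------------------------------------------------------------------
# Confinement and tail helpers
# ----------------------------------------------------------------------

def confinement_ratio(traj, field: NormalizedField) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of particles inside the Lo domain per recorded frame.

    Returns (times, ratio); the first recorded frame (t = 0, e.g. the
    random initial distribution) is included.
    """
    if isinstance(traj, TrajectorySet):
        pos = traj.wrapped()
        times = traj.times
    else:
        pos, interval = _as_positions(traj)
        pos = np.mod(pos, field.box)
        times = np.arange(pos.shape[0]) * interval
    n_t, n_p = pos.shape[0], pos.shape[1]
    flat = pos.reshape(n_t * n_p, 2)
    lo = (field.interpolate(flat) < field.threshold).reshape(n_t, n_p)
    return times, lo.mean(axis=1)


def log_binned_density(samples, bins_per_decade: int = 8,
                       t_range: tuple[float, float] | None = None,
                       n_total: int | None = None):
    """Normalized histogram density on logarithmic bins.

    ``n_total`` overrides the normalization count (e.g. to keep the density
    scale of a censored sample where some events exceeded the observation
    window).  Returns (bin centers, density), empty bins dropped.
    """
    s = np.asarray(samples, dtype=float)
    lo, hi = t_range if t_range is not None else (s.min(), s.max())
    n_bins = max(3, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(s, bins=edges)
    widths = np.diff(edges)
    norm = n_total if n_total is not None else len(s)
    dens = counts / (norm * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    return centers[keep], dens[keep]


def fit_tail_slope(t, density, t_range: tuple[float, float] | None = None) -> float:
    """Log-log slope of a density curve, optionally over a t window."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(density, dtype=float)
    keep = d > 0
    if t_range is not None:
        keep &= (t >= t_range[0]) & (t <= t_range[1])
    if np.count_nonzero(keep) < 3:
        raise ValueError("tail window contains fewer than 3 points")
    slope, _ = np.polyfit(np.log(t[keep]), np.log(d[keep]), 1)
    return float(slope)


def ks_distance_fpt(passages: np.ndarray, x: float, D: float,
                    t_max: float | None = None) -> float:
    """KS distance between simulated passages and the closed-form FPT law.

    When the simulation was capped at ``t_max``, both sides are compared
    conditional on T <= t_max.
    """
    if t_max is None:
        cdf = lambda t: fpt_cdf_oracle(x, D, t)
    else:
        f_cap = fpt_cdf_oracle(x, D, t_max)
        cdf = lambda t: np.asarray(fpt_cdf_oracle(x, D, t)) / f_cap
    res = sp_stats.kstest(passages, cdf)
    return float(res.statistic)
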