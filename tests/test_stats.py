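"""Estimators: TAMSD, RSD, local exponents, residence times, FPT oracle."""

import numpy as np
import pytest
from scipy import integrate

import ldpf
from ldpf import stats
from ldpf.tracers import TrajectorySet
from conftest import make_uniform


def brownian_tracks(n_traj, n_steps, D, dt=1.0, seed=0, dim=2):
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_steps, n_traj, dim)) * np.sqrt(2 * D * dt)
    pos = np.concatenate([np.zeros((1, n_traj, dim)), np.cumsum(steps, axis=0)])
    return TrajectorySet(times=np.arange(n_steps + 1) * dt, positions=pos,
                         sampling_interval=dt, box=np.inf)


class TestTamsd:
    def test_ballistic_hand_computed(self):
        curve = stats.tamsd(np.array([0.0, 1.0, 2.0, 3.0]), lags=[1, 2])
        assert curve.values[0] == pytest.approx(1.0)
        assert curve.values[1] == pytest.approx(4.0)

    def test_constant_trajectory_is_zero(self):
        curve = stats.tamsd(np.full(50, 2.5), lags=[1, 5, 10])
        assert np.all(curve.values == 0)

    def test_lag_must_be_below_measurement_time(self):
        with pytest.raises(ValueError):
            stats.tamsd(np.zeros(10), lags=[10])

    def test_brownian_ensemble_matches_4_d_lag(self):
        D = 0.7
        traj = brownian_tracks(200, 400, D, dt=0.5, seed=4)
        curve = stats.ensemble_tamsd(traj, lags=[0.5, 2.0, 8.0])
        # standard error of the ensemble TAMSD is well below 3%
        assert np.allclose(curve.values, 4 * D * curve.lags, rtol=0.05)

    def test_time_and_ensemble_averages_agree_for_brownian_motion(self):
        D = 1.0
        traj = brownian_tracks(300, 500, D, seed=9)
        ta = stats.ensemble_tamsd(traj, lags=[5.0]).values[0]
        ea = np.mean(np.sum((traj.positions[5] - traj.positions[0])**2, axis=-1))
        se = ea * np.sqrt(2 / 300)
        assert abs(ta - ea) < 3 * se


class TestRsd:
    def test_identical_trajectories_have_zero_rsd(self):
        base = np.cumsum(np.random.default_rng(0).standard_normal(100))
        pos = np.repeat(base[:, None, None], 5, axis=1)
        traj = TrajectorySet(times=np.arange(100.0), positions=pos,
                             sampling_interval=1.0, box=np.inf)
        curve = stats.rsd(traj, lag=1.0)
        assert np.allclose(curve.values, 0.0, atol=1e-12)

    def test_population_convention_on_two_known_tamsds(self):
        # ballistic tracks with per-step displacement 1 and sqrt(3) have
        # TAMSD(1) = 1 and 3 at every measurement time: RSD = sd/mean = 0.5
        n = 50
        pos = np.stack([np.arange(n, dtype=float),
                        np.sqrt(3.0) * np.arange(n)], axis=1)[:, :, None]
        traj = TrajectorySet(times=np.arange(float(n)), positions=pos,
                             sampling_interval=1.0, box=np.inf)
        curve = stats.rsd(traj, lag=1.0)
        assert np.allclose(curve.values, 0.5, atol=1e-12)

    def test_matches_bruteforce_recomputation(self):
        traj = brownian_tracks(6, 60, 1.0, seed=3)
        d = 2
        curve = stats.rsd(traj, lag=float(d))
        for k, t in enumerate(curve.times):
            m = int(round(t))
            vals = [stats.tamsd(traj.positions[: m + 1, i, :], lags=[d]).values[0]
                    for i in range(6)]
            expect = np.std(vals) / np.mean(vals)
            assert curve.values[k] == pytest.approx(expect, rel=1e-10)

    def test_needs_two_trajectories(self):
        traj = brownian_tracks(1, 50, 1.0)
        with pytest.raises(ValueError):
            stats.rsd(traj, lag=1.0)

    def test_two_state_diffusivity_shows_plateau_then_decay(self):
        # dichotomous D-switching: RSD plateaus on the residence timescale,
        # then decays ~ t^-0.5; the plateau grows with the D contrast
        def two_state(contrast, seed):
            rng = np.random.default_rng(seed)
            n_traj, n = 200, 4000
            state = rng.random(n_traj) < 0.5
            pos = np.zeros((n + 1, n_traj, 1))
            for s in range(n):
                D = np.where(state, 1.0, 1.0 / contrast)
                pos[s + 1] = pos[s] + (np.sqrt(2 * D) * rng.standard_normal(n_traj))[:, None]
                flip = rng.random(n_traj) < 1e-3   # mean residence 1000 steps
                state ^= flip
            return TrajectorySet(times=np.arange(n + 1.0), positions=pos,
                                 sampling_interval=1.0, box=np.inf)

        curves = {c: stats.rsd(two_state(c, seed=8), lag=1.0) for c in (2.0, 10.0)}
        for c, curve in curves.items():
            mid = curve.values[(curve.times > 50) & (curve.times < 500)]
            late_t = curve.times[curve.times > 100]
            late = curve.values[curve.times > 100]
            slope = np.polyfit(np.log(late_t), np.log(late), 1)[0]
            assert mid.std() / mid.mean() < 0.35      # plateau-like mid region
            assert slope < -0.2                        # decay sets in later
        mid_lo = curves[2.0].values[(curves[2.0].times > 50) & (curves[2.0].times < 500)]
        mid_hi = curves[10.0].values[(curves[10.0].times > 50) & (curves[10.0].times < 500)]
        assert mid_hi.mean() > mid_lo.mean()


class TestLocalAlpha:
    def test_exact_diffusive_input_gives_one(self):
        lags = np.geomspace(1, 100, 20)
        assert np.allclose(stats.local_alpha(lags, 4 * 0.5 * lags), 1.0, atol=1e-10)

    def test_exact_ballistic_input_gives_two(self):
        lags = np.geomspace(1, 100, 20)
        assert np.allclose(stats.local_alpha(lags, 2.0 * lags**2), 2.0, atol=1e-10)

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            stats.local_alpha([1, 2, 4], [1.0, 0.0, 2.0])

    def test_fit_alpha_recovers_exponent(self):
        lags = np.geomspace(0.1, 50, 30)
        assert stats.fit_alpha(lags, 3.0 * lags**0.85) == pytest.approx(0.85)


class TestDomains:
    @pytest.mark.parametrize("cbar,label", [
        (0.2, "Lo"), (0.5, "Ld"), (0.8, "Ld"),
    ])
    def test_threshold_convention(self, cbar, label):
        assert stats.domain_label((5.0, 5.0), make_uniform(cbar)) == label

    def test_run_length_encoding_with_censoring(self, stripe_field):
        # x < 32 reads Lo on the stripe; labels: Lo Lo Ld Ld Ld Lo
        x = np.array([10.0, 12.0, 40.0, 42.0, 44.0, 11.0])
        pos = np.stack([x, np.full(6, 5.0)], axis=1)
        res = stats.residence_times(pos, stripe_field)
        assert list(res.duration) == [2.0, 3.0, 1.0]
        assert list(res.censored) == [True, False, True]
        assert list(res.lo) == [True, False, True]
        assert list(res.durations()) == [3.0]

    def test_never_leaving_a_domain_yields_only_censored(self, stripe_field):
        pos = np.stack([np.full(30, 10.0), np.linspace(1, 50, 30)], axis=1)
        res = stats.residence_times(pos, stripe_field)
        assert len(res.durations(censored=True)) == 1
        assert len(res.durations()) == 0

    def test_pooling_never_merges_runs_across_trajectories(self, stripe_field):
        # particle 0 ends in Lo, particle 1 starts in Lo: pooled analysis
        # must not create an uncensored run spanning the join
        p0 = np.stack([np.array([40.0, 10.0, 10.0]), np.full(3, 5.0)], axis=1)
        p1 = np.stack([np.array([10.0, 10.0, 40.0]), np.full(3, 5.0)], axis=1)
        pos = np.stack([p0, p1], axis=1)
        traj = TrajectorySet(times=np.arange(3.0), positions=pos,
                             sampling_interval=1.0, box=64.0)
        pooled = stats.residence_times(traj, stripe_field)
        assert len(pooled.durations()) == 0
        assert len(pooled.durations(censored=True)) == 4


class TestTruncatedPowerlawFit:
    @staticmethod
    def sample_truncated_powerlaw(beta, tau, t_min, n, seed):
        """Rejection sampling: power-law proposals thinned by exp(-t/tau)."""
        rng = np.random.default_rng(seed)
        out = []
        while len(out) < n:
            u = rng.random(4 * n)
            t = t_min * u ** (-1.0 / (beta - 1.0))   # pure power-law tail
            keep = rng.random(4 * n) < np.exp(-t / tau)
            out.extend(t[keep][: n - len(out)])
        return np.asarray(out)

    def test_parameter_recovery(self):
        t_min = 5e-4
        samples = self.sample_truncated_powerlaw(1.5, 1e-2, t_min, 10_000, seed=6)
        fit = stats.fit_truncated_powerlaw(samples, t_min=t_min)
        assert fit.beta == pytest.approx(1.5, abs=0.1)
        assert fit.tau == pytest.approx(1e-2, rel=0.2)

    def test_pure_exponential_gives_beta_near_zero(self):
        rng = np.random.default_rng(2)
        samples = rng.exponential(1.0, 10_000)
        fit = stats.fit_truncated_powerlaw(samples, t_min=0.01)
        assert abs(fit.beta) < 0.15
        assert fit.tau == pytest.approx(1.0, rel=0.15)

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError, match="at least"):
            stats.fit_truncated_powerlaw(np.ones(50) * 2.0, t_min=1.0)

    def test_bootstrap_is_seeded_and_pure(self):
        samples = self.sample_truncated_powerlaw(1.5, 1e-2, 5e-4, 2000, seed=1)
        f1 = stats.fit_truncated_powerlaw(samples, t_min=5e-4, n_bootstrap=10, seed=3)
        f2 = stats.fit_truncated_powerlaw(samples, t_min=5e-4, n_bootstrap=10, seed=3)
        assert f1.beta_se == f2.beta_se and f1.beta == f2.beta
        assert f1.beta_se > 0


class TestFptOracle:
    def test_density_is_normalized(self):
        total, err = integrate.quad(lambda t: stats.fpt_density_oracle(5.0, 1.0, t),
                                    0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_at_x_squared_over_6d(self):
        x, D = 3.0, 2.0
        t = np.linspace(0.1, 3.0, 20_000)
        dens = stats.fpt_density_oracle(x, D, t)
        assert t[np.argmax(dens)] == pytest.approx(x**2 / (6 * D), rel=1e-2)

    def test_asymptotic_tail_slope_is_minus_three_halves(self):
        t = np.geomspace(1e3, 1e5, 50)
        dens = stats.fpt_density_oracle(2.0, 1.0, t)
        slope = np.polyfit(np.log(t), np.log(dens), 1)[0]
        assert slope == pytest.approx(-1.5, abs=1e-3)

    def test_cdf_is_integral_of_density(self):
        part, _ = integrate.quad(lambda t: stats.fpt_density_oracle(5.0, 1.0, t),
                                 0, 7.0)
        assert stats.fpt_cdf_oracle(5.0, 1.0, 7.0) == pytest.approx(part, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            stats.fpt_density_oracle(5.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            stats.fpt_density_oracle(0.0, 1.0, 1.0)


class TestConfinementRatio:
    def test_all_particles_in_lo(self, stripe_field):
        pos = np.full((4, 10, 2), 10.0)
        traj = TrajectorySet(times=np.arange(4.0), positions=pos,
                             sampling_interval=1.0, box=64.0)
        _, ratio = stats.confinement_ratio(traj, stripe_field)
        assert np.all(ratio == 1.0)

    def test_uniform_positions_match_lo_area_fraction(self, stripe_field):
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 64, size=(1, 4000, 2))
        traj = TrajectorySet(times=np.zeros(1), positions=pos,
                             sampling_interval=1.0, box=64.0)
        _, ratio = stats.confinement_ratio(traj, stripe_field)
        se = np.sqrt(0.25 / 4000)
        assert abs(ratio[0] - 0.5) < 4 * se + 1 / 64  # binomial + boundary band

    def test_first_frame_is_included(self, stripe_field):
        pos = np.zeros((3, 5, 2))
        traj = TrajectorySet(times=np.array([0.0, 1.0, 2.0]), positions=pos,
                             sampling_interval=1.0, box=64.0)
        times, ratio = stats.confinement_ratio(traj, stripe_field)
        assert times[0] == 0.0 and len(ratio) == 3
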