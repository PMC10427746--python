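"""Cahn–Hilliard field dynamics: operators, noise, stability, models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ldpf
from ldpf import phasefield as pf


def small_params(**kw):
    base = dict(tau_r=np.inf, Lambda=-1.0, W=1.0, H=0.0, l_rec=1.0, L=32)
    base.update(kw)
    return pf.ModelParams(**base)


class TestChemicalPotential:
    def test_uniform_zero_field_gives_zero(self):
        p = small_params(Lambda=3.0)
        mu = pf.chemical_potential(np.zeros((32, 32)), p)
        assert np.all(mu == 0)

    @pytest.mark.parametrize("c0,Lam", [(0.4, -1.0), (-1.2, 2.5)])
    def test_uniform_field_keeps_only_bulk_terms(self, c0, Lam):
        p = small_params(Lambda=Lam)
        mu = pf.chemical_potential(np.full((32, 32), c0), p)
        assert np.allclose(mu, Lam * c0 + c0**3, rtol=0, atol=1e-12)

    def test_single_mode_matches_spectral_form(self):
        # sin(qx) is an eigenfunction of the periodic Laplacian; on a fine
        # grid the discrete eigenvalue converges to q^2 at O(dx^2)
        L = 256
        p = small_params(Lambda=-1.0, W=1.0, L=L)
        x = np.arange(L)
        c = np.sin(2 * np.pi * x / L)[:, None] * np.ones((1, L))
        q = 2 * np.pi / L
        mu = pf.chemical_potential(c, p)
        expected = p.W**2 * q**2 * c + p.Lambda * c + c**3
        assert np.allclose(mu, expected, atol=1e-6)

    def test_nonfinite_field_raises(self):
        c = np.zeros((32, 32))
        c[3, 3] = np.nan
        with pytest.raises(pf.FieldInstabilityError):
            pf.chemical_potential(c, small_params())

    def test_rho_required_iff_pinning(self):
        p_pin = small_params(alpha=1 / np.pi, N_imp=10)
        with pytest.raises(ValueError):
            pf.chemical_potential(np.zeros((32, 32)), p_pin)
        with pytest.raises(ValueError):
            pf.chemical_potential(np.zeros((32, 32)), small_params(),
                                  rho=np.zeros((32, 32)))


class TestImmobileProteinDensity:
    def test_peak_value_at_protein_center(self):
        sig = 0.5
        rho = pf.immobile_protein_density([(8.0, 8.0)], sig, 32)
        assert rho[8, 8] == pytest.approx(1.0 / (np.pi * sig**2))

    def test_value_at_sqrt2_sigma_is_e_inverse(self):
        sig = 0.5
        d = sig * np.sqrt(2.0)
        rho = pf.immobile_protein_density([(9.0 - d, 8.0)], sig, 32)
        assert rho[9, 8] == pytest.approx(np.exp(-1.0) / (np.pi * sig**2), rel=1e-10)

    def test_superposition_of_two_proteins(self):
        sig = 0.5
        a = pf.immobile_protein_density([(5.3, 7.1)], sig, 32)
        b = pf.immobile_protein_density([(20.0, 21.5)], sig, 32)
        both = pf.immobile_protein_density([(5.3, 7.1), (20.0, 21.5)], sig, 32)
        assert np.allclose(both, a + b, rtol=0, atol=1e-15)

    def test_empty_positions_give_zero_grid(self):
        assert np.all(pf.immobile_protein_density([], 0.5, 16) == 0)

    def test_periodic_minimum_image(self):
        sig = 0.5
        rho = pf.immobile_protein_density([(0.5, 0.0)], sig, 32)
        # node (31, 0) is at minimum-image distance 1.5, not 30.5
        assert rho[31, 0] == pytest.approx(
            np.exp(-1.5**2 / (2 * sig**2)) / (np.pi * sig**2), rel=1e-10)


class TestRecyclingNoise:
    def test_zero_amplitude_gives_zero_grid(self):
        eta = pf.recycling_noise(small_params(H=0.0), np.random.default_rng(0))
        assert np.all(eta == 0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            small_params(H=-1.0)

    def test_every_sample_has_exactly_zero_mean(self):
        p = small_params(H=2.12, l_rec=0.1)
        rng = np.random.default_rng(1)
        for _ in range(5):
            assert abs(np.mean(pf.recycling_noise(p, rng))) < 1e-14

    def test_power_spectrum_matches_filter(self):
        # E|eta_hat(q)|^2 = A(q)^2 * L^2 for white unit input noise
        p = small_params(H=1.7, l_rec=0.5, L=16)
        rng = np.random.default_rng(7)
        n = 8000
        acc = np.zeros((16, 9))
        for _ in range(n):
            acc += np.abs(np.fft.rfft2(pf.recycling_noise(p, rng)))**2
        acc /= n * 16.0**2
        A2 = pf._noise_amplitude(p)**2
        mask = A2 > 0
        ratio = acc[mask] / A2[mask]
        assert np.all(np.abs(ratio - 1.0) < 0.05)


class TestStepField:
    def test_reservoir_fixed_point(self):
        p = small_params(tau_r=5.0, H=0.0)
        c0 = np.full((32, 32), p.c_r)
        state = pf.FieldState(c=c0.copy(), rng=np.random.default_rng(0))
        out = pf.step_field(state, p)
        assert np.allclose(out.c, c0, atol=1e-15)
        assert out.t == pytest.approx(p.dt_field)

    def test_mass_conserved_without_noise_and_reservoir(self):
        p = small_params(H=0.0, tau_r=np.inf)
        rng = np.random.default_rng(3)
        state = pf.FieldState(c=0.1 * rng.standard_normal((32, 32)), rng=rng)
        total0 = np.sum(state.c)
        for _ in range(1000):
            state = pf.step_field(state, p)
        assert abs(np.sum(state.c) - total0) <= 1e-10 * max(abs(total0), 1.0)

    def test_uniform_field_relaxes_to_reservoir_composition(self):
        # uniform field: the CH term vanishes, leaving dc/dt = -(c - cr)/tau
        tau = 5.0
        p = small_params(tau_r=tau, H=0.0)
        state = pf.FieldState(c=np.full((32, 32), 0.8), rng=np.random.default_rng(0))
        devs = []
        for _ in range(200):
            state = pf.step_field(state, p)
            devs.append(state.c[0, 0] - p.c_r)
        rate = -np.polyfit(np.arange(200) * p.dt_field, np.log(np.abs(devs)), 1)[0]
        assert rate == pytest.approx(1.0 / tau, rel=0.01)

    @pytest.mark.parametrize("c0,mode,grows", [
        (0.0, 4, True),    # Lambda + 3c0^2 + W^2 q^2 = -1 + 0.154 < 0
        (0.0, 12, False),  # q^2 = 1.39 stabilizes the mode
        (0.7, 4, False),   # 3c0^2 = 1.47 > 1: inside the binodal but stable
    ])
    def test_linear_stability_criterion(self, c0, mode, grows):
        L = 64
        p = small_params(Lambda=-1.0, W=1.0, H=0.0, L=L)
        x = np.arange(L)
        pert = 1e-4 * np.sin(2 * np.pi * mode * x / L)[:, None] * np.ones((1, L))
        state = pf.FieldState(c=c0 + pert, rng=np.random.default_rng(0))
        amp0 = np.abs(np.fft.fft(state.c[:, 0])[mode])
        state = pf.advance_field(state, p, 500)
        amp1 = np.abs(np.fft.fft(state.c[:, 0])[mode])
        assert (amp1 > amp0) == grows

    def test_dynamics_commute_with_sign_flip_at_zero_reservoir(self):
        p = small_params(c_r=0.0, tau_r=10.0, H=0.0)
        rng = np.random.default_rng(5)
        c = 0.3 * rng.standard_normal((32, 32))
        plus = pf.step_field(pf.FieldState(c=c.copy()), p).c
        minus = pf.step_field(pf.FieldState(c=-c.copy()), p).c
        assert np.array_equal(plus, -minus)

    def test_blowup_detection_names_the_step(self):
        state = pf.FieldState(c=np.full((32, 32), 2e3), t=0.05)
        with pytest.raises(pf.FieldInstabilityError, match="step"):
            pf.step_field(state, small_params())

    def test_fast_path_matches_per_step_reference(self):
        p = pf.model_params(5, L=32)
        c0 = np.random.default_rng(3).standard_normal((32, 32))
        ref = pf.FieldState(c=c0.copy(), rng=np.random.default_rng(9))
        for _ in range(20):
            ref = pf.step_field(ref, p)
        fast = pf.advance_field(
            pf.FieldState(c=c0.copy(), rng=np.random.default_rng(9)), p, 20)
        assert np.allclose(ref.c, fast.c, atol=1e-12)
        assert fast.t == pytest.approx(ref.t)


class TestEquilibrateModels:
    def test_same_seed_reproduces_field_exactly(self):
        a = pf.equilibrate_model(1, L=32, seed=11, n_steps=300)
        b = pf.equilibrate_model(1, L=32, seed=11, n_steps=300)
        assert np.array_equal(a.c, b.c)

    def test_reservoir_model_phase_separates_bimodally(self, model5_field_64):
        hist, _ = np.histogram(model5_field_64.cbar, bins=10, range=(0, 1))
        mid = hist[4:6].mean()
        assert hist[0] > 3 * mid and hist[-1] > 3 * mid

    def test_miscible_model_stays_unimodal(self):
        state = pf.equilibrate_model(3, L=64, seed=2, n_steps=180)
        c = state.c
        hist, edges = np.histogram(c, bins=11)
        peak = np.argmax(hist)
        assert 3 <= peak <= 7            # single central peak
        assert hist[0] < hist[peak] / 3  # no binodal shoulders
        assert hist[-1] < hist[peak] / 3
        assert np.std(c) < 0.75          # fluctuations decayed from sigma = 1

    def test_pinning_model_runs_and_stores_proteins(self):
        state = pf.equilibrate_model(2, L=32, seed=4, n_steps=200)
        assert state.imp_positions is not None
        assert len(state.imp_positions) == pf.model_params(2, L=32).N_imp
        assert np.all(np.isfinite(state.c))


class TestNormalizedField:
    def test_extremes_map_to_zero_and_one(self):
        c = np.random.default_rng(0).standard_normal((16, 16))
        nf = pf.NormalizedField.from_raw(c)
        assert nf.cbar.min() == 0.0 and nf.cbar.max() == 1.0
        assert nf.cbar.flat[np.argmin(c)] == 0.0
        assert nf.cbar.flat[np.argmax(c)] == 1.0

    @settings(deadline=None, max_examples=25)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        c = np.random.default_rng(1).standard_normal((16, 16))
        nf1 = pf.NormalizedField.from_raw(c)
        nf2 = pf.NormalizedField.from_raw(a * c + b)
        assert np.allclose(nf1.cbar, nf2.cbar, atol=1e-9)

    def test_constant_field_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            pf.NormalizedField.from_raw(np.ones((16, 16)))

    def test_frozen_map_clips_later_excursions(self):
        c = np.linspace(0, 1, 256).reshape(16, 16)
        nf = pf.NormalizedField.from_raw(c)
        nf2 = nf.renormalize(c + 0.5)
        assert nf2.cbar.max() == 1.0 and nf2.c_min == nf.c_min

    def test_interpolation_matches_grid_nodes(self, bimodal_field):
        pts = np.array([[3.0, 5.0], [10.0, 63.0]])
        vals = bimodal_field.interpolate(pts)
        assert vals[0] == pytest.approx(bimodal_field.cbar[3, 5])
        assert vals[1] == pytest.approx(bimodal_field.cbar[10, 63])
        near = bimodal_field.interpolate(pts + 0.4, method="nearest")
        assert near[0] == bimodal_field.cbar[3, 5]


class TestClassifyPhaseRegime:
    @pytest.mark.parametrize("Lam,c0,label", [
        (10.0, 0.0, "Mixed"),
        (-1.0, 0.0, "Spinodal Decomposition"),
        (-1.0, 0.8, "Nucleation"),
        (-1.0, 1.1, "Mixed"),
    ])
    def test_reference_points(self, Lam, c0, label):
        assert pf.classify_phase_regime(Lam, c0) == label


class TestModelParamsValidation:
    def test_grid_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            small_params(L=48)

    def test_pinning_needs_proteins(self):
        with pytest.raises(ValueError):
            small_params(alpha=0.3, N_imp=0)

    def test_table_presets_match_reference_values(self):
        m5 = pf.model_params(5)
        assert (m5.tau_r, m5.Lambda, m5.l_rec, m5.H) == (500.0, -1.0, 0.1, 2.12)
        assert m5.n_steps == 720_000
        m2 = pf.model_params(2)
        assert m2.alpha == pytest.approx(1 / np.pi)
        assert m2.N_imp == 1500
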