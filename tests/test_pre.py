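"""SBMF machinery: order parameters, spectral densities, Γ₂ limits,
population weighting, Q-factor scoring and population fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from hingepre import (ConformerEnsemble, CorrelationTimes,
                      PREPhysicalConstants, SBMFParameters, TwoStateModel,
                      agreement, combine_states, ensemble_pre_profile,
                      fit_populations, gamma2, order_parameter,
                      spectral_density, synthesize_pre_profile,
                      vector_statistics)
from hingepre.pre import fit_tau_i, internal_correlation


def stats_frame(inv_r6, s2, tau_i=1e-9, residue_id=1):
    return pd.DataFrame({"residue_id": [residue_id], "mean_inv_r6": [inv_r6],
                         "s2": [s2], "tau_i": [tau_i]})


def two_atom_ensemble(frames):
    """Label at origin, one 1H site at the given per-frame positions."""
    coords = np.zeros((len(frames), 2, 3))
    coords[:, 1, :] = frames
    meta = pd.DataFrame({"residue_id": [1, 2], "atom_name": ["CA", "CA"],
                         "domain": ["NTD", "CTD"]})
    return ConformerEnsemble(coords, meta)


class TestOrderParameter:
    def test_static_vector_is_rigid(self):
        v = np.tile(np.array([3.0, 4.0, 12.0]), (50, 1, 1))
        ens = two_atom_ensemble(v[:, 0, :])
        stats = vector_statistics(ens, 0, [1])
        assert stats["s2"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert stats["mean_inv_r6"].iloc[0] == pytest.approx(13.0 ** -6)

    def test_isotropic_vector_decays_to_zero(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((100_000, 1, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        assert order_parameter(15.0 * v)[0] <= 0.02

    @pytest.mark.parametrize("beta_deg", [15.0, 30.0, 45.0])
    def test_wobble_in_cone_closed_form(self, beta_deg):
        """Uniform sampling of a cone of semiangle β at fixed r gives
        S² = [cosβ(1+cosβ)/2]²."""
        rng = np.random.default_rng(int(beta_deg))
        beta = np.radians(beta_deg)
        n = 150_000
        u = rng.uniform(np.cos(beta), 1.0, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        st = np.sqrt(1 - u ** 2)
        v = np.stack([st * np.cos(phi), st * np.sin(phi), u], axis=1)
        s2 = order_parameter(12.0 * v[:, None, :])[0]
        expect = (np.cos(beta) * (1 + np.cos(beta)) / 2) ** 2
        assert s2 == pytest.approx(expect, abs=0.01)

    def test_fewer_than_two_frames_rejected(self):
        ens = two_atom_ensemble(np.array([[10.0, 0, 0]]))
        with pytest.raises(ValueError, match="2 frames"):
            vector_statistics(ens, 0, [1])


class TestInternalTime:
    def test_rotational_diffusion_correlation_time(self):
        """Free rotational diffusion has C₂(t) = exp(−6Dt); the fitted
        internal time matches 1/(6D)."""
        rng = np.random.default_rng(1)
        d, dt, n = 0.02, 1.0, 60_000
        e = np.array([0.0, 0.0, 1.0])
        vs = np.empty((n, 1, 3))
        for i in range(n):
            step = rng.standard_normal(3) * np.sqrt(2 * d * dt)
            e = e + np.cross(step, e)
            e /= np.linalg.norm(e)
            vs[i, 0] = 12.0 * e
        corr = internal_correlation(vs, max_lag=200)
        tau = fit_tau_i(corr, np.zeros(1), dt)[0]
        assert tau == pytest.approx(1.0 / (6 * d), rel=0.15)

    def test_near_rigid_vector_reports_lower_bound(self):
        vs = np.tile(np.array([0.0, 0.0, 10.0]), (50, 1, 1))
        corr = internal_correlation(vs, max_lag=10)
        with pytest.warns(UserWarning, match="lower bound"):
            tau = fit_tau_i(corr, np.ones(1), dt=1.0)
        assert tau[0] > 0


class TestSpectralDensity:
    def test_rigid_limit_j0(self):
        times = CorrelationTimes(tau_r=10e-9, tau_i=1e-9)
        j0 = spectral_density(0.0, 2.0e-8, 1.0, times)
        assert j0 == pytest.approx(2.0e-8 * times.tau_c, rel=1e-12)

    def test_monotone_decay_in_frequency(self):
        times = CorrelationTimes(tau_r=10e-9, tau_i=1e-9)
        omegas = np.linspace(0, 1e10, 200)
        j = np.array([spectral_density(w, 1.0, 0.5, times) for w in omegas])
        assert np.all(np.diff(j) < 0)

    def test_two_lorentzian_sum_direct_arithmetic(self):
        s2, tau_r, tau_i = 0.5, 10e-9, 1e-9
        times = CorrelationTimes(tau_r=tau_r, tau_i=tau_i)
        w = 2 * np.pi * 500e6
        tau_t = 1 / (1 / tau_r + 1 / tau_i)
        expect = (s2 * tau_r / (1 + (w * tau_r) ** 2)
                  + (1 - s2) * tau_t / (1 + (w * tau_t) ** 2))
        assert spectral_density(w, 1.0, s2, times) == pytest.approx(
            expect, rel=1e-12)

    def test_intermediate_s2_between_rigid_and_flexible(self):
        times = CorrelationTimes(tau_r=20e-9, tau_i=0.3e-9)
        j_rigid = spectral_density(0.0, 1.0, 1.0, times)
        j_flex = spectral_density(0.0, 1.0, 0.0, times)
        j_mid = spectral_density(0.0, 1.0, 0.5, times)
        assert j_flex < j_mid < j_rigid

    def test_correlation_time_composition(self):
        t = CorrelationTimes(tau_r=10e-9, tau_i=2e-9, tau_s=5e-9)
        assert 1 / t.tau_c == pytest.approx(1 / 10e-9 + 1 / 5e-9)
        assert 1 / t.tau_t == pytest.approx(1 / t.tau_c + 1 / 2e-9)
        ignored = CorrelationTimes(tau_r=10e-9, tau_i=2e-9, tau_s=None)
        assert ignored.tau_c == ignored.tau_r
        assert 0 < ignored.tau_t <= ignored.tau_c


class TestGamma2:
    def test_rigid_limit_closed_form(self):
        """At S² = 1, Γ₂ equals the Solomon-Bloembergen rigid form to
        1e-10 relative."""
        params = SBMFParameters(times=CorrelationTimes(tau_r=20e-9))
        r = 22.0
        g = gamma2(stats_frame(r ** -6, 1.0), params)["gamma2"].iloc[0]
        c = params.constants
        tau_c = params.times.tau_c
        w = params.omega_i
        expect = (c.prefactor * (r * 1e-10) ** -6
                  * (4 * tau_c + 3 * tau_c / (1 + (w * tau_c) ** 2)))
        assert g == pytest.approx(expect, rel=1e-10)

    def test_linear_in_mean_inv_r6(self):
        params = SBMFParameters()
        g1 = gamma2(stats_frame(1e-8, 0.7), params)["gamma2"].iloc[0]
        g2 = gamma2(stats_frame(2e-8, 0.7), params)["gamma2"].iloc[0]
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_vanishes_with_correlation_time(self):
        g = [gamma2(stats_frame(1e-8, 0.8),
                    SBMFParameters(times=CorrelationTimes(tau_r=tr)))
             ["gamma2"].iloc[0] for tr in (1e-9, 1e-11, 1e-13)]
        assert g[0] > g[1] > g[2]
        assert g[2] < 1e-3 * g[0]

    def test_unit_sentinel_rejects_si_distances(self):
        with pytest.raises(ValueError, match="m\\^-6"):
            gamma2(stats_frame(1e50, 1.0))

    def test_invariant_under_global_rigid_motion(self, default_spec,
                                                 state_ensembles):
        open_ens, _ = state_ensembles
        prof = ensemble_pre_profile(open_ens, default_spec.label_site,
                                    default_spec.h_sites)
        rng = np.random.default_rng(3)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = ConformerEnsemble(open_ens.coords @ rot.T + 25.0,
                                  open_ens.atom_meta)
        prof2 = ensemble_pre_profile(moved, default_spec.label_site,
                                     default_spec.h_sites)
        assert np.allclose(prof["gamma2"], prof2["gamma2"], rtol=1e-9)


class TestCombineAndAgreement:
    def profile(self, values):
        return pd.DataFrame({"residue_id": np.arange(1, len(values) + 1),
                             "gamma2": np.asarray(values, dtype=float)})

    def test_zero_minor_population_returns_open(self):
        po, pm_ = self.profile([1, 2, 3]), self.profile([4, 5, 6])
        out = combine_states([po, pm_], [1.0, 0.0])
        assert np.allclose(out["gamma2"], po["gamma2"])

    def test_equal_populations_arithmetic_mean(self):
        po, pm_ = self.profile([1, 2, 3]), self.profile([5, 6, 7])
        out = combine_states([po, pm_], [0.5, 0.5])
        assert np.allclose(out["gamma2"], [3, 4, 5])

    def test_95_5_weighting_hand_arithmetic(self):
        po, pm_ = self.profile([10, 20, 30]), self.profile([110, 120, 130])
        out = combine_states([po, pm_], [0.95, 0.05])
        assert np.allclose(out["gamma2"], [15, 25, 35])

    def test_combination_linear_in_populations(self):
        rng = np.random.default_rng(0)
        po, pm_ = self.profile(rng.uniform(1, 50, 8)), \
            self.profile(rng.uniform(1, 50, 8))
        a = combine_states([po, pm_], [0.7, 0.3])
        b = combine_states([po, pm_], [0.3, 0.7])
        half = combine_states([po, pm_], [0.5, 0.5])
        assert np.allclose(0.5 * (a["gamma2"] + b["gamma2"]), half["gamma2"])

    def test_residue_mismatch_rejected(self):
        po = self.profile([1, 2, 3])
        pm_ = self.profile([1, 2, 3]).assign(residue_id=[4, 5, 6])
        with pytest.raises(ValueError, match="mismatch"):
            combine_states([po, pm_], [0.5, 0.5])

    def test_identical_profiles_perfect_score(self):
        p = self.profile([3, 1, 4, 1, 5])
        q, r = agreement(p, p)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_doubled_profile_q_of_one(self):
        obs = self.profile([3, 1, 4, 1, 5])
        calc = self.profile([6, 2, 8, 2, 10])
        q, _ = agreement(calc, obs)
        assert q == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError, match="Q undefined"):
            agreement(self.profile([1, 2, 3]), self.profile([0, 0, 0]))


class TestPopulationFit:
    def test_observed_equals_open_gives_zero(self, default_spec,
                                             state_ensembles):
        open_ens, minor_ens = state_ensembles
        po = ensemble_pre_profile(open_ens, default_spec.label_site,
                                  default_spec.h_sites)
        pm_ = ensemble_pre_profile(minor_ens, default_spec.label_site,
                                   default_spec.h_sites)
        fit = fit_populations([po, pm_], po)
        assert fit.p_minor == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_self_consistency_recovers_5_percent(
            self, default_spec, state_ensembles, two_state_model):
        open_ens, minor_ens = state_ensembles
        obs = synthesize_pre_profile(open_ens, minor_ens, two_state_model,
                                     default_spec, noise_sd=0.0, seed=1)
        fit = fit_populations([obs.attrs["profile_open"],
                               obs.attrs["profile_minor"]], obs)
        assert fit.p_minor == pytest.approx(0.05, abs=0.005)
        assert fit.q_min < 1e-8

    def test_degenerate_identical_states_flagged(self):
        p = pd.DataFrame({"residue_id": [1, 2, 3],
                          "gamma2": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="undetermined"):
            fit = fit_populations([p, p.copy()], p)
        assert fit.degenerate

    def test_misfit_curve_covers_unit_interval(self, default_spec,
                                               state_ensembles,
                                               two_state_model):
        open_ens, minor_ens = state_ensembles
        obs = synthesize_pre_profile(open_ens, minor_ens, two_state_model,
                                     default_spec, seed=5)
        fit = fit_populations([obs.attrs["profile_open"],
                               obs.attrs["profile_minor"]], obs)
        assert fit.p_grid[0] == 0.0 and fit.p_grid[-1] == pytest.approx(1.0)
        assert len(fit.p_grid) == len(fit.q_grid)
        assert fit.q_min <= fit.q_grid.min() + 1e-12


class TestConstants:
    def test_invalid_spin_rejected(self):
        with pytest.raises(ValueError):
            PREPhysicalConstants(s=0.3)
        with pytest.raises(ValueError):
            PREPhysicalConstants(g=-1.0)

    def test_larmor_frequency_tracks_field(self):
        p600 = SBMFParameters(b0=14.1)
        p800 = SBMFParameters(b0=18.8)
        assert p600.omega_i / (2 * np.pi) == pytest.approx(600e6, rel=0.01)
        assert p800.omega_i > p600.omega_i
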