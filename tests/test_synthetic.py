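"""Generator contracts: mixture statistics, landscape ground truth,
synthetic PRE profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import binom

from hingepre import (HingeModelSpec, TwoStateModel, generate_hinge_ensemble,
                      generate_landscape, barrier_calibrated_double_well,
                      single_state_ensemble, synthesize_pre_profile,
                      interdomain_angle_series, partition_from_tags, KB_KCAL)
class TestHingeEnsemble:
    def test_degenerate_mixture_all_open(self):
        spec = HingeModelSpec(p_minor=0.0)
        ens = generate_hinge_ensemble(spec, 100, seed=1)
        assert set(ens.frame_labels) == {"open"}

    def test_minor_fraction_within_binomial_band(self):
        """Empirical minor fraction at n=10^4 sits in the central 99%
        binomial interval around p_minor = 0.05."""
        spec = HingeModelSpec(p_minor=0.05)
        ens = generate_hinge_ensemble(spec, 10_000, seed=7)
        k = int(np.sum(ens.frame_labels == "minor"))
        lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.05)
        assert lo <= k <= hi

    def test_noiseless_open_frames_identical(self):
        spec = HingeModelSpec(p_minor=0.0, jitter_sd=0.0, label_jitter_sd=0.0,
                              angle_sd=1e-12)
        ens = generate_hinge_ensemble(spec, 5, seed=3)
        for i in range(1, 5):
            assert np.allclose(ens.coords[i], ens.coords[0], atol=1e-6)

    def test_deterministic_for_fixed_seed(self):
        spec = HingeModelSpec()
        a = generate_hinge_ensemble(spec, 50, seed=9)
        b = generate_hinge_ensemble(spec, 50, seed=9)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.frame_labels, b.frame_labels)

    def test_invalid_fields_name_the_offender(self):
        with pytest.raises(ValueError, match="p_minor"):
            HingeModelSpec(p_minor=1.5)
        with pytest.raises(ValueError, match="angle_open"):
            HingeModelSpec(angle_open=140.0, angle_minor=146.0)
        with pytest.raises(ValueError, match="label_site"):
            HingeModelSpec(label_site=99)
        with pytest.raises(ValueError, match="n_frames"):
            generate_hinge_ensemble(HingeModelSpec(), 0)

    def test_measured_angles_recover_state_means(self):
        """Geometry-module angles on generated frames recover the two
        construction means within 3·angle_sd/sqrt(n) per state."""
        spec = HingeModelSpec(p_minor=0.3, jitter_sd=0.0, label_jitter_sd=0.0)
        n = 400
        ens = generate_hinge_ensemble(spec, n, seed=21)
        theta = interdomain_angle_series(ens, partition_from_tags(ens))
        for state, mean in (("open", spec.angle_open),
                            ("minor", spec.angle_minor)):
            sel = theta.theta_deg[ens.frame_labels == state]
            tol = 3 * spec.angle_sd / np.sqrt(len(sel))
            assert abs(sel.mean() - mean) < tol

    def test_open_minor_angle_gap_matches_construction(self):
        spec = HingeModelSpec(p_minor=0.5)
        ens = generate_hinge_ensemble(spec, 600, seed=5)
        theta = interdomain_angle_series(ens, partition_from_tags(ens))
        gap = (theta.theta_deg[ens.frame_labels == "open"].mean()
               - theta.theta_deg[ens.frame_labels == "minor"].mean())
        expect = spec.angle_open - spec.angle_minor
        noise = 3 * spec.angle_sd * np.sqrt(2.0 / 300)
        assert abs(gap - expect) < noise + 0.2


class TestLandscapes:
    def test_harmonic_minimum_at_origin(self):
        land = generate_landscape("harmonic", [1.0])
        assert land.potential(0.0) == 0.0
        assert land.potential(2.0) == pytest.approx(2.0)
        assert land.gradient(3.0) == pytest.approx(3.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_landscape("triple_well", [1.0])

    def test_symmetric_double_well_populations_half(self):
        land = generate_landscape("double_well_1d", [1.0, 1.5])
        for t in (150.0, 300.0, 600.0):
            p = land.populations(t)
            assert p[0] == pytest.approx(0.5, abs=1e-6)

    def test_tilted_well_populations_match_quadrature_oracle(self):
        """Populations agree with an independent Boltzmann quadrature."""
        a, b, c = 2.0, 1.2, 0.35
        land = generate_landscape("double_well_1d", [a, b, c],
                                  domain=(-4.0, 4.0))
        t = 300.0
        beta = 1.0 / (KB_KCAL * t)

        def v(x):
            return a * (x * x - b * b) ** 2 + c * x

        def boltz(x):
            return np.exp(-beta * v(x))

        from scipy.optimize import minimize_scalar
        xb = minimize_scalar(lambda x: -v(x), bounds=(-b, b),
                             method="bounded").x
        zl = quad(boltz, -4.0, xb, epsabs=1e-10)[0]
        zr = quad(boltz, xb, 4.0, epsabs=1e-10)[0]
        p = land.populations(t)
        assert p[0] == pytest.approx(zl / (zl + zr), abs=1e-6)
        assert p[1] == pytest.approx(zr / (zl + zr), abs=1e-6)

    def test_barrier_calibration_exact_for_symmetric_wells(self):
        land = barrier_calibrated_double_well(2.0, minima=(6.0, 13.0),
                                              domain=(4.0, 15.0))
        assert land.barrier_height() == pytest.approx(2.0, abs=1e-5)
        lo, hi = land.minima()
        assert lo == pytest.approx(6.0, abs=1e-4)
        assert hi == pytest.approx(13.0, abs=1e-4)

    def test_double_well_has_two_minima(self):
        land = generate_landscape("double_well_1d", [1.0, 1.0, 0.1])
        lo, hi = land.minima()
        assert lo < land.barrier_location() < hi


class TestSyntheticPREProfiles:
    def test_zero_noise_zero_minor_equals_open_profile(self, default_spec,
                                                       state_ensembles):
        open_ens, minor_ens = state_ensembles
        obs = synthesize_pre_profile(open_ens, minor_ens,
                                     TwoStateModel.from_minor(0.0),
                                     default_spec, noise_sd=0.0, seed=1)
        assert np.allclose(obs["gamma2"],
                           obs.attrs["profile_open"]["gamma2"])

    def test_equal_weighting_is_arithmetic_mean(self, default_spec,
                                                state_ensembles):
        open_ens, minor_ens = state_ensembles
        obs = synthesize_pre_profile(open_ens, minor_ens,
                                     TwoStateModel.from_minor(0.5),
                                     default_spec, noise_sd=0.0, seed=1)
        mean = 0.5 * (obs.attrs["profile_open"]["gamma2"]
                      + obs.attrs["profile_minor"]["gamma2"])
        assert np.allclose(obs["gamma2"], mean)

    def test_reproducible_csv_for_fixed_seed(self, tmp_path, default_spec,
                                             state_ensembles):
        open_ens, minor_ens = state_ensembles
        model = TwoStateModel.from_minor(0.05)
        paths = []
        for tag in ("a", "b"):
            obs = synthesize_pre_profile(open_ens, minor_ens, model,
                                         default_spec, seed=42)
            p = tmp_path / f"{tag}.csv"
            obs.to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_mismatched_site_lists_rejected(self, default_spec):
        open_ens = single_state_ensemble(default_spec, "open", 20, seed=1)
        other = HingeModelSpec(n_beads_ctd=10)
        minor_ens = single_state_ensemble(other, "minor", 20, seed=2)
        with pytest.raises(ValueError):
            synthesize_pre_profile(open_ens, minor_ens,
                                   TwoStateModel.from_minor(0.05),
                                   default_spec)
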