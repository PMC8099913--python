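"""Local and global melting-curve fits: round trips, nesting, fu profiles."""

import numpy as np
import pytest

from dsfbind import BindingStudy, MeltingCurve, fu_profile, ground_truth_fu
from dsfbind.fitting import fit_global, fit_local

from conftest import DEFAULT_BASELINE, make_model_study, make_two_state_curve


class TestLocalFit:
    def test_noiseless_round_trip_recovers_all_six_parameters(self):
        curve = make_two_state_curve(50.0, 120.0)
        r = fit_local(curve)
        assert r.converged
        assert r.tm_celsius == pytest.approx(50.0, abs=1e-3 * 50)
        assert r.params.dh == pytest.approx(120.0, rel=1e-3)
        assert r.baseline.mf == pytest.approx(DEFAULT_BASELINE.mf, rel=1e-3)
        assert r.baseline.mu == pytest.approx(DEFAULT_BASELINE.mu, rel=1e-3)
        assert r.baseline.bf == pytest.approx(DEFAULT_BASELINE.bf, rel=1e-3)
        assert r.baseline.bu == pytest.approx(DEFAULT_BASELINE.bu, rel=1e-3)

    def test_constant_signal_flagged_not_raised(self):
        tc = np.arange(20.0, 95.1, 0.5)
        r = fit_local(MeltingCurve(tc, np.full_like(tc, 1.2), l0=0.0))
        assert not r.converged
        assert "no transition" in r.message

    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_two_percent_noise_tm_within_03_celsius(self, seed):
        curve = make_two_state_curve(50.0, 120.0, noise=0.02, seed=seed)
        r = fit_local(curve)
        assert r.converged
        assert abs(r.tm_celsius - 50.0) < 0.3

    def test_too_few_points_in_window_is_an_input_error(self):
        curve = make_two_state_curve(50.0, 120.0)
        with pytest.raises(ValueError, match="window"):
            fit_local(curve, window=(20.0, 22.0))

    def test_tm_constrained_to_window(self):
        curve = make_two_state_curve(50.0, 120.0)
        r = fit_local(curve, window=(55.0, 95.0))
        assert 55.0 <= r.tm_celsius <= 95.0
        assert not r.converged  # transition excluded -> pinned at the edge


class TestGlobalFit:
    def test_noiseless_study_recovered_to_machine_precision(self):
        study, tms, dhs = make_model_study()
        locs = [fit_local(c, study.window) for c in study.curves]
        g = fit_global(study, locs)
        assert g.converged
        assert abs(g.mf / DEFAULT_BASELINE.mf - 1) < 1e-6
        assert abs(g.mu / DEFAULT_BASELINE.mu - 1) < 1e-6
        np.testing.assert_allclose(g.tm_celsius, tms, atol=1e-4)
        np.testing.assert_allclose(g.dh, dhs, rtol=1e-6)

    def test_per_curve_parameters_invariant_to_other_curves(self):
        study, tms, _ = make_model_study(n_curves=8)
        locs = [fit_local(c, study.window) for c in study.curves]
        g_full = fit_global(study, locs)
        sub = BindingStudy(study.curves[:4], p0=study.p0)
        g_sub = fit_global(sub, locs[:4])
        np.testing.assert_allclose(g_sub.tm_celsius, g_full.tm_celsius[:4],
                                   atol=1e-6)

    def test_global_cost_bounded_below_by_local_fits(self, study_dcp8_noisy,
                                                     dcp8_fits):
        # local fits have strictly more freedom (per-curve slopes), so the
        # summed local residual cannot exceed the shared-slope global one
        _, study = study_dcp8_noisy
        fixed, _ = dcp8_fits
        locs = [fit_local(c, study.window, dcp=0.0) for c in study.curves]
        local_ss = sum(r.residual_norm ** 2 for r in locs)
        assert local_ss <= fixed.residual_norm ** 2 * (1 + 1e-9)

    def test_fitted_dcp_nests_fixed_dcp(self, dcp8_fits):
        fixed, fitted = dcp8_fits
        assert fitted.residual_norm <= fixed.residual_norm
        assert fitted.residual_norm < fixed.residual_norm  # dCp truly != 0

    def test_fitted_dcp_recovers_truth_at_two_percent_noise(self, dcp8_fits):
        _, fitted = dcp8_fits
        assert fitted.dcp == pytest.approx(8.0, abs=1.0)
        assert fitted.dcp_err < 1.0

    def test_failed_local_fits_are_excluded_not_fatal(self):
        study, _, _ = make_model_study(n_curves=6)
        tc = study.t_celsius
        flat = MeltingCurve(tc, np.full_like(tc, 1.2), l0=1e-3, label="flat")
        study2 = BindingStudy(study.curves + [flat], p0=study.p0)
        locs = [fit_local(c, study2.window) for c in study2.curves]
        g = fit_global(study2, locs)
        assert g.excluded == ["flat"]
        assert len(g.labels) == 6


class TestFuProfile:
    def test_fu_half_at_each_curves_tm(self, global_fit_noiseless):
        g = global_fit_noiseless
        for i in range(len(g.labels)):
            prof = fu_profile(g, float(g.tm_celsius[i]))
            assert prof["fu"].iloc[i] == pytest.approx(0.5, abs=1e-9)

    def test_matches_generator_ground_truth(self, spec_noiseless,
                                            global_fit_noiseless):
        prof = fu_profile(global_fit_noiseless, 50.0)
        truth = np.array([ground_truth_fu(spec_noiseless, 50.0, l0)
                          for l0 in prof["L0_M"]])
        np.testing.assert_allclose(prof["fu"].to_numpy(), truth, atol=1e-3)

    def test_monotone_in_temperature(self, global_fit_noiseless):
        temps = np.linspace(40.0, 60.0, 21)
        fus = np.array([fu_profile(global_fit_noiseless, t)["fu"].to_numpy()
                        for t in temps])
        assert np.all(np.diff(fus, axis=0) >= 0)

    def test_outside_window_rejected(self, global_fit_noiseless):
        with pytest.raises(ValueError, match="window"):
            fu_profile(global_fit_noiseless, 150.0)
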