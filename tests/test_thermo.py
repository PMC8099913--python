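"""Unit and property tests for the closed-form thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from dsfbind import (
    R_KCAL,
    BaselineParams,
    ThermoParams,
    apparent_ku,
    dg_total,
    dg_unfolding,
    estimate_dcp,
    exact_free_ligand,
    fraction_unfolded,
    free_ligand,
    signal,
)

HYP = settings(derandomize=True, max_examples=200, deadline=None)


class TestDgUnfolding:
    def test_zero_at_tm(self):
        assert dg_unfolding(323.15, 323.15, 100.0, 5.0) == 0.0

    @HYP
    @given(
        tm=st.floats(280.0, 380.0),
        dh=st.floats(10.0, 500.0),
        dcp=st.floats(0.0, 20.0),
    )
    def test_zero_at_tm_random_sweep(self, tm, dh, dcp):
        assert dg_unfolding(tm, tm, dh, dcp) == 0.0

    def test_dcp_zero_closed_form(self):
        # ΔH (1 - T/Tm) when the heat-capacity term vanishes
        assert dg_unfolding(313.15, 323.15, 100.0, 0.0) == pytest.approx(
            3.094538140182579, rel=1e-12
        )

    def test_nonzero_dcp_against_term_by_term_evaluation(self):
        # frozen from the independent sum ΔH + ΔCp(T-Tm) - T(ΔH/Tm + ΔCp ln(T/Tm))
        assert dg_unfolding(313.15, 323.15, 100.0, 8.0) == pytest.approx(
            1.8437533581240224, rel=1e-12
        )
        T, Tm, dH, dCp = 313.15, 323.15, 100.0, 8.0
        oracle = dH + dCp * (T - Tm) - T * (dH / Tm + dCp * np.log(T / Tm))
        assert dg_unfolding(T, Tm, dH, dCp) == pytest.approx(oracle, rel=1e-12)

    def test_continuous_and_decreasing_through_tm_without_dcp(self):
        t = np.linspace(300.0, 350.0, 201)
        dg = dg_unfolding(t, 323.15, 120.0, 0.0)
        assert np.all(np.diff(dg) < 0)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            dg_unfolding(bad, 323.15, 100.0)
        with pytest.raises(ValueError):
            dg_unfolding(313.15, bad, 100.0)


class TestDgTotal:
    P = ThermoParams(tm=323.15, dh=100.0, dcp=0.0)

    def test_no_ligand_reduces_to_unfolding(self):
        assert dg_total(313.15, self.P, 0.0, 1e-6) == pytest.approx(
            dg_unfolding(313.15, 323.15, 100.0), rel=1e-14
        )

    def test_lfree_equal_kd_adds_rt_ln2(self):
        got = dg_total(313.15, self.P, 1e-6, 1e-6)
        assert got == pytest.approx(
            dg_unfolding(313.15, 323.15, 100.0) + R_KCAL * 313.15 * np.log(2.0),
            rel=1e-12,
        )

    def test_at_tm_pure_ligand_term(self):
        # ΔG_U(Tm)=0 so only RT ln(1 + Lfree/Kd) remains; frozen R·323.15·ln 11
        got = dg_total(323.15, self.P, 1e-5, 1e-6)
        assert got == pytest.approx(1.539844352154235, rel=1e-12)

    @HYP
    @given(
        t=st.floats(280.0, 370.0),
        lfree=st.floats(0.0, 1e-2),
        kd=st.floats(1e-10, 1e-2),
    )
    def test_ligand_never_destabilizes(self, t, lfree, kd):
        base = dg_unfolding(t, 323.15, 100.0)
        assert dg_total(t, self.P, lfree, kd) >= base

    def test_bad_kd(self):
        with pytest.raises(ValueError):
            dg_total(313.15, self.P, 1e-6, 0.0)


class TestFreeLigand:
    def test_no_ligand(self):
        assert free_ligand(0.0, 1e-6, 1.0, 1e-6) == 0.0

    def test_fully_unfolded_protein_binds_nothing(self):
        assert free_ligand(1e-5, 1e-5, 1e12, 1e-6) == pytest.approx(1e-5, rel=1e-9)

    def test_agrees_with_quadratic_root_oracle(self):
        # positive root of L^2 + (P0/(Ku+1) + Kd - L0) L - Kd L0 = 0, located
        # independently by bisection on the equivalent monotone mass balance
        rng = np.random.default_rng(20240515)
        n = 10_000
        l0 = 10.0 ** rng.uniform(-10, -1, n)
        p0 = 10.0 ** rng.uniform(-10, -1, n)
        ku = 10.0 ** rng.uniform(-4, 4, n)
        kd = 10.0 ** rng.uniform(-10, -1, n)
        got = free_ligand(l0, p0, ku, kd)
        for i in range(n):
            peff = p0[i] / (ku[i] + 1.0)

            def balance(x):
                return x + peff * x / (kd[i] + x) - l0[i]

            if balance(l0[i]) <= 0:
                oracle = l0[i]
            else:
                oracle = brentq(balance, 0.0, l0[i], xtol=5e-324, rtol=8.9e-16)
            assert got[i] == pytest.approx(oracle, rel=1e-12)

    def test_matches_half_sum_plus_root_form_directly(self):
        # the stabilized evaluation is algebraically the printed closed form
        rng = np.random.default_rng(7)
        l0 = 10.0 ** rng.uniform(-6, -2, 200)
        p0 = 10.0 ** rng.uniform(-7, -4, 200)
        ku = 10.0 ** rng.uniform(-2, 2, 200)
        kd = 10.0 ** rng.uniform(-7, -3, 200)
        peff = p0 / (ku + 1.0)
        printed = (l0 - peff - kd) / 2.0 + np.sqrt(
            (l0 + peff + kd) ** 2 / 4.0 - l0 * peff
        )
        np.testing.assert_allclose(free_ligand(l0, p0, ku, kd), printed, rtol=1e-9)

    @HYP
    @given(
        l0=st.floats(1e-9, 1e-2),
        p0=st.floats(1e-9, 1e-3),
        ku=st.floats(1e-4, 1e4),
        kd=st.floats(1e-9, 1e-2),
    )
    def test_bounded_by_total_ligand(self, l0, p0, ku, kd):
        lf = free_ligand(l0, p0, ku, kd)
        assert 0.0 <= lf <= l0

    def test_monotone_in_l0_ku_kd(self):
        base = dict(l0=1e-5, p0=5e-6, ku=1.0, kd=1e-6)
        ref = free_ligand(**base)
        assert free_ligand(2e-5, 5e-6, 1.0, 1e-6) >= ref
        assert free_ligand(1e-5, 5e-6, 2.0, 1e-6) >= ref
        assert free_ligand(1e-5, 5e-6, 1.0, 2e-6) >= ref

    def test_exact_mass_balance_cross_check(self):
        # exact three-species solution converges to the quadratic when the
        # unfolded fraction is negligible, and differs when Ku is large
        close = exact_free_ligand(1e-5, 5e-6, 1e-8, 1e-6)
        assert close == pytest.approx(free_ligand(1e-5, 5e-6, 1e-8, 1e-6), rel=1e-6)
        big_ku = exact_free_ligand(1e-6, 5e-6, 10.0, 1e-6)
        assert big_ku != pytest.approx(free_ligand(1e-6, 5e-6, 10.0, 1e-6), rel=1e-4)


class TestEquilibrium:
    def test_apparent_ku_values(self):
        assert apparent_ku(0.0, 300.0) == 1.0
        assert apparent_ku(R_KCAL * 300.0 * np.log(2.0), 300.0) == pytest.approx(0.5)
        assert apparent_ku(3.0946, 313.15) == pytest.approx(0.00692304790856874,
                                                            rel=1e-12)

    def test_fraction_unfolded_values(self):
        assert fraction_unfolded(1.0) == 0.5
        assert fraction_unfolded(0.0) == 0.0
        assert fraction_unfolded(3.0) == 0.75
        assert fraction_unfolded(np.inf) == 1.0

    @HYP
    @given(k=st.floats(0.0, 1e6))
    def test_fraction_unfolded_in_unit_interval(self, k):
        assert 0.0 <= fraction_unfolded(k) <= 1.0

    def test_sigmoid_composition_monotone_in_temperature(self):
        t = np.linspace(300.0, 350.0, 500)
        fu = fraction_unfolded(apparent_ku(dg_unfolding(t, 323.15, 120.0, 0.0), t))
        assert np.all(np.diff(fu) > 0)
        assert fraction_unfolded(apparent_ku(dg_unfolding(323.15, 323.15, 120.0),
                                             323.15)) == 0.5


class TestSignal:
    B = BaselineParams(mf=-0.002, bf=1.5, mu=0.001, bu=1.1)

    def test_endpoints_and_midpoint(self):
        t = 320.0
        assert signal(t, 0.0, self.B) == self.B.folded(t)
        assert signal(t, 1.0, self.B) == self.B.unfolded(t)
        assert signal(t, 0.5, self.B) == pytest.approx(
            0.5 * (self.B.folded(t) + self.B.unfolded(t))
        )

    def test_rejects_fu_outside_unit_interval(self):
        with pytest.raises(ValueError):
            signal(320.0, 1.5, self.B)


class TestEstimateDcp:
    @pytest.mark.parametrize("nres,expected", [(422, 5.9), (535, 7.4), (374, 5.2)])
    def test_residue_count_estimates(self, nres, expected):
        assert round(estimate_dcp(nres), 1) == expected

    @pytest.mark.parametrize("bad", [0, -10, 3.5])
    def test_rejects_non_positive_or_fractional(self, bad):
        with pytest.raises(ValueError):
            estimate_dcp(bad)


class TestTypes:
    def test_thermo_params_validation(self):
        with pytest.raises(ValueError):
            ThermoParams(tm=-1.0, dh=100.0)
        with pytest.raises(ValueError):
            ThermoParams(tm=323.15, dh=-5.0)

    def test_baseline_params_validation(self):
        with pytest.raises(ValueError):
            BaselineParams(mf=np.nan, bf=1.0, mu=0.0, bu=1.0)
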