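import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from llps_assembly.exchange import k_eff, partition_equilibrium
from llps_assembly.params import AssemblyModelParams
from llps_assembly.scaling import (
    a_half,
    elongation_time,
    elongation_time_llps,
    llps_speedup,
    log_s_nuc,
    median_time,
    nucleation_speedup,
    nucleation_threshold,
    nucleation_time,
    robustness_optima,
    trap_threshold,
)


class TestElongationTime:
    def test_direct_value(self, ng_params):
        # 120/(1e5 * 1e-6) = 1.2e3 s
        assert elongation_time(1e-6, ng_params) == pytest.approx(1.2e3)

    def test_cnt_exponent_halves_size_dependence(self, cnt_params):
        t120 = elongation_time(1e-6, cnt_params)
        t30 = elongation_time(1e-6, AssemblyModelParams(model_kind="CNT", N=30, g_sub=-17.0, n_nuc=None))
        assert t120 / t30 == pytest.approx(2.0)

    def test_no_llps_reduction(self, ng_params):
        assert elongation_time_llps(1e-6, ng_params, 1.0, 1e-3) == pytest.approx(
            elongation_time(1e-6, ng_params)
        )

    def test_compartment_dominates_at_large_kc(self, ng_params):
        # with V_r*K_c^n_nuc >> 1 the weighted time approaches N/(f*rho1_c)
        kc, vr = 100.0, 1e-3
        rho1c = kc * k_eff(kc, vr) * 1e-6
        assert elongation_time_llps(1e-6, ng_params, kc, vr) == pytest.approx(
            elongation_time(rho1c, ng_params), rel=1e-2
        )


class TestNucleationTime:
    def test_barrierless_dimer_nucleus(self):
        p = AssemblyModelParams(n_nuc=2)
        assert nucleation_time(1e-6, p) == pytest.approx(1.0 / (1e5 * 1e-12))

    def test_power_law_in_concentration(self, ng_params):
        assert nucleation_time(1e-6, ng_params) / nucleation_time(
            2e-6, ng_params
        ) == pytest.approx(2.0**3)

    def test_direct_value(self, ng_params):
        # f^-1 exp(G_2) rho^-3 = 1e-5 * e^-4 * 1e18 s
        assert nucleation_time(1e-6, ng_params) == pytest.approx(
            1e-5 * math.exp(-4.0) * 1e18, rel=1e-12
        )


class TestMedianTime:
    def test_prefactors(self):
        assert a_half(2) == pytest.approx(1.5)
        assert a_half(4) == pytest.approx(15.0 / 4.0)

    def test_no_llps_identity(self, ng_params):
        assert median_time(1e-6, ng_params, 1.0, 0.0) == median_time(1e-6, ng_params)

    def test_loglog_slope_is_minus_nhat(self, ng_params):
        t1, t2 = median_time(1e-6, ng_params), median_time(1e-5, ng_params)
        assert math.log10(t1 / t2) == pytest.approx(2.0)  # nhat = 2

    def test_speedup_divides_median_time(self, ng_params):
        t0 = median_time(2e-7, ng_params)
        t = median_time(2e-7, ng_params, 10.0, 1e-3)
        assert t0 / t == pytest.approx(math.exp(log_s_nuc(10.0, 1e-3, 3)), rel=1e-12)


class TestNucleationThreshold:
    def test_round_trip_identity(self, ng_params):
        tau_obs = 9e4
        rho = nucleation_threshold(tau_obs, ng_params)
        assert median_time(rho, ng_params) == pytest.approx(tau_obs, rel=1e-9)

    def test_monotone_in_observation_time(self, ng_params):
        r1 = nucleation_threshold(9e4, ng_params)
        r2 = nucleation_threshold(9e6, ng_params)
        assert r2 < r1

    def test_llps_shift(self, ng_params):
        r0 = nucleation_threshold(9e4, ng_params)
        r = nucleation_threshold(9e4, ng_params, K_c=10.0, V_r=1e-3)
        s = math.exp(log_s_nuc(10.0, 1e-3, 3))
        assert r == pytest.approx(r0 / s ** (1.0 / 2.0), rel=1e-9)


class TestNucleationSpeedup:
    def test_no_partitioning(self):
        for vr in (0.0, 1e-3, 0.5):
            assert nucleation_speedup(1.0, vr, 3)["s_nuc"] == pytest.approx(1.0)

    def test_printed_example(self):
        # K_eff^3 * (1 + V_r K_c^3)/(1 + V_r) ~ 1.945
        res = nucleation_speedup(10.0, 1e-3, 3)
        assert res["s_nuc"] == pytest.approx(1.9451, rel=1e-4)

    def test_vanishing_compartment(self):
        assert nucleation_speedup(10.0, 1e-12, 3)["s_nuc"] == pytest.approx(1.0, rel=1e-6)

    def test_optimum_beats_endpoints(self):
        res = nucleation_speedup(10.0, 1e-3, 3)
        assert res["s_nuc_star"] >= res["s_nuc"]
        assert res["s_nuc_star"] > 1.0
        # optimal V_r should be near K_c^-nhat = 0.01 (order of magnitude)
        assert 1e-3 < res["V_r_opt"] < 1.0

    @given(
        kc=st.floats(min_value=1.0, max_value=1e3),
        vr=st.floats(min_value=1e-6, max_value=1.0),
        n_nuc=st.integers(min_value=2, max_value=8),
    )
    def test_identity_with_initial_rate_ratio(self, kc, vr, n_nuc):
        """s_nuc equals the ratio of total initial nucleation rates computed
        directly from the partitioned initial concentrations (exact algebra)."""
        rho_T = 1e-6
        eq = partition_equilibrium(rho_T, kc, vr)
        rate_llps = (vr * eq["rho1_c"] ** n_nuc + eq["rho1_bg"] ** n_nuc) / (1 + vr)
        rate_hom = rho_T**n_nuc
        s = math.exp(log_s_nuc(kc, vr, n_nuc))
        assert s == pytest.approx(rate_llps / rate_hom, rel=1e-9)


class TestTrapThreshold:
    def test_round_trip_at_root(self, ng_params):
        res = trap_threshold(ng_params, K_c=10.0, V_r=1e-3)
        rho = res["rho_star"]
        t_half = median_time(rho, ng_params, 10.0, 1e-3)
        t_el = elongation_time_llps(rho, ng_params, 10.0, 1e-3)
        assert abs(t_half - t_el) / t_el < 1e-8

    def test_no_llps_closed_form_agrees_with_root(self, ng_params, ng5_params):
        for p in (ng_params, ng5_params):
            res = trap_threshold(p)
            assert res["rho_star"] == pytest.approx(res["rho_star0_closed"], rel=1e-8)

    def test_llps_shift_identity(self, ng_params):
        """rho* equals the homogeneous value times (Kc*Keff/s_nuc)^(1/(n_nuc-2))."""
        for kc, vr in [(3.0, 1e-3), (10.0, 1e-3), (30.0, 1e-2), (100.0, 1e-4)]:
            res = trap_threshold(ng_params, K_c=kc, V_r=vr)
            shift = (kc * k_eff(kc, vr) / math.exp(log_s_nuc(kc, vr, 3))) ** (1.0 / 1.0)
            assert res["rho_star_closed"] == pytest.approx(
                res["rho_star0_closed"] * shift, rel=1e-9
            )

    def test_cnt_self_consistent_root(self, cnt_params):
        res = trap_threshold(cnt_params)
        rho = res["rho_star"]
        t_half = median_time(rho, cnt_params)
        t_el = elongation_time_llps(rho, cnt_params)
        assert abs(t_half - t_el) / t_el < 1e-6
        # the concentration-dependent nucleus at the root is small but > 2
        from llps_assembly.cnt import cnt_critical_nucleus

        assert 3 <= cnt_critical_nucleus(rho, cnt_params)["n_nuc_discrete"] <= 8


class TestLlpsSpeedup:
    def test_modest_for_large_compartment(self, ng_params):
        res = llps_speedup(0.9, 0.15 * 1.9e-6, ng_params)
        assert res["s_llps_numeric"] < 10.0

    def test_grows_as_compartment_shrinks(self, ng_params):
        vals = [
            llps_speedup(vr, 0.15 * 1.9e-6, ng_params)["s_llps_numeric"]
            for vr in (1e-2, 1e-3, 1e-4)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_closed_form_tracks_numeric(self, ng_params):
        res = llps_speedup(1e-3, 0.15 * 1.9e-6, ng_params)
        ratio = res["s_llps_numeric"] / res["s_llps_closed_form"]
        assert 0.5 < ratio < 2.0

    def test_requires_subcritical_concentration(self, ng_params):
        with pytest.raises(ValueError):
            llps_speedup(1e-3, 1e-5, ng_params)


class TestRobustnessOptima:
    def test_boundary_maximizer_near_closed_form(self, ng_params):
        res = robustness_optima(1e-3, ng_params)
        # closed form (1/(V_r*nhat))^(1/(nhat+1)) = 500^(1/3) ~ 7.9
        assert res["K_c_starstar_closed"] == pytest.approx(7.937, rel=1e-3)
        assert res["K_c_starstar"] == pytest.approx(res["K_c_starstar_closed"], rel=0.3)

    def test_gain_monotone_in_shrinking_compartment(self, ng_params):
        gains = [
            robustness_optima(vr, ng_params)["rho_star_ratio"]
            for vr in (1e-2, 1e-3, 1e-4)
        ]
        assert gains[0] < gains[1] < gains[2]

    def test_window_ratio_approaches_one_for_large_compartment(self, ng_params):
        res = robustness_optima(0.9, ng_params)
        assert res["window_ratio"] == pytest.approx(1.0, abs=0.5)

    def test_nucleation_window_optimum_exceeds_one(self, ng_params):
        res = robustness_optima(1e-3, ng_params)
        assert res["K_c_nuc"] > 1.0
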