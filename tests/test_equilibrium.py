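import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from llps_assembly.equilibrium import (
    chain_equilibrium,
    critical_assembly_concentration,
    equilibrium_selectivity,
    solve_equilibrium,
)
from llps_assembly.params import AssemblyModelParams, CompartmentParams


class TestSolveEquilibrium:
    def test_mass_balance_closes(self, ng_params, make_compartment):
        comp = make_compartment(K_c=36.0)
        res = solve_equilibrium(2e-7, ng_params, comp)
        vr = comp.V_r
        mass = (
            vr * (res.rho1_c + 120 * res.rhoN_c) + res.rho1_bg + 120 * res.rhoN_bg
        ) / (1 + vr)
        assert mass == pytest.approx(2e-7, rel=1e-10)

    def test_law_of_mass_action_per_phase(self, ng_params, make_compartment):
        res = solve_equilibrium(2e-7, ng_params, make_compartment(K_c=10.0))
        g = ng_params.normalized().g_sub
        for rho1, rhoN in [(res.rho1_bg, res.rhoN_bg), (res.rho1_c, res.rhoN_c)]:
            assert math.log(rhoN) == pytest.approx(
                120 * (math.log(rho1) - g), rel=1e-9
            )
        assert res.rho1_c / res.rho1_bg == pytest.approx(10.0, rel=1e-12)

    def test_negligible_yield_below_cac(self, ng_params, make_compartment):
        comp = make_compartment(K_c=1.0, V_r=0.0)
        cac = critical_assembly_concentration(ng_params, comp)["rho_CAC0"]
        res = solve_equilibrium(cac / 10, ng_params, comp)
        assert res.xN < 1e-10

    def test_saturated_regime_matches_asymptote(self, ng_params, make_compartment):
        comp = make_compartment(K_c=1.0, V_r=0.0)
        cac = critical_assembly_concentration(ng_params, comp)["rho_CAC0"]
        res = solve_equilibrium(100 * cac, ng_params, comp)
        assert res.xN == pytest.approx(1 - cac / (100 * cac), rel=0.02)

    def test_smooth_between_asymptotes(self, ng_params, make_compartment):
        comp = make_compartment(K_c=1.0, V_r=0.0)
        cac = critical_assembly_concentration(ng_params, comp)["rho_CAC0"]
        xs = [
            solve_equilibrium(r, ng_params, comp).xN
            for r in np.geomspace(0.1 * cac, 10 * cac, 12)
        ]
        assert all(a < b for a, b in zip(xs, xs[1:]))
        assert xs[0] < 1e-10 and xs[-1] > 0.85

    def test_no_llps_limits_agree(self, ng_params, make_compartment):
        hom = solve_equilibrium(2e-7, ng_params, make_compartment(K_c=1.0, V_r=0.0))
        kc1 = solve_equilibrium(2e-7, ng_params, make_compartment(K_c=1.0, V_r=1e-3))
        assert hom.xN == pytest.approx(kc1.xN, rel=1e-9)
        assert hom.rho1_bg == pytest.approx(kc1.rho1_bg, rel=1e-9)

    def test_positive_gsub_rejected(self, make_compartment):
        with pytest.raises(ValueError):
            solve_equilibrium(
                1e-6, AssemblyModelParams(g_elong=5.0), make_compartment()
            )


class TestCAC:
    def test_homogeneous_value(self, ng_params, make_compartment):
        res = critical_assembly_concentration(
            ng_params, make_compartment(K_c=1.0, V_r=0.0)
        )
        # 120^(-1/120)*exp(-17) M, direct evaluation
        assert res["rho_CAC0"] == pytest.approx(3.978e-8, rel=1e-3)
        assert res["rho_CAC"] == res["rho_CAC0"]

    def test_enhancement_saturates_at_inverse_vr(self, ng_params, make_compartment):
        res = critical_assembly_concentration(ng_params, make_compartment(K_c=1e6))
        assert res["enhancement"] == pytest.approx(1e3, rel=0.15)

    def test_moderate_kc_enhancement_near_kc(self, ng_params, make_compartment):
        # K_c*V_r << 1: the CAC drops by ~K_c
        res = critical_assembly_concentration(ng_params, make_compartment(K_c=10.0))
        assert res["enhancement"] == pytest.approx(10.0, rel=0.2)


class TestSelectivity:
    def test_no_partitioning_gives_volume_fraction(self):
        assert equilibrium_selectivity(1.0, 1e-3, 120) == pytest.approx(
            1e-3 / 1.001, rel=1e-9
        )

    def test_kc2_is_essentially_total(self):
        x = equilibrium_selectivity(2.0, 1e-3, 120)
        assert 1.0 - x == pytest.approx(2.0**-120 / 1e-3, rel=1e-6)

    @given(
        kc=st.floats(min_value=1.0, max_value=50.0),
        vr=st.floats(min_value=1e-5, max_value=0.5),
        n=st.integers(min_value=10, max_value=200),
    )
    def test_monotone_in_each_argument(self, kc, vr, n):
        base = equilibrium_selectivity(kc, vr, n)
        assert equilibrium_selectivity(kc * 1.1, vr, n) >= base
        assert equilibrium_selectivity(kc, vr * 1.1, n) >= base
        assert equilibrium_selectivity(kc, vr, n + 1) >= base


class TestChainEquilibrium:
    def test_two_state_is_good_for_nucleated_chain(self, make_compartment):
        """With a nucleation barrier and a shell-closure bonus, intermediates
        are exponentially rare and the full chain must coincide with the
        two-state solution evaluated at the chain's per-subunit energy."""
        from llps_assembly.ng import ng_intermediate_energy

        p = AssemblyModelParams(N=20)
        g_sub = float(ng_intermediate_energy(p, 20)) / 20  # chain's per-subunit energy
        p = AssemblyModelParams(N=20, g_sub=g_sub)
        comp = make_compartment(K_c=1.0, V_r=0.0, rho_T=2e-7)
        full = chain_equilibrium(2e-7, p, comp)
        two = solve_equilibrium(2e-7, p, comp)
        assert full["xN"] == pytest.approx(two.xN, rel=1e-3)
        # intermediates carry negligible mass
        inter = np.sum(np.arange(2, 20) * full["rho_bg"][1:-1])
        assert inter < 1e-4 * 2e-7
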