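import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendrosim.errors import ConfigError, DomainError, UnsupportedModulationError
from dendrosim.mechanisms import (
    CaLVAParams,
    CaPoolParams,
    ConductanceProfile,
    GenericGateParams,
    IhAlmogParams,
    IhHayParams,
    NeuromodSpec,
    ProfileForm,
    RateTerm,
    RegionSelector,
    apply_neuromod,
    block,
    ca_pool_step,
    calva_rates,
    clear_hot_zones,
    constant_profile,
    hot_zone,
    ih_almog_rates,
    ih_hay_rates,
    nernst_eca,
)

V_GRID = np.arange(-120.0, 60.0 + 1e-9, 0.1)


class TestIhHay:
    def test_alpha_limit_at_voff(self):
        # L'Hopital limit of the linoid alpha at V = v_off_a
        h_inf, tau = ih_hay_rates(-154.9)
        alpha = 11.9 / 155.521
        beta = math.exp(-154.9 / 33.1) / 5.18135
        assert 1.0 / tau == pytest.approx(alpha + beta, rel=1e-6)

    def test_h_inf_at_voff_matches_independent_evaluation(self):
        alpha = 11.9 / 155.521
        beta = math.exp(-154.9 / 33.1) / 5.18135
        h_inf, _ = ih_hay_rates(-154.9)
        assert h_inf == pytest.approx(alpha / (alpha + beta), rel=1e-6)
        assert h_inf == pytest.approx(0.977, abs=5e-4)

    def test_asymptotics(self):
        assert ih_hay_rates(-400.0)[0] == pytest.approx(1.0, abs=1e-6)
        assert ih_hay_rates(100.0)[0] == pytest.approx(0.0, abs=1e-6)

    def test_continuous_through_singularity(self):
        vals = [ih_hay_rates(v)[0] for v in (-154.9 - 1e-4, -154.9, -154.9 + 1e-4)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[0] - vals[2] < 1e-5

    def test_monotone_decreasing(self):
        h_inf, _ = ih_hay_rates(V_GRID)
        assert np.all(np.diff(h_inf) < 0)

    def test_gates_bounded_taus_positive(self):
        h_inf, tau = ih_hay_rates(V_GRID)
        assert np.all((h_inf >= 0) & (h_inf <= 1))
        assert np.all(tau > 0)


class TestIhAlmog:
    def test_half_point(self):
        assert ih_almog_rates(-91.0)[0] == pytest.approx(0.5, abs=1e-12)

    def test_direct_evaluation_at_minus85(self):
        assert ih_almog_rates(-85.0)[0] == pytest.approx(1.0 / (1.0 + math.e), rel=1e-9)

    def test_tau_at_minus91_independent_evaluation(self):
        t_adj = 2.3 ** ((34.0 - 22.0) / 10.0)
        expected = 1.0 / (
            t_adj
            * (
                math.exp((0.0 + 91.0) / 40.1606426) / 2542.5883549
                + math.exp(-(0.0 + 91.0) / 16.1290323) / 11.40250855
            )
        )
        _, tau = ih_almog_rates(-91.0)
        assert tau == pytest.approx(expected, rel=1e-9)
        assert tau == pytest.approx(89.7, abs=0.2)

    def test_monotone_decreasing(self):
        h_inf, _ = ih_almog_rates(V_GRID)
        assert np.all(np.diff(h_inf) < 0)


class TestCaLVA:
    def test_half_points(self):
        m_inf, _, h_inf, _ = calva_rates(-40.0)
        assert m_inf == pytest.approx(0.5, abs=1e-12)
        m_inf, _, h_inf, _ = calva_rates(-90.0)
        assert h_inf == pytest.approx(0.5, abs=1e-12)

    def test_m_inf_direct_evaluation(self):
        m_inf, _, _, _ = calva_rates(-34.0)
        assert m_inf == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), rel=1e-9)

    def test_activation_rises_inactivation_falls(self):
        m_inf, _, h_inf, _ = calva_rates(V_GRID)
        assert np.all(np.diff(m_inf) > 0)
        assert np.all(np.diff(h_inf) < 0)

    def test_tau_temperature_adjustment(self):
        p = CaLVAParams()
        t_adj = 2.3 ** ((34.0 - 21.0) / 10.0)
        _, tau_m, _, tau_h = calva_rates(-35.0, p)
        assert tau_m == pytest.approx((5.0 + 20.0 / 2.0) / t_adj, rel=1e-9)
        _, _, _, tau_h50 = calva_rates(-50.0, p)
        assert tau_h50 == pytest.approx((20.0 + 50.0 / 2.0) / t_adj, rel=1e-9)

    def test_bounded(self):
        m_inf, tau_m, h_inf, tau_h = calva_rates(V_GRID)
        for g in (m_inf, h_inf):
            assert np.all((g >= 0) & (g <= 1))
        for t in (tau_m, tau_h):
            assert np.all(t > 0)


@given(v=st.floats(min_value=-120, max_value=60))
@settings(max_examples=50, deadline=None)
def test_all_gates_bounded_property(v):
    for h_inf, tau in (ih_hay_rates(v), ih_almog_rates(v)):
        assert 0.0 <= h_inf <= 1.0
        assert tau > 0
    m_inf, tau_m, h_inf, tau_h = calva_rates(v)
    assert 0.0 <= m_inf <= 1.0 and 0.0 <= h_inf <= 1.0
    assert tau_m > 0 and tau_h > 0


def test_gate_ode_converges_to_steady_state():
    # exponential updates at fixed V must reach the analytic steady state
    v = -70.0
    h_inf, tau = ih_hay_rates(v)
    h = 0.0
    dt = tau / 20.0
    for _ in range(200):  # 10 time constants
        h = h_inf + (h - h_inf) * math.exp(-dt / tau)
    assert abs(h - h_inf) < 1e-6


class TestNeuromod:
    def test_identity_is_bit_for_bit(self):
        p = IhHayParams()
        assert apply_neuromod(p, NeuromodSpec(dv=0.0, tau_scale=1.0)) is p

    def test_almog_shift_moves_half_point(self):
        p = apply_neuromod(IhAlmogParams(), NeuromodSpec(dv=5.0))
        assert ih_almog_rates(-86.0, p)[0] == pytest.approx(0.5, abs=1e-12)

    def test_hay_shift_pointwise(self):
        p = apply_neuromod(IhHayParams(), NeuromodSpec(dv=-10.0))
        base = IhHayParams()
        for v in np.linspace(-120, 40, 33):
            shifted, _ = ih_hay_rates(v, p)
            ref, _ = ih_hay_rates(v + 10.0, base)
            assert shifted == pytest.approx(ref, abs=1e-12)

    def test_shift_and_unshift_roundtrip(self):
        p0 = IhAlmogParams()
        p = apply_neuromod(apply_neuromod(p0, NeuromodSpec(dv=7.0)),
                           NeuromodSpec(dv=-7.0))
        for v in np.linspace(-120, 40, 17):
            a, ta = ih_almog_rates(v, p)
            b, tb = ih_almog_rates(v, p0)
            assert a == pytest.approx(b, abs=1e-12)
            assert ta == pytest.approx(tb, rel=1e-12)

    def test_tau_shift_switchable(self):
        base = IhHayParams()
        p = apply_neuromod(base, NeuromodSpec(dv=10.0, shift_tau=False))
        v = -80.0
        assert ih_hay_rates(v, p)[1] == pytest.approx(ih_hay_rates(v, base)[1])
        assert ih_hay_rates(v, p)[0] != pytest.approx(ih_hay_rates(v, base)[0])

    def test_tau_scale(self):
        p = apply_neuromod(IhAlmogParams(), NeuromodSpec(dv=0.0, tau_scale=0.25))
        _, tau = ih_almog_rates(-91.0, p)
        _, tau0 = ih_almog_rates(-91.0)
        assert tau == pytest.approx(tau0 / 4.0, rel=1e-12)

    def test_non_ih_target_rejected(self):
        with pytest.raises(UnsupportedModulationError):
            apply_neuromod(CaLVAParams(), NeuromodSpec(dv=5.0))


class TestProfiles:
    def hay_lva_profile(self):
        prof = constant_profile(("apical",), 187e-6)
        return hot_zone(prof, (685.0, 885.0), multiplier=100.0)

    def test_hot_zone_multiplier(self):
        prof = self.hay_lva_profile()
        assert prof.density_at("apical", 700.0) == pytest.approx(100 * 187e-6)
        assert prof.density_at("apical", 600.0) == pytest.approx(187e-6)

    def test_hot_zone_closed_boundaries_absolute(self):
        prof = constant_profile(("apical",), 3e-3)
        prof = hot_zone(prof, (585.0, 985.0), absolute=0.3)
        for x in (585.0, 985.0, 700.0):
            assert prof.density_at("apical", x) == pytest.approx(0.3)
        assert prof.density_at("apical", 584.99) == pytest.approx(3e-3)
        assert prof.density_at("apical", 985.01) == pytest.approx(3e-3)

    def test_removal_restores_baseline_everywhere(self):
        prof = clear_hot_zones(self.hay_lva_profile())
        xs = np.linspace(0, 1300, 53)
        assert np.allclose(prof.density(np.full(xs.shape, "apical"), xs), 187e-6)

    def test_block_to_zero_everywhere(self):
        prof = block(self.hay_lva_profile(), 0.0)
        xs = np.linspace(0, 1300, 27)
        assert np.all(prof.density(np.full(xs.shape, "apical"), xs) == 0.0)

    def test_block_identity(self):
        prof = block(self.hay_lva_profile(), 1.0)
        for x in (100.0, 700.0):
            assert prof.density_at("apical", x) == pytest.approx(
                self.hay_lva_profile().density_at("apical", x)
            )

    def test_block_restricted_to_dendrites_spares_soma(self):
        prof = constant_profile(("soma", "apical", "basal"), 2e-4)
        sel = RegionSelector(regions=("apical", "basal"))
        blocked = block(prof, 0.0, sel)
        assert blocked.density_at("soma", 0.0) == pytest.approx(2e-4)
        assert blocked.density_at("apical", 300.0) == 0.0
        assert blocked.density_at("basal", 100.0) == 0.0

    def test_overexpression_factor_two(self):
        prof = block(constant_profile(("apical",), 2e-4), 2.0)
        assert prof.density_at("apical", 10.0) == pytest.approx(4e-4)

    def test_negative_factor_rejected(self):
        with pytest.raises(ConfigError):
            block(constant_profile(("apical",), 1e-4), -1.0)

    def test_exp_form(self):
        form = ProfileForm(kind="exp", value=2e-4, c0=-0.8696, c1=2.087, lam=359.5)
        prof = ConductanceProfile(forms=(("apical", form),))
        x = 700.0
        expected = 2e-4 * (-0.8696 + 2.087 * math.exp(x / 359.5))
        assert prof.density_at("apical", x) == pytest.approx(expected, rel=1e-12)

    @given(x=st.floats(min_value=0, max_value=1300),
           factor=st.floats(min_value=0, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_densities_never_negative(self, x, factor):
        prof = block(self.hay_lva_profile(), factor)
        assert prof.density_at("apical", x) >= 0.0


class TestNernst:
    def test_printed_range_value(self):
        assert nernst_eca(1e-4, 2.0, 307.15) == pytest.approx(131.0, abs=0.1)

    def test_equal_concentrations(self):
        assert nernst_eca(0.5, 0.5, 307.15) == 0.0

    def test_monotone_decreasing_in_cai(self):
        cas = np.logspace(-5, 0, 13)
        es = [nernst_eca(c, 2.0, 307.15) for c in cas]
        assert np.all(np.diff(es) < 0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(DomainError):
            nernst_eca(0.0, 2.0, 307.15)


class TestCaPool:
    def test_fixed_point(self):
        p = CaPoolParams(gamma=2.0, tau_decay=50.0, ca_rest=1e-4)
        assert ca_pool_step(1e-4, 0.0, p, 0.5) == pytest.approx(1e-4, rel=1e-12)

    def test_decay_matches_closed_form(self):
        p = CaPoolParams(gamma=2.0, tau_decay=50.0, ca_rest=1e-4)
        ca = 5e-3
        t = 0.0
        for _ in range(400):
            ca = ca_pool_step(ca, 0.0, p, 0.25)
            t += 0.25
        expected = 1e-4 + (5e-3 - 1e-4) * math.exp(-t / 50.0)
        assert ca == pytest.approx(expected, rel=1e-9)

    def test_constant_inward_current_steady_state(self):
        p = CaPoolParams(gamma=0.01, tau_decay=20.0, ca_rest=1e-4)
        i_ca = -0.5  # inward (negative by convention)
        ca = p.ca_rest
        for _ in range(5000):
            ca = ca_pool_step(ca, i_ca, p, 0.1)
        assert ca == pytest.approx(p.ca_rest + 0.01 * 0.5 * 20.0, rel=1e-6)


class TestGenericGates:
    def test_sigmoid_form_half_point(self):
        g = GenericGateParams(name="m", v_half=-30.0, k_inf=5.0,
                              tau_min=1.0, tau_diff=2.0, v_half_t=-30.0, k_t=5.0)
        inf, tau = g.rates(-30.0)
        assert inf == pytest.approx(0.5)
        assert tau == pytest.approx(2.0)

    def test_alphabeta_form(self):
        g = GenericGateParams(
            name="n", form="alphabeta",
            alpha=RateTerm("exp", a=0.1, vh=-40.0, k=20.0),
            beta=RateTerm("exp", a=0.1, vh=-40.0, k=-20.0),
        )
        inf, tau = g.rates(-40.0)
        assert inf == pytest.approx(0.5)
        assert tau == pytest.approx(1.0 / 0.2)

    def test_linoid_rate_term_limit(self):
        term = RateTerm("linoid", a=0.01, vh=-55.0, k=-10.0)
        near = term(-55.0 + 1e-8)
        at = term(-55.0)
        assert at == pytest.approx(near, rel=1e-4)

    def test_evaluable_over_wide_range(self):
        for g in (
            GenericGateParams(name="m", v_half=-40.0, k_inf=6.0, tau_min=0.05),
            GenericGateParams(name="h", v_half=-45.0, k_inf=-6.0, tau_min=0.4,
                              tau_diff=6.0, v_half_t=-42.0, k_t=6.0),
        ):
            inf, tau = g.rates(np.array([-120.0, 0.0, 60.0]))
            assert np.all(np.isfinite(inf)) and np.all(np.isfinite(tau))
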