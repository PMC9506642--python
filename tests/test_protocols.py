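import itertools
import math

import numpy as np
import pytest
import scipy.stats

import dendrosim.protocols as P
from dendrosim.cable_engine import SimConfig, settle
from dendrosim.errors import ConfigError, DomainError
from dendrosim.protocols import (
    FICurve,
    combined_basal_apical,
    distance_sweep,
    fi_auc,
    fi_curve,
    find_threshold,
    grid_cells,
    grid_experiment,
    mann_whitney_u,
    split_neuromod_experiment,
    split_neuromod_variants,
)
from dendrosim.synapses import SquarePulse, SynapsePopulation

from conftest import passive_single_compartment


# ---------------------------------------------------------------------------
# f-I
# ---------------------------------------------------------------------------

class TestFICurve:
    def test_toy_trapezoid(self):
        assert fi_auc([0.0, 1.0], [0.0, 10.0]) == pytest.approx(5.0)

    def test_all_subthreshold_auc_zero(self):
        assert fi_auc([0.0, 0.5, 1.0], [0.0, 0.0, 0.0]) == 0.0

    def test_amplitudes_must_increase(self):
        with pytest.raises(ConfigError):
            FICurve(amplitudes=np.array([0.2, 0.1]),
                    frequencies=np.array([0.0, 1.0]), auc=0.0)

    def test_reduced_model_curve_monotone_and_positive(self, hotzone_model,
                                                       settled):
        curve = fi_curve(hotzone_model, [0.1, 0.25, 0.4],
                         onset=100.0, t_stop=1100.0,
                         count_window=(300.0, 1100.0),
                         initial_state=settled)
        assert curve.frequencies[-1] > 0
        assert np.all(np.diff(curve.frequencies) >= 0)
        assert curve.auc > 0

    def test_overexpression_increases_auc(self, hotzone_model, settled):
        over = hotzone_model.blocked("ih", 2.0)
        kw = dict(onset=100.0, t_stop=1100.0, count_window=(300.0, 1100.0))
        c0 = fi_curve(hotzone_model, [0.15, 0.3], initial_state=settled, **kw)
        c2 = fi_curve(over, [0.15, 0.3], settle_ms=1500.0, **kw)
        assert c2.auc >= c0.auc


# ---------------------------------------------------------------------------
# Threshold search (bisection contract on a synthetic predicate)
# ---------------------------------------------------------------------------

class _FakeResult:
    def __init__(self, spiking):
        self.spike_times = np.array([1.0]) if spiking else np.empty(0)


@pytest.fixture
def fake_run(monkeypatch):
    """Replace the simulator with a step predicate: spike iff amp >= 1.0."""

    def _run(model, stimuli, cfg, initial_state=None, **kw):
        return _FakeResult(stimuli[0] >= 1.0)

    monkeypatch.setattr(P, "run", _run)


class TestBisection:
    def test_step_predicate_threshold(self, fake_run):
        tr = find_threshold(None, lambda x: [x], cfg=SimConfig(t_stop=1.0),
                            seed_value=0.5, cap=300.0, tol=0.01)
        assert tr.converged and not tr.no_ap
        assert tr.value == pytest.approx(1.0, rel=0.01)

    def test_tol_halving_adds_one_iteration(self, fake_run):
        tr1 = find_threshold(None, lambda x: [x], cfg=SimConfig(t_stop=1.0),
                             seed_value=0.5, tol=0.02)
        tr2 = find_threshold(None, lambda x: [x], cfg=SimConfig(t_stop=1.0),
                             seed_value=0.5, tol=0.01)
        w1 = tr1.bracket_history[-1][1] - tr1.bracket_history[-1][0]
        w2 = tr2.bracket_history[-1][1] - tr2.bracket_history[-1][0]
        assert tr2.iterations == tr1.iterations + 1
        assert w2 == pytest.approx(w1 / 2.0)

    def test_no_spike_at_cap_flags_no_ap(self, monkeypatch):
        monkeypatch.setattr(P, "run",
                            lambda *a, **k: _FakeResult(False))
        tr = find_threshold(None, lambda x: [x], cfg=SimConfig(t_stop=1.0),
                            seed_value=0.5, cap=100.0)
        assert tr.no_ap and not tr.converged
        assert math.isnan(tr.value)

    def test_bisection_matches_exhaustive_scan(self, small_scenario):
        # brute-force 1 % grid scan as the independent oracle
        model = small_scenario
        state = settle(model, 1500.0)
        soma = model.tree.site(model.tree.root.id, 0.5)
        cfg = SimConfig(dt=0.025, t_stop=120.0)
        fam = lambda a: [SquarePulse(site=soma, onset=20.0, duration=2.0,
                                     amplitude=a)]
        tr = find_threshold(model, fam, cfg=cfg, initial_state=state, tol=0.01)

        def spikes(a):
            return len(P.run(model, fam(a), cfg,
                             initial_state=state).spike_times) > 0

        grid = tr.value * np.geomspace(0.9, 1.1, 22)  # ~1 % spacing
        first = next(a for a in grid if spikes(a))
        assert tr.value == pytest.approx(first, rel=0.02)

    def test_threshold_scales_inversely_in_linear_model(self):
        model = passive_single_compartment()
        state = None
        soma = model.tree.site(0, 0.5)
        cfg = SimConfig(dt=0.025, t_stop=60.0, v_init=-70.0,
                        spike_threshold=-30.0)

        def fam(scale_factor):
            return lambda x: [SquarePulse(site=soma, onset=5.0, duration=30.0,
                                          amplitude=x * scale_factor)]

        t1 = find_threshold(model, fam(1.0), cfg=cfg, tol=0.001).value
        t3 = find_threshold(model, fam(3.0), cfg=cfg, tol=0.001).value
        assert t3 == pytest.approx(t1 / 3.0, rel=0.01)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def brute_force_two_sided_p(a, b):
    """Enumerate every assignment of the pooled values to groups of size
    len(a)/len(b).  Counting arrangements whose min(U_a, U_b) is at most the
    observed one covers both tails, so no doubling is applied (this equals
    2·P(U ≤ u_min) by the symmetry of the null distribution)."""
    pooled = np.concatenate([a, b])
    n = len(a)
    obs_u = mann_whitney_u(a, b)[0]
    total = 0
    at_most = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u_min, _ = mann_whitney_u(pooled[mask], pooled[~mask])
        total += 1
        if u_min <= obs_u:
            at_most += 1
    return min(1.0, at_most / total)


class TestMannWhitney:
    def test_separated_pairs_exact(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_samples(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_symmetry(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 3.0, 6.0]
        assert mann_whitney_u(a, b)[1] == pytest.approx(mann_whitney_u(b, a)[1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_enumeration_n4(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, 4)
        b = rng.normal(0.5, 1.0, 4)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(brute_force_two_sided_p(a, b), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.0, 1.0, 5)
        _, p = mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.6, 1.0, 40)
        _, p = mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_constant_offset_significant_at_nsamp_40(self):
        rng = np.random.default_rng(5)
        a = rng.lognormal(0.0, 0.2, 40)
        b = a * 1.5  # constant relative offset between conditions
        _, p = mann_whitney_u(a, b)
        assert p < 0.05 / 66.0

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Grid experiments
# ---------------------------------------------------------------------------

def test_bonferroni_m_is_66_on_standard_grid():
    cells = grid_cells(range(200, 1301, 100))
    assert len(cells) == 66


def test_three_way_m_is_198():
    cells = grid_cells(range(200, 1301, 100))
    assert len(cells) * 3 == 198


SMALL_GRID = dict(x_values=(300.0, 800.0, 1300.0), n_samp=3,
                  t_stop=120.0, settle_ms=1000.0, cap=2.0)


@pytest.fixture(scope="module")
def small_pop():
    return SynapsePopulation(n=60, regions=("apical",), g_max=1.0, seed=0)


class TestGridExperiment:
    def test_identity_variants_null_result(self, small_scenario, small_pop):
        res = grid_experiment(
            {"a": small_scenario, "b": small_scenario}, small_pop, **SMALL_GRID
        )
        pair = ("a", "b")
        finite = np.isfinite(res.ratios[pair])
        assert np.allclose(res.ratios[pair][finite], 1.0)
        assert not res.significant[pair].any()
        assert res.m_tests == 3

    def test_thresholds_shared_placement_across_conditions(self, small_scenario,
                                                           small_pop):
        res = grid_experiment(
            {"a": small_scenario, "b": small_scenario}, small_pop, **SMALL_GRID
        )
        assert np.allclose(res.thresholds["a"], res.thresholds["b"],
                           equal_nan=True)

    def test_blocked_variant_differs(self, small_scenario, small_pop):
        res = grid_experiment(
            {"control": small_scenario,
             "blocked": small_scenario.blocked("ih", 0.0)},
            small_pop, **SMALL_GRID
        )
        pair = ("control", "blocked")
        finite = np.isfinite(res.ratios[pair])
        assert finite.any()
        assert not np.allclose(res.ratios[pair][finite], 1.0)

    def test_statistics_invariant_under_repeat_permutation(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 0.3, 10)
        b = rng.lognormal(0.2, 0.3, 10)
        u1, p1 = mann_whitney_u(a, b)
        perm = rng.permutation(10)
        u2, p2 = mann_whitney_u(a[perm], b[rng.permutation(10)])
        assert (u1, p1) == (u2, p2)

    def test_to_frame_round_trip(self, small_scenario, small_pop):
        res = grid_experiment(
            {"a": small_scenario, "b": small_scenario.blocked("ih", 0.0)},
            small_pop, **SMALL_GRID
        )
        df = res.to_frame()
        assert len(df) == 3
        assert {"x1_um", "x2_um", "median_a", "ratio_b_vs_a"} <= set(df.columns)

    def test_nsamp_validation(self, small_scenario, small_pop):
        with pytest.raises(ConfigError):
            grid_experiment({"a": small_scenario}, small_pop, n_samp=1)


class TestCombinedBasalApical:
    def test_zero_conductance_basal_equals_plain_grid(self, small_scenario,
                                                      small_pop):
        variants = {"control": small_scenario,
                    "blocked": small_scenario.blocked("ih", 0.0)}
        kw = dict(x_values=(300.0, 1300.0), n_samp=2, t_stop=120.0,
                  settle_ms=1000.0, cap=2.0)
        plain = grid_experiment(variants, small_pop, **kw)
        combo = combined_basal_apical(variants, small_pop, basal_kind="gaba",
                                      basal_n_gaba=20, basal_gaba_g_ns=0.0,
                                      **kw)
        for cond in variants:
            assert np.allclose(plain.thresholds[cond], combo.thresholds[cond],
                               equal_nan=True)

    def test_unknown_basal_kind(self, small_scenario, small_pop):
        with pytest.raises(ConfigError):
            combined_basal_apical({"a": small_scenario}, small_pop,
                                  basal_kind="dopamine")


class TestSplitNeuromod:
    def test_zero_shift_identical_to_control(self, small_scenario):
        df = split_neuromod_experiment(
            small_scenario, 0.0, 0.0, [400.0, 900.0],
            t_stop=120.0, settle_ms=1000.0, record_peak=False,
        )
        ctrl = df[df.variant == "control"].threshold.to_numpy()
        prox = df[df.variant == "proximal"].threshold.to_numpy()
        both = df[df.variant == "proximal_distal"].threshold.to_numpy()
        assert np.allclose(ctrl, prox)
        assert np.allclose(ctrl, both)

    def test_variant_construction(self, small_scenario):
        variants = split_neuromod_variants(small_scenario, 10.0, -10.0)
        assert set(variants) == {"control", "proximal", "proximal_distal"}
        assert len(variants["proximal"].neuromods) == 1
        assert len(variants["proximal_distal"].neuromods) == 2

    def test_boundary_outside_apical_rejected(self, small_scenario):
        with pytest.raises(ConfigError):
            split_neuromod_variants(small_scenario, 5.0, -5.0, boundary_um=5000.0)


class TestDistanceSweep:
    def test_determinism(self, small_scenario):
        variants = {"control": small_scenario}
        kw = dict(t_stop=120.0, settle_ms=1000.0, record_peak=False)
        df1 = distance_sweep(variants, [300.0, 700.0], **kw)
        df2 = distance_sweep(variants, [300.0, 700.0], **kw)
        assert np.array_equal(df1.threshold.to_numpy(), df2.threshold.to_numpy())

    def test_unknown_kind_rejected(self, small_scenario):
        with pytest.raises(ConfigError):
            distance_sweep({"a": small_scenario}, [300.0], kind="ramp")

    def test_peak_voltage_recorded(self, small_scenario):
        df = distance_sweep({"a": small_scenario}, [500.0],
                            t_stop=120.0, settle_ms=1000.0)
        assert np.isfinite(df.peak_local_v.iloc[0])
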