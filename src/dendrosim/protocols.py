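"""Excitability protocols: f-I curves, bisection threshold search, distance
sweeps, distributed-synapse grid experiments with nonparametric statistics,
combined basal/apical stimulation and split proximal/distal neuromodulation.

All stochastic protocols are driven by explicit seeds; repeats share seeds
across conditions so that synapse placements are paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cable_engine import (
    CompartmentalModel,
    EngineState,
    Probe,
    SimConfig,
    run,
    settle,
)
from .errors import ConfigError, DomainError
from .mechanisms import NeuromodSpec, RegionSelector
from .morphology import SiteRef, select_site
from .synapses import (
    AlphaSynapse,
    SquarePulse,
    SynapsePopulation,
    realize_population,
    scale_population,
)

APICAL_GRID_UM = tuple(float(x) for x in range(200, 1301, 100))


# ---------------------------------------------------------------------------
# f-I curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FICurve:
    amplitudes: np.ndarray  # nA, strictly increasing
    frequencies: np.ndarray  # Hz
    auc: float  # nA·Hz, trapezoid over the sampled amplitude range

    def __post_init__(self):
        if np.any(np.diff(self.amplitudes) <= 0):
            raise ConfigError("amplitudes must be strictly increasing")
        if np.any(self.frequencies < 0):
            raise ConfigError("frequencies must be non-negative")


def fi_auc(amplitudes, frequencies) -> float:
    """Trapezoid area under an f-I curve (nA·Hz)."""
    return float(np.trapezoid(np.asarray(frequencies), np.asarray(amplitudes)))


def fi_curve(
    model: CompartmentalModel,
    amplitudes: Sequence[float],
    *,
    onset: float = 200.0,
    t_stop: float = 16000.0,
    count_window: tuple[float, float] = (500.0, 16000.0),
    dt: float = 0.025,
    settle_ms: float = 1500.0,
    initial_state: EngineState | None = None,
) -> FICurve:
    """Somatic DC steps; frequency = spikes in ``count_window`` / window length.

    The pulse starts at ``onset`` and lasts to the end of the simulation.
    """
    amps = np.asarray(sorted(amplitudes), dtype=float)
    state = initial_state if initial_state is not None else settle(model, settle_ms, dt=dt)
    window_s = (count_window[1] - count_window[0]) / 1e3
    soma = model.tree.site(model.tree.root.id, 0.5)
    freqs = []
    for amp in amps:
        stim = SquarePulse(site=soma, onset=onset, duration=t_stop - onset,
                           amplitude=float(amp))
        res = run(model, [stim], SimConfig(dt=dt, t_stop=t_stop),
                  initial_state=state)
        n = np.count_nonzero(
            (res.spike_times >= count_window[0]) & (res.spike_times <= count_window[1])
        )
        freqs.append(n / window_s)
    freqs = np.asarray(freqs)
    return FICurve(amplitudes=amps, frequencies=freqs, auc=fi_auc(amps, freqs))


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Outcome of a bisection threshold search over a scalar stimulus family."""

    value: float  # nA or nS; NaN when flagged no-AP
    converged: bool
    no_ap: bool
    bracket_history: list[tuple[float, float]] = field(default_factory=list)
    iterations: int = 0
    peak_local_v: float = float("nan")  # mV at the stimulus site, at threshold


def find_threshold(
    model: CompartmentalModel,
    stimulus_family: Callable[[float], Sequence],
    *,
    cfg: SimConfig,
    initial_state: EngineState | None = None,
    seed_value: float = 0.1,
    cap: float = 300.0,
    tol: float = 0.01,
    site: SiteRef | None = None,
    max_iter: int = 60,
) -> ThresholdResult:
    """Bisect the smallest stimulus scalar that elicits a somatic spike.

    The bracket is found by doubling from ``seed_value`` up to ``cap``; if no
    spike occurs at the cap the result is flagged ``no_ap`` (not raised).
    Bisection stops when the relative bracket width falls below ``tol`` and
    the midpoint is returned.  When ``site`` is given, the local membrane
    potential peak at threshold is recorded.
    """
    if seed_value <= 0 or cap <= 0 or tol <= 0:
        raise ConfigError("seed_value, cap and tol must be positive")
    state = initial_state

    def spikes(x: float) -> bool:
        res = run(model, stimulus_family(x), cfg, initial_state=state)
        return len(res.spike_times) > 0

    history: list[tuple[float, float]] = []
    lo, hi = 0.0, seed_value
    iters = 0
    while not spikes(hi):
        iters += 1
        lo, hi = hi, hi * 2.0
        if hi > cap:
            return ThresholdResult(value=float("nan"), converged=False,
                                   no_ap=True, bracket_history=history,
                                   iterations=iters)
    history.append((lo, hi))
    # With co-active stimuli the family can be suprathreshold down to 0;
    # the absolute floor below keeps bisection on [0, x] from looping forever.
    floor = seed_value * tol * 1e-6
    while (hi - lo) > tol * hi and hi > floor and iters < max_iter:
        iters += 1
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
        history.append((lo, hi))
    value = 0.5 * (lo + hi)

    peak = float("nan")
    if site is not None:
        probe = Probe.voltage("_stim_site", site)
        cfg2 = replace(cfg, probes=tuple(cfg.probes) + (probe,))
        res = run(model, stimulus_family(value), cfg2, initial_state=state)
        peak = float(res.traces["_stim_site"].max())
    return ThresholdResult(value=value, converged=True, no_ap=False,
                           bracket_history=history, iterations=iters,
                           peak_local_v=peak)


# ---------------------------------------------------------------------------
# Distance sweeps
# ---------------------------------------------------------------------------

def distance_sweep(
    variants: dict[str, CompartmentalModel],
    distances: Sequence[float],
    *,
    region: str = "apical",
    kind: str = "pulse",  # 'pulse' (current) | 'alpha' (conductance)
    pulse_ms: float = 0.2,
    alpha_tau_ms: float = 5.0,
    onset: float = 20.0,
    t_stop: float = 200.0,
    dt: float = 0.025,
    settle_ms: float = 1500.0,
    cap: float = 300.0,
    tol: float = 0.01,
    extra_stimuli: Sequence = (),
    record_peak: bool = True,
) -> pd.DataFrame:
    """Threshold-vs-distance curves for several model variants.

    Sites are chosen by :func:`select_site` (thickest section at each
    distance).  Returns a tidy frame with columns variant, distance_um,
    threshold, no_ap, peak_local_v, peak_unphysiological (>100 mV).
    """
    if kind not in ("pulse", "alpha"):
        raise ConfigError(f"unknown stimulus kind {kind!r}")
    rows = []
    cfg = SimConfig(dt=dt, t_stop=t_stop)
    for name, model in variants.items():
        state = settle(model, settle_ms, dt=dt)
        for d in distances:
            site = select_site(model.tree, region, float(d))

            if kind == "pulse":
                fam = lambda x, s=site: [SquarePulse(site=s, onset=onset,
                                                     duration=pulse_ms,
                                                     amplitude=x),
                                         *extra_stimuli]
            else:
                fam = lambda x, s=site: [AlphaSynapse(site=s, onset=onset,
                                                      tau=alpha_tau_ms,
                                                      g_max=x),
                                         *extra_stimuli]
            tr = find_threshold(model, fam, cfg=cfg, initial_state=state,
                                cap=cap, tol=tol,
                                site=site if record_peak else None)
            rows.append(dict(
                variant=name,
                distance_um=float(d),
                threshold=tr.value,
                no_ap=tr.no_ap,
                peak_local_v=tr.peak_local_v,
                peak_unphysiological=bool(tr.peak_local_v > 100.0)
                if np.isfinite(tr.peak_local_v) else False,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements per U value (Gaussian-binomial recursion)."""
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)  # last element from sample A: U += m? (shifted)
    b = _u_counts(n, m - 1)
    size = n * m + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties.  The p-value uses
    exact enumeration of the U distribution when min(n, m) ≤ 8 and there are
    no ties, otherwise a normal approximation with tie and continuity
    corrections.  Returns ``(U_min, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise DomainError("samples must be non-empty")
    combined = np.concatenate([a, b])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(n + m)
    sorted_vals = combined[order]
    # midranks for ties
    i = 0
    while i < n + m:
        j = i
        while j + 1 < n + m and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_a = ranks[:n].sum()
    u_a = r_a - n * (n + 1) / 2.0
    u_b = n * m - u_a
    u_min = min(u_a, u_b)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and min(n, m) <= 8:
        counts = _u_counts(n, m)
        total = math.comb(n + m, n)
        cum = sum(counts[: int(u_min) + 1])
        p = min(1.0, 2.0 * cum / total)
        return u_min, p

    mu = n * m / 2.0
    nt = n + m
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (nt * (nt - 1))
    var = n * m / 12.0 * (nt + 1 - tie_term)
    if var <= 0:
        return u_min, 1.0
    z = (u_min + 0.5 - mu) / math.sqrt(var)
    from scipy.stats import norm  # local import keeps module load light

    p = min(1.0, 2.0 * float(norm.cdf(z)))
    return u_min, p


# ---------------------------------------------------------------------------
# Grid experiments
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    """Per-(x₁, x₂) threshold-conductance distributions and statistics.

    ``thresholds[cond]`` has shape (n_cells, n_samp); NaN marks no-AP
    repeats.  One statistical comparison per (cell, pair); Bonferroni m is
    the total number of tests actually performed.
    """

    x_values: tuple[float, ...]
    cells: list[tuple[float, float]]
    conditions: list[str]
    comparisons: list[tuple[str, str]]
    thresholds: dict[str, np.ndarray]
    medians: dict[str, np.ndarray]
    ratios: dict[tuple[str, str], np.ndarray]  # median(b)/median(a)
    u_stats: dict[tuple[str, str], np.ndarray]
    p_values: dict[tuple[str, str], np.ndarray]
    significant: dict[tuple[str, str], np.ndarray]
    no_ap: np.ndarray  # (n_cells,) bool: nothing spiked in some condition
    m_tests: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, (x1, x2) in enumerate(self.cells):
            row = dict(x1_um=x1, x2_um=x2, no_ap=bool(self.no_ap[ci]))
            for cond in self.conditions:
                row[f"median_{cond}"] = self.medians[cond][ci]
            for pair in self.comparisons:
                tag = f"{pair[1]}_vs_{pair[0]}"
                row[f"ratio_{tag}"] = self.ratios[pair][ci]
                row[f"U_{tag}"] = self.u_stats[pair][ci]
                row[f"p_{tag}"] = self.p_values[pair][ci]
                row[f"sig_{tag}"] = bool(self.significant[pair][ci])
            rows.append(row)
        return pd.DataFrame(rows)


def grid_cells(x_values: Sequence[float]) -> list[tuple[float, float]]:
    """Upper-triangular (x₁ < x₂) cells of the distance grid."""
    xs = sorted(float(x) for x in x_values)
    return [(x1, x2) for i, x1 in enumerate(xs) for x2 in xs[i + 1:]]


def grid_experiment(
    variants: dict[str, CompartmentalModel],
    pop_template: SynapsePopulation,
    *,
    x_values: Sequence[float] = APICAL_GRID_UM,
    n_samp: int = 40,
    base_seed: int = 0,
    activation_ms: float = 20.0,
    t_stop: float = 300.0,
    dt: float = 0.025,
    settle_ms: float = 1500.0,
    seed_value: float = 1e-3,  # nS (1 pS)
    cap: float = 1.0,  # nS per synapse
    tol: float = 0.01,
    alpha: float = 0.05,
    comparisons: list[tuple[str, str]] | None = None,
    extra_stimuli: Callable[[int], Sequence] | None = None,
) -> GridResult:
    """Threshold-conductance grids for spatially distributed synaptic stimuli.

    For every cell [x₁, x₂] and repeat, a population is placed with the
    repeat's seed (placement shared across conditions), the per-synapse
    threshold conductance is bisected per condition, and conditions are
    compared with a two-sided U-test, Bonferroni-corrected by the number of
    tests performed.  ``extra_stimuli(rep_seed)`` may supply co-active
    stimuli (e.g. basal drive), re-drawn per repeat.
    """
    if n_samp < 2:
        raise ConfigError("n_samp must be >= 2")
    conditions = list(variants)
    if comparisons is None:
        ref = conditions[0]
        comparisons = [(ref, c) for c in conditions[1:]]
    cells = grid_cells(x_values)
    n_cells = len(cells)
    m_tests = n_cells * len(comparisons)

    states = {c: settle(variants[c], settle_ms, dt=dt) for c in conditions}
    cfg = SimConfig(dt=dt, t_stop=t_stop)
    thresholds = {c: np.full((n_cells, n_samp), np.nan) for c in conditions}

    any_tree = variants[conditions[0]].tree
    for ci, (x1, x2) in enumerate(cells):
        for rep in range(n_samp):
            seed = base_seed + rep
            pop = replace(pop_template, interval=(x1, x2), seed=seed,
                          g_max=1.0, time_fixed=activation_ms)
            placed = realize_population(pop, any_tree)
            extra = list(extra_stimuli(seed)) if extra_stimuli is not None else []
            for cond in conditions:
                fam = lambda g, p=placed, e=extra: scale_population(p, g) + e
                tr = find_threshold(variants[cond], fam, cfg=cfg,
                                    initial_state=states[cond],
                                    seed_value=seed_value, cap=cap, tol=tol)
                thresholds[cond][ci, rep] = tr.value

    medians: dict[str, np.ndarray] = {}
    for c in conditions:
        med = np.full(n_cells, np.nan)
        for ci in range(n_cells):
            vals = thresholds[c][ci]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                med[ci] = np.median(vals)
        medians[c] = med

    no_ap = np.zeros(n_cells, dtype=bool)
    for ci in range(n_cells):
        for c in conditions:
            if not np.isfinite(thresholds[c][ci]).any():
                no_ap[ci] = True

    ratios, u_stats, p_values, significant = {}, {}, {}, {}
    for pair in comparisons:
        ca, cb = pair
        ratio = np.full(n_cells, np.nan)
        uu = np.full(n_cells, np.nan)
        pp = np.full(n_cells, np.nan)
        sig = np.zeros(n_cells, dtype=bool)
        for ci in range(n_cells):
            va, vb = thresholds[ca][ci], thresholds[cb][ci]
            ok = np.isfinite(va) & np.isfinite(vb)
            if no_ap[ci] or ok.sum() < 2:
                continue
            ratio[ci] = np.median(vb[ok]) / np.median(va[ok])
            uu[ci], pp[ci] = mann_whitney_u(va[ok], vb[ok])
            sig[ci] = pp[ci] < alpha / m_tests
        ratios[pair] = ratio
        u_stats[pair] = uu
        p_values[pair] = pp
        significant[pair] = sig

    return GridResult(
        x_values=tuple(sorted(float(x) for x in x_values)),
        cells=cells,
        conditions=conditions,
        comparisons=comparisons,
        thresholds=thresholds,
        medians=medians,
        ratios=ratios,
        u_stats=u_stats,
        p_values=p_values,
        significant=significant,
        no_ap=no_ap,
        m_tests=m_tests,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Combined basal/apical stimulation
# ---------------------------------------------------------------------------

def basal_threshold_conductance(
    model: CompartmentalModel,
    *,
    n_synapses: int = 2000,
    seed: int = 0,
    activation_ms: float = 20.0,
    t_stop: float = 300.0,
    dt: float = 0.025,
    settle_ms: float = 1500.0,
    cap: float = 1.0,
) -> float:
    """Per-synapse threshold conductance (nS) for a whole-basal population."""
    pop = SynapsePopulation(n=n_synapses, regions=("basal",), interval=None,
                            g_max=1.0, time_fixed=activation_ms, seed=seed)
    placed = realize_population(pop, model.tree)
    state = settle(model, settle_ms, dt=dt)
    tr = find_threshold(model, lambda g: scale_population(placed, g),
                        cfg=SimConfig(dt=dt, t_stop=t_stop),
                        initial_state=state, seed_value=1e-3, cap=cap)
    if tr.no_ap:
        raise DomainError("basal population cannot elicit a spike at the cap")
    return tr.value


def combined_basal_apical(
    variants: dict[str, CompartmentalModel],
    pop_template: SynapsePopulation,
    *,
    basal_kind: str = "glut",  # 'glut' | 'gaba' | 'none'
    basal_n_glut: int = 2000,
    basal_glut_fraction: float = 0.8,
    basal_n_gaba: int = 500,
    basal_gaba_g_ns: float = 0.2,  # 200 pS
    gaba_halfwidth_ms: float = 25.0,
    activation_ms: float = 20.0,
    basal_seed: int = 12345,
    **grid_kw,
) -> GridResult:
    """Grid experiment with a co-active basal stimulus.

    'glut': 2000 basal synapses at ``basal_glut_fraction`` of the control
    (first variant) basal threshold conductance, activated with the apical
    population.  'gaba': 500 GABAergic synapses at 200 pS with activation
    times drawn uniformly within ±25 ms of the apical activation time,
    re-drawn for every repeat from the repeat's seed.
    """
    if basal_kind not in ("glut", "gaba", "none"):
        raise ConfigError(f"unknown basal kind {basal_kind!r}")
    control = variants[next(iter(variants))]
    extra: Callable[[int], Sequence] | None = None

    if basal_kind == "glut":
        g_thr = basal_threshold_conductance(
            control, n_synapses=basal_n_glut, seed=basal_seed,
            activation_ms=activation_ms,
            t_stop=grid_kw.get("t_stop", 300.0),
            dt=grid_kw.get("dt", 0.025),
            settle_ms=grid_kw.get("settle_ms", 1500.0),
        )
        pop = SynapsePopulation(n=basal_n_glut, regions=("basal",),
                                g_max=basal_glut_fraction * g_thr,
                                time_fixed=activation_ms, seed=basal_seed)
        placed = realize_population(pop, control.tree)

        def extra(_seed: int, placed=placed):
            return list(placed)

    elif basal_kind == "gaba":
        def extra(seed: int):
            pop = SynapsePopulation(
                n=basal_n_gaba, regions=("basal",), g_max=basal_gaba_g_ns,
                composition="gaba", time_fixed=None,
                time_window=(activation_ms, gaba_halfwidth_ms),
                seed=seed + 7919,  # offset so placement ≠ apical placement
            )
            return realize_population(pop, control.tree)

    return grid_experiment(variants, pop_template,
                           activation_ms=activation_ms,
                           extra_stimuli=extra, **grid_kw)


# ---------------------------------------------------------------------------
# Split proximal/distal neuromodulation
# ---------------------------------------------------------------------------

def split_neuromod_variants(
    model: CompartmentalModel,
    dv_proximal: float,
    dv_distal: float,
    *,
    boundary_um: float = 500.0,
    shift_tau: bool = True,
    tau_scale: float = 1.0,
) -> dict[str, CompartmentalModel]:
    """Control / proximal-only / proximal+distal Ih modulation variants.

    Proximal = apical path distances in [0, boundary]; distal = beyond the
    boundary to the tip.
    """
    apical_hi = model.tree.region_extent("apical")[1]
    if not 0.0 < boundary_um < apical_hi:
        raise ConfigError("boundary must lie within the apical extent")
    prox = NeuromodSpec(
        selector=RegionSelector(regions=("apical",), interval=(0.0, boundary_um)),
        dv=dv_proximal, shift_tau=shift_tau, tau_scale=tau_scale,
    )
    dist = NeuromodSpec(
        selector=RegionSelector(regions=("apical",),
                                interval=(np.nextafter(boundary_um, np.inf),
                                          apical_hi)),
        dv=dv_distal, shift_tau=shift_tau, tau_scale=tau_scale,
    )
    return {
        "control": model,
        "proximal": model.modulated(prox),
        "proximal_distal": model.modulated(prox).modulated(dist),
    }


def split_neuromod_experiment(
    model: CompartmentalModel,
    dv_proximal: float,
    dv_distal: float,
    distances: Sequence[float],
    *,
    boundary_um: float = 500.0,
    shift_tau: bool = True,
    tau_scale: float = 1.0,
    **sweep_kw,
) -> pd.DataFrame:
    """Threshold-vs-distance curves under split apical Ih neuromodulation."""
    variants = split_neuromod_variants(
        model, dv_proximal, dv_distal,
        boundary_um=boundary_um, shift_tau=shift_tau, tau_scale=tau_scale,
    )
    return distance_sweep(variants, distances, **sweep_kw)
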