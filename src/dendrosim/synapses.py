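"""Stimulus and synapse models: square pulses, alpha conductances,
single-exponential AMPA/GABA synapses, two-state NMDA with Mg²⁺ block,
and seeded spatially-restricted synapse populations.

Conductances are in nS, currents in nA (I = g·(E − V) with g in μS would be
the engine's convention; these helpers return nS and the engine converts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np

from .errors import ConfigError, DomainError
from .morphology import SectionTree, SiteRef

E_GLU = 0.0  # mV, glutamatergic reversal
E_GABA = -80.0  # mV
MG_DEFAULT = 1.0  # mM; not printed in the source protocols, config-exposed


@dataclass(frozen=True)
class SquarePulse:
    """Injected current: ``amplitude`` nA for t in [onset, onset+duration)."""

    site: SiteRef
    onset: float
    duration: float
    amplitude: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigError("pulse duration must be positive")


def pulse_current(t, p: SquarePulse):
    t = np.asarray(t, dtype=float)
    out = np.where((t >= p.onset) & (t < p.onset + p.duration), p.amplitude, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AlphaSynapse:
    """Peak-normalized alpha conductance: g(t) peaks at g_max at onset + tau."""

    site: SiteRef
    onset: float
    tau: float
    g_max: float  # nS
    e_rev: float = E_GLU

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigError("alpha tau must be positive")
        if self.g_max < 0:
            raise ConfigError("g_max must be non-negative")


def alpha_conductance(t, p: AlphaSynapse):
    """g(t) = g_max·((t−onset)/τ)·exp(1−(t−onset)/τ) for t ≥ onset, else 0."""
    t = np.asarray(t, dtype=float)
    x = (t - p.onset) / p.tau
    out = np.where(x >= 0.0, p.g_max * x * np.exp(1.0 - x), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ExpSynapse:
    """Single-exponential synapse (AMPA default; set e_rev=-80 for GABA-A).

    The state s decays as exp(−dt/τ_s) between events and jumps by 1 at each
    spike; the current is g_max·s·(E_rev − V).
    """

    site: SiteRef
    spike_times: tuple[float, ...]
    tau_s: float = 2.0
    g_max: float = 0.0  # nS
    e_rev: float = E_GLU
    s: float = 0.0

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ConfigError("tau_s must be positive")
        if self.s < 0:
            raise ConfigError("state s must be non-negative")


def gaba_synapse(site: SiteRef, spike_times, tau_s: float = 2.0, g_max: float = 0.0) -> ExpSynapse:
    return ExpSynapse(site=site, spike_times=tuple(spike_times), tau_s=tau_s,
                      g_max=g_max, e_rev=E_GABA)


def exp_syn_update(s: float, dt: float, n_spikes: int, tau_s: float) -> float:
    """Exact decay over ``dt`` then ``n_spikes`` unit increments."""
    if dt <= 0:
        raise ConfigError("dt must be positive")
    return s * math.exp(-dt / tau_s) + n_spikes


def exp_syn_current(s: float, v: float, g_max: float, e_rev: float) -> float:
    """Synaptic current in nA for g_max in nS (g·(E − V), depolarizing > 0)."""
    return g_max * 1e-3 * s * (e_rev - v)


@dataclass
class NMDASynapse:
    """Two-state NMDA synapse with voltage-dependent Mg²⁺ block.

    dx/dt = −x/τ_x + δ(t − t_spike);
    ds/dt = −s/τ_s + α_s·x·(1 − s), so s saturates at 1.
    """

    site: SiteRef
    spike_times: tuple[float, ...]
    tau_x: float = 2.0
    tau_s: float = 100.0
    alpha_s: float = 2.0  # kHz
    mg: float = MG_DEFAULT
    g_max: float = 0.0  # nS
    e_rev: float = E_GLU
    s: float = 0.0
    x: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise ConfigError("NMDA state s must lie in [0, 1]")
        if self.x < 0:
            raise ConfigError("NMDA state x must be non-negative")


def nmda_block(v, mg: float = MG_DEFAULT):
    """Unblocked fraction B(V) = 1/(1 + [Mg]·exp(−0.062·V)/3.57)."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + mg * np.exp(-0.062 * v) / 3.57)
    return float(out) if out.ndim == 0 else out


def nmda_update(s: float, x: float, dt: float, n_spikes: int, p: NMDASynapse):
    """One step of the two-state kinetics (exact x decay, exponential-Euler s).

    The saturating drive α_s·x·(1−s) is integrated with x frozen at its
    within-step average, which keeps s in [0, 1] for any dt.
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    x_new = x * math.exp(-dt / p.tau_x)
    # mean of x over the step (exact for the pure-decay trajectory)
    x_bar = (x - x_new) * p.tau_x / dt if dt > 0 else x
    rate = 1.0 / p.tau_s + p.alpha_s * x_bar
    s_inf = p.alpha_s * x_bar / rate
    s_new = s_inf + (s - s_inf) * math.exp(-rate * dt)
    return min(max(s_new, 0.0), 1.0), x_new + n_spikes


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapsePopulation:
    """N synapses placed uniformly per unit dendritic length in a region band.

    ``composition``: 'ampa_nmda' places co-located AMPA+NMDA pairs sharing
    g_max; 'gaba' places GABA-A synapses.  ``time_window`` of (center, half)
    draws each activation time uniformly from [center−half, center+half];
    ``time_fixed`` activates every synapse at the same instant.
    """

    n: int
    regions: tuple[str, ...] = ("apical",)
    interval: tuple[float, float] | None = None  # closed [x1, x2] μm
    g_max: float = 0.0  # nS per synapse (per receptor for ampa_nmda)
    composition: str = "ampa_nmda"
    time_fixed: float | None = 2000.0
    time_window: tuple[float, float] | None = None  # (center, halfwidth)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("population size must be >= 1")
        if self.composition not in ("ampa_nmda", "gaba", "ampa", "nmda"):
            raise ConfigError(f"unknown composition {self.composition!r}")
        if (self.time_fixed is None) == (self.time_window is None):
            raise ConfigError("specify exactly one of time_fixed/time_window")


def _candidate_segments(tree: SectionTree, pop: SynapsePopulation):
    """Eligible (section, frac_lo, frac_hi, length) stretches inside the band."""
    segs = []
    for sec in tree.sections:
        if sec.region not in pop.regions or sec.region == "soma":
            continue
        d0, d1 = tree.start_distance(sec.id), tree.end_distance(sec.id)
        if pop.interval is None:
            lo, hi = d0, d1
        else:
            lo, hi = max(d0, pop.interval[0]), min(d1, pop.interval[1])
            if lo > hi:
                continue
        f0 = (lo - d0) / sec.length
        f1 = (hi - d0) / sec.length
        segs.append((sec.id, f0, f1, (f1 - f0) * sec.length))
    return segs


def realize_population(pop: SynapsePopulation, tree: SectionTree):
    """Place the population and draw activation times; deterministic per seed.

    Returns a list of :class:`ExpSynapse` / :class:`NMDASynapse` objects
    (AMPA+NMDA pairs share site and g_max).  Raises :class:`DomainError` if
    the selector contains no dendrite.
    """
    segs = _candidate_segments(tree, pop)
    total = sum(s[3] for s in segs)
    if not segs or total <= 0:
        raise DomainError("population selector matches no dendritic length")
    rng = np.random.default_rng(pop.seed)
    cum = np.cumsum([s[3] for s in segs])
    draws = rng.uniform(0.0, total, size=pop.n)
    seg_idx = np.searchsorted(cum, draws, side="right")
    seg_idx = np.minimum(seg_idx, len(segs) - 1)

    if pop.time_fixed is not None:
        times = np.full(pop.n, float(pop.time_fixed))
    else:
        c, h = pop.time_window
        times = rng.uniform(c - h, c + h, size=pop.n)

    out = []
    for k in range(pop.n):
        sid, f0, f1, seg_len = segs[seg_idx[k]]
        offset = draws[k] - (cum[seg_idx[k]] - seg_len)
        frac = f0 + (f1 - f0) * (offset / seg_len if seg_len > 0 else 0.0)
        frac = min(max(frac, 0.0), 1.0)
        site = tree.site(sid, frac)
        t = (float(times[k]),)
        if pop.composition == "gaba":
            out.append(gaba_synapse(site, t, g_max=pop.g_max))
        elif pop.composition == "ampa":
            out.append(ExpSynapse(site=site, spike_times=t, g_max=pop.g_max))
        elif pop.composition == "nmda":
            out.append(NMDASynapse(site=site, spike_times=t, g_max=pop.g_max))
        else:  # ampa_nmda pair sharing site and conductance
            out.append(ExpSynapse(site=site, spike_times=t, g_max=pop.g_max))
            out.append(NMDASynapse(site=site, spike_times=t, g_max=pop.g_max))
    return out


def scale_population(synapses, factor: float):
    """Return copies of placed synapses with g_max scaled by ``factor``."""
    return [replace(s, g_max=s.g_max * factor) if isinstance(s, (ExpSynapse, NMDASynapse))
            else s for s in synapses]


def population_rows(synapses, seed: int | None = None):
    """Placed synapses as plain dict rows (CSV-ready): site, distance, kind,
    g_max, activation times and the generating seed."""
    rows = []
    for s in synapses:
        kind = "nmda" if isinstance(s, NMDASynapse) else (
            "gaba" if s.e_rev == E_GABA else "ampa")
        rows.append(dict(
            section=s.site.section,
            frac=s.site.frac,
            distance_um=s.site.path_distance,
            kind=kind,
            g_max_ns=s.g_max,
            times_ms=";".join(f"{t:g}" for t in s.spike_times),
            seed=seed,
        ))
    return rows
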