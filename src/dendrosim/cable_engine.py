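"""Multicompartment membrane-equation integrator.

Solves C dV/dt = −Σ g·(V − E) − L·V + I_inj implicitly on the tree
(fixed-step; backward Euler by default, a Crank–Nicolson variant via
``scheme='cn'``), with Hodgkin-Huxley-style gates advanced by exponential
updates at fixed voltage within each step and an exactly-updated first-order
calcium pool.  Supports gating-trace capture and replay (clamping one gate to
a recorded time course).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernel
from .errors import ConfigError, DomainError, IntegrationError, UnsupportedModulationError
from .mechanisms import (
    CaPoolParams,
    ConductanceProfile,
    MechanismDef,
    NeuromodSpec,
    RegionSelector,
    block as _block_profile,
    clear_hot_zones,
    hot_zone as _add_hot_zone,
    shell_gamma,
    R_GAS,
    FARADAY,
)
from .morphology import REGIONS, CompartmentGraph, SectionTree, SiteRef, discretize
from .synapses import AlphaSynapse, ExpSynapse, NMDASynapse, SquarePulse

TAB_VMIN = -150.0
TAB_VMAX = 150.0
TAB_DV = 0.05


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """A membrane mechanism plus its spatial conductance distribution."""

    mech: MechanismDef
    profile: ConductanceProfile


class CompartmentalModel:
    """Discretized cell: compartments, mechanism instances, density profiles.

    Treat instances as immutable; the variant helpers (``blocked``,
    ``modulated``, ...) return modified copies so cached kernel arrays are
    never shared across variants.
    """

    def __init__(
        self,
        tree: SectionTree,
        channels: dict[str, Channel],
        *,
        cm_uf_cm2: float = 1.0,
        ra_ohm_cm: float = 100.0,
        max_seg_length: float = 20.0,
        ca_pool: CaPoolParams | None = None,
        v_init: float = -75.0,
        neuromods: tuple[tuple[str, NeuromodSpec], ...] = (),
        graph: CompartmentGraph | None = None,
    ):
        self.tree = tree
        self.graph = graph if graph is not None else discretize(
            tree, max_seg_length, ra_ohm_cm=ra_ohm_cm
        )
        self.channels = dict(channels)
        self.cm_uf_cm2 = cm_uf_cm2
        self.ca_pool = ca_pool
        self.v_init = v_init
        self.neuromods = neuromods
        self._cache: dict | None = None

    # -- variants --------------------------------------------------------
    def _copy(self, **kw) -> "CompartmentalModel":
        args = dict(
            tree=self.tree,
            channels=self.channels,
            cm_uf_cm2=self.cm_uf_cm2,
            ca_pool=self.ca_pool,
            v_init=self.v_init,
            neuromods=self.neuromods,
            graph=self.graph,
        )
        args.update(kw)
        return CompartmentalModel(**args)

    def with_channel(self, name: str, channel: Channel) -> "CompartmentalModel":
        ch = dict(self.channels)
        ch[name] = channel
        return self._copy(channels=ch)

    def with_profile(self, name: str, profile: ConductanceProfile) -> "CompartmentalModel":
        ch = dict(self.channels)
        ch[name] = replace(ch[name], profile=profile)
        return self._copy(channels=ch)

    def blocked(self, name: str, factor: float = 0.0,
                selector: RegionSelector = RegionSelector()) -> "CompartmentalModel":
        """Scale a channel's density by ``factor`` inside ``selector``."""
        return self.with_profile(
            name, _block_profile(self.channels[name].profile, factor, selector)
        )

    def with_hot_zone(self, name: str, interval, multiplier=None, absolute=None,
                      region: str = "apical") -> "CompartmentalModel":
        return self.with_profile(
            name,
            _add_hot_zone(self.channels[name].profile, interval,
                          multiplier=multiplier, absolute=absolute, region=region),
        )

    def without_hot_zones(self, name: str) -> "CompartmentalModel":
        return self.with_profile(name, clear_hot_zones(self.channels[name].profile))

    def modulated(self, spec: NeuromodSpec) -> "CompartmentalModel":
        """Apply (possibly region-restricted) Ih neuromodulation."""
        if spec.target not in self.channels:
            raise UnsupportedModulationError(f"no channel named {spec.target!r}")
        if spec.target != "ih":
            raise UnsupportedModulationError(
                "neuromodulation is only supported for the Ih channel"
            )
        return self._copy(neuromods=self.neuromods + ((spec.target, spec),))

    # -- assembly --------------------------------------------------------
    def _assembled(self) -> dict:
        if self._cache is not None:
            return self._cache
        g = self.graph
        n = g.n
        region_names = np.array([REGIONS[r] for r in g.region])
        names = sorted(self.channels)
        n_mech = len(names)
        mech_gbar = np.zeros((n_mech, n))
        mech_erev = np.zeros(n_mech)
        mech_is_ca = np.zeros(n_mech, dtype=np.bool_)
        gate_mech: list[int] = []
        gate_exp: list[int] = []
        gate_names: dict[tuple[str, str], int] = {}
        inf_rows: list[np.ndarray] = []
        tau_rows: list[np.ndarray] = []
        v_grid = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)

        for m, name in enumerate(names):
            ch = self.channels[name]
            dens = ch.profile.density(region_names, g.path_dist)  # S/cm²
            mech_gbar[m] = dens * g.area * 1e6  # μS
            if ch.mech.erev == "ca":
                mech_is_ca[m] = True
                if self.ca_pool is None:
                    raise ConfigError(
                        f"channel {name!r} needs a calcium pool (erev='ca')"
                    )
            else:
                mech_erev[m] = float(ch.mech.erev)
            for gd in ch.mech.gates:
                gate_names[(name, gd.name)] = len(gate_mech)
                gate_mech.append(m)
                gate_exp.append(gd.exponent)
                inf, tau = gd.rates(v_grid)
                inf = np.clip(np.asarray(inf, dtype=float), 0.0, 1.0)
                tau = np.maximum(np.asarray(tau, dtype=float), 1e-4)
                if not (np.all(np.isfinite(inf)) and np.all(np.isfinite(tau))):
                    raise ConfigError(
                        f"gate {name}.{gd.name} not evaluable over the table range"
                    )
                inf_rows.append(inf)
                tau_rows.append(tau)

        n_gate = len(gate_mech)
        nv = len(v_grid)
        inf_tab = np.vstack(inf_rows) if n_gate else np.zeros((0, nv))
        tau_tab = np.vstack(tau_rows) if n_gate else np.zeros((0, nv))
        dv_inf = np.zeros((n_gate, n))
        dv_tau = np.zeros((n_gate, n))
        tau_scale = np.ones((n_gate, n))
        for target, spec in self.neuromods:
            mask = spec.selector.mask(region_names, g.path_dist)
            for (name, _gname), gi in gate_names.items():
                if name == target:
                    dv_inf[gi, mask] += spec.dv
                    if spec.shift_tau:
                        dv_tau[gi, mask] += spec.dv
                    tau_scale[gi, mask] *= spec.tau_scale

        has_ca = bool(mech_is_ca.any()) and self.ca_pool is not None
        if has_ca:
            pool = self.ca_pool
            gamma = np.array(
                [shell_gamma(a, pool.depth_um, pool.free_fraction) for a in g.area]
            )
            eca_coef = R_GAS * pool.temp_k / (2.0 * FARADAY) * 1e3
        else:
            pool = CaPoolParams()
            gamma = np.zeros(n)
            eca_coef = 0.0

        self._cache = dict(
            names=names,
            parent=g.parent.astype(np.int64),
            ga=g.g_axial.astype(float),
            cm=self.cm_uf_cm2 * g.area * 1e3,  # μF/cm²·cm² = μF → nF
            mech_gbar=mech_gbar,
            mech_erev=mech_erev,
            mech_is_ca=mech_is_ca,
            gate_mech=np.asarray(gate_mech, dtype=np.int64),
            gate_exp=np.asarray(gate_exp, dtype=np.int64),
            gate_names=gate_names,
            inf_tab=inf_tab,
            tau_tab=tau_tab,
            v_grid=v_grid,
            dv_inf=dv_inf,
            dv_tau=dv_tau,
            tau_scale=tau_scale,
            has_ca=has_ca,
            gamma=gamma,
            eca_coef=eca_coef,
            pool=pool,
        )
        return self._cache

    def gate_index(self, mech: str, gate: str) -> int:
        a = self._assembled()
        key = (mech, gate)
        if key not in a["gate_names"]:
            raise DomainError(f"no gate {gate!r} in mechanism {mech!r}")
        return a["gate_names"][key]


# ---------------------------------------------------------------------------
# Simulation configuration, probes, results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Probe:
    """Something to record: membrane voltage, a gate state, [Ca] or E_Ca."""

    name: str
    kind: str  # 'v' | 'gate' | 'ca' | 'eca'
    site: SiteRef | None = None  # None = soma
    mech: str = ""
    gate: str = ""

    @staticmethod
    def voltage(name: str = "v_soma", site: SiteRef | None = None) -> "Probe":
        return Probe(name=name, kind="v", site=site)

    @staticmethod
    def gate_state(mech: str, gate: str, site: SiteRef | None = None,
                   name: str | None = None) -> "Probe":
        return Probe(name=name or f"{mech}.{gate}", kind="gate", site=site,
                     mech=mech, gate=gate)

    @staticmethod
    def calcium(name: str = "ca", site: SiteRef | None = None) -> "Probe":
        return Probe(name=name, kind="ca", site=site)


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.025
    t_stop: float = 1000.0
    scheme: str = "be"  # 'be' backward Euler | 'cn' Crank-Nicolson
    v_init: float | None = None  # None: use the model's v_init
    settle_ms: float = 0.0
    probes: tuple[Probe, ...] = ()
    spike_threshold: float = 0.0
    spike_min_isi: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.t_stop <= 0:
            raise ConfigError("dt and t_stop must be positive")
        if self.scheme not in ("be", "cn"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")


@dataclass
class EngineState:
    """Full dynamic state, reusable as the initial condition of a later run."""

    v: np.ndarray
    gates: np.ndarray
    ca: np.ndarray
    eca: np.ndarray

    def copy(self) -> "EngineState":
        return EngineState(self.v.copy(), self.gates.copy(), self.ca.copy(),
                           self.eca.copy())


@dataclass
class SimResult:
    t: np.ndarray
    traces: dict[str, np.ndarray]
    spike_times: np.ndarray
    final_state: EngineState | None = None

    def trace(self, name: str) -> np.ndarray:
        return self.traces[name]


# ---------------------------------------------------------------------------
# Spike detection
# ---------------------------------------------------------------------------

def detect_spikes(t, v, window=None, threshold: float = 0.0,
                  min_isi: float = 1.0) -> np.ndarray:
    """Times of upward threshold crossings with a minimum inter-event gap.

    Crossing times are linearly interpolated between samples; ``window`` is a
    closed interval (ms) restricting detection.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    if len(up) == 0:
        return np.empty(0)
    frac = (threshold - v[up]) / (v[up + 1] - v[up])
    times = t[up] + frac * (t[up + 1] - t[up])
    kept = [times[0]]
    for x in times[1:]:
        if x - kept[-1] >= min_isi:
            kept.append(x)
    times = np.asarray(kept)
    if window is not None:
        times = times[(times >= window[0]) & (times <= window[1])]
    return times


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------

def _initial_state(model: CompartmentalModel, v0: float) -> EngineState:
    a = model._assembled()
    n = model.graph.n
    v = np.full(n, float(v0), dtype=float)
    gates = np.zeros((a["inf_tab"].shape[0], n))
    for gi in range(gates.shape[0]):
        vv = v - a["dv_inf"][gi]
        gates[gi] = np.interp(vv, a["v_grid"], a["inf_tab"][gi])
    if a["has_ca"]:
        pool = a["pool"]
        ca = np.full(n, pool.ca_rest)
        eca = np.full(n, a["eca_coef"] * math.log(pool.ca_out / pool.ca_rest))
    else:
        ca = np.full(n, 1e-4)
        eca = np.zeros(n)
    return EngineState(v=v, gates=gates, ca=ca, eca=eca)


def _collect_stimuli(model: CompartmentalModel, stimuli, dt: float):
    g = model.graph

    def comp_of(site: SiteRef | None) -> int:
        return 0 if site is None else g.site_to_comp(site)

    pulses = [s for s in stimuli if isinstance(s, SquarePulse)]
    alphas = [s for s in stimuli if isinstance(s, AlphaSynapse)]
    esyns = [s for s in stimuli if isinstance(s, ExpSynapse)]
    nsyns = [s for s in stimuli if isinstance(s, NMDASynapse)]
    known = len(pulses) + len(alphas) + len(esyns) + len(nsyns)
    if known != len(list(stimuli)):
        raise ConfigError("unknown stimulus type in stimuli list")

    events = []
    for j, s in enumerate(esyns):
        for ts in s.spike_times:
            events.append((float(ts), 0, j))
    for j, s in enumerate(nsyns):
        for ts in s.spike_times:
            events.append((float(ts), 1, j))
    events.sort()

    return dict(
        pulse_comp=np.array([comp_of(s.site) for s in pulses], dtype=np.int64),
        pulse_on=np.array([s.onset for s in pulses]),
        pulse_off=np.array([s.onset + s.duration for s in pulses]),
        pulse_amp=np.array([s.amplitude for s in pulses]),
        alpha_comp=np.array([comp_of(s.site) for s in alphas], dtype=np.int64),
        alpha_on=np.array([s.onset for s in alphas]),
        alpha_tau=np.array([s.tau for s in alphas]),
        alpha_g=np.array([s.g_max * 1e-3 for s in alphas]),  # nS → μS
        alpha_e=np.array([s.e_rev for s in alphas]),
        esyn_comp=np.array([comp_of(s.site) for s in esyns], dtype=np.int64),
        esyn_decay=np.array([math.exp(-dt / s.tau_s) for s in esyns]),
        esyn_g=np.array([s.g_max * 1e-3 for s in esyns]),
        esyn_e=np.array([s.e_rev for s in esyns]),
        esyn_s=np.array([float(s.s) for s in esyns]),
        nsyn_comp=np.array([comp_of(s.site) for s in nsyns], dtype=np.int64),
        nsyn_g=np.array([s.g_max * 1e-3 for s in nsyns]),
        nsyn_e=np.array([s.e_rev for s in nsyns]),
        nsyn_s=np.array([float(s.s) for s in nsyns]),
        nsyn_x=np.array([float(s.x) for s in nsyns]),
        nsyn_xdecay=np.array([math.exp(-dt / s.tau_x) for s in nsyns]),
        nsyn_taux=np.array([s.tau_x for s in nsyns]),
        nsyn_taus=np.array([s.tau_s for s in nsyns]),
        nsyn_alpha=np.array([s.alpha_s for s in nsyns]),
        nsyn_mg=np.array([s.mg for s in nsyns]),
        ev_time=np.array([e[0] for e in events]),
        ev_kind=np.array([e[1] for e in events], dtype=np.int64),
        ev_idx=np.array([e[2] for e in events], dtype=np.int64),
    )


def _resolve_probes(model: CompartmentalModel, probes: Sequence[Probe]):
    g = model.graph
    kinds = {"v": 0, "gate": 1, "ca": 2, "eca": 3}
    kind_arr, a_arr, b_arr, names = [], [], [], []
    for p in probes:
        comp = 0 if p.site is None else g.site_to_comp(p.site)
        kind_arr.append(kinds[p.kind])
        a_arr.append(model.gate_index(p.mech, p.gate) if p.kind == "gate" else 0)
        b_arr.append(comp)
        names.append(p.name)
    return (
        np.asarray(kind_arr, dtype=np.int64),
        np.asarray(a_arr, dtype=np.int64),
        np.asarray(b_arr, dtype=np.int64),
        names,
    )


def run(
    model: CompartmentalModel,
    stimuli: Sequence = (),
    cfg: SimConfig = SimConfig(),
    *,
    initial_state: EngineState | None = None,
    return_state: bool = False,
    _replay: tuple[int, int, np.ndarray, np.ndarray] | None = None,
) -> SimResult:
    """Integrate the model and return recorded traces plus somatic spikes.

    A soma voltage probe named ``v_soma`` is always recorded.  When
    ``initial_state`` is given it is used verbatim (no settle phase);
    otherwise gates start at their steady state for the initial voltage and
    an optional stimulus-free settle phase of ``cfg.settle_ms`` runs first.
    """
    a = model._assembled()
    v0 = model.v_init if cfg.v_init is None else cfg.v_init
    if initial_state is not None:
        state = initial_state.copy()
    else:
        state = _initial_state(model, v0)
        if cfg.settle_ms > 0:
            state = settle(model, cfg.settle_ms, dt=cfg.dt, v0=v0, scheme=cfg.scheme)

    probes = list(cfg.probes)
    if not any(p.name == "v_soma" for p in probes):
        probes.insert(0, Probe.voltage())
    pk, pa, pb, names = _resolve_probes(model, probes)

    stim = _collect_stimuli(model, stimuli, cfg.dt)
    nsteps = int(round(cfg.t_stop / cfg.dt))
    out = np.empty((nsteps + 1, len(probes)))
    theta = 1.0 if cfg.scheme == "be" else 0.5

    if _replay is None:
        replay_gate, replay_comp = -1, 0
        replay_t = np.empty(0)
        replay_y = np.empty(0)
    else:
        replay_gate, replay_comp, replay_t, replay_y = _replay

    pool = a["pool"]
    err = _kernel.step_loop(
        a["parent"], a["ga"], a["cm"], theta,
        a["mech_gbar"], a["mech_erev"], a["mech_is_ca"],
        a["gate_mech"], a["gate_exp"],
        a["inf_tab"], a["tau_tab"], TAB_VMIN, TAB_DV,
        a["dv_inf"], a["dv_tau"], a["tau_scale"],
        state.gates,
        a["has_ca"], state.ca, a["gamma"], pool.ca_rest, pool.tau_decay,
        a["eca_coef"], pool.ca_out, state.eca,
        stim["pulse_comp"], stim["pulse_on"], stim["pulse_off"], stim["pulse_amp"],
        stim["alpha_comp"], stim["alpha_on"], stim["alpha_tau"],
        stim["alpha_g"], stim["alpha_e"],
        stim["esyn_comp"], stim["esyn_decay"], stim["esyn_g"], stim["esyn_e"],
        stim["esyn_s"],
        stim["nsyn_comp"], stim["nsyn_g"], stim["nsyn_e"], stim["nsyn_s"],
        stim["nsyn_x"], stim["nsyn_xdecay"], stim["nsyn_taux"], stim["nsyn_taus"],
        stim["nsyn_alpha"], stim["nsyn_mg"],
        stim["ev_time"], stim["ev_kind"], stim["ev_idx"],
        replay_gate, replay_comp, replay_t, replay_y,
        state.v, 0.0, cfg.dt, nsteps,
        pk, pa, pb, out,
    )
    if err >= 0:
        bad = np.flatnonzero(~np.isfinite(state.v))
        comp = int(bad[0]) if len(bad) else 0
        raise IntegrationError((err + 1) * cfg.dt, comp)

    t = np.arange(nsteps + 1) * cfg.dt
    traces = {name: out[:, q] for q, name in enumerate(names)}
    spikes = detect_spikes(t, traces["v_soma"], threshold=cfg.spike_threshold,
                           min_isi=cfg.spike_min_isi)
    return SimResult(
        t=t,
        traces=traces,
        spike_times=spikes,
        final_state=state if return_state else None,
    )


def settle(model: CompartmentalModel, settle_ms: float = 1000.0, *,
           dt: float = 0.025, v0: float | None = None,
           scheme: str = "be") -> EngineState:
    """Relax the model with no stimulus and return the steady state reached."""
    cfg = SimConfig(dt=dt, t_stop=settle_ms, scheme=scheme,
                    v_init=model.v_init if v0 is None else v0)
    res = run(model, (), cfg, initial_state=_initial_state(model, cfg.v_init),
              return_state=True)
    return res.final_state


# ---------------------------------------------------------------------------
# Gating capture & replay
# ---------------------------------------------------------------------------

def capture_gating(model, stimuli, cfg: SimConfig, mech: str, gate: str,
                   site: SiteRef | None = None):
    """Record one gate's time course; returns ``(t, values)``."""
    probe = Probe.gate_state(mech, gate, site, name="_capture")
    cfg2 = replace(cfg, probes=tuple(cfg.probes) + (probe,))
    res = run(model, stimuli, cfg2)
    return res.t, res.traces["_capture"]


def run_with_replay(model, stimuli, cfg: SimConfig, mech: str, gate: str,
                    trace_t, trace_y, site: SiteRef | None = None,
                    initial_state: EngineState | None = None) -> SimResult:
    """Re-run with the named gate clamped to a recorded trace.

    The trace must cover [0, t_stop]; all other state variables evolve
    normally.
    """
    trace_t = np.asarray(trace_t, dtype=float)
    trace_y = np.asarray(trace_y, dtype=float)
    if len(trace_t) != len(trace_y):
        raise DomainError("replay trace time/value length mismatch")
    if len(trace_t) < 2 or trace_t[0] > 0.0 or trace_t[-1] < cfg.t_stop - 1e-9:
        raise DomainError("replay trace must cover [0, t_stop]")
    gi = model.gate_index(mech, gate)
    comp = 0 if site is None else model.graph.site_to_comp(site)
    return run(model, stimuli, cfg, initial_state=initial_state,
               _replay=(gi, comp, trace_t, trace_y))
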