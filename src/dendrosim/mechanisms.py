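"""Channel kinetics, calcium handling, conductance profiles and modulation operators.

Units: voltages mV, times ms, concentrations mM, temperatures K unless noted,
channel densities S/cm².

Two hyperpolarization-activated (Ih) kinetic variants are provided, plus the
low-voltage-activated (LVA, T-type) Ca²⁺ channel gated as m²h.  Channels whose
kinetics are not built in are supported through :class:`GenericGateParams`
(sigmoid or α/β rational rate forms) loaded from configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, DomainError, UnsupportedModulationError

R_GAS = 8.314462618  # J/(mol K)
FARADAY = 96485.33212  # C/mol


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IhHayParams:
    """Ih gating in α/β form: α from a linoid term, β exponential.

    ``dv_inf``/``dv_tau`` shift the voltage dependence of the steady state /
    time constant (a +ΔV shift moves the curves rightward along the voltage
    axis); ``tau_scale`` multiplies the time constant.
    """

    v_off_a: float = -154.9
    v_slo_a: float = 11.9
    tau_a: float = 155.521
    v_off_b: float = 0.0
    v_slo_b: float = 33.1
    tau_b: float = 5.18135
    e_h: float = -45.0
    dv_inf: float = 0.0
    dv_tau: float = 0.0
    tau_scale: float = 1.0

    def __post_init__(self):
        if self.v_slo_a <= 0 or self.v_slo_b <= 0:
            raise ConfigError("slope factors must be positive")
        if self.tau_a <= 0 or self.tau_b <= 0 or self.tau_scale <= 0:
            raise ConfigError("time constants and tau_scale must be positive")


@dataclass(frozen=True)
class IhAlmogParams:
    """Ih gating as a closed-form sigmoid with a two-exponential time constant."""

    v_off: float = -91.0
    v_slo: float = 6.0
    t0: float = 2542.5883549
    t1: float = 11.40250855
    v_off_t1: float = 0.0
    v_off_t2: float = 0.0
    v_slo_t1: float = 40.1606426
    v_slo_t2: float = 16.1290323
    q10: float = 2.3
    temp_c: float = 34.0
    e_h: float = -33.0
    dv_inf: float = 0.0
    dv_tau: float = 0.0
    tau_scale: float = 1.0

    @property
    def t_adj(self) -> float:
        return self.q10 ** ((self.temp_c - 22.0) / 10.0)


@dataclass(frozen=True)
class CaLVAParams:
    """Low-voltage-activated Ca²⁺ channel, current gbar·m²·h·(E_Ca − V).

    The temperature adjustment t_adj = q10^((T − T_ref)/10) divides both time
    constants; the reference temperature is not printed with the kinetics and
    defaults to 21 °C (config-exposed).
    """

    v_off_m: float = -40.0
    v_slo_m: float = 6.0
    v_off_m_t: float = -35.0
    v_slo_m_t: float = 5.0
    v_off_h: float = -90.0
    v_slo_h: float = 6.4
    v_off_h_t: float = -50.0
    v_slo_h_t: float = 7.0
    tau_m_min: float = 5.0
    tau_m_diff: float = 20.0
    tau_h_min: float = 20.0
    tau_h_diff: float = 50.0
    q10: float = 2.3
    temp_ref_c: float = 21.0
    temp_c: float = 34.0

    def __post_init__(self):
        for name in ("v_slo_m", "v_slo_m_t", "v_slo_h", "v_slo_h_t"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def t_adj(self) -> float:
        return self.q10 ** ((self.temp_c - self.temp_ref_c) / 10.0)


@dataclass(frozen=True)
class CaPoolParams:
    """First-order intracellular Ca²⁺ pool.

    d[Ca]/dt = −γ·I_Ca − ([Ca] − ca_rest)/tau_decay, with the NEURON sign
    convention (inward Ca²⁺ current is negative, hence raises [Ca]).
    ``gamma`` is in mM per nA·ms for a single compartment; use
    :func:`shell_gamma` to derive it from a sub-membrane shell.
    """

    gamma: float = 1.0
    tau_decay: float = 80.0
    ca_rest: float = 1e-4
    ca_out: float = 2.0
    temp_k: float = 307.15
    free_fraction: float = 0.05
    depth_um: float = 0.1

    def __post_init__(self):
        for name in ("gamma", "tau_decay", "ca_rest", "ca_out", "temp_k"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


def shell_gamma(area_cm2: float, depth_um: float = 0.1, free_fraction: float = 0.05) -> float:
    """γ (mM per nA·ms) for a shell of ``depth_um`` under ``area_cm2`` of membrane."""
    depth_cm = depth_um * 1e-4
    volume_l = area_cm2 * depth_cm * 1e-3
    # 1 nA·ms = 1e-12 C; divalent ion; mmol = mol*1e3
    return free_fraction * 1e-12 / (2.0 * FARADAY) * 1e3 / volume_l


# ---------------------------------------------------------------------------
# Rate functions
# ---------------------------------------------------------------------------

def _linoid(x, v_slo):
    """x / (exp(x/v_slo) - 1) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    out = np.where(
        small,
        v_slo * (1.0 - x / (2.0 * v_slo)),
        safe / np.expm1(safe / v_slo),
    )
    return out


def ih_hay_rates(v, p: IhHayParams = IhHayParams()):
    """Steady state and time constant of the α/β-form Ih gate.

    α = (V − v_off_a) / (τ_a·(exp((V − v_off_a)/v_slo_a) − 1)), with the
    limit v_slo_a/τ_a at V = v_off_a; β = exp((V − v_off_b)/v_slo_b)/τ_b.
    Returns ``(h_inf, tau_ms)``; accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    vi = v - p.dv_inf
    vt = v - p.dv_tau

    def alpha(vv):
        return _linoid(vv - p.v_off_a, p.v_slo_a) / p.tau_a

    def beta(vv):
        return np.exp((vv - p.v_off_b) / p.v_slo_b) / p.tau_b

    a_i, b_i = alpha(vi), beta(vi)
    h_inf = a_i / (a_i + b_i)
    a_t, b_t = alpha(vt), beta(vt)
    tau = p.tau_scale / (a_t + b_t)
    return h_inf, tau


def ih_almog_rates(v, p: IhAlmogParams = IhAlmogParams()):
    """Steady state and time constant of the sigmoid-form Ih gate."""
    v = np.asarray(v, dtype=float)
    vi = v - p.dv_inf
    vt = v - p.dv_tau
    h_inf = 1.0 / (1.0 + np.exp((vi - p.v_off) / p.v_slo))
    rate = p.t_adj * (
        np.exp((p.v_off_t1 - vt) / p.v_slo_t1) / p.t0
        + np.exp(-(p.v_off_t2 - vt) / p.v_slo_t2) / p.t1
    )
    tau = p.tau_scale / rate
    return h_inf, tau


def calva_rates(v, p: CaLVAParams = CaLVAParams()):
    """LVA Ca²⁺ gating: returns ``(m_inf, tau_m, h_inf, tau_h)``.

    Activation m rises with depolarization, inactivation h falls; both time
    constants are sigmoid in V and divided by the q10 temperature factor.
    """
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(v - p.v_off_m) / p.v_slo_m))
    h_inf = 1.0 / (1.0 + np.exp((v - p.v_off_h) / p.v_slo_h))
    t_adj = p.t_adj
    tau_m = (
        p.tau_m_min + p.tau_m_diff / (1.0 + np.exp((v - p.v_off_m_t) / p.v_slo_m_t))
    ) / t_adj
    tau_h = (
        p.tau_h_min + p.tau_h_diff / (1.0 + np.exp((v - p.v_off_h_t) / p.v_slo_h_t))
    ) / t_adj
    return m_inf, tau_m, h_inf, tau_h


# ---------------------------------------------------------------------------
# Generic (config-loaded) gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateTerm:
    """One α or β term: 'exp' a·e^((V−vh)/k), 'linoid' a·(V−vh)/(e^((V−vh)/k)−1),
    or 'sigmoid' a/(1+e^((V−vh)/k))."""

    kind: str
    a: float
    vh: float
    k: float

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "exp":
            return self.a * np.exp((v - self.vh) / self.k)
        if self.kind == "linoid":
            return self.a * _linoid(v - self.vh, self.k)
        if self.kind == "sigmoid":
            return self.a / (1.0 + np.exp((v - self.vh) / self.k))
        raise ConfigError(f"unknown rate term kind {self.kind!r}")


@dataclass(frozen=True)
class GenericGateParams:
    """A plug-in gate: either sigmoid steady state + sigmoid time constant
    (``form='sigmoid'``) or α/β rational rates (``form='alphabeta'``).

    For the sigmoid form, ``k_inf`` is signed: positive for activation gates
    (rising with V), negative for inactivation gates.
    """

    name: str
    exponent: int = 1
    form: str = "sigmoid"
    # sigmoid form
    v_half: float = 0.0
    k_inf: float = 1.0
    tau_min: float = 1.0
    tau_diff: float = 0.0
    v_half_t: float = 0.0
    k_t: float = 1.0
    # alphabeta form
    alpha: RateTerm | None = None
    beta: RateTerm | None = None

    def rates(self, v):
        v = np.asarray(v, dtype=float)
        if self.form == "sigmoid":
            inf = 1.0 / (1.0 + np.exp(-(v - self.v_half) / self.k_inf))
            tau = self.tau_min + self.tau_diff / (
                1.0 + np.exp((v - self.v_half_t) / self.k_t)
            )
            return inf, tau
        if self.form == "alphabeta":
            a, b = self.alpha(v), self.beta(v)
            return a / (a + b), 1.0 / (a + b)
        raise ConfigError(f"unknown gate form {self.form!r}")


# ---------------------------------------------------------------------------
# Mechanism definitions (consumed by the cable engine)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateDef:
    name: str
    exponent: int
    rates: Callable  # V (mV) -> (inf, tau_ms)


@dataclass(frozen=True)
class MechanismDef:
    """A conductance-based membrane mechanism: product of gates times gbar.

    ``erev`` is a fixed reversal potential (mV) or the string ``'ca'`` for the
    Nernst potential of the local calcium pool.  ``feeds_ca`` marks currents
    that charge the pool.
    """

    name: str
    gates: tuple[GateDef, ...]
    erev: float | str
    feeds_ca: bool = False


def ih_hay_mechanism(p: IhHayParams = IhHayParams()) -> MechanismDef:
    return MechanismDef(
        name="ih",
        gates=(GateDef("h", 1, lambda v, p=p: ih_hay_rates(v, p)),),
        erev=p.e_h,
    )


def ih_almog_mechanism(p: IhAlmogParams = IhAlmogParams()) -> MechanismDef:
    return MechanismDef(
        name="ih",
        gates=(GateDef("h", 1, lambda v, p=p: ih_almog_rates(v, p)),),
        erev=p.e_h,
    )


def calva_mechanism(p: CaLVAParams = CaLVAParams()) -> MechanismDef:
    def m_rates(v, p=p):
        m_inf, tau_m, _, _ = calva_rates(v, p)
        return m_inf, tau_m

    def h_rates(v, p=p):
        _, _, h_inf, tau_h = calva_rates(v, p)
        return h_inf, tau_h

    return MechanismDef(
        name="calva",
        gates=(GateDef("m", 2, m_rates), GateDef("h", 1, h_rates)),
        erev="ca",
        feeds_ca=True,
    )


def generic_mechanism(
    name: str, gates: Sequence[GenericGateParams], erev: float | str, feeds_ca: bool = False
) -> MechanismDef:
    """Assemble a plug-in mechanism from config-loaded gate parameters."""
    gdefs = tuple(
        GateDef(g.name, g.exponent, (lambda v, g=g: g.rates(v))) for g in gates
    )
    return MechanismDef(name=name, gates=gdefs, erev=erev, feeds_ca=feeds_ca)


# ---------------------------------------------------------------------------
# Neuromodulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSelector:
    """Regions plus an optional closed path-distance interval (μm)."""

    regions: tuple[str, ...] | None = None  # None = everywhere
    interval: tuple[float, float] | None = None  # closed [lo, hi]

    def mask(self, region_names: np.ndarray, path_dist: np.ndarray) -> np.ndarray:
        m = np.ones(len(region_names), dtype=bool)
        if self.regions is not None:
            m &= np.isin(region_names, np.asarray(self.regions))
        if self.interval is not None:
            lo, hi = self.interval
            m &= (path_dist >= lo) & (path_dist <= hi)
        return m


WHOLE_CELL = RegionSelector()


@dataclass(frozen=True)
class NeuromodSpec:
    """A shift of Ih voltage dependence, optionally region-restricted.

    ``dv`` > 0 models cAMP-enhancing modulation (half-activation moved toward
    depolarized potentials), ``dv`` < 0 the cAMP-inhibiting direction.
    ``shift_tau`` selects whether the time constant's voltage dependence
    shifts along with the steady state; ``tau_scale`` rescales it.
    """

    target: str = "ih"
    selector: RegionSelector = WHOLE_CELL
    dv: float = 0.0
    tau_scale: float = 1.0
    shift_tau: bool = True

    def __post_init__(self):
        if self.tau_scale <= 0:
            raise ConfigError("tau_scale must be positive")


def apply_neuromod(p, spec: NeuromodSpec):
    """Return Ih params with the voltage dependence shifted by ``spec.dv``.

    Identity when dv = 0 and tau_scale = 1.  Raises
    :class:`UnsupportedModulationError` for non-Ih parameter types.
    """
    if spec.target != "ih" or not isinstance(p, (IhHayParams, IhAlmogParams)):
        raise UnsupportedModulationError(
            f"neuromodulation is only defined for Ih, got {type(p).__name__}"
        )
    if spec.dv == 0.0 and spec.tau_scale == 1.0:
        return p
    return replace(
        p,
        dv_inf=p.dv_inf + spec.dv,
        dv_tau=p.dv_tau + (spec.dv if spec.shift_tau else 0.0),
        tau_scale=p.tau_scale * spec.tau_scale,
    )


# ---------------------------------------------------------------------------
# Conductance profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileForm:
    """Functional form of a density (S/cm²) vs path distance (μm).

    kinds: 'constant' (value), 'linear' (value + slope·x),
    'exp' (value·(c0 + c1·e^(x/lam))), 'piecewise' (linear interp through
    xs/ys), 'table' (step function, value of the nearest-left knot).
    """

    kind: str
    value: float = 0.0
    slope: float = 0.0
    c0: float = 0.0
    c1: float = 1.0
    lam: float = 1.0
    xs: tuple[float, ...] = ()
    ys: tuple[float, ...] = ()

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "constant":
            return np.full_like(x, self.value)
        if self.kind == "linear":
            return self.value + self.slope * x
        if self.kind == "exp":
            return self.value * (self.c0 + self.c1 * np.exp(x / self.lam))
        if self.kind == "piecewise":
            return np.interp(x, self.xs, self.ys)
        if self.kind == "table":
            idx = np.clip(np.searchsorted(self.xs, x, side="right") - 1, 0, len(self.ys) - 1)
            return np.asarray(self.ys)[idx]
        raise ConfigError(f"unknown profile form {self.kind!r}")


@dataclass(frozen=True)
class HotZoneSpec:
    """Closed-interval override: multiply the base density or replace it."""

    lo: float
    hi: float
    multiplier: float | None = None
    absolute: float | None = None
    region: str = "apical"

    def __post_init__(self):
        if self.lo > self.hi:
            raise ConfigError("hot-zone interval reversed")
        if (self.multiplier is None) == (self.absolute is None):
            raise ConfigError("specify exactly one of multiplier/absolute")


@dataclass(frozen=True)
class ConductanceProfile:
    """Per-region density rules with hot-zone overrides and block factors.

    Evaluation order: base form → hot zones (closed intervals) → block
    multipliers.  Densities are clamped to be non-negative.
    """

    forms: tuple[tuple[str, ProfileForm], ...]  # (region, form)
    hot_zones: tuple[HotZoneSpec, ...] = ()
    blocks: tuple[tuple[RegionSelector, float], ...] = ()

    def density(self, region, x):
        """Density (S/cm²) at path distance ``x`` μm in ``region`` (vectorized)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        region = np.broadcast_to(np.atleast_1d(np.asarray(region)), x.shape)
        out = np.zeros_like(x)
        for reg, form in self.forms:
            m = region == reg
            if m.any():
                out[m] = form(x[m])
        for hz in self.hot_zones:
            m = (region == hz.region) & (x >= hz.lo) & (x <= hz.hi)
            if hz.multiplier is not None:
                out[m] *= hz.multiplier
            else:
                out[m] = hz.absolute
        for sel, factor in self.blocks:
            m = np.ones_like(x, dtype=bool)
            if sel.regions is not None:
                m &= np.isin(region, np.asarray(sel.regions))
            if sel.interval is not None:
                m &= (x >= sel.interval[0]) & (x <= sel.interval[1])
            out[m] *= factor
        return np.maximum(out, 0.0)

    def density_at(self, region: str, x: float) -> float:
        return float(self.density(region, x)[0])


def constant_profile(regions: Sequence[str], value: float) -> ConductanceProfile:
    form = ProfileForm(kind="constant", value=value)
    return ConductanceProfile(forms=tuple((r, form) for r in regions))


def block(profile: ConductanceProfile, factor: float,
          selector: RegionSelector = WHOLE_CELL) -> ConductanceProfile:
    """Scale densities inside ``selector`` by ``factor`` (0 = full block,
    2 = +100 % over-expression); densities elsewhere are untouched."""
    if factor < 0:
        raise ConfigError("block factor must be >= 0")
    return replace(profile, blocks=profile.blocks + ((selector, factor),))


def hot_zone(profile: ConductanceProfile, interval: tuple[float, float],
             multiplier: float | None = None, absolute: float | None = None,
             region: str = "apical") -> ConductanceProfile:
    """Add a hot-zone override over the closed ``interval`` (μm)."""
    hz = HotZoneSpec(lo=interval[0], hi=interval[1], multiplier=multiplier,
                     absolute=absolute, region=region)
    return replace(profile, hot_zones=profile.hot_zones + (hz,))


def clear_hot_zones(profile: ConductanceProfile) -> ConductanceProfile:
    """Remove every hot-zone override (zone density reverts to the baseline)."""
    return replace(profile, hot_zones=())


# ---------------------------------------------------------------------------
# Calcium pool
# ---------------------------------------------------------------------------

def nernst_eca(ca_i, ca_o, temp_k: float) -> float:
    """Nernst reversal (mV) of a divalent cation: (RT/2F)·ln(ca_o/ca_i)."""
    ca_i = np.asarray(ca_i, dtype=float)
    ca_o = np.asarray(ca_o, dtype=float)
    if np.any(ca_i <= 0) or np.any(ca_o <= 0):
        raise DomainError("concentrations must be positive")
    e = R_GAS * temp_k / (2.0 * FARADAY) * np.log(ca_o / ca_i) * 1e3
    return float(e) if e.ndim == 0 else e


def ca_pool_step(ca, i_ca, p: CaPoolParams, dt: float):
    """Advance the pool one step with the exact exponential update.

    ``i_ca`` (nA) follows the convention that inward Ca²⁺ current is
    negative; holding it constant over the step, the ODE
    d[Ca]/dt = −γ·I − ([Ca]−rest)/τ has fixed point rest − γ·I·τ.
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    ca = np.asarray(ca, dtype=float)
    i_ca = np.asarray(i_ca, dtype=float)
    ca_ss = p.ca_rest - p.gamma * i_ca * p.tau_decay
    out = ca_ss + (ca - ca_ss) * math.exp(-dt / p.tau_decay)
    return float(out) if out.ndim == 0 else out
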