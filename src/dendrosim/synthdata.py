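"""Stylized thick-tufted pyramidal morphologies and reduced-model scenarios.

The generated cell is a "ball and tuft": spherical soma, a long tapering
apical trunk (default 1300 μm) ending in a small tuft, and a handful of basal
branches.  The reduced mechanism set is leak + Ih (either kinetic variant,
exponential apical gradient) + LVA Ca²⁺ with an optional hot zone + calcium
pool + a generic two-gate-Na/one-gate-K somatic spike mechanism, which is
enough to exercise every protocol without any downloaded morphology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cable_engine import Channel, CompartmentalModel
from .errors import ConfigError
from .mechanisms import (
    CaLVAParams,
    CaPoolParams,
    ConductanceProfile,
    GenericGateParams,
    IhAlmogParams,
    IhHayParams,
    NeuromodSpec,
    ProfileForm,
    calva_mechanism,
    generic_mechanism,
    hot_zone,
    ih_almog_mechanism,
    ih_hay_mechanism,
)
from .morphology import Section, SectionTree

HOT_ZONE_HAY = (685.0, 885.0)  # μm, multiplier-style zone
HOT_ZONE_ALMOG = (585.0, 985.0)  # μm, absolute-density zone


@dataclass(frozen=True)
class BallAndTuftParams:
    soma_diam: float = 20.0
    trunk_length: float = 1300.0
    trunk_diam_prox: float = 4.0
    trunk_diam_dist: float = 2.0
    tuft_count: int = 2
    tuft_length: float = 300.0
    tuft_diam: float = 1.2
    basal_count: int = 5
    basal_length: float = 200.0
    basal_diam: float = 1.6
    length_jitter: float = 0.0  # fractional, seeded
    seed: int = 0

    def __post_init__(self):
        if self.trunk_length < 1300.0:
            raise ConfigError("apical trunk must reach at least 1300 μm")


def make_ball_and_tuft(p: BallAndTuftParams = BallAndTuftParams()) -> SectionTree:
    """Deterministic stylized L5-like morphology (given the seed)."""
    rng = np.random.default_rng(p.seed)

    def jit(x: float) -> float:
        if p.length_jitter <= 0:
            return x
        return x * float(1.0 + p.length_jitter * rng.uniform(-1.0, 1.0))

    sections = [
        Section(id=0, parent=-1, parent_frac=0.0, region="soma",
                length=p.soma_diam, diam_prox=p.soma_diam, diam_dist=p.soma_diam)
    ]
    nid = 1
    # apical trunk
    trunk_id = nid
    sections.append(
        Section(id=nid, parent=0, parent_frac=1.0, region="apical",
                length=p.trunk_length, diam_prox=p.trunk_diam_prox,
                diam_dist=p.trunk_diam_dist)
    )
    nid += 1
    for k in range(p.tuft_count):
        sections.append(
            Section(id=nid, parent=trunk_id, parent_frac=1.0, region="apical",
                    length=jit(p.tuft_length),
                    diam_prox=p.tuft_diam, diam_dist=max(p.tuft_diam * 0.6, 0.3))
        )
        nid += 1
    for k in range(p.basal_count):
        # slight monotone calibre spread keeps select_site ties deterministic
        d = p.basal_diam * (1.0 - 0.04 * k)
        sections.append(
            Section(id=nid, parent=0, parent_frac=1.0, region="basal",
                    length=jit(p.basal_length), diam_prox=d, diam_dist=d * 0.7)
        )
        nid += 1
    return SectionTree(sections)


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

# Generic somatic spike mechanism (standard two-gate Na / one-gate K).  The
# parameters are package defaults, not published constants.
NA_GATES = (
    GenericGateParams(name="m", exponent=3, v_half=-40.0, k_inf=6.0,
                      tau_min=0.06, tau_diff=0.0, v_half_t=-30.0, k_t=10.0),
    GenericGateParams(name="h", exponent=1, v_half=-45.0, k_inf=-6.0,
                      tau_min=0.4, tau_diff=6.0, v_half_t=-42.0, k_t=6.0),
)
K_GATES = (
    GenericGateParams(name="n", exponent=4, v_half=-40.0, k_inf=12.0,
                      tau_min=1.0, tau_diff=4.0, v_half_t=-50.0, k_t=15.0),
)
E_NA = 55.0
E_K = -85.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Reduced-model scenario: morphology plus channel-distribution choices."""

    morphology: BallAndTuftParams = BallAndTuftParams()
    ih_variant: str = "hay"  # 'hay' | 'almog' | 'none'
    ih_params: IhHayParams | IhAlmogParams | None = None
    # Ih apical gradient g(x) = base·(c0 + c1·exp(x/lam)); soma/basal constant
    ih_base: float = 2e-4  # S/cm²
    ih_c0: float = -0.8696
    ih_c1: float = 2.087
    ih_lam: float = 359.5  # μm
    ih_somatic: float = 2e-4
    # LVA Ca²⁺ distribution
    calva_base: float = 187e-6  # S/cm² along the apical dendrite
    calva_params: CaLVAParams = CaLVAParams()
    hot_zone_on: bool = True
    hot_zone_interval: tuple[float, float] = HOT_ZONE_HAY
    hot_zone_multiplier: float = 100.0
    hot_zone_absolute: float | None = None  # set to use an absolute density
    # passive / spike mechanism
    g_pas: float = 4e-5  # S/cm²
    e_pas: float = -88.0
    cm: float = 1.0
    ra: float = 100.0
    g_na: float = 0.6  # S/cm², soma only
    g_k: float = 0.5  # S/cm², soma only
    ca_pool: CaPoolParams = CaPoolParams()
    v_init: float = -75.0
    max_seg_length: float = 20.0
    neuromods: tuple[NeuromodSpec, ...] = ()

    def __post_init__(self):
        lo, hi = self.hot_zone_interval
        if self.hot_zone_on and hi > self.apical_extent():
            raise ConfigError("hot-zone interval outside the apical extent")

    def apical_extent(self) -> float:
        m = self.morphology
        return m.trunk_length + m.tuft_length


def make_scenario(spec: ScenarioSpec = ScenarioSpec()) -> CompartmentalModel:
    """Assemble the reduced compartmental model described by ``spec``."""
    tree = make_ball_and_tuft(spec.morphology)

    channels: dict[str, Channel] = {}
    leak_form = ProfileForm(kind="constant", value=spec.g_pas)
    channels["leak"] = Channel(
        mech=generic_mechanism("leak", (), erev=spec.e_pas),
        profile=ConductanceProfile(
            forms=tuple((r, leak_form) for r in ("soma", "axon", "basal", "apical"))
        ),
    )

    if spec.ih_variant != "none":
        if spec.ih_variant == "hay":
            p = spec.ih_params or IhHayParams()
            mech = ih_hay_mechanism(p)
        elif spec.ih_variant == "almog":
            p = spec.ih_params or IhAlmogParams()
            mech = ih_almog_mechanism(p)
        else:
            raise ConfigError(f"unknown ih variant {spec.ih_variant!r}")
        apical_form = ProfileForm(kind="exp", value=spec.ih_base, c0=spec.ih_c0,
                                  c1=spec.ih_c1, lam=spec.ih_lam)
        flat = ProfileForm(kind="constant", value=spec.ih_somatic)
        channels["ih"] = Channel(
            mech=mech,
            profile=ConductanceProfile(
                forms=(("apical", apical_form), ("soma", flat), ("basal", flat))
            ),
        )

    if spec.calva_base > 0:
        prof = ConductanceProfile(
            forms=(("apical", ProfileForm(kind="constant", value=spec.calva_base)),)
        )
        if spec.hot_zone_on:
            if spec.hot_zone_absolute is not None:
                prof = hot_zone(prof, spec.hot_zone_interval,
                                absolute=spec.hot_zone_absolute)
            else:
                prof = hot_zone(prof, spec.hot_zone_interval,
                                multiplier=spec.hot_zone_multiplier)
        channels["calva"] = Channel(mech=calva_mechanism(spec.calva_params),
                                    profile=prof)

    soma_only = lambda v: ConductanceProfile(
        forms=(("soma", ProfileForm(kind="constant", value=v)),)
    )
    channels["na"] = Channel(mech=generic_mechanism("na", NA_GATES, erev=E_NA),
                             profile=soma_only(spec.g_na))
    channels["kdr"] = Channel(mech=generic_mechanism("kdr", K_GATES, erev=E_K),
                              profile=soma_only(spec.g_k))

    model = CompartmentalModel(
        tree,
        channels,
        cm_uf_cm2=spec.cm,
        ra_ohm_cm=spec.ra,
        max_seg_length=spec.max_seg_length,
        ca_pool=spec.ca_pool if spec.calva_base > 0 else None,
        v_init=spec.v_init,
    )
    for nm in spec.neuromods:
        model = model.modulated(nm)
    return model


def scenario_manifest(model: CompartmentalModel, step_um: float = 10.0):
    """Channel densities sampled every ``step_um`` along each region.

    Returns a list of dict rows (region, distance_um, channel, density_S_cm2)
    suitable for CSV export; reproducible byte-for-byte from the scenario.
    """
    rows = []
    for region in ("soma", "basal", "apical"):
        try:
            lo, hi = model.tree.region_extent(region)
        except Exception:
            continue
        xs = np.arange(lo, hi + 1e-9, step_um) if hi > lo else np.array([0.0])
        for name in sorted(model.channels):
            prof = model.channels[name].profile
            dens = prof.density(np.full(xs.shape, region, dtype=object), xs)
            for x, d in zip(xs, dens):
                rows.append(
                    dict(region=region, distance_um=float(x), channel=name,
                         density_S_cm2=float(d))
                )
    return rows
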