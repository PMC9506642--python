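# dendrosim

Compartmental cable simulation of layer-V-pyramidal-like neurons, focused on
how hyperpolarization-activated (Ih/HCN) channels interact with a dendritic
hot zone of low-voltage-activated (LVA, T-type) Ca²⁺ channels to switch
between boosting and shunting dendritic input.

The package provides:

- **morphology** — SWC read/write, a branched `SectionTree` representation,
  thickest-section site selection at a path distance, and frustum-based
  spatial discretization into a `CompartmentGraph`.
- **mechanisms** — two Ih kinetic variants (α/β "linoid" form and closed-form
  sigmoid), LVA Ca²⁺ (m²h) kinetics, a first-order calcium pool with Nernst
  reversal, spatial conductance profiles (constant/linear/exponential/
  piecewise, with hot-zone overrides), channel block/over-expression
  operators, Ih neuromodulation (±ΔV half-activation shifts, optional τ
  scaling, region-restricted), and a generic plug-in gate interface for
  config-loaded channels.
- **synapses** — square current pulses, peak-normalized alpha conductances,
  single-exponential AMPA/GABA-A synapses, two-state NMDA with Mg²⁺ block,
  and seeded synapse populations placed uniformly per unit dendritic length.
- **cable_engine** — implicit fixed-step integration on the tree
  (Hines-ordered elimination; backward Euler, optional Crank–Nicolson),
  exponential gate updates from precomputed rate tables, spike detection,
  and gating-trace capture/replay (clamping one gate to a recorded time
  course). The inner loop is numba-JIT-compiled (set `DENDROSIM_NO_NUMBA=1`
  for the pure-Python fallback).
- **protocols** — f-I curves with trapezoid AUC, bisection threshold search
  with no-AP flagging, threshold-vs-distance sweeps, distributed-synapse
  threshold grids with a two-sided Mann-Whitney U test (exact enumeration for
  small ties-free samples) and Bonferroni correction, combined basal/apical
  stimulation, and split proximal/distal neuromodulation.
- **synthdata** — a deterministic "ball and tuft" stylized morphology
  (soma, ≥1300 μm tapering apical trunk + tuft, basal branches) and reduced
  scenarios (leak + Ih + LVA + Ca pool + generic Na/K soma spikes) so every
  protocol runs without downloaded data.
- **cli_io** — a `dendrosim` command with `make-morph`, `simulate`, `fi`,
  `threshold`, `sweep`, `grid`, `combo` and `splitmod` subcommands driven by
  one YAML config, writing CSV tables plus a JSON run manifest.

## CLI example

```yaml
# cfg.yaml
scenario:
  ih_variant: hay       # 'hay' | 'almog' | 'none'
  hot_zone_on: true
protocol:
  amplitudes_na: [0.1, 0.2, 0.3, 0.4]
output:
  dir: out
```

```bash
dendrosim fi --config cfg.yaml          # f-I curve + AUC
dendrosim sweep --config cfg.yaml       # threshold vs distance, control vs Ih-blocked
dendrosim grid --config cfg.yaml        # distributed-synapse grid + U-test stats
```

## Library example

```python
from dendrosim import make_scenario, ScenarioSpec, NeuromodSpec, settle
from dendrosim.protocols import distance_sweep

model = make_scenario(ScenarioSpec())          # reduced hot-zone scenario
variants = {
    "control": model,
    "ih_blocked": model.blocked("ih", 0.0),
    "camp_enhanced": model.modulated(NeuromodSpec(dv=+10.0)),
}
curves = distance_sweep(variants, distances=range(100, 1001, 100))
```

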