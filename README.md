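# neflow

Spatiotemporal analysis of neuromodulator sensor imaging: from two-channel
two-photon movies (a green extracellular norepinephrine sensor on neuropil,
a red somatic calcium indicator) to norepinephrine release/reuptake event
catalogs, NE-synchrony traces, and per-cell encoding models — together with
a synthetic movie generator that produces such recordings with known ground
truth for every stage.

## Who this is for

Labs imaging GPCR-based neuromodulator sensors alongside activity
indicators and asking *where and when* a neuromodulator is released, and
*whether the neuromodulator concentration immediately around a neuron
predicts that neuron's activity better than the field-wide average*. The
package implements the full chain as tested, configurable library code, and
— because raw in vivo data of this kind is rarely shareable — a first-class
simulator so that every analysis stage can be validated against planted
structure.

## The core quantities

For each cell *i* with soma mask S_i, a perisomatic annulus A_i (disk of
radius 15 µm minus somata and overlaps) and global field G_i (rest of the
FOV) define three standardized traces: localNE_i, globalNE_i (sensor
channel) and Ca_i (indicator channel). The analyses are:

* **Encoding model** (ordinary least squares, forced entry):

  Ca_i(t) ~ β₁·localNE_i(t) + β₂·globalNE_i(t) + β₃·globalCa_i(t)
            + β₄·localNE_i(t)·globalNE_i(t)

  fitted per cell, on all frames and split by NE-synchrony regime, and
  across expanding annulus radii.
* **NE synchrony**: sliding 30 s Pearson correlation between localNE_i and
  globalNE_i; the run-average trace below its own mean defines the
  low-synchrony regime.
* **Release/reuptake events**: Horn–Schunck optic flow on the preprocessed
  sensor channel; critical points classified by the Jacobian (source, sink,
  saddle, spirals); a high-fluorescence source followed by a nearby high
  sink is one release event, the low-fluorescence analog one reuptake
  event. Event maps give the spatial correlation of release vs reuptake
  sites; per-frame active-event counts give their temporal correlation.
* **Controls**: spatial autocorrelation with a double-exponential fit,
  partial correlation against the sensor-expression map, a permutation
  noise control (per-pixel time shuffling, full pipeline re-run on n null
  movies), and a mixed model `correlation ~ drug + (drug || mouse) +
  (drug || cell)` for condition contrasts.

See `docs/methods.md` for the models, the generator and all numerical
choices.

## Worked example

A complete synthetic run — simulate, preprocess, spatial statistics,
synchrony, event detection, per-cell models — in one command
(~1.5 minutes):

```sh
neflow run-all --out demo --seed 3 --fov-px 96 --duration-s 150 \
    --n-cells 9 --n-varicosities 24 --n-iter 30
```

prints (abridged):

```json
{
 "n_true_events": 212,
 "n_detected_events": 25,
 "spatial_r": 0.120,
 "temporal_r": -0.480,
 "spatial_fit_um": {"lambda1": 13.06, "lambda2": 999893.9},
 "n_low_periods": 3,
 "mean_beta": {
  "local_ne": 0.314,
  "global_ne": -0.175,
  "global_ca": 0.465,
  "local_x_global": -0.031
 }
}
```

Reading these numbers: the generator planted β_local = 0.3 and
β_globalCa = 0.5 — the population means recover them at 0.314 and 0.465
(the negative global-NE loading is the collinearity compensation discussed
in the methods note; local and global NE correlate at ~0.8). The short
spatial-autocorrelation length scale, 13.1 µm, tracks the 12 µm plume
diffusion scale; the second exponential is degenerate (flat shared
component). Detected release and reuptake events are spatially co-located
(r = +0.12) but temporally anti-phase (r = −0.48), the signature of reuptake
rebounding between release volleys at shared sites. Detection finds 25 of
212 true events: at this density plumes overlap heavily and only
well-isolated ones survive the precision-oriented thresholds — the
dedicated recovery benchmark with isolated events reaches ≥ 85% recall and
precision.

Individual stages are available as subcommands (`simulate`, `preprocess`,
`spatial-acf`, `synchrony`, `flow-events`, `cell-glm`, `radius-sweep`,
`noise-control`); every run writes a manifest with the package version,
seed, knob values and input hashes, and reruns with the same seed are
bit-identical. The same functionality is importable:

```python
from neflow import SimulationConfig, simulate_run
from neflow.preprocess import bleedthrough_correct, build_fields, extract_traces

movie, ne_field, truth = simulate_run(SimulationConfig(seed=1))
```

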