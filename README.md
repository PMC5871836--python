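# larvataxis

Analysis pipeline for larval phototaxis tracking experiments, together with
an agent-based synthetic larva generator that stands in for raw tracking
data.

The package covers:

* **stimulus** — the two lightscapes (a planar directional gradient and a
  triangular temporal intensity ramp with hold plateaus), the light-relative
  navigational compass (toward = 0°, left/CCW positive) and the 4-bin /
  2-bin heading partitions.
* **segmentation** — conversion of midline trajectories (13 fps, cm) into
  runs, reorientations (turns with head sweeps, or pauses) using a 20°/10°
  body-bend hysteresis, a per-animal speed threshold, a 1 s minimum run
  duration, and track-level filters (≥ 0.5 cm, ≥ 30 s, first minute
  discarded).
* **metrics** — navigation index, first-head-sweep direction, turn
  direction, run steering per heading bin, per-phase head-sweep acceptance
  rates, turn size/rate and their increase−decrease deltas, run speed and
  head-sweep sizes, with binomial SEMs for binary choice data.
* **stats** — two-tailed exact binomial and Fisher tests, one-/two-sample
  t-tests, one-way ANOVA with Dunnett many-to-one comparisons, and
  Benjamini–Hochberg adjustment across declared test families.
* **simulator** — run-and-turn agents with separable sensory channels: a
  temporal (klinotaxis) channel that accepts head sweeps depending on the
  sign of the intensity change sensed during the sweep, and a spatial
  (tropotaxis) channel that biases sweep side and run steering by the
  left–right eye intensity difference. Eye ablation, directional eye
  acceptance cones and wall reflection are modeled; output is midline
  trajectories plus a ground-truth event log.
* **io / cli** — tab-separated trajectory and event dialects, YAML stimulus
  and simulation configs, and a `larvataxis` command with `simulate`,
  `segment`, `analyze` and `report` subcommands.

## CLI

```bash
# generate a synthetic experiment batch
larvataxis simulate --config sim.yaml --out out/sim --seed 1

# segment one trajectory file
larvataxis segment --tracks out/sim/tracks_exp000.tsv --out out/seg

# full analysis (metrics + statistics)
larvataxis analyze --tracks out/sim/tracks_exp000.tsv \
    --stimulus stimulus.yaml --out out/analysis

# human-readable summary
larvataxis report --in out/analysis
```

Exit codes: 0 success, 2 validation failure, 3 empty result after
filtering. For achiral pooling of lateralized groups pass the group to be
mirrored via `--tracks-mirror` together with `--achiral-merge`.

A minimal stimulus config:

```yaml
type: temporal        # or: directional | none
i_max: 380.0
t_ramp_s: 25.5
t_hold_s: 4.5
n_cycles: 11
exclusion_margin_s: 1.0
phase_order: up_first
```

## Conventions

Units are cm, seconds, degrees and µW/cm² throughout. Arena coordinates
have the origin at the corner of the light-side edge; headings are degrees
CCW from +x; compass angles are relative to the light direction with the
animal's left positive. All randomness flows through explicit seeds.
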