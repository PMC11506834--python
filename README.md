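# myostab

Involuntary posture stabilization on desk-scale musculoskeletal chains:
an actor–critic reinforcement learner on a normalized Gaussian network
(ACRL–NGN) combined with antagonistic feedback control of muscle length
change, plus the comparative experiment protocols (muscle-length feedback
vs joint-angle feedback vs none) and frozen-policy posture-change
predictions.

## What is in here

| module | role |
| --- | --- |
| `myostab.plant` | deterministic forward simulation of a gravity-loaded rigid-link chain driven by muscle action lines (constant moment arms, semi-implicit Euler at 0.01 s) |
| `myostab.ngn` | normalized Gaussian network: clipped (angle-error, velocity-error) state, basis evaluation, linear critic/actor read-outs, JSON snapshots |
| `myostab.acrl` | continuous-time actor–critic step: reward, TD error (discount 0.8/step), eligibility traces (decay 0.8/step), critic/actor updates, value-modulated uniform noise, sigmoid activation map |
| `myostab.fcm` | activation-ceiling feedback models: muscle-length (`ml`), joint-angle contribution table (`ja`), constant (`none`) |
| `myostab.experiments` | 300-trial training protocol with ±5° stabilization scoring, report-trial summary tables, frozen-policy predictions |
| `myostab.fixtures` | desk-scale plants: `upper_limb_analog` (5 joints / 14 muscles), `lower_limb_analog` (5 joints / 16 muscles, biarticular-loaded), `two_link_arm`, randomized plants for property tests |
| `myostab.config`, `myostab.cli` | YAML run configs with strict schema + provenance, `myostab train/predict/summarize` |

## CLI

```bash
# 300-trial training run (defaults) on the upper-limb analog
myostab train --fixture upper --fcm ml --seed 0 --out runs/upper_ml

# short smoke run
myostab train --fixture two-link --fcm none --trials 5 --out runs/smoke

# frozen-policy prediction from a fixed posture
myostab predict --snapshot runs/upper_ml/network_trial300.json \
                --posture examples/case_a.yaml --out runs/case_a

# merge summaries from several runs into one table
myostab summarize runs/*/summary.json --out summary_all.csv
```

A posture YAML maps joint names to initial angles in degrees and may name
the fixture: `{fixture: upper_limb_analog, ELV: 0, ELW: 0, SHU: 0, SHV: -90, SHW: 0}`.

Run configs are YAML with sections `plant`, `learner`, `ngn`, `fcm`,
`protocol`, `reward_targets`, `seed`; unknown keys are rejected and every
default is tagged in `myostab.config.PROVENANCE` as a published default or
an artifact choice.  Every output directory contains `run_metadata.json`
(config + seed + package version) sufficient to reproduce the run.

## Notes on the length-feedback sign

The muscle-length feedback ceiling is `sig(∓500·Δl + 5)` with
`Δl = (l − l0)/l0`.  The module exposes both slopes via
`ml_sign: as_printed | narrative`:

* `as_printed` (module default) lowers a stretched muscle's ceiling.  As
  positional feedback this is destabilizing: on every fixture it drives
  the limb to its joint stops (0/5 stabilized) and no learning recovers it.
* `narrative` raises a stretched muscle's ceiling — a stretch reflex —
  and reproduces the comparative results.  The experiment configurations
  and the acceptance report use this slope.

Fixture masses, damping, gravity coefficients and muscle forces are
artifact choices (documented in `myostab.fixtures`), sized so the
stretch-feedback spring still holds posture in the learner's late
low-co-activation regime.
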