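# afsnapshot

Simulation toolkit for estimating how well **once-daily snapshot ECG
monitoring** detects atrial tachycardia / atrial fibrillation (AT/AF), given
per-patient daily AT/AF burden recorded by a continuously monitoring cardiac
implantable electronic device (CIED).

The model: on a day with `b` hours of AT/AF, a single instantaneous snapshot
succeeds with probability `b / 24`; a patient is detected if any day in a
contiguous monitoring window (default lengths 14/28/56/112/365 days, starting
day 31 after a 30-day post-implant blanking period) succeeds. Detection is
estimated two ways — by Bernoulli Monte Carlo (default 5,000 repetitions) and
by the exact closed form `1 − Π(1 − b_d/24)` — so each path serves as an
oracle for the other. A day counts as an AF day only when its burden strictly
exceeds 5 minutes; by default such sub-threshold days contribute zero
detection probability (`--policy raw` uses the raw ratio instead).

## Layout

- `afsnapshot.burden_model` — sparse daily-burden series, validation,
  blanking, AF-day rule, burden summaries, long-form CSV I/O.
- `afsnapshot.synthetic_cohort` — seeded generator of synthetic cohorts
  (zero-inflated log-normal AF-day occurrence and burden, plus a persistent-AF
  point mass) calibrated against its own targets: cohort median average
  burden ≈ 0.044 h/day, median max daily burden ≈ 5.5 h, median ≈ 1.6% of
  days with AF, ~80% of patients under 1 h/day.
- `afsnapshot.snapshot_simulator` — per-patient, per-window Monte Carlo and
  analytic detection; per-patient RNG substreams derived from one master seed
  by stable hashing of the patient id (cohort subsetting never shifts draws).
- `afsnapshot.cohort_analysis` — eligibility, CIED-detected denominators,
  CHADS₂ and burden stratification (cohort-median split or fixed cutoff such
  as 5.5 h/day), detection tables with 95% binomial CIs. Clopper–Pearson is
  the default CI method: it exactly reproduces the printed intervals of the
  reference tables (e.g. 126/254 → 49.6 [43.3–55.9]%), whereas Wilson gives
  [43.5–55.7].
- `afsnapshot.pipeline` / `afsnapshot.cli` — YAML-configured, fully seeded
  `generate` / `simulate` / `report` / `run` subcommands; identical
  config + seed yields byte-identical JSON artifacts, and `manifest.json` can
  replay a run exactly.

## CLI

```bash
# synthetic cohort (CSV + covariates + calibration report)
afsnapshot generate --seed 1 --out out/

# stratified detection table from a cohort CSV
afsnapshot report --cohort out/cohort.csv --covariates out/covariates.csv \
    --windows 14,28,56,112,365 --reps 5000 --seed 1 \
    --strata chads2,median_burden --out report/

# or everything from a YAML config
afsnapshot run --config config.yaml
```

Example `config.yaml`:

```yaml
seed: 1
windows: [14, 28, 56, 112, 365]
n_reps: 5000
policy: zero            # or raw
ci_method: clopper_pearson
strata: [all, chads2, median_burden]   # also fixed_burden:5.5
generator:              # omit and set burden_csv/covariates_csv to use real data
  n_patients: 370
output_dir: out
```

Input format: long-form CSV `patient_id,day_index,burden_hours` (1-based day
since implant, hours in [0, 24]; absent days are zero burden) plus a
covariates CSV `patient_id,chads2,baseline_flag,followup_days`.

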