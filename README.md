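# ptvmargin

PTV-margin estimation for robotically tracked moving tumors.

The package implements the van Herk margin recipes (the classic
`2.5Σ + 0.7σ` rule and the SBRT variant with a penumbra term), their
five-component extension for robotic tracking systems, and a
covariance-augmented modification in which the combined random error of the
correlation-model and prediction residuals carries their covariance:
`σ_new² = σ_mod² + σ_pred² + 2·cov`. Around the formulas it provides the full
workflow: a documented CSV schema for per-fraction tracking-error logs,
systematic/random error decomposition, Pearson/covariance/distance-correlation
estimation between the model- and prediction-error streams, per-patient
cohort aggregation, two validation scenarios (adaptive first-fraction margins
and min/max covariance envelopes), one-way ANOVA comparison of margin
methods, and a seeded synthetic-cohort generator so everything is testable
without clinical data.

## Layout

| module                  | contents |
|-------------------------|----------|
| `ptvmargin.logio`       | `TrackingSample` / `FractionLog` / `CohortLog`, CSV read/write, cohort validation |
| `ptvmargin.errors`      | fraction summaries, population Σ/σ decomposition, static uncertainty table (segmentation / deformation / E2E targeting), total tracking error, `ErrorComponents` |
| `ptvmargin.correlation` | stream pairing (`nearest_in_time`, `window_mean`), Pearson, covariance, distance correlation, cohort aggregation |
| `ptvmargin.margins`     | `vhf_basic`, `vhf_recipe`, `combined_sd`, `vhf_extended`, `mvhf`, `relative_difference` |
| `ptvmargin.scenarios`   | adaptive first-fraction margins, covariance envelopes |
| `ptvmargin.stats`       | one-way ANOVA across methods, two-sample variance-ratio F-test |
| `ptvmargin.synth`       | `SynthConfig`, `simulate_cohort`, `lung_like` / `liver_like` presets |
| `ptvmargin.cli`         | `ptvmargin` command-line interface |

## Tracking-log CSV schema

One file per fraction, UTF-8, LF endings:

```
# patient_id=P0001 fraction=1 site=lower_left_lung tracking=XLT version=VSI_8_5 motion_cm=1.5
time_s,source,err_si_mm,err_lr_mm,err_ap_mm
60.0,model,0.12,-0.3,0.05
60.0,prediction,0.02,-0.1,0.0
...
```

`source` is `model` or `prediction`; errors are mm in fixed (SI, LR, AP)
order; time is seconds from fraction start. Write/read is a byte-stable
round trip at full float precision.

## CLI

```bash
# synthetic cohort (one CSV per fraction + manifest.json)
ptvmargin simulate --preset lung_like --out cohort/ --seed 1

ptvmargin validate cohort/

# per-site margin table (VHF, MVHF, relative difference)
ptvmargin margins cohort/ --method both --out margins.csv

# per-patient long-format margins (input for `compare`)
ptvmargin margins cohort/ --per-patient --out per_patient.csv
ptvmargin compare per_patient.csv --out ftest.csv

# scenario 1: first-fraction covariance applied to later fractions
ptvmargin adaptive cohort/ --out adaptive.csv

# scenario 2: min/max covariance envelopes per patient
ptvmargin envelope cohort/ --out envelope.csv
```

Common flags: `--sigma-rho` (penumbra width, default 6.4 mm), `--beta`
(default 0.84), `--pairing {nearest,window}`, `--static-table <file>` to
override the static uncertainty assignments. Every command writes a
`<out>.prov.json` provenance record.

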