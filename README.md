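# qocprofile

Facility-level quality-of-care profiling from EMR-like HIV care records.

The package turns patient-level tables (patients, pharmacy dispense events,
viral-load lab events, facilities) into a facility performance profile:

1. **Indicators** – six failure proportions per facility: three process
   indicators (ART started within 30 days of diagnosis, viral-load testing
   up to date, multi-month scripts restricted to stable patients) and three
   continuity indicators (timely ART refill pick-up, 6-month retention for
   non-pregnant adults, and for women pregnant/post-partum at initiation).
2. **Case-mix adjustment** – national binomial/logistic regressions on
   demographics and baseline clinical covariates yield, per facility, an
   indirectly standardized expected proportion and a logit-scale contrast
   `y_i` with standard error `s_i` for the continuity indicators.
3. **Profiling** – exact binomial tests (indicators 1–3) and normal tests on
   `y_i/s_i` (4–6) against a Bonferroni-corrected threshold `alpha/I`, with
   over-dispersion handled multiplicatively (standard errors inflated by
   `sqrt(phi)`, phi from winsorized z-scores) or additively (between-facility
   variance `tau2`, method of moments) as a sensitivity analysis.
4. **Funnel plots** – target lines, plain and over-dispersed control-limit
   curves at the conventional and Bonferroni-corrected levels, facility
   placement, and optional rendered figures.
5. **Composite score** – indicator z-scores capped at ±3, combined with
   relevance weights (1.5, 1.5, 1.5, 0.5, 0.5, 1 by default) and an
   empirical-correlation adjustment, re-standardized to mean 0 / sd 1;
   facilities beyond ±2 are classified as low/high performers.

A synthetic EMR generator (`qocprofile.simulate`) produces all input tables
with known ground truth — facility effects on the logit scale, planted
outliers, case-mix confounding, intra-patient correlation for the refill
indicator — so every stage is testable without access to governed EMR data.

## CLI

```bash
# full pipeline on a simulated scenario
qocprofile run --config config.yaml --seed 1 --out out/

# stage by stage
qocprofile simulate  --config config.yaml --out data/
qocprofile indicators --in data/ --out data/
qocprofile adjust     --in data/ --out data/
qocprofile profile    --in data/ --out data/
qocprofile funnel     --in data/ --out data/ --plots
qocprofile composite  --in data/ --out data/
qocprofile report     --in out/
```

All stage outputs are plain CSV (`indicator_aggregates.csv`,
`casemix_contrasts.csv`, `profiling.csv`, `funnel_curves.csv`,
`composite.csv`, …) plus a `manifest.json` (config hash, seed, versions,
row counts) and a human-readable `report.md`. Re-running with the same
config and seed is bit-identical. Exit codes: 0 success, 2 validation
failure, 3 estimation failure.

A YAML config may override any block (defaults shown partially):

```yaml
seed: 1
simulate:
  n_facilities: 90
  volume_range: [150, 1300]
  overdispersion_sd: 0.4
  planted_outliers:
    - {facility: 0, indicator: 5, shift: 2.0}
profiling:
  alpha: 0.05
  method: multiplicative   # or: additive
composite:
  weights: [1.5, 1.5, 1.5, 0.5, 0.5, 1]
  cap: 3
  threshold: 2
```

To run on real extracts instead of simulating, point `input_dir` at a
directory with `facilities.csv`, `patients.csv`, `dispenses.csv`, `labs.csv`
following the documented column schema (see `qocprofile/pipeline.py`).

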