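# hipcea

Cost-utility analysis of robotic arm-assisted (rTHA) versus manual (mTHA)
total hip arthroplasty: a deterministic QALY-accrual and incremental-cost
model with volume sweeps, sensitivity and threshold checks, plus a
synthetic-cohort generator and a covariate-adjusted EQ-5D utility-gain
estimator so the full pipeline is testable end to end without patient data.

## What it computes

- **Parameters** (`hipcea.parameters`) — every cost, rate and horizon in one
  validated bundle, overridable from a flat YAML config.
- **QALY accrual** (`hipcea.qaly`) — an annual utility uplift accrued over a
  10-year or lifetime (17-year) horizon, with explicit, user-selectable
  conventions for survival diminution (none / multiplicative / linear) and
  discounting (off / multiplicative from year 1 or 2 / compound interest).
- **Costs** (`hipcea.costs`) — annual robot rental amortised over unit case
  volume plus per-case consumables and CT; expected revision cost (cancels
  from the incremental comparison under equal revision rates).
- **ICERs** (`hipcea.icer`) — cost per QALY for the four base cases
  ({10-year, lifetime} × {undiscounted, 5%/yr discounted}), volume sweeps,
  break-even volume, uplift sensitivity and willingness-to-pay /
  price-threshold checks.
- **Synthetic cohorts** (`hipcea.cohort`) — two-arm patient tables drawn
  from range-truncated normals with a built-in ceiling effect (change
  depends negatively on preoperative EQ-5D) and a known true group effect.
- **Cohort statistics** (`hipcea.cohort_stats`) — group comparisons
  (t-tests, chi-square, odds ratio, Pearson correlations), the multivariable
  OLS adjustment whose group coefficient is the uplift, and the two-group
  normal-approximation sample-size formula.
- **Report** (`hipcea.report`) — end-to-end run rendering the summary-table
  layout and a deterministic machine-readable JSON.

At the base case (uplift 0.091, 100 cases/year) the model reproduces the
published figures: incremental cost £1,516 (robot £1,152 + consumables £278 +
CT £86), lifetime QALY gains 1.5470 / 1.0590, cost per QALY £980 / £1,432
(lifetime) and £1,910 (10-year undiscounted). The 10-year discounted cell is
a documented best fit: no simple accrual convention reproduces the printed
0.6453 QALY gain exactly; the calibrated convention yields 0.6439, i.e.
£2,355 vs the printed £2,349 (0.24% residual).

## CLI

```sh
hipcea params show                      # resolved parameter bundle
hipcea cost --volume 100                # incremental cost block
hipcea qaly --policy lifetime-discounted
hipcea icer --volume 100                # the four base-case ICERs
hipcea sweep --volumes 10:250:10        # cost/QALY vs annual volume (curve data)
hipcea sensitivity --uplift 0.017
hipcea simulate --seed 1 --out cohort.tsv
hipcea estimate cohort.tsv --json > effect.json
hipcea icer --uplift-from effect.json
hipcea report [--config cfg.yaml] [--cohort cohort.tsv] [--json]
```

Configs are flat YAML key-value documents matching the parameter field names
(e.g. `adjusted_uplift: 0.017`, `annual_rate: 0.0`); unknown keys are
rejected.

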