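# adhkit

Tools for measuring antiretroviral-therapy (ART) adherence from the kinds
of routine records that exist in resource-limited HIV clinics — pharmacy
dispensing logs, visit/attendance logs, and self-reports jotted in medical
records — and for validating those measures against early clinical change.

Clinics that cannot run electronic monitoring or viral-load testing still
need to know which patients are slipping off therapy. `adhkit` computes
eight practical indicators from plain event logs, cumulatively from ART
initiation to any "as-of" date:

| measure | definition |
|---|---|
| average self-report | mean of visit codes (1 = perfect, 2 = good, 3 = poor) |
| any poor self-report | ever coded 3 |
| any imperfect self-report | ever coded 2 or 3 |
| % days covered | supply-pool model: each dispensing adds its days of supply, one unit is consumed per day, unfinished supply carries over |
| gap > 30 days | any run of > 30 consecutive uncovered days |
| % visits on/before schedule | attendance vs the scheduled date |
| % visits within 3 days | same, with a 3-day grace window |
| % visits before exhaustion | attended before the previous visit's supply ran out (no carryover, by design) |

On top of the indicator engine the package provides:

* an eligibility screen (adults, treatment-naïve, continuous early
  follow-up, self-report and dispensing data, recent baseline CD4);
* pairwise correlations among measures (Pearson for continuous pairs,
  Kendall tau-b when a binary measure is involved);
* validation models: a GEE marginal model of weight change at every visit
  in the first 270 days (patient-clustered, exchangeable working
  correlation, sandwich errors) and an OLS model of CD4 change at a
  follow-up test in days 91–270 — each adherence indicator entered
  separately over a fixed covariate set, plus typical-patient and
  population-averaged adjusted predictions;
* a seeded synthetic cohort generator in which one latent adherence
  propensity drives refill lateness, missed visits and treatment
  interruptions, and outcomes respond to *true* coverage — so the whole
  pipeline is testable, with known ground truth, without patient data.

## Worked example

```python
import adhkit as ak

cohort, trace = ak.generate_cohort(ak.default_config(), seed=1)
report = ak.screen_eligibility(cohort)
snaps = ak.snapshot_table(cohort, report.included_ids)   # index visit ~ day 180

print(f"full coverage: {100 * (snaps.pct_days_covered == 100).mean():.1f}%")
print(f"gap >30 days:  {100 * snaps.gap_gt30.mean():.1f}%")

panel, _ = ak.build_weight_panel(cohort, report.included_ids)
res = ak.WeightGainModel(panel, "gap_gt30").fit()
print(res.indicator_terms()[["term", "estimate", "ci_low", "ci_high"]])
```

prints

```
full coverage: 62.6%
gap >30 days:  2.3%
       term  estimate    ci_low   ci_high
0  gap_gt30 -4.055929 -5.259751 -2.852107
```

That is: in this simulated cohort of 488 patients, 62.6% kept an unbroken
medicine supply through month six, 2.3% had a >30-day treatment gap, and —
after adjustment for demographics, clinical stage, time on therapy and
baseline values — patients with a gap gained about 4.1 kg less weight than
patients without one (95% CI −5.3 to −2.9).  The fitted deficit exceeds
the −3.26 kg gap penalty configured in the generator because patients with
long gaps also fall into low-coverage bands, which carry their own
penalty.

A command-line interface covers the same pipeline: `adhkit synth`,
`screen`, `indicators`, `correlate`, `validate`, and `adhkit run --out
dir/` for the full report bundle (tables 1–5 plus a reproducibility
manifest).

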