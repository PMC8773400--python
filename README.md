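# cardtrace

Tools for evaluating Bluetooth proximity cards as a contact-tracing
instrument against traditional interview-based contact tracing.

During a week-long community pilot of a BLE proximity card, two records of
the same social process were collected: directed card detections (card *i*
observed card *j*, with RSSI-derived proximity classes) and case-investigation
interviews in which a subset of participants recalled their contacts, dates
and durations. Neither instrument observes the truth, so the analysis rests
on *internal consistency* — do both sides of an interaction register it? —
and on *concordance* — do the two instruments agree with each other?

`cardtrace` implements that full analysis as a reusable, tested pipeline:

- **`synthetic_data`** — generates cohorts with households, ground-truth
  dyadic contact events, 15-s RSSI streams under a log-distance path-loss
  model (RSSI(d) = RSSI(1 m) − 20 log₁₀ d + noise), decaying wear
  compliance, the "cards left at home together" household artifact, and an
  interview process with imperfect recall and ±1-day date errors.
- **`card_pipeline`** — the card's storage chain: 2-minute windows classed
  from the maximum RSSI (class 0: ≤ 1 m, [−20, −50] dBm; class 1: 1–2 m,
  (−50, −56]; class 2: 2–4 m, (−56, −62]; below −62 dBm nothing stored),
  2-hour blocks, daily per-dyad minutes, the symmetric-role cohort filter
  and first/last-day trim.
- **`case_investigation`** — report normalisation, nesting of interviewees
  within the card cohort, and the one-shot reassignment of unreciprocated
  reports to an adjacent day when that creates a mutual dyad.
- **`reciprocity`** — dyad census (mutual/asymmetric/null), classical
  reciprocity r = 2m/(2m + a) with binomial SE, the Garlaschelli–Loffredo
  density-adjusted ρ̂ = (r − ā)/(1 − ā), a leave-one-dyad-out jackknife SE,
  and pooled estimates with Wald and Agresti–Coull intervals.
- **`model_comparison`** — nested grouped-binomial logistic models
  logit(r) ~ dataset [+ day + day² [+ dataset×day(²)]], likelihood-ratio
  tests, and the dataset odds ratio (all basis-invariant).
- **`concordance`** — card-vs-report confusion matrices over an explicit
  dyad-day universe, detection/unreported rates by proximity-class
  threshold and day, and non-compliance signatures (zero-interaction cards,
  unreported ≥ 22 h class-0 dyads).

The published per-day summaries (daily reciprocity counts, confusion-matrix
panels) ship as constants in `cardtrace.printed_tables`, so every statistic
derivable from them is recomputed from first principles.

## Worked example

Reciprocity of the first interview day (16 directed reports among the 65
retained interviewees, 6 mutual and 4 asymmetric dyads):

```python
from cardtrace.reciprocity import estimate_reciprocity, network_from_census

net = network_from_census(n_nodes=65, mutual=6, asymmetric=4)
est = estimate_reciprocity(net)
print(f"r = {est.r:.4f} ({est.sigma_r:.4f})  rho = {est.rho_hat:.4f}  "
      f"density = {est.a_bar:.4f}  n = {est.n_edges}")
```

```
r = 0.7500 (0.1083)  rho = 0.7490  density = 0.0038  n = 16
```

Three quarters of the day's reported contact events were reported by both
people involved; the density adjustment barely moves the estimate because
only 16 of 4,160 possible directed edges are present.

Fitting the trend models on the twelve daily (reciprocated, total) counts —
five card days, seven interview days:

```sh
$ cardtrace model --basis orthonormal
model 1: deviance 19.969 on 9 df
model 2: deviance 7.860 on 8 df
model 3: deviance 6.004 on 6 df
model 1 vs 2: G2 = 12.110, df 1, p = 0.0005016
model 2 vs 3: G2 = 1.856, df 2, p = 0.3954
dataset OR = 4.748 (3.022, 7.462), z = 6.755
```

The quadratic day term earns its place (G² = 12.11 on 1 df); a
dataset-by-day interaction does not (G² = 1.856 on 2 df). Under the
preferred quadratic model, the odds of a card-detected contact event being
reciprocated are 4.75 (95% CI 3.02–7.46) times those of an
interview-reported one: the cards are far more internally consistent than
human recall.

A fully synthetic trial can be run end to end from the shell:

```sh
cardtrace simulate --seed 4 --out-prefix trial
cardtrace ingest --readings trial_readings.csv --out daily.csv --filter-report filters.json
cardtrace reports-ingest --reports trial_reports.csv --reassign-dates --out edges.csv
cardtrace reciprocity --edges edges.csv --pooled --out table.csv
cardtrace concordance --card daily.csv --reports trial_reports.csv --by-day --out concordance.json
```

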