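# Methods

## The measurement problem

Two instruments record the same week of social contacts. Bluetooth cards
produce *directed* detections — card *i* scanning card *j* is a different
record from *j* scanning *i* — and interviews produce directed reports
(reporter → named contact, per day). Neither observes ground truth. The
package therefore works with three linked quantities:

1. **internal consistency** of each instrument, measured as directed-network
   reciprocity per day;
2. **trend** in that consistency over the trial, modelled jointly for the
   two instruments;
3. **concordance** between instruments over a common cohort of people and
   days.

## Reciprocity

For a day's network with explicit node set of size N and edge set A, each
unordered pair of nodes is a *mutual* (both directions), *asymmetric*
(one direction) or *null* dyad. With m mutual and a asymmetric dyads:

- r = 2m / (2m + a), the share of directed edges whose reverse exists, with
  binomial SE σ_r = √(r(1−r)/n), n = 2m + a. This treats each directed
  edge's reciprocation as an independent Bernoulli draw — a simplification,
  since the two edges of one mutual dyad are not independent.
- ρ̂ = (r − ā)/(1 − ā) with density ā = n / (N(N−1)); ρ̂ subtracts the
  reciprocity expected if the same n edges fell at random, ranges from
  −ā/(1−ā) to 1, and tends to r as ā → 0.
- σ̂_ρ = √(Σ_{i<j} (ρ̂_{−(ij)} − ρ̂)²), the leave-one-dyad-out jackknife;
  null dyads leave ρ̂ unchanged, so the O(N²) loop reduces to two
  closed-form terms weighted by m and a.

The node set is *explicit* and may exceed the active nodes: densities for
the interview networks use all 65 retained interviewees (not just the 23
appearing in reciprocity edges), and card densities use the 736 cards that
pass the symmetric-role filter before the day trim. These are the rosters
under which the published daily ρ̂ values reproduce to 4 decimals; the
published final cohort of 673 does not reproduce them, a documented
inconsistency we resolve in favour of arithmetic.

The jackknife as stated does **not** reproduce the published σ̂_ρ column
(first interview day: formula gives ≈ 0.133 vs 0.2014 published). The
formula is implemented exactly as written and verified against a
brute-force matrix-deletion oracle; the published column is retained as
reference data but asserted nowhere. A node-level (rather than dyad-level)
jackknife or an extra scaling factor could explain the gap; without the raw
data this cannot be settled.

Pooled reciprocity sums daily counts: r = Σ2m_d / Σ(2m_d + a_d), with a
Wald interval and an Agresti–Coull interval (z²-augmented counts), the
latter preferred at interview sample sizes.

## Trend models

Daily (reciprocated, total) edge counts are grouped-binomial observations
(12 rows: card days 2–6, interview days 1–7). Nested logistic models —
dataset; dataset + day; + day²; + dataset×day + dataset×day² — are fitted
by maximum likelihood (statsmodels binomial GLM, IRLS; an independent
BFGS maximisation of the log-likelihood is the oracle in the tests).
Inference uses deviance differences G² against χ² and a Wald odds ratio for
the dataset dummy.

Day coding: published day/day² coefficients are not recoverable under raw
1–7 powers, so the basis is ambiguous. The module exposes `raw` and
`orthonormal` (Gram–Schmidt over the observed rows) bases, labels every fit
with its basis, and asserts only basis-invariant quantities — deviances,
G², and the dataset coefficient, which is orthogonal to any day
reparameterisation.

## Concordance

The confusion-matrix universe is every ordered (reporter, other, day)
triple with reporters the interviewed-and-nested cohort, others the full
card roster, over the five analysis days. Self-pairs are included: the
65 × 736 × 5 = 239,200 universe is the only composition matching every
published panel total, and self-pairs can only ever land in the
true-negative cell. A pair-day is card-positive if the dyad logged any
minutes at an included proximity class in *either* direction (reports are
direction-agnostic about who detected whom), and report-positive if the
reporter named that contact for that day. Widening the class set from {0}
to {0,1} to {0,1,2} can only add card-positives, so the per-day
(fpr, tpr) points trace a partial ROC curve; this monotonicity is asserted
as an invariant.

Non-compliance signatures: per day, the fraction of reporters whose cards
logged nothing in either role (card not worn); and unreported dyad-days
with more than 22 h (configurable) at class 0 (cards left at home
together — a genuine 24 h co-location is physically implausible for two
people).

## Synthetic generator

The generator emulates the study conditions so the pipeline is testable
without the (non-public) trial data: a ~700-participant, 7-day cohort.
Defaults, chosen once as a plausible community-pilot regime:

| parameter | default | meaning |
|---|---|---|
| `household_size_distribution` | 1:0.25 … 6:0.04 | i.i.d. household sizes, last household truncated |
| `contact_rate` | 2.0 /person/day | population random-mixing event rate (Poisson) |
| `household_contact_prob` | 0.5 /pair/day | extra within-household events (field added to the config: cohabitation must generate contacts for the household artifact to matter) |
| `distance_distribution` | 0.5 m:0.40, 1.5:0.35, 3.0:0.25 | true distances, one per class band; support capped at 4 m (beyond it no reading can clear the −62 dBm floor noiselessly) |
| `duration_distribution` | 2–120 min mixture, mode short | durations ≥ 2 min, matching the reporting floor |
| `wear_prob_by_day` | 0.90 → 0.55 | decaying compliance over the week |
| `p_household_card_left_home` | 0.05 /household-day | ≥ 2 cards co-located at ~0.5 m for a full 24 h |
| `rssi_at_1m` | −50 dBm | path-loss calibration; the only value consistent with the class edges (−50, −56.02 at 2 m, −62.04 at 4 m) |
| `rssi_noise_sd` | 2 dBm | i.i.d. Gaussian per reading per direction |
| `p_report` | 0.7 | per-event per-participant recall |
| `p_date_shift` | 0.05 | recalled event reported ±1 day, clamped at trial boundaries |

Event start times snap to the card's 2-minute recording grid, so a
noiseless d-minute event yields ⌊d/2⌋ stored windows per direction; this
makes the noiseless class-recovery property exact rather than
alignment-dependent. Randomness flows from one seed through per-stage child
streams (population, contacts, wear, RSSI, reports), so each stage is
bit-reproducible independently of call order.

What the generator does *not* model: multipath, body shadowing and other
real RSSI pathologies (noise is i.i.d. Gaussian on a log-distance mean);
pseudonym rotation; battery or memory limits; interviewer effects.
Passing recovery tests therefore shows the *pipeline* is correct under the
stated generative assumptions, not that the instruments behave this way in
the field — where RSSI–distance relationships are known to invert in some
environments.

Analytic recovery targets used in tests: with independent recall at rate p,
a both-interviewed dyad is mutual with probability p² and asymmetric with
2p(1−p), so report-network r → 2p²/(2p² + 2p(1−p)) = p; with noise σ, a
direction detects a 2-minute event at distance d with probability
q = Φ((μ(d) + 62.5)/σ)⁸ (eight 15-s readings, integer rounding at the −62
floor), and card-network r → q.

## Card pipeline conventions

The storage rule "not obtained continuously for 2 min or less than −62 dBm"
is read strictly: a window is stored only if **all eight** 15-s slots hold
a reading at or above −62 dBm. The alternative (only the window maximum
must clear the floor) is noted as a sensitivity; the strict reading follows
from sub-floor readings lying outside the class table's support. Readings
above −20 dBm clamp into class 0 (hardware ceiling, not a filter).
Duplicate readings within a slot keep the maximum. Time grids — 2-min
windows from the top of the hour, 2-h blocks at even hours, days at local
midnight — are conventions; the firmware's actual alignment is undocumented.

The symmetric-role filter runs in a single pass (cards losing their only
partner are not re-examined), then the first/last-day trim; this order
mirrors the reported filtering sequence.

## Date reassignment

An unreciprocated report i→j on day d may move to d±1 when, in the original
data, i has no report of j on the target day and j reported i there. All
qualifying moves are computed against the original networks and resolved in
one shot, sweeping destinations in the preferred direction (earlier by
default, configurable): accepting a move pins its partner edge in place,
and proposals whose edge is pinned, whose partner already moved, or whose
destination slot is taken are cancelled. Consequences, verified by
exhaustive enumeration over all two-node three-day configurations: every
applied move creates a mutual dyad, total edge count is conserved, the
mutual-dyad count never decreases, and fully reciprocated networks are
untouched. When both neighbours qualify, the earlier day wins by default —
a documented convention; the source material is silent.

## Numerical conventions

Statistics are computed at full double precision and rounded to 4 decimals
only for table output. GLM convergence: coefficient tolerance 1e−10, 100
iterations, explicit errors on rank deficiency, non-convergence or boundary
fitted probabilities. The 95% quantile is 1.959964 throughout. Degenerate
inputs (zero edges, N < 2, density 1, all edges in one dyad, trims that
empty the data) raise typed errors rather than returning NaN.

## Problem sizes

The test suite and acceptance script run at desk scale by design: published
table recomputations are exact and instantaneous; synthetic recovery tests
use 500-dyad cohorts (Monte-Carlo SE small enough for ±2–3 SE assertions)
and 200-replicate rate checks, keeping the full suite under a minute.
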