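# Methods

`alertlog` measures clinician response to noninterruptive clinical-decision-
support alerts from EHR access and audit logs.  An alert here is a message
delivered to a primary care physician's (PCP's) EHR inbox ("InBasket") about
a recently discharged older patient's medications; it does not interrupt
workflow, so whether and when it gets opened — and what the physician does
next — must be reconstructed from time-stamped log events.  This note
documents the measurement model, the estimation machinery, the synthetic
data generator, and the numerical and design choices behind them.

## Event model

The atomic record is a `LogEvent`: `(event_id, ts, actor_id, actor_role,
action, …)` with one-second timestamp resolution.  Access-log content
(alert openings, chart-section views, order placement) and InBasket audit
content (message delivered / opened / completed / postponed) share one
stream, discriminated by `action`.  Events sort by `(ts, event_id)`; the
lexicographic tiebreak makes every downstream computation deterministic
under same-second ties, which one-second logs produce routinely.

Timestamps are timezone-aware end to end.  All window arithmetic runs in a
single configured clinic timezone (default `America/New_York`) because
office hours, Saturday flags, and "the following day" are local-time
concepts; absolute-time quantities (delays in seconds) are unaffected by
the convention.

Two action classes are deliberately excluded from "navigation": deliveries
(`alert_delivered`, `message_delivered`) are passive, and message lifecycle
events belong to the inbox subsystem rather than the chart.  Neither can
open a 5-minute window, terminate a dwell span, or certify that a physician
was active in the chart.

## Opening detection

For each alert the earliest `alert_opened` event gives the first opening;
the earliest one by the addressed PCP gives the PCP opening.  Derived
context:

- **Delay bins.** Delivery→first-opening delay, measured in exact seconds,
  binned with inclusive upper bounds: ≤24 h, (24, 48] h, >48 h.  A second,
  coarse categorization (≤1 h, (1, 24] h, >24 h) is also emitted, since both
  groupings are useful descriptively.  Exactly-24 h and exactly-48 h deltas
  fall in the earlier bin.
- **Office hours.** `[08:00, 17:00)` local, Monday–Friday.  The half-open
  interval avoids double counting the 17:00 boundary; the source convention
  ("8 AM–5 PM") does not specify boundary semantics.
- **Saturday delivery.** Flagged because a Saturday delivery is the only
  case in which the first 24 post-delivery hours contain no weekday time.

An opening earlier than its alert's delivery is a data-consistency error,
never silently repaired.

## Immediate (5-minute) action

Only alerts whose *first* opener is the addressed PCP are evaluable: the
physician's immediate reaction is undefined if staff triaged the message
first.  The window is half-open, `[t_open, t_open + 300 s)`.  The first
navigation event in the window decides the classification: a section view,
alert-link summary, or order for the alert's patient is a *relevant*
immediate action; opening a different patient's notification, viewing a
different patient's chart, or an empty window is not.  An order counts as
relevant — it is an action inside the patient's record — which is an
interpretation the classification isolates in one predicate.

**Time attribution.** Access logs record openings, not closings, so "time
with the alert on display" is estimated as the gap from opening to the
actor's next navigation event of any kind, capped at 300 s; this next-event
truncation is the only timestamp-derivable estimate.  Relevant-patient time
sums the dwell spans whose current event is a relevant-patient view, each
span ending at the actor's next event or the window end.  By construction
`total = display + relevant ≤ 300` and all durations are integer seconds.

**Evaluability.** An opened alert with an empty window is the genuine "did
nothing for 5 minutes" case only if the actor demonstrably kept using the
EHR afterwards; if the actor shows no navigation at all after the opening,
there is nothing to estimate from and the alert is flagged
`no_window_data`.  The canonical fixture constructs its 11 such alerts as
each provider's final navigation event.  The sampled generator's
`missing_window_prob` suppresses an alert's follow-up trace; when the
provider is active later anyway, such alerts degrade to no-action rather
than non-evaluable — a known limitation of sampling-based missingness, which
is why recovery experiments run with this probability at zero.

## Subsequent (two-day) action

Physicians often open alerts between visits and return later, so the second
stage asks: from the first opening (by anyone) through the end of the *next
local calendar day*, did the addressed PCP touch the alert's patient?
Calendar-day semantics (not a 48-hour clock) follow the "by the end of the
following day" framing: an opening at 23:59 Monday still gives a window
ending Wednesday 00:00 (exclusive).  The tracked actor is always the
addressed PCP, even for staff-opened alerts.

Classification is monotone in the event set:

- **general** — any section view, alert-link summary, or order for the
  patient;
- **medication-specific** — medication-list view or medication order
  (new / change / discontinue);
- **laboratory-specific** — laboratory-section view, results view flagged
  as a laboratory result, or laboratory order.  Logs distinguish sections,
  not result types, so the generator tags results views with a lab flag;
  unflagged results views count only toward general.  Eye-exam
  recommendations map to general ordering, not laboratory.

The specific flags imply the general one on all inputs.  The module reports
temporal co-occurrence only; no causal attribution is made.

## InBasket reconstruction by replay

Logs keep no snapshots of an inbox, so the state at a past instant `t` is
rebuilt by replay: candidate messages are those delivered in
`[t − 365 d, t)`; messages completed (deleted) or postponed strictly before
`t` are removed; a survivor with no opening at or before `t` is unopened;
prior-week arrivals are deliveries in `[t − 7 d, t)`.  The one-year
lookback is a deliberate truncation mirroring how such reconstructions are
bounded in practice: a still-open message older than a year is invisible.
Comparisons use full timestamp resolution (not day resolution) for
determinism.  A lifecycle event preceding its own delivery is a consistency
error.  The implementation is verified event-for-event against a naive
forward mailbox simulation on 1,000 random traffic streams.

Contextual covariates are binned categorically: InBasket totals, unopened
counts, prior-week arrivals, provider encounter counts and patient office
visits each get four categories.  Published category edges are the default;
`quartile_bin` recomputes empirical quartile cuts for new data.  Values
equal to a cut point fall in the lower bin; all-equal inputs collapse into
the lowest bin with a warning.

## Estimation

Alert-level binary outcomes are clustered: the same physician receives many
alerts.  Effects are estimated by generalized estimating equations — a
marginal logistic model (logit link, binomial variance) with an
**exchangeable** working correlation, clustered on provider, with robust
(sandwich) standard errors.  Exchangeable is the standard working structure
for repeated alerts within a provider; the sandwich variance makes the
inference valid even when it is wrong.  Odds ratios are exponentiated
coefficients; 95% intervals are Wald intervals on the linear-predictor
scale, exponentiated.  Covariates enter as unordered categoricals with
explicit reference levels (information-only alerts, ≤24 h opening,
staff-opened, female, etc.).  Empty covariate levels are dropped with a
warning; a constant outcome raises a degenerate-outcome error;
non-convergence is carried in the result object and blocks report
rendering, never silently ignored.  No multiple-testing adjustment is
applied, and the report footer says so.

Two oracle properties pin the estimator down: with singleton clusters the
GEE reproduces ordinary logistic regression to four decimals, and under
no-effect simulation the 95% interval covers 1 in [0.91, 0.99] of 200
replicates.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 75 PCPs,
~800 alerts in a 593:37:169 type mix (information-only, medication
recommendation, test recommendation), ~78% of first openings by the
addressed PCP, right-skewed opening delays, and a year of InBasket traffic.

Outcomes follow marginal logistic models: per-outcome intercepts on the
information-only baseline (immediate 0.28; general 0.64; medication-specific
0.16; laboratory-specific 0.17) plus additive log-odds offsets for the two
recommendation types (defaults: immediate ln 4.03 / ln 2.14;
medication-specific ln 5.59 / ln 1.71; laboratory-specific ln 7.37 /
ln 2.75; general ln 2.0 / ln 1.7), perturbed by a per-provider normal random
intercept (default SD 0.3) that induces within-provider clustering — the
simplest mechanism compatible with a marginal-model analysis at small SD.

Two structural choices matter for interpretation:

- **Comonotone outcome coupling.** One engagement uniform per alert drives
  all outcome draws.  Every outcome keeps exactly its marginal logistic
  probability, while specific actions nest inside general ones the way
  engaged chart review does in practice.  Independent draws would OR
  together into a realized general-action rate far above its logit (and
  produce separation in small arms).
- **Channel separability.** Immediate-session views draw only from neutral
  sections (encounters, demographics, other clinical, information entry,
  alert-link summary), never medications/laboratory/results, so the
  medication- and laboratory-specific two-day outcomes are governed solely
  by their own logits and the full pipeline can recover the generating odds
  ratios cleanly.

Distributional stand-ins (no forms are reported for them anywhere): opening
delays are log-normal in hours (μ=2.85, σ=1.44, matching the observed delay
margins of roughly 59% ≤24 h and 24% >48 h), truncated at 30 days; session
dwell is log-normal in seconds (median ≈20 s); InBasket arrivals are Poisson
(default 450/week, the scale of the observed prior-week quartiles) with
daily opening/completion hazards and a postponement probability.  All of
these live in `BehaviorModel`/`TrafficModel` so nothing downstream depends
on their shape.  Every generator is a pure function of its seed.

**What the generator does not emulate:** clinical content (drug names, lab
values), intra-day workload rhythms, vendor-specific audit codes, multiple
simultaneous sessions, or informative missingness beyond the single
missing-window mechanism.  Passing recovery tests therefore demonstrates
internal consistency of the measurement pipeline and estimator — not
validity against real EHR logs.

## Canonical fixture

For bit-exact end-to-end tests the package hard-constructs (quota
assignment, not sampling) a 799-alert dataset whose stage-by-stage
accounting is known by construction: 627 PCP-opened (78.5%), 616 evaluable
(11 missing-window), 208 immediate relevant (33.8%) split 125/17/66 over
445/31/140, two-day outcomes 538 general (67.3%; 382/29/127 by type),
154 medication-specific (95/18/41), 180 laboratory-specific (100/20/60),
delay margins 472/137/190 over all alerts and 119/252/245 (coarse) over the
616, 304 in-office openings, 166 Saturday deliveries.  Alert specs are
shuffled (seeded) before provider assignment: a plain round-robin would
give every provider an almost identical outcome mix, inducing a negative
intra-cluster correlation at the exchangeable boundary that destabilizes
the GEE.  Provider encounter counts are constructed so their empirical
quartiles reproduce the published category edges (2326 / 2783 / 3173).
Rebuilding from the same constant is byte-identical.  InBasket traffic is
omitted from the fixture by default (none of its margins involve the
inbox); `include_traffic=True` adds a scaled-down stream.

## Problem sizes

The recovery experiment uses 20 cohorts of 800 alerts over 75 providers
(per-seed cohorts derived from one master seed) and averages estimated odds
ratios on the log scale — the geometric mean, the natural averaging scale
for ratios, avoiding the upward Jensen bias of arithmetic OR averaging.
At this scale the medication-recommendation contrasts (arm size ≈37 per
cohort) carry a Monte-Carlo standard deviation of roughly 8% on the
seed-averaged estimate; the test-recommendation contrasts are about twice
as precise.  Null calibration uses 200 replicates of 5,000 rows; the replay
oracle uses 1,000 streams of ~20 days; the law-of-large-numbers fidelity
check uses 20,000 single-alert providers.

## Known limitations

- Display time is an upper-bound-style estimate (next-event truncation,
  300 s cap); true on-screen time is unobservable in access logs.
- The two-day window starts at the opening instant; same-day actions taken
  *before* opening are not counted (an interpretation; the alternative —
  start of the opening day — is not implemented).
- Sampling-based missing-window data degrade to no-action when the provider
  remains active (see above).
- The InBasket replay shares the one-year-lookback truncation of the
  reconstruction it models.
- GEE non-convergence is possible under separation (an outcome constant
  within a covariate level), e.g. tiny simulated cohorts; it is reported,
  and report rendering refuses non-converged fits.
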