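# alertlog

Measuring clinician response to noninterruptive EHR alerts from access and
audit logs.

Noninterruptive clinical-decision-support alerts are delivered to a
physician's EHR inbox (the *InBasket*) rather than popping up in the middle
of a workflow, so nothing about their effect is directly observed: whether
the addressed primary care physician (PCP) ever opened the alert, how fast,
what they did in the chart next — all of it has to be reconstructed from
time-stamped access/audit-log events.  `alertlog` is a pipeline for doing
exactly that, aimed at health-services and clinical-informatics researchers
evaluating InBasket-based interventions:

- **Opening detection** — first opening per alert, attribution to the
  addressed PCP vs staff, delivery→opening delay categories, office-hours
  and Saturday-delivery context.
- **Immediate action** — classification of the first navigation event in
  the 5-minute window after the PCP's first opening (relevant-patient view
  vs other patient vs nothing), plus viewing-time attribution
  (alert-display time + relevant-patient dwell, next-event truncated).
- **Subsequent action** — whether the PCP touched the alert's patient
  between the opening and the end of the following calendar day, classified
  as general / medication-specific / laboratory-specific.
- **InBasket reconstruction** — the inbox state (total, unopened,
  prior-week arrivals) at any past instant, rebuilt by replaying message
  lifecycle events over a one-year lookback.
- **Clustered estimation** — adjusted odds ratios of action by alert type
  via logistic GEE (exchangeable working correlation, robust SEs clustered
  on provider), with bivariate tables and report rendering.
- **Synthetic data** — a seeded generator of cohorts, alert-response event
  streams and InBasket traffic with the statistical structure the analysis
  assumes, plus a deterministic canonical fixture for bit-exact end-to-end
  tests.

The model at the core of the inference stage: for alert $i$ of provider
$j$, a binary action outcome $Y_{ij}$ follows the marginal logistic model

$$\operatorname{logit} \Pr(Y_{ij} = 1) = \beta_0 + \beta^\top x_{ij},$$

estimated by generalized estimating equations with an exchangeable working
correlation within provider and sandwich variance, so that repeated alerts
to the same physician do not masquerade as independent observations.
Reported effects are odds ratios $e^{\beta_k}$ with Wald 95% intervals.

See `docs/methods.md` for the measurement definitions, generator design and
numerical choices.

## Worked example

```python
from alertlog import make_canonical_fixture, run_pipeline, fit_clustered_logit

fx = make_canonical_fixture()            # 799 alerts, 75 PCPs, deterministic
result = run_pipeline(fx.events, fx.alerts)
df = result.table                        # one analysis row per opened alert

print(f"opened by PCP:        {df.opened_by_pcp.sum()} "
      f"({100*df.opened_by_pcp.mean():.1f}%)")
imm = df[df.immediate_evaluable]
print(f"immediate evaluable:  {len(imm)}")
print(f"immediate action:     {imm.immediate_relevant.sum()} "
      f"({100*imm.immediate_relevant.mean():.1f}%)")
print(f"two-day action:       {df.general.sum()} ({100*df.general.mean():.1f}%)")

fit = fit_clustered_logit(df, "laboratory_specific", ["alert_type"])
for t in fit.terms:
    print(f"{t.level:<28} OR {t.odds_ratio:.2f} "
          f"(95% CI {t.ci_low:.2f}-{t.ci_high:.2f})")
```

prints

```
opened by PCP:        627 (78.5%)
immediate evaluable:  616
immediate action:     208 (33.8%)
two-day action:       538 (67.3%)
medication_recommendation    OR 5.79 (95% CI 3.05-11.00)
test_recommendation          OR 2.69 (95% CI 1.81-4.00)
```

Reading: of 799 delivered alerts, 627 were first opened by the physician
they were addressed to; immediate reactions could be tracked for 616 of
those (11 lack usable window data), and 208 of them show the physician
going straight to the relevant patient's chart within 5 minutes.  538
alerts show some PCP action for the patient by the end of the following
day.  Compared with information-only alerts, a test-recommendation alert
multiplies the odds of a laboratory-specific follow-up action by about 2.7,
and a medication-recommendation alert by about 5.8, adjusting for nothing
else here but alert type and clustering within provider.

A command-line surface wraps the same functions:

```sh
alertlog simulate --seed 3 --providers 25 --alerts 300 --out data/
alertlog track --events data/events.jsonl --alerts data/alerts.csv --out tracked/
alertlog analyze --table tracked/analysis.csv --out results/
alertlog fixture --out fixture/
```

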