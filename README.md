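# catchball

Model-based analysis of **target-changing** and **conformity** in a
four-player catch-ball aggression task, built as a fully synthetic,
end-to-end testable pipeline.

In the task, three scripted agents (P1, P3, P4) and one human participant
(P2) throw normal or *strong* (aggressive) balls over eight sessions.  The
agents stage an episode of group aggression against P4, send boost/threat
messages, and the participant's 64 throws reveal whether they conform to the
aggression (keep attacking the victim P4) or *change target* (redirect
strong balls at the instigators P1/P3) — a bistrategic act that is
simultaneously prosocial (helping the victim) and coercive.

The behavioral core is a multinomial-logit utility model over the six
actions X ∈ {N1, N3, N4, S1, S3, S4}:

    U(X) = β₀ + β₁f₁(X) + β₂·react(t)·f₂(X) + β₃·conf(t)·f₃(X)
         + β₄·message(t)·f₄(X) + β₅·total_strong_balls(t)·f₅(X)
         + β₆·change(t)·f₆(X)
    P(X) ∝ exp(β·U(X))          (β = inverse temperature / slope)

with β₃ the conformity weight, β₆ the target-change weight, and session-
dependent context regressors (react/conf/message/strong-ball count/change
gate).  Parameters are fitted per participant by bounded maximum likelihood.
Downstream stages mirror a complete study analysis: group t tests and
repeated-measures session effects, trait regressions (Big-Five, IRI),
bullying/victimization classification, LASSO selection of predictive
connectivity edges from 146×146 Fisher-z matrices with Bonferroni-corrected
edge tests, and bootstrap mediation (trait → connectivity → behavior).

Because no behavioral or imaging data are deposited anywhere, the package
ships a first-class synthetic-data generator (scripted agents, softmax
participant with known ground-truth β, trait scores and connectivity edges
with planted correlations), and the central evidence of correctness is
**parameter recovery** plus calibration of every statistical stage.  See
`docs/methods.md` for the model conventions and their rationale.

## Worked example

```python
from catchball import (BetaVector, SimConfig, simulate_task,
                       FitConfig, fit_participant, ModelOptions)

truth = BetaVector(beta1=-1.0, beta3=2.0, beta6=3.0, slope=1.0)
record = simulate_task(truth, config=SimConfig(seed=10))
est = fit_participant(record, FitConfig(
    fix_slope=True,
    options=ModelOptions(z_normalize_tsb=True, change_mode="record"),
))
print(len(record.p2_events()), record.messages)
print(round(est.beta.beta1, 2), round(est.beta.beta3, 2),
      round(est.beta.beta6, 2), round(est.nll, 1))
```

prints

```
64 {6: 'boost', 7: 'boost'}
-1.02 2.47 3.03 78.4
```

— a complete 64-throw run (this participant joined the aggression in
session 6, so the second message is a boost rather than a threat), with the
baseline, conformity and target-change weights recovered near their
generating values (−1.0, 2.0, 3.0) from a single record, and the fitted
negative log-likelihood well below the 64·log 6 ≈ 114.7 of a random-choice
model.

The full study-scale analysis is the numbered scripts in `analysis/`
(each prints what it found and writes tables under `results/`):

```bash
python analysis/01_simulate_cohort.py   # 43 participants, 64 throws each
python analysis/02_fit_betas.py         # per-participant MLE + recovery check
python analysis/03_group_stats.py       # t tests, session effects, trait regressions
python analysis/04_connectivity.py      # LASSO edge selection + Bonferroni tests
python analysis/05_mediation.py         # bootstrap mediation screen
```

On the default seeds this reports, e.g., recovery correlations
r(true, estimated) of 0.76 / 0.72 / 0.69 for β₁ / β₃ / β₆, a significantly
positive cohort-level β₃ (t(42) = +6.61) and negative β₁ (t(42) = −5.70),
a planted insula edge surviving Bonferroni correction at R = 0.657, and the
insula–dACC edge emerging as the significant mediator between extraversion
and target-changing (bootstrap p = 0.034).

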