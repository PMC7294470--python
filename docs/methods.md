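# Methods

## The task and the behavioral model

The catch-ball task is a four-player ball-tossing game in which three players
(P1, P3, P4) are scripted computer agents and the human participant (P2)
chooses, on each of 64 throws (8 per session, 8 sessions), a target (P1, P3
or P4) and a ball strength (normal or strong; the strong ball carries an
unpleasant sound and is the aggressive option).  The agents stage an episode
of group aggression: P4 lashes out at everyone in session 3; P1 (from session
4) and P1+P3 (from session 5) throw strong balls at P4 with probability 0.8;
a "throw more strong balls at P4" boost message arrives before session 6; and
before session 7 the participant receives either another boost or — if they
threw no strong ball at P4 in session 6 — a threat, after which the
instigators aim their strong balls at P2 and P4 equally.

The participant's choice among the six actions
X ∈ {N1, N3, N4, S1, S3, S4} (strength × target) is modeled with a linear
utility

U(X) = β₀ + β₁f₁(X) + β₂·react(t)·f₂(X) + β₃·conf(t)·f₃(X)
     + β₄·message(t)·f₄(X) + β₅·total_strong_balls(t)·f₅(X)
     + β₆·change(t)·f₆(X)

and softmax choice probabilities P(X) ∝ exp(β·U(X)) with inverse temperature
β (called `slope` in the code).  The six signed feature functions encode:
strong vs normal (f₁), strong-to-victim vs everything else (f₂ = f₄),
conformity direction with normal balls to the instigators counting +0.5 as
indirect assistance (f₃), a strong-ball indicator for the accumulation
regressor (f₅), and strong-to-instigator redirection (f₆).  The context
regressors are session case tables: react = 1 only in session 3, conf =
0/1/2 for sessions 1–3 / 4 / 5–8, message = 1 from session 6,
total_strong_balls counts strong balls by all four players strictly before
the decision, and change gates the target-change term in sessions 6–8.

N1/N3 and S1/S3 have identical features, so the six-way softmax is
effectively a four-category model with tied pairs; the intercept β₀ cancels
and is fixed at 0.

## Deliberately configurable conventions

Two pieces of the model are ambiguous as printed and are exposed as explicit
options (`ModelOptions`):

- **change(t)** mixes past information (strong ball to P4 in session 4/5)
  with whole-record information (strong ball to P1/P3 in sessions 6–8).
  `change_mode="record"` (default for fitting) treats it as a
  participant-level indicator computed from the complete record, constant
  over sessions 6–8 — the natural reading for an offline maximum-likelihood
  fit.  `"causal"` evaluates the sessions-6–8 clause only on history up to
  the current trial.  `"onset"` uses only the session-4/5 precondition; this
  is the generative convention in the simulator, because the whole-record
  indicator does not exist mid-simulation and the strictly causal variant
  would leave the target-change drive inert until a first chance redirect.
  For any participant whose redirection actually occurs, "record" and
  "onset" agree on every trial.
- **z_normalize_tsb** (default on) z-scores the strong-ball count across the
  participant's 64 trials.  It is the only unbounded regressor; leaving it
  raw makes the ±10 box on β₅ effectively infinite and lets
  quasi-separation drive (β₁, β₃, β₅) to degenerate corners.

## Fitting

Per participant, (β₁…β₆, slope) are estimated by L-BFGS-B with an analytic
gradient, box bounds [−10, 10] on β₁…β₆ and [0, 10] on slope, and 10
restarts (first at zero with slope 1, the rest uniform in the bounds).  The
bound of 10 is suggested by pinned estimates of exactly 10.000 in this kind
of fit.  Because (k·slope, β/k) is likelihood-equivalent for any k > 0, the
recommended and tested configuration fixes slope = 1, which reduces the
problem to a convex multinomial logit.  Two safeguards matter at n = 64:

- a regressor that is identically zero over a record (typically the change
  gate) leaves its coefficient unidentified; it is excluded from the
  optimization, reported as 0 and flagged in `BetaEstimate.unidentified`;
- a restart must improve the NLL by more than 1e-5 to replace an earlier
  solution, so near-flat ridges stay pinned at the zeros initialization
  instead of inheriting arbitrary values from random restarts.

Estimates pinned at a bound are flagged in `at_bound`.  Complete separation
(e.g. a participant who throws only N1/N3 after session 3) still produces
bound-pinned β₃/β₁; this is genuine maximum-likelihood behavior at this
sample size and is left visible rather than regularized away.

## Synthetic cohort

The generator produces ground-truth parameter vectors, trait scores,
bullying/victimization scores and connectivity matrices with planted,
recoverable structure.  The true joint distribution of β across participants
is unobservable; the conventions below were chosen so that simulated cohorts
match the study-level behavioral facts (roughly one-quarter to one-third of
throws strong; a majority of participants joining the aggression against P4
in sessions 4–5; target-changers emerging from among the conformers; slope
comparable across participants):

- β₁ ~ N(−1, 0.8) (normal balls are the default action),
- β₂ ~ N(0, 0.8), β₄ ~ N(−0.5, 0.8),
- β₃ ~ |N(0, 2)| (positive-skewed conformity),
- β₅ ~ N(−0.01, 0.01) (small per-ball accumulation effect on the raw count
  scale),
- β₆ = 0 for non-changers; with probability 0.5, participants whose β₃ > 1
  are changers with β₆ ~ |N(0, 4)| clipped at 10,
- slope = 1.

Trait scores are built copula-style: a planted trait equals
r·z(parameter) + √(1−r²)·noise with z the standardized parameter, giving a
population correlation of exactly r without touching the parameter's
marginal; all traits are then standardized within-cohort.  Default planted
effects are extraversion↔β₆ at r = 0.346 and personal distress (IRI
D)↔β₃ at r = 0.324.  Bullying and victimization raw scores follow
moment-matched beta-binomials on the 0–6 scale (means 1.744 and 2.744, SDs
1.399 and 1.727), coupled rank-wise (r = 0.3, a convention) to β₆ and β₃
respectively; a positive standardized score classifies a participant as
bully and/or victim.

Connectivity is generated directly in Fisher-z edge space: 146×146 symmetric
matrices whose edges are Gaussian noise except for a small planted set whose
values correlate with a behavioral parameter at a chosen r (defaults: three
insula edges for β₆ at 0.512/0.490/0.487 and one amygdala–TPJ edge for β₃
at 0.45, the last being a convention because its original effect size is
unprinted).  Generating edges rather than time series is intentional — the
downstream analysis consumes only edge values; a thin
`generate_roi_timeseries` path exists to exercise the Pearson→Fisher-z
construction.  The named ROI labels are synthetic stand-ins placed at fixed
matrix indices.

What the generator does **not** emulate: BOLD autocorrelation and
preprocessing artifacts, distance-dependent edge correlations, the P1-vs-P3
asymmetry of real retaliation after a threat (the model ties S1 = S3, so
simulated cohorts cannot reproduce a session-6→7 increase specific to P1),
free-text messages, or player ratings.  Passing tests therefore validate the
statistical machinery on data generated under the model's own assumptions,
not the ecological claims of the original experiment.

## Analysis stages

- **Group statistics**: two-sided one-sample t tests of β₁…β₆ against 0
  (df = n−1); one-way repeated-measures ANOVA over the 8 sessions on
  strong-ball counts to P1 and P3 with uncorrected degrees of freedom
  (7, 7(n−1)) — no sphericity correction, matching the printed convention —
  plus paired t tests for the session 5→6 (P3) and 6→7 (P1) transitions;
  OLS trait regressions with intercept and bivariate Pearson correlations,
  with an optional (off by default) exclusion of points with externally
  studentized residual |t| > 3, because the original outlier rule is
  unstated.
- **Connectivity**: edges standardized to unit variance, LASSO with the
  penalty chosen at minimum mean 10-fold cross-validated error
  (fold assignment stratified by outcome quantile and seeded, since at
  n = 43 fold-to-fold variance otherwise dominates), selected edges tested
  with Pearson correlations under Bonferroni correction with family size =
  number of selected edges.  Selection and testing deliberately reuse the
  same cohort; the pipeline reproduces this circularity rather than
  correcting it, and at n = 43 the cross-validated penalty can honestly
  select zero edges.
- **Mediation**: single-mediator path model (a, b, c, c′) estimated by
  least squares with the exact decomposition c = c′ + a·b; inference on the
  indirect effect by participant bootstrap (default 10,000 resamples),
  two-sided percentile p with a bias-corrected option.  Under the joint null
  (a = b = 0) the product test is conservative — its rejection rate sits far
  below α, which is the expected behavior of bootstrap product tests, while
  on the boundary null (a ≠ 0, b = 0) it attains its nominal level; the
  test suite checks both regimes rather than asserting uniform calibration.

## Numerical choices and problem sizes

Softmax probabilities use max-subtraction; NLL evaluation runs on a
precomputed (trials × actions × features) design tensor.  Optimizer
tolerances: ftol 1e-9, gtol 1e-8, 500 iterations.  The parameter-recovery
check uses three replicate cohorts of 43 participants × 64 trials (a single
cohort of 43 gives a noisy correlation estimate; averaging three replicates
measures the same property with less sampling variance) and requires mean
Pearson r(true, estimated) > 0.6 for β₃ and β₆.  Calibration checks use
1000 replicates (type-I error of the regression and edge stages), 300
replicates (mediation nulls), 20 seeds (planted-edge LASSO recovery at
n = 200 with 500 noise edges), and 10,000 Monte-Carlo draws (agent-script
rates).  The analysis drivers run the full 146-ROI, 10,585-edge pipeline at
the study size n = 43.

## Known limitations

- β₂ and β₄ are weakly identified from 8 session-3 trials and the
  threat-arm contrast respectively; their recovery is noticeably worse than
  β₁/β₃/β₆ and nothing downstream depends on them.
- Bound-pinned and separated estimates are flagged but not regularized;
  cohort-level correlations inherit their noise.
- The simulator's turn structure (fixed P1→P2→P3→P4 rounds) and the agents'
  20% non-aggressive fallback (uniform normal ball) are conventions; nothing
  in the utility model depends on turn order.
- The bootstrap mediation p is percentile-based; it is not a replication of
  any particular toolbox's default, and z/p pairs are internally consistent
  by construction.
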