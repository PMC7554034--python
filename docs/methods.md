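# Methods

## The task and the question

Each trial of the two-tone discrimination task presents two 100 ms pure
tones separated by 1 s; the listener reports whether their frequencies
were the same or different. A session has 120 trials in three 40-trial
blocks ordered by increasing difficulty — the "different" trials differ
by 3%, then 2%, then 1% — with the first tone drawn from
{500, 750, 1000, 1500} Hz and half of each block physically identical
pairs. A 16-trial feedback training block (8 trials at 4%, 8 at 1%)
precedes the task and is repeated until 75% accuracy.

Serial dependence makes this task a probe of perceptual inference: the
memory of the first tone is pulled toward recently heard stimuli
("contraction bias"). Depending on where the previous trial's tones sat
relative to the current pair, that pull either stretches the perceived
within-pair difference (aiding a correct "different") or shrinks it
(hurting it). The pipeline quantifies this through a trial-level
contrast between those two trial classes and through a generative
observer whose contraction weight can be recovered from trial logs.

## Generative observer

All computations are in log frequency, u = ln f, the natural scale for
ratio-defined stimuli (a d% difference is a fixed log offset at any
base). Per trial:

- encodings: x1 = u1 + e1, x2 = u2 + e2, with e ~ N(0, sigma^2) i.i.d.;
- contraction of the first-tone memory toward the attractor pi:
  m1 = (1 − lambda) x1 + lambda pi (m1 = x1 before any history);
- decision: respond "different" iff |x2 − m1| > c (two-sided; a
  one-sided variant x2 − m1 > c is available);
- lapse: with probability gamma the response is replaced by a fair coin;
- attractor update toward the trial's veridical pair mean
  v = (u1 + u2)/2 with recency weight eta: pi ← (1 − eta) pi + eta v.
  With eta = 1 (default) the attractor is exactly the previous trial's
  pair mean, matching the previous-trial (t − 1) bias classification.
  A variant builds the attractor from the noisy encodings instead.

The two-sided rule is the default because contraction must hurt *all*
same trials (any pull away from the second tone creates a spurious
perceived difference); under a one-sided rule a downward pull could
never produce a false "different".

`psychometric_prediction` gives the exact response probability for a
fixed trial geometry: x2 − m1 is Gaussian with mean
Delta − lambda·(pi − u1), Delta = ln(1 + d/100), and variance
sigma^2 (1 + (1 − lambda)^2), so P("different") has a closed normal
form; lapses mix in 1/2. It serves as the independent oracle for the
Monte-Carlo simulator and for the model analyses below.

### Parameters, units, defaults

| parameter | meaning | units | default |
|---|---|---|---|
| lambda | attractor weight in the first-tone memory | – | 0.006 (TD/LAD-like), 0.001 (ASD-like) |
| sigma | per-tone encoding noise SD | log-frequency | 0.007 |
| c | decision bound | log-frequency | ln(1.011) ≈ 0.0109 |
| gamma | lapse probability | – | 0.02 |
| eta | attractor recency weight | – | 1.0 |
| rt_model | lognormal(mu, s) on log-ms | – | median ≈ 900–930 ms |

A crucial geometric fact drives the defaults: the attractor can sit up
to ln 3 ≈ 1.1 log-units from the current first tone (the base
frequencies span a factor of three), while within-pair differences are
only 0.01–0.03 log-units. The contraction shift is lambda times the
attractor distance, so *small* lambda values already produce large
perceptual effects on cross-base transitions; lambda of order 0.1 or
more drives every cross-base same trial to a false "different" and
pushes overall accuracy to chance. The defaults were therefore
calibrated so the simulated cohort lands in the study's observed
regime — overall accuracy in the mid-70s%, roughly three quarters of a
pre-exclusion cohort passing the >60% filter, a clear Bias+/Bias− gap
for strong-contraction (TD/LAD-like) observers and a near-flat gap for
weak-contraction (ASD-like) observers, with the weak:strong ratio kept
at about 1:6. With sigma = 0.007 and c = ln(1.011), a veridical
observer scores ≈ 74% overall and ≈ 84% in the 3% block, and its
same-trial and mean different-trial accuracies roughly balance, so the
Bias+/Bias− contrast is driven by contraction rather than by a
same/different response asymmetry.

### Model properties worth knowing

- **Overshoot.** On Bias− different trials the perceived difference is
  Delta − lambda·offset. As lambda grows this crosses zero and then
  grows in magnitude — under the two-sided rule the observer answers
  "different" (correct) again, for the wrong reason. The Bias+/Bias−
  gap on different trials is therefore *non-monotonic* in lambda: it
  rises on the pre-overshoot range (lambda up to roughly
  Delta/offset ≈ 0.01 for cross-base transitions), peaks, and falls
  back toward zero. Monotonicity of the gap in lambda holds only in the
  pre-overshoot regime where the defaults live.
- **Identifiability.** For the same reason, the two matched moments
  (overall accuracy, Bias+/Bias− gap) saturate once lambda exceeds the
  overshoot scale: for sigma ≈ 0.012 both moments are constant to
  ~0.003 across lambda in [0.2, 0.6]. Contraction strength can be
  recovered accurately only in the pre-overshoot regime; the recovery
  API reports the full evaluated grid so saturation is visible to the
  caller.

## Bias classification

The preceding pair is summarized by its log-mean attractor
A = (ln f1' + ln f2')/2 — faithful because the pair differs by at most
a few percent. With u1 = ln f1 of the current trial (the design
guarantees f2 ≥ f1):

- same trials → **Bias−** (contraction can only hurt them);
- different and A < u1 − tol → **Bias+** (pull stretches the pair);
- different and A > u1 + tol → **Bias−** (pull shrinks the pair);
- |A − u1| ≤ tol → **Neutral** (tol = 1e-9 log-units).

The neutral case is real, not hypothetical: a same-pair at, say,
1000 Hz followed by a different-trial at the same base gives A = u1
exactly (12 of the 256 design transitions). Neutral trials stay in
overall accuracy but are dropped from the Bias+/Bias− contrast. The
first trial of a session is excluded (no predecessor); block boundaries
do *not* reset the predecessor by default, since blocks run
back-to-back (a reset flag exists). A strict variant requiring both
previous tones to flank is available; on the design grid it differs
from the log-mean rule only at the degenerate A = u1 transitions.

## Inclusion filter

Participants are retained when accuracy in the easiest condition — the
block with the largest frequency difference — strictly exceeds 60%
(a 50% robustness variant is exposed as the same `threshold` argument).
The rationale is binomial: a guessing participant clears 24/40 with
probability P(X ≥ 25 | 40, 1/2) ≈ 0.077, computed by exact integer
summation. The easiest-condition trial set defaults to the whole
40-trial block; an `n_trials` parameter restricts it (e.g. to 30) for
studies that scored a subset. The synthetic pre-exclusion cohort
(29/27/23 per group) adds coin-flipping (gamma = 1) subjects — 8/6/5
per group — so that running the filter reproduces inclusion fractions
near the study's 72/78/78%.

## Statistics

The primary model is a trial-level *linear probability* mixed model:
correctness (0/1) on Group, BiasType and their interaction as fixed
effects with a per-subject random intercept, estimated by maximum
likelihood (statsmodels MixedLM). Per-term F statistics are Wald tests
on the fixed-effect blocks with residual denominator degrees of freedom
(n_obs − k), which is why denominator dfs land in the thousands.
Design choices:

- **Boundary handling.** With homogeneous simulated observers the true
  random-intercept variance is zero; the ML optimum sits on the
  boundary, where the mixed model *is* OLS. When the optimizer stalls
  there (non-convergence, singular Hessian, or tau^2 ≈ 0), the fit
  switches to the exact boundary solution — OLS with an HC1
  heteroskedasticity-robust covariance, the standard treatment for
  linear probability models. So calibrated, the null interaction
  rejects at 5.0% (500 null cohorts).
- **Conservatism under serial dependence.** When lambda > 0, a
  subject's Bias+ and Bias− accuracies share the attractor path, which
  slightly correlates the cells and makes the far tail of the
  interaction test conservative. Type-I calibration is therefore
  checked on fully null (lambda = 0) cohorts.
- Pairwise group contrasts refit the two groups and compare the
  interaction p against alpha divided by the number of parallel
  comparisons (Bonferroni; 3 by default).
- Cohen's d for the trial-type effect uses the paired convention:
  mean per-subject (Bias+ − Bias−) accuracy difference over its SD.
  Note that with parameter-homogeneous simulated subjects the
  between-subject SD is nearly pure binomial noise, so simulated d
  values run larger than human ones at the same trial-level F.
- RT summaries are subject-mean based (group mean ± SEM) with the same
  mixed-model structure on RT; RTs in the simulator are decorative
  (lognormal draws) and never feed the decision.
- A logistic variant (Bayesian binomial mixed GLM, variational fit,
  Wald z² statistics) sits behind `logistic=True`.
- Power for the paired design is estimated by simulation (normal
  per-subject standardized differences, two-sided paired t), with the
  smallest detectable effect found by bisection; at n = 18 the 80%
  power point is d ≈ 0.70.

## Contraction-strength recovery

`fit_lambda_sigma` matches two observed moments — overall accuracy over
labeled trials and the Bias+/Bias− accuracy gap (Bias− including same
trials) — against moments simulated on a (lambda, sigma) grid, holding
gamma and c at configured values. Grid-then-refine with common random
numbers: one standard-normal/uniform noise block is drawn per fit and
rescaled at every grid point, so the objective surface is smooth in the
parameters and the whole fit is deterministic given its seed. The best
grid point gets a local quadratic refinement on lambda (vertex of the
parabola through the three neighboring objective values, clipped to
the bracket). Observed moments outside the grid's achievable envelope
raise a no-fit error carrying that envelope. In the pre-overshoot
regime the recovery error is below 0.001 with 1e5-trial logs; the full
grid is serialized for audit.

## Synthetic data: what it does and does not emulate

Emulated: the exact task design and trial counts; mid-70s% accuracy;
the strong/weak contraction split between TD/LAD-like and ASD-like
groups with included-sample sizes 18/21/21; a disengaged subgroup that
the inclusion filter removes at realistic rates; RT magnitudes around
0.9–1 s.

Not emulated: between-subject parameter heterogeneity (all engaged
observers in a group are parameter-identical clones, so subject-level
accuracy spread is binomial-only and subject-level effect sizes are
inflated relative to human data); RT–accuracy coupling and RT decay
effects; multi-trial-back history kernels (eta = 1 looks one trial
back); learning or fatigue within a session. Passing tests therefore
demonstrate the pipeline's correctness and the model's qualitative
regime, not distributional realism of individual differences.

## Numerical choices and degenerate inputs

- f2 closure is validated at relative tolerance 1e-12; the bias-rule
  tolerance is 1e-9 log-units; both far below any physical scale.
- sigma = 0 degenerates the psychometric prediction to a 0/1 indicator.
- All randomness flows from numpy Generators seeded per subject via
  SeedSequence(seed, subject index, stream), making cohorts
  byte-reproducible; the scalar per-trial simulator consumes exactly
  four draws per trial so stream positions are predictable.
- Degenerate model inputs fail loudly: all-correct outcomes (no
  residual variability), a zero paired SD for Cohen's d, subjects with
  a single bias level (warned, then dropped), unknown groups.
- Test and script problem sizes: 1e5-trial Monte-Carlo checks for
  observer properties, 2e4 draws per design cell for simulator/oracle
  agreement, 500 null cohorts (12 subjects, 80 trials) for calibration,
  100 seeded cohorts for the headline contrast, 4e4–1e5 simulated
  trials per grid point in recovery. These sizes put Monte-Carlo error
  well below every asserted tolerance while keeping the full suite
  fast.

## Known limitations

- The contraction acts on the full distance to the attractor; real
  serial dependence is distance-limited. With this task's wide base
  grid that makes the model extremely sensitive to lambda and produces
  the overshoot/saturation behavior described above. A
  similarity-weighted pull would be the natural extension.
- The linear probability model can predict outside [0, 1]; the
  logistic variant avoids that at the cost of exact F tests.
- Recovery identifies lambda only below the overshoot scale, and its
  sigma grid must bracket the true noise level.
- The inclusion filter's binomial rationale assumes within-subject
  homogeneity across the easiest block.
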