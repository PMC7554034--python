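# contrabias

Analysis pipeline for **contraction bias** in a two-tone same/different
discrimination task, built for auditory psychophysics and computational
psychiatry work comparing serial dependence across groups (e.g.
typically developing listeners, autistic listeners, and individuals who
have lost an early autism diagnosis).

## The problem

On every trial a listener hears two 100 ms tones (1 s apart) and judges
whether their frequencies are identical. Sessions have 120 trials in
three blocks of 40 (20 same + 20 different), ordered by increasing
difficulty: different-trials at 3%, then 2%, then 1% above the first
tone, which is drawn from {500, 750, 1000, 1500} Hz.

Perception in such sequences is not memoryless. The remembered first
tone is pulled toward recently heard stimuli — *contraction bias*, the
behavioral signature of Bayesian perceptual inference. Writing
u = ln f, the model at the core of the package is

    x1 = u1 + e1,   x2 = u2 + e2,        e ~ N(0, sigma^2)
    m1 = (1 - lambda) * x1 + lambda * pi
    respond "different"  iff  |x2 - m1| > c,   lapse rate gamma
    pi <- (1 - eta) * pi + eta * (u1 + u2) / 2

where pi is the attractor (with eta = 1, the previous trial's pair
mean) and lambda the contraction weight. Depending on where the
previous pair sat, the pull *stretches* the perceived difference
(**Bias+** trials: attractor beyond the first tone, away from the
second) or *shrinks* it (**Bias−** trials, including every "same"
trial). The per-group difference in Bias+ vs Bias− accuracy is the
trial-level fingerprint of contraction strength.

The pipeline provides, as library modules with a CLI and numbered
analysis drivers on top:

- `design` — task generation and validation (plus training block);
- `observer` — the generative contraction-bias observer, cohort
  simulator, and an exact psychometric oracle;
- `bias` — Bias+/Bias−/neutral trial classification;
- `inclusion` — the above-chance (>60% easiest-condition) participant
  filter and its exact binomial rationale;
- `stats` — trial-level linear-probability mixed models (Group ×
  BiasType, random intercept per subject), Bonferroni pairwise
  contrasts, within-group tests, paired Cohen's d, RT summaries,
  simulation-based power;
- `recovery` — contraction-strength estimation by simulation-based
  moment matching with common random numbers.

No public trial-level human dataset exists for this task, so the
package ships a calibrated synthetic-cohort generator (strong
contraction for TD/LAD-like observers, weak for ASD-like, plus a
disengaged coin-flipping subgroup) that reproduces the published
phenomenology; any user data in the same CSV schema drops straight in.

## Worked example

Simulate the pre-exclusion cohort (29/27/23 subjects), then run the
full analysis:

```sh
python analysis/01_simulate_cohorts.py --seed 1 --out results
python analysis/03_bias_contrast.py --log results/cohort_full.csv --out results
```

which prints (seed 1):

```
inclusion ASD: 22/29 (76%)
inclusion LAD: 21/27 (78%)
inclusion TD: 18/23 (78%)

Group x BiasType mixed model:
correct ~ C(group) * C(bias) + (1 | subject_id), ML
n_obs=6795, n_subjects=61
  C(group): F(2,6789) = 1.74e-46, p = 1
  C(bias): F(1,6789) = 3.59, p = 0.05802
  C(group):C(bias): F(2,6789) = 6.11, p = 0.002227
pairwise ASD vs LAD: F = 10.3, p = 0.00131 (significant at alpha/3 = 0.01667)
pairwise ASD vs TD: F = 7.53, p = 0.006088 (significant at alpha/3 = 0.01667)
pairwise LAD vs TD: F = 0.104, p = 0.7471 (ns at alpha/3 = 0.01667)
within ASD: F(1,2436) = 3.6, p = 0.05793, d = 0.45
within LAD: F(1,2342) = 51.5, p = 9.659e-13, d = 1.98
within TD: F(1,2011) = 35.3, p = 3.281e-09, d = 1.22

RT: ASD: 962 +/- 3 ms; LAD: 962 +/- 5 ms; TD: 928 +/- 6 ms
```

Reading it: roughly three quarters of each group pass the above-chance
filter; overall accuracy does not differ between groups (Group main
effect ≈ 0), but the Group × BiasType interaction is significant — the
TD- and LAD-like groups perform better on Bias+ than Bias− trials
(strong within-group effects) while the ASD-like group is flat, and
both ASD contrasts survive the Bonferroni-corrected threshold. That is
the "weaker contraction in ASD, typical contraction in LAD" pattern
the pipeline is built to detect. Recovering the generative parameters
from the same log:

```sh
python analysis/04_recover_contraction.py --log results/cohort_labeled_included.csv
```

```
ASD: accuracy=0.730 gap=+0.041 -> lambda_hat=0.0014, sigma_hat=0.0070
LAD: accuracy=0.721 gap=+0.145 -> lambda_hat=0.0067, sigma_hat=0.0070
TD:  accuracy=0.719 gap=+0.132 -> lambda_hat=0.0062, sigma_hat=0.0070
```

close to the generating values (0.001 / 0.006 / 0.006). The same
pipeline is available as a CLI (`contrabias simulate|analyze|recover`,
see `contrabias --help` and `configs/default.yaml`).

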