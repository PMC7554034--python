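"""Trial-level mixed-model contrasts and effect sizes.

The inferential core is a linear probability model on 0/1 correctness
with Group, BiasType and their interaction as fixed effects and a
random intercept per subject, estimated by maximum likelihood. F tests
per term use Wald statistics with residual denominator degrees of
freedom (n_observations - n_fixed_parameters). Neutral and excluded
bias labels are dropped before fitting. Pairwise group contrasts refit
the model on two groups and apply a Bonferroni-divided threshold.

A logistic variant (Bayesian mixed GLM, variational fit, Wald z tests
instead of F) is available behind ``logistic=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .bias import BiasLabel
from .errors import InputError, StatsError

_CONTRAST_LEVELS = (BiasLabel.PLUS.value, BiasLabel.MINUS.value)


@dataclass
class FitResult:
    """Fixed-effect estimates and per-term F tests of one mixed model."""

    fixed_effects: pd.DataFrame  # term, estimate, se
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    n_observations: int
    n_subjects: int
    model_spec: str

    def term(self, name: str) -> pd.Series:
        rows = self.anova[self.anova["term"] == name]
        if len(rows) == 0:
            raise KeyError(f"no term {name!r} in {list(self.anova['term'])}")
        return rows.iloc[0]

    def __str__(self) -> str:
        lines = [self.model_spec,
                 f"n_obs={self.n_observations}, n_subjects={self.n_subjects}"]
        for r in self.anova.itertuples(index=False):
            lines.append(
                f"  {r.term}: F({int(r.df_num)},{int(r.df_den)}) = {r.F:.3g}, p = {r.p:.4g}"
            )
        return "\n".join(lines)


@dataclass
class EffectSize:
    cohens_d: float
    n: int
    method: str


@dataclass
class PairwiseResult:
    """A two-group refit plus its Bonferroni-corrected decision."""

    fit: FitResult
    groups: Tuple[str, str]
    f_interaction: float
    p_raw: float
    alpha: float
    n_comparisons: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_comparisons

    @property
    def significant(self) -> bool:
        return self.p_raw < self.threshold


def _prepare(trial_log: pd.DataFrame, outcome: str = "correct") -> pd.DataFrame:
    df = trial_log[trial_log["bias_label"].isin(_CONTRAST_LEVELS)].copy()
    df = df[df["response"].isin(["same", "different"])]
    if outcome == "rt_ms":
        df = df[pd.notna(df["rt_ms"])]
    df["bias"] = pd.Categorical(df["bias_label"], categories=_CONTRAST_LEVELS)
    if len(df) == 0:
        raise StatsError("no Bias+/Bias- trials with responses to model")
    # subjects must carry both bias levels for a within-subject contrast
    ok = df.groupby("subject_id")["bias"].nunique() == 2
    bad = set(ok.index[~ok])
    if bad:
        warnings.warn(
            f"dropping {len(bad)} subject(s) with a single bias level: {sorted(bad)}",
            stacklevel=3,
        )
        df = df[~df["subject_id"].isin(bad)]
    if len(df) == 0:
        raise StatsError("no subjects with both bias levels")
    return df


def _wald_f_table(result, design_info, df_den: int) -> pd.DataFrame:
    """Per-term Wald F tests of the fixed effects (residual-df convention)."""
    fe = result.fe_params if hasattr(result, "fe_params") else result.params
    cov = np.asarray(result.cov_params())[: len(fe), : len(fe)]
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        b = np.asarray(fe)[idx]
        v = cov[np.ix_(idx, idx)]
        q = len(idx)
        try:
            stat = float(b @ np.linalg.solve(v, b)) / q
        except np.linalg.LinAlgError:
            stat = np.nan
        p = float(sps.f.sf(stat, q, df_den)) if np.isfinite(stat) else np.nan
        rows.append({"term": term, "F": stat, "df_num": q, "df_den": df_den, "p": p})
    return pd.DataFrame(rows)


def _fit_lmm(df: pd.DataFrame, formula: str, outcome: str) -> FitResult:
    if df[outcome].nunique() <= 1:
        raise StatsError(f"outcome {outcome!r} has no variability; nothing to model")
    with warnings.catch_warnings():
        # boundary fits (zero random-intercept variance) are legitimate here
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject_id"])
        # At tau^2 ~ 0 the ML solution degenerates to OLS exactly, but the
        # numerical optimizer can stall on the boundary and report a
        # singular/garbage Hessian; detect that and use the boundary (OLS)
        # solution, which is then the exact ML fit.
        try:
            result = model.fit(reml=False)
            tau2 = float(np.asarray(result.cov_re)[0, 0])
            try:
                bse_ok = bool(np.all(np.isfinite(result.bse_fe)))
            except np.linalg.LinAlgError:
                bse_ok = False
            boundary = (
                not getattr(result, "converged", True)
                or not bse_ok
                or tau2 <= 1e-6 * float(result.scale)
            )
        except np.linalg.LinAlgError:
            result, bse_ok, boundary = None, False, True
        design_info = model.data.design_info
        k = model.exog.shape[1]
        df_den = len(df) - k
        spec = f"{formula} + (1 | subject_id), ML"
        if boundary:
            ols = smf.ols(formula, df).fit()
            if result is None or not bse_ok or ols.llf >= result.llf - 1e-6:
                # 0/1 outcomes are heteroskedastic by construction, so the
                # boundary (OLS) solution uses an HC1 robust covariance
                result = ols.get_robustcov_results(cov_type="HC1")
                spec += " [random-intercept variance at boundary: OLS + HC1]"
        if hasattr(result, "fe_params"):
            params, bse = result.fe_params, result.bse_fe
        else:
            params, bse = result.params, result.bse
        anova = _wald_f_table(result, design_info, df_den)
        fixed = pd.DataFrame(
            {
                "term": design_info.column_names,
                "estimate": np.asarray(params)[: len(design_info.column_names)],
                "se": np.asarray(bse)[: len(design_info.column_names)],
            }
        )
    return FitResult(
        fixed_effects=fixed,
        anova=anova,
        n_observations=len(df),
        n_subjects=df["subject_id"].nunique(),
        model_spec=spec,
    )


def _fit_logistic(df: pd.DataFrame, formula: str, outcome: str) -> FitResult:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")
        model = BinomialBayesMixedGLM.from_formula(
            formula, {"subject": "0 + C(subject_id)"}, df
        )
        result = model.fit_vb()
    k = len(model.exog_names)
    means = result.params[:k]
    sds = result.fe_sd[:k]
    z = means / sds
    p = 2 * sps.norm.sf(np.abs(z))
    fixed = pd.DataFrame({"term": model.exog_names, "estimate": means, "se": sds})
    anova = pd.DataFrame(
        {
            "term": model.exog_names,
            "F": z**2,  # Wald z^2, 1 df each
            "df_num": 1,
            "df_den": len(df) - k,
            "p": p,
        }
    )
    return FitResult(
        fixed_effects=fixed,
        anova=anova[anova["term"] != "Intercept"].reset_index(drop=True),
        n_observations=len(df),
        n_subjects=df["subject_id"].nunique(),
        model_spec=f"{formula} + (1 | subject_id), logistic (VB); Wald z^2 per column",
    )


def fit_bias_model(trial_log: pd.DataFrame, logistic: bool = False) -> FitResult:
    """Correctness ~ Group * BiasType with a per-subject random intercept.

    Requires >= 2 groups for the interaction; with a single group a
    main-effects-only (bias) model is fit instead.
    """
    df = _prepare(trial_log)
    df["correct"] = df["correct"].astype(float)
    n_groups = df["group"].nunique()
    if n_groups >= 2:
        formula = "correct ~ C(group) * C(bias)"
    else:
        formula = "correct ~ C(bias)"
    fitter = _fit_logistic if logistic else _fit_lmm
    return fitter(df, formula, "correct")


def _interaction_row(fit: FitResult) -> pd.Series:
    inter = fit.anova[fit.anova["term"].str.contains(":")]
    if len(inter) == 0:
        raise StatsError("model has no interaction term")
    return inter.iloc[0]


def posthoc_pairwise(
    trial_log: pd.DataFrame,
    group_pair: Sequence[str],
    n_comparisons: int = 3,
    alpha: float = 0.05,
    logistic: bool = False,
) -> PairwiseResult:
    """Two-group refit with a Bonferroni-divided significance threshold."""
    a, b = group_pair
    present = set(trial_log["group"].unique())
    missing = {a, b} - present
    if missing:
        raise InputError(f"unknown group(s): {sorted(missing)}")
    sub = trial_log[trial_log["group"].isin([a, b])]
    fit = fit_bias_model(sub, logistic=logistic)
    row = _interaction_row(fit)
    return PairwiseResult(
        fit=fit,
        groups=(a, b),
        f_interaction=float(row["F"]),
        p_raw=float(row["p"]),
        alpha=alpha,
        n_comparisons=n_comparisons,
    )


def within_group_trialtype_test(
    trial_log: pd.DataFrame, group: str, logistic: bool = False
) -> FitResult:
    """BiasType effect on correctness within one group (random intercept)."""
    sub = trial_log[trial_log["group"] == group]
    if len(sub) == 0:
        raise InputError(f"unknown group: {group!r}")
    df = _prepare(sub)
    df["correct"] = df["correct"].astype(float)
    fitter = _fit_logistic if logistic else _fit_lmm
    return fitter(df, "correct ~ C(bias)", "correct")


def cohens_d_trialtype(trial_log: pd.DataFrame, group: str) -> EffectSize:
    """Paired Cohen's d of the per-subject Bias+ minus Bias- accuracy."""
    sub = trial_log[trial_log["group"] == group]
    if sub["subject_id"].nunique() < 2:
        raise InputError("need >= 2 subjects for an effect size")
    df = _prepare(sub)
    acc = (
        df.assign(correct=df["correct"].astype(float))
        .groupby(["subject_id", "bias"], observed=True)["correct"]
        .mean()
        .unstack("bias")
    )
    diffs = (acc[BiasLabel.PLUS.value] - acc[BiasLabel.MINUS.value]).dropna()
    sd = float(diffs.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise StatsError("paired SD of the accuracy difference is zero; d undefined")
    return EffectSize(
        cohens_d=float(diffs.mean()) / sd,
        n=len(diffs),
        method="paired (mean within-subject Bias+ - Bias- difference / its SD)",
    )


@dataclass
class RTSummary:
    by_group: pd.DataFrame  # group, n_subjects, mean_ms, sem_ms
    fit: Optional[FitResult]
    n_dropped_missing: int

    def __str__(self) -> str:
        parts = [
            f"{r.group}: {r.mean_ms:.0f} +/- {r.sem_ms:.0f} ms"
            for r in self.by_group.itertuples(index=False)
        ]
        return "; ".join(parts) + f" (subject-mean based; {self.n_dropped_missing} missing dropped)"


def rt_summary(trial_log: pd.DataFrame) -> RTSummary:
    """Per-group mean +/- SEM of RT over subject means, plus the mixed model."""
    if "rt_ms" not in trial_log or trial_log["rt_ms"].isna().all():
        raise InputError("rt_ms missing from the trial log")
    n_missing = int(trial_log["rt_ms"].isna().sum())
    df = trial_log[pd.notna(trial_log["rt_ms"])]
    subj = df.groupby(["group", "subject_id"], observed=True)["rt_ms"].mean().reset_index()
    rows = []
    for g, gg in subj.groupby("group", sort=True):
        vals = gg["rt_ms"].to_numpy(float)
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {"group": g, "n_subjects": len(vals), "mean_ms": float(vals.mean()), "sem_ms": sem}
        )
    by_group = pd.DataFrame(rows)
    fit = None
    try:
        mdf = _prepare(df, outcome="rt_ms")
        n_groups = mdf["group"].nunique()
        formula = "rt_ms ~ C(group) * C(bias)" if n_groups >= 2 else "rt_ms ~ C(bias)"
        fit = _fit_lmm(mdf, formula, "rt_ms")
    except StatsError:
        fit = None  # e.g. constant RTs: summary still meaningful
    return RTSummary(by_group=by_group, fit=fit, n_dropped_missing=n_missing)


def power_by_simulation(
    d_target: float,
    n_subjects: int,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Power of the paired t test at standardized effect ``d_target``.

    Simulates per-subject standardized paired differences ~ N(d, 1),
    applies the two-sided one-sample t test, and returns (rejection
    fraction, its binomial standard error).
    """
    if n_reps < 100:
        raise InputError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    x = rng.normal(d_target, 1.0, size=(n_reps, n_subjects))
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    t = m / (s / np.sqrt(n_subjects))
    p = 2 * sps.t.sf(np.abs(t), df=n_subjects - 1)
    power = float(np.mean(p < alpha))
    se = float(np.sqrt(power * (1 - power) / n_reps))
    return power, se


def minimal_detectable_d(
    n_subjects: int,
    power_target: float = 0.8,
    alpha: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
    tol: float = 0.005,
) -> float:
    """Smallest standardized paired effect reaching ``power_target``, by bisection."""
    lo, hi = 0.0, 3.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        pw, _ = power_by_simulation(mid, n_subjects, alpha=alpha, n_reps=n_reps, seed=seed)
        if pw < power_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
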