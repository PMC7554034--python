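"""End-to-end analysis of a trial log and the two-panel summary figure."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from . import bias, inclusion, stats
from .errors import InputError, StatsError

log = logging.getLogger("contrabias")


@dataclass
class AnalysisResult:
    labeled: pd.DataFrame
    included: pd.DataFrame
    inclusion_report: pd.DataFrame
    full_fit: Optional[stats.FitResult]
    pairwise: dict = field(default_factory=dict)  # (a, b) -> PairwiseResult
    within_group: dict = field(default_factory=dict)  # group -> FitResult
    effect_sizes: dict = field(default_factory=dict)  # group -> EffectSize
    rt: Optional[stats.RTSummary] = None
    notices: list = field(default_factory=list)

    def summary_text(self) -> str:
        lines = ["Contraction-bias analysis", "=" * 25]
        rep = self.inclusion_report
        for g, gg in rep.groupby("group"):
            lines.append(
                f"inclusion {g}: {int(gg['included'].sum())}/{len(gg)} "
                f"({100 * gg['included'].mean():.0f}%)"
            )
        if self.full_fit is not None:
            lines += ["", "Group x BiasType mixed model:", str(self.full_fit)]
        for pair, res in self.pairwise.items():
            lines.append(
                f"pairwise {pair[0]} vs {pair[1]}: F = {res.f_interaction:.3g}, "
                f"p = {res.p_raw:.4g} ({'significant' if res.significant else 'ns'} "
                f"at alpha/{res.n_comparisons} = {res.threshold:.4g})"
            )
        for g, fit in self.within_group.items():
            row = fit.anova.iloc[0]
            d = self.effect_sizes.get(g)
            dtxt = f", d = {d.cohens_d:.2f}" if d else ""
            lines.append(
                f"within {g}: F({int(row['df_num'])},{int(row['df_den'])}) = "
                f"{row['F']:.3g}, p = {row['p']:.4g}{dtxt}"
            )
        if self.rt is not None:
            lines += ["", f"RT: {self.rt}"]
        for n in self.notices:
            lines.append(f"note: {n}")
        return "\n".join(lines)


def analyze_trial_log(
    trial_log: pd.DataFrame,
    criterion: float = 0.60,
    reset_per_block: bool = False,
    strict_flanking: bool = False,
    logistic: bool = False,
    apply_filter: bool = True,
) -> AnalysisResult:
    """Label, filter, and fit the full inferential pipeline.

    Runs bias labeling, the above-chance inclusion filter, the full
    Group x BiasType mixed model, all pairwise group contrasts at the
    Bonferroni-divided threshold, within-group trial-type tests with
    paired Cohen's d, and the RT summary.
    """
    labeled = bias.label_cohort(
        trial_log, reset_per_block=reset_per_block, strict_flanking=strict_flanking
    )
    if apply_filter:
        included, rep = inclusion.apply_inclusion(labeled, threshold=criterion)
    else:
        _, rep = inclusion.apply_inclusion(labeled, threshold=criterion)
        included = labeled
    result = AnalysisResult(
        labeled=labeled, included=included, inclusion_report=rep, full_fit=None
    )
    if len(included) == 0:
        raise InputError("all subjects excluded by the inclusion filter")

    groups = sorted(included["group"].unique())
    result.full_fit = stats.fit_bias_model(included, logistic=logistic)

    pairs = list(combinations(groups, 2))
    if len(groups) < 2:
        result.notices.append("single group: pairwise contrasts skipped")
    else:
        for pair in pairs:
            result.pairwise[pair] = stats.posthoc_pairwise(
                included, pair, n_comparisons=max(len(pairs), 1), logistic=logistic
            )
    for g in groups:
        try:
            result.within_group[g] = stats.within_group_trialtype_test(
                included, g, logistic=logistic
            )
            result.effect_sizes[g] = stats.cohens_d_trialtype(included, g)
        except (StatsError, InputError) as exc:
            result.notices.append(f"within-group test for {g} skipped: {exc}")
    try:
        result.rt = stats.rt_summary(included)
    except InputError:
        result.notices.append("no reaction times in the log; RT summary skipped")
    return result


def figure_trialtype(result: AnalysisResult, path) -> None:
    """Two panels: overall accuracy by group; accuracy by bias type per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.included
    df = df[df["response"].isin(["same", "different"])]
    fig, (ax_a, ax_b) = plt.subplots(1, 2, figsize=(9, 4))

    subj = df.groupby(["group", "subject_id"], observed=True)["correct"].mean().reset_index()
    groups = sorted(subj["group"].unique())
    xs = np.arange(len(groups))
    means = [subj.loc[subj["group"] == g, "correct"].mean() for g in groups]
    sems = [
        subj.loc[subj["group"] == g, "correct"].std(ddof=1)
        / np.sqrt((subj["group"] == g).sum())
        for g in groups
    ]
    ax_a.bar(xs, means, yerr=sems, capsize=4, color="lightgray", edgecolor="k")
    for i, g in enumerate(groups):
        vals = subj.loc[subj["group"] == g, "correct"]
        ax_a.plot(np.full(len(vals), i) + np.random.default_rng(0).uniform(-0.15, 0.15, len(vals)),
                  vals, "o", ms=3, alpha=0.6, color="tab:blue")
    ax_a.set_xticks(xs, groups)
    ax_a.set_ylabel("Accuracy")
    ax_a.set_title("A  Overall accuracy")
    ax_a.set_ylim(0, 1)

    lab = df[df["bias_label"].isin(["plus", "minus"])]
    cell = (
        lab.groupby(["group", "subject_id", "bias_label"], observed=True)["correct"]
        .mean()
        .reset_index()
    )
    for g in groups:
        gg = cell[cell["group"] == g]
        piv = gg.pivot(index="subject_id", columns="bias_label", values="correct")
        y = [piv["minus"].mean(), piv["plus"].mean()]
        e = [
            piv[c].std(ddof=1) / np.sqrt(piv[c].notna().sum())
            for c in ("minus", "plus")
        ]
        ax_b.errorbar([0, 1], y, yerr=e, marker="o", capsize=3, label=g)
    ax_b.set_xticks([0, 1], ["Bias-", "Bias+"])
    ax_b.set_xlim(-0.4, 1.4)
    ax_b.set_ylabel("Accuracy")
    ax_b.set_title("B  Accuracy by trial type")
    ax_b.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
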