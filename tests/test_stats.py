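import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from contrabias import stats as cstats
from contrabias.errors import InputError, StatsError


def _cell_log(spec):
    """Trial log from {(group, subject, bias): list of 0/1} patterns."""
    rows = []
    t = {}
    for (group, sid, bias), corrects in spec.items():
        for c in corrects:
            t[sid] = t.get(sid, 0) + 1
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "block_index": 1,
                    "trial_index": t[sid],
                    "f1_hz": 1000.0,
                    "f2_hz": 1010.0,
                    "diff_percent": 1.0,
                    "truth": "different",
                    "response": "different" if c else "same",
                    "correct": float(c),
                    "rt_ms": 900.0,
                    "bias_label": bias,
                }
            )
    return pd.DataFrame(rows)


PATTERN = [1, 1, 1, 0, 0, 1, 0, 1, 1, 0]  # 60% correct


class TestFitBiasModel:
    def test_identical_cells_zero_interaction(self):
        spec = {
            (g, f"{g}{i}", b): PATTERN
            for g in ("A", "B")
            for i in range(3)
            for b in ("plus", "minus")
        }
        fit = cstats.fit_bias_model(_cell_log(spec))
        row = fit.term("C(group):C(bias)")
        assert row["F"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0, abs=1e-6)

    def test_neutral_and_excluded_dropped(self, labeled_cohort):
        fit = cstats.fit_bias_model(labeled_cohort)
        kept = labeled_cohort["bias_label"].isin(["plus", "minus"]).sum()
        assert fit.n_observations == kept
        assert (fit.anova["p"].between(0, 1)).all()
        assert (fit.anova["df_den"] > 0).all()

    def test_subject_id_relabeling_invariance(self, labeled_cohort):
        fit_a = cstats.fit_bias_model(labeled_cohort)
        relabeled = labeled_cohort.copy()
        ids = sorted(relabeled["subject_id"].unique())
        mapping = dict(zip(ids, np.roll(ids, 3)))
        relabeled["subject_id"] = relabeled["subject_id"].map(mapping)
        fit_b = cstats.fit_bias_model(relabeled)
        np.testing.assert_allclose(fit_a.anova["F"], fit_b.anova["F"], rtol=1e-6)

    def test_single_group_main_effects_only(self, labeled_cohort):
        one = labeled_cohort[labeled_cohort["group"] == "TD"]
        fit = cstats.fit_bias_model(one)
        assert list(fit.anova["term"]) == ["C(bias)"]

    def test_single_bias_level_subject_dropped_with_warning(self, labeled_cohort):
        df = labeled_cohort.copy()
        sid = df["subject_id"].iloc[0]
        df.loc[(df["subject_id"] == sid) & (df["bias_label"] == "plus"), "bias_label"] = (
            "neutral"
        )
        with pytest.warns(UserWarning, match="single bias level"):
            fit = cstats.fit_bias_model(df)
        assert fit.n_subjects == df["subject_id"].nunique() - 1

    def test_all_correct_degenerate(self):
        spec = {
            ("A", f"A{i}", b): [1] * 10 for i in range(3) for b in ("plus", "minus")
        }
        with pytest.raises(StatsError, match="variability"):
            cstats.fit_bias_model(_cell_log(spec))

    def test_logistic_variant_runs(self, labeled_cohort):
        fit = cstats.fit_bias_model(labeled_cohort, logistic=True)
        assert "logistic" in fit.model_spec
        assert (fit.anova["p"].between(0, 1)).all()

    def test_matches_r_lme4_fixed_effects(self, labeled_cohort, tmp_path):
        """Independent oracle: lme4's ML fixed-effect estimates on the same
        data agree with ours to within numerical tolerance."""
        d = labeled_cohort[labeled_cohort["bias_label"].isin(["plus", "minus"])].copy()
        d["correct"] = d["correct"].astype(float)
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$bias <- factor(d$bias_label, levels=c("plus", "minus"))
                d$group <- factor(d$group, levels=c("ASD", "TD"))
                m <- lmer(correct ~ group*bias + (1|subject_id), data=d, REML=FALSE)
                write.csv(data.frame(est=fixef(m)), "{tmp_path}/fe.csv")
                """
            )
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        r_fe = pd.read_csv(tmp_path / "fe.csv")["est"].to_numpy()
        ours = cstats.fit_bias_model(labeled_cohort)
        # same contrasts: ASD/plus reference in both parameterizations
        np.testing.assert_allclose(
            ours.fixed_effects["estimate"].to_numpy(), r_fe, atol=2e-4
        )


class TestPosthocPairwise:
    def test_exchangeable_groups_flat_interaction(self):
        spec = {
            (g, f"{g}{i}", b): PATTERN
            for g in ("A", "B")
            for i in range(3)
            for b in ("plus", "minus")
        }
        res = cstats.posthoc_pairwise(_cell_log(spec), ("A", "B"))
        assert res.f_interaction == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_bonferroni_threshold_arithmetic(self, labeled_cohort):
        res = cstats.posthoc_pairwise(labeled_cohort, ("TD", "ASD"), n_comparisons=3)
        assert res.threshold == pytest.approx(0.05 / 3)

    def test_order_symmetry(self, labeled_cohort):
        ab = cstats.posthoc_pairwise(labeled_cohort, ("TD", "ASD"))
        ba = cstats.posthoc_pairwise(labeled_cohort, ("ASD", "TD"))
        assert ab.f_interaction == pytest.approx(ba.f_interaction, rel=1e-9)

    def test_unknown_group_rejected(self, labeled_cohort):
        with pytest.raises(InputError):
            cstats.posthoc_pairwise(labeled_cohort, ("TD", "NOPE"))


class TestWithinGroupAndEffectSize:
    def test_within_group_runs(self, labeled_cohort):
        fit = cstats.within_group_trialtype_test(labeled_cohort, "TD")
        assert list(fit.anova["term"]) == ["C(bias)"]
        assert 0 <= fit.anova.iloc[0]["p"] <= 1

    def test_symmetric_diffs_give_zero_d(self):
        spec = {
            ("A", "A1", "plus"): [1] * 6 + [0] * 4,  # 0.6
            ("A", "A1", "minus"): [1] * 5 + [0] * 5,  # 0.5 -> diff +0.1
            ("A", "A2", "plus"): [1] * 5 + [0] * 5,
            ("A", "A2", "minus"): [1] * 6 + [0] * 4,  # diff -0.1
        }
        d = cstats.cohens_d_trialtype(_cell_log(spec), "A")
        assert d.cohens_d == pytest.approx(0.0, abs=1e-12)
        assert d.n == 2

    def test_zero_spread_d_undefined(self):
        spec = {
            ("A", f"A{i}", b): ([1] * 6 + [0] * 4 if b == "plus" else [1] * 5 + [0] * 5)
            for i in range(3)
            for b in ("plus", "minus")
        }
        with pytest.raises(StatsError, match="SD"):
            cstats.cohens_d_trialtype(_cell_log(spec), "A")


class TestRTSummary:
    def test_two_subject_arithmetic(self):
        spec = {
            ("A", "A1", b): PATTERN for b in ("plus", "minus")
        } | {("A", "A2", b): PATTERN for b in ("plus", "minus")}
        log = _cell_log(spec)
        log.loc[log["subject_id"] == "A1", "rt_ms"] = 900.0
        log.loc[log["subject_id"] == "A2", "rt_ms"] = 1000.0
        rt = cstats.rt_summary(log)
        row = rt.by_group.iloc[0]
        assert row["mean_ms"] == pytest.approx(950.0)
        assert row["sem_ms"] == pytest.approx(50.0)

    def test_constant_rt_zero_sem_no_model(self):
        spec = {
            ("A", f"A{i}", b): PATTERN for i in range(3) for b in ("plus", "minus")
        }
        rt = cstats.rt_summary(_cell_log(spec))  # rt constant at 900
        assert rt.by_group["sem_ms"].iloc[0] == 0.0
        assert rt.fit is None  # no RT variability to model

    def test_missing_rts_counted(self, labeled_cohort):
        df = labeled_cohort.copy()
        df.loc[df.index[:50], "rt_ms"] = np.nan
        rt = cstats.rt_summary(df)
        assert rt.n_dropped_missing == 50

    def test_group_rt_model_fits(self, labeled_cohort):
        rt = cstats.rt_summary(labeled_cohort)
        assert rt.fit is not None
        assert any(":" in t for t in rt.fit.anova["term"])


class TestPower:
    def test_null_power_equals_alpha(self):
        power, se = cstats.power_by_simulation(0.0, 18, n_reps=2000, seed=0)
        assert abs(power - 0.05) < 3 * max(se, 0.005)

    def test_huge_effect_saturates(self):
        power, _ = cstats.power_by_simulation(3.0, 18, n_reps=500, seed=0)
        assert power == 1.0

    def test_minimal_detectable_d_bracket(self):
        """At n=18, the smallest paired effect with 80% power sits near
        the conventional closed-form value ~0.70."""
        d = cstats.minimal_detectable_d(18, n_reps=800, seed=1, tol=0.02)
        assert 0.55 < d < 0.85

    def test_n_reps_floor(self):
        with pytest.raises(InputError):
            cstats.power_by_simulation(0.5, 18, n_reps=10)
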