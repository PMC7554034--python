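import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from contrabias.design import TaskConfig, TrialRecord, generate_session
from contrabias.errors import ConfigError, InputError
from contrabias.observer import (
    GROUP_PARAMS,
    ObserverParams,
    ObserverState,
    default_cohort,
    psychometric_prediction,
    simulate_batch,
    simulate_cohort,
    simulate_response,
)
from contrabias.recovery import simulate_moments


def _trial(f1, d, idx=1):
    return TrialRecord(
        subject_id="S",
        group="TD",
        block_index=1,
        trial_index=idx,
        f1_hz=f1,
        f2_hz=f1 * (1 + d / 100.0),
        diff_percent=d,
        truth="same" if d == 0 else "different",
    )


NOISELESS = dict(sigma_encoding=0.0, gamma_lapse=0.0)


class TestObserverParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_contraction": 1.2},
            {"sigma_encoding": -0.1},
            {"gamma_lapse": -0.01},
            {"eta_history": 0.0},
            {"criterion": -1.0},
            {"decision_rule": "bogus"},
            {"rt_model": ("lognormal", 6.8)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ObserverParams(**kwargs)


class TestSimulateResponse:
    def test_noiseless_unbiased_observer_is_veridical_on_same(self):
        p = ObserverParams(lambda_contraction=0.0, **NOISELESS)
        rng = np.random.default_rng(0)
        resp, _ = simulate_response(p, _trial(1000.0, 0.0), ObserverState(), rng)
        assert resp == "same"

    def test_noiseless_observer_exceeds_bound_on_3pct(self):
        p = ObserverParams(
            lambda_contraction=0.0, criterion=math.log(1.01) / 2, **NOISELESS
        )
        rng = np.random.default_rng(0)
        resp, _ = simulate_response(p, _trial(1000.0, 3.0), ObserverState(), rng)
        assert resp == "different"

    def test_contraction_turns_same_into_different(self):
        """Closed form: prev (1500,1500), current same (1000,1000), lam=0.5:
        |x2 - m1| = 0.5*ln(1.5) ~ 0.2027 > c, so the unbiased-correct 'same'
        becomes an erroneous 'different' (the Bias- mechanism)."""
        p = ObserverParams(
            lambda_contraction=0.5, criterion=math.log(1.01) / 2, **NOISELESS
        )
        rng = np.random.default_rng(0)
        state = ObserverState()
        _, state = simulate_response(p, _trial(1500.0, 0.0, 1), state, rng)
        assert state.attractor == pytest.approx(math.log(1500.0))
        resp, state = simulate_response(p, _trial(1000.0, 0.0, 2), state, rng)
        assert resp == "different"
        assert state.trial_count == 2

    def test_attractor_update_recency_weight(self):
        p = ObserverParams(eta_history=0.5, **NOISELESS)
        state = ObserverState()
        rng = np.random.default_rng(0)
        _, state = simulate_response(p, _trial(1000.0, 0.0, 1), state, rng)
        _, state = simulate_response(p, _trial(500.0, 0.0, 2), state, rng)
        want = 0.5 * math.log(1000.0) + 0.5 * math.log(500.0)
        assert state.attractor == pytest.approx(want)

    def test_nonpositive_frequency_rejected(self):
        p = ObserverParams()
        bad = _trial(1000.0, 0.0)
        bad.f1_hz = -5.0
        with pytest.raises(InputError):
            simulate_response(p, bad, ObserverState(), np.random.default_rng(0))

    def test_batch_matches_scalar_when_deterministic(self, default_config):
        p = ObserverParams(lambda_contraction=0.4, **NOISELESS)
        design = generate_session(default_config, seed=21)
        state = ObserverState()
        rng = np.random.default_rng(5)
        scalar = []
        for rec in design.records():
            resp, state = simulate_response(p, rec, state, rng)
            scalar.append(resp == "different")
        f1 = design.trials["f1_hz"].to_numpy()[None, :]
        f2 = design.trials["f2_hz"].to_numpy()[None, :]
        batch = simulate_batch(p, f1, f2, np.random.default_rng(5))[0]
        np.testing.assert_array_equal(np.asarray(scalar), batch)


class TestPsychometricPrediction:
    def test_no_contraction_ignores_attractor(self):
        p = ObserverParams(lambda_contraction=0.0)
        vals = {psychometric_prediction(p, 1.0, off) for off in (-0.3, 0.0, 0.5)}
        assert len(vals) == 1

    def test_infinite_bound_suppresses_different(self):
        p = ObserverParams(lambda_contraction=0.0, gamma_lapse=0.0, criterion=10.0)
        assert psychometric_prediction(p, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_sigma_zero_indicator(self):
        p = ObserverParams(lambda_contraction=0.0, sigma_encoding=0.0, gamma_lapse=0.0)
        assert psychometric_prediction(p, 3.0, 0.0) == 1.0
        assert psychometric_prediction(p, 0.0, 0.0) == 0.0

    def test_quadrature_oracle_and_monte_carlo_agree(self):
        """The closed form equals brute-force double quadrature over the two
        encoding noises and matches >=1e6 Monte-Carlo draws."""
        lam, sig, c = 0.3, 0.012, math.log(1.01) / 2
        p = ObserverParams(
            lambda_contraction=lam, sigma_encoding=sig, gamma_lapse=0.0, criterion=c
        )
        offset = -math.log(1.03)  # attractor 3% below the first tone
        diff = 1.0
        closed = psychometric_prediction(p, diff, offset)

        delta = math.log(1 + diff / 100.0)

        def integrand(e2, e1):
            m1 = (1 - lam) * e1 + lam * offset  # relative to u1
            x2 = delta + e2
            return (
                (abs(x2 - m1) > c)
                * norm.pdf(e1, scale=sig)
                * norm.pdf(e2, scale=sig)
            )

        quad, _ = integrate.dblquad(
            integrand, -8 * sig, 8 * sig, lambda _: -8 * sig, lambda _: 8 * sig
        )
        assert closed == pytest.approx(quad, abs=1e-4)

        rng = np.random.default_rng(2024)
        n = 1_200_000
        e1 = rng.normal(0, sig, n)
        e2 = rng.normal(0, sig, n)
        mc = np.mean(np.abs(delta + e2 - ((1 - lam) * e1 + lam * offset)) > c)
        assert closed == pytest.approx(mc, abs=3 * math.sqrt(0.25 / n) + 1e-4)

    def test_one_sided_rule_variant(self):
        p2 = ObserverParams(lambda_contraction=0.0)
        p1 = ObserverParams(lambda_contraction=0.0, decision_rule="one_sided")
        # a same trial: the one-sided rule only fires on upward noise
        assert psychometric_prediction(p1, 0.0, 0.0) < psychometric_prediction(
            p2, 0.0, 0.0
        )


class TestLimits:
    def test_vanishing_noise_perfect_accuracy(self):
        p = ObserverParams(
            lambda_contraction=0.0,
            sigma_encoding=0.0,
            gamma_lapse=0.0,
            criterion=math.log(1.01) / 2,  # strictly inside (0, ln 1.01)
        )
        m = simulate_moments(p, n_trials=5000, seed=0)
        assert m.accuracy == 1.0

    def test_pure_lapse_is_chance(self):
        p = ObserverParams(lambda_contraction=0.0, gamma_lapse=1.0)
        m = simulate_moments(p, n_trials=100_000, seed=0)
        assert m.accuracy == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / 100_000))


class TestSimulateCohort:
    def test_row_count_single_subject_single_block(self):
        cfg = TaskConfig(block_diff_percent=(3.0,), trials_per_block=40)
        df = simulate_cohort([("TD", 1, ObserverParams())], config=cfg, seed=0)
        assert len(df) == 40

    def test_group_sizes_match_included_counts(self):
        df = default_cohort(seed=0)
        sizes = df.groupby("group")["subject_id"].nunique()
        assert sizes.to_dict() == {"ASD": 21, "LAD": 21, "TD": 18}
        assert len(df) == 60 * 120

    def test_seed_determinism(self, small_config):
        spec = [("TD", 3, GROUP_PARAMS["TD"])]
        a = simulate_cohort(spec, config=small_config, seed=9)
        b = simulate_cohort(spec, config=small_config, seed=9)
        assert a.equals(b)
        assert not a.equals(simulate_cohort(spec, config=small_config, seed=10))

    def test_rt_model_fills_rts(self, small_config):
        p = ObserverParams(rt_model=("lognormal", 6.8, 0.25))
        df = simulate_cohort([("TD", 2, p)], config=small_config, seed=0)
        assert df["rt_ms"].notna().all()
        assert (df["rt_ms"] > 0).all()
        df2 = simulate_cohort([("TD", 2, ObserverParams())], config=small_config, seed=0)
        assert df2["rt_ms"].isna().all()

    def test_accuracy_in_study_regime(self, default_labeled_cohort):
        """The default cohort lands in the study's regime: overall accuracy
        in the 70s%, ASD-like observers slightly above TD-like."""
        acc = default_labeled_cohort.groupby("group")["correct"].mean()
        assert 0.68 < acc.min() and acc.max() < 0.80
        assert acc["ASD"] > acc["TD"]


class TestSimulatorOracleAgreement:
    def test_response_rates_match_prediction_by_condition(self):
        """Monte-Carlo 'different' rates per (difficulty, attractor offset)
        cell agree with the analytic prediction (two-trial sessions)."""
        p = GROUP_PARAMS["TD"]
        rng = np.random.default_rng(77)
        n = 30_000
        for f1p, f1c, dc in [
            (1000.0, 1000.0, 1.0),
            (1500.0, 1000.0, 0.0),
            (500.0, 1500.0, 3.0),
            (750.0, 1000.0, 2.0),
        ]:
            f2p, f2c = f1p, f1c * (1 + dc / 100.0)
            off = math.log(f1p) - math.log(f1c)
            pred = psychometric_prediction(p, dc, off)
            F1 = np.tile([f1p, f1c], (n, 1))
            F2 = np.tile([f2p, f2c], (n, 1))
            got = simulate_batch(p, F1, F2, rng)[:, 1].mean()
            se = math.sqrt(pred * (1 - pred) / n)
            assert abs(got - pred) < 4 * se + 1e-9, (f1p, f1c, dc)
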