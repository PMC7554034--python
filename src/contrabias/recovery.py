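"""Contraction-strength recovery by simulation-based moment matching.

The observer's likelihood under the two-sided rule with history is
awkward, but two summary moments -- overall accuracy and the
Bias+/Bias- accuracy gap -- respond in complementary ways to the
encoding noise sigma and the contraction weight lambda. Recovery
therefore simulates those moments on a (lambda, sigma) grid with
common random numbers, picks the grid point closest to the observed
moments in squared distance, and refines lambda with a local quadratic
step. Lapse rate and criterion are held at their configured values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bias import BiasLabel, label_arrays
from .design import TaskConfig
from .errors import InputError, NoFitError
from .observer import ObserverParams, simulate_batch

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.6001, 0.05), 4))
DEFAULT_SIGMA_GRID = (0.006, 0.009, 0.012, 0.016, 0.020)


@dataclass(frozen=True)
class Moments:
    """Summary moments of a labeled trial log."""

    accuracy: float
    bias_gap: float  # accuracy(Bias+) - accuracy(Bias-)
    n_trials: int = 0


@dataclass
class RecoveryResult:
    lambda_hat: float
    sigma_hat: float
    objective_value: float
    grid: pd.DataFrame  # lambda, sigma, accuracy, bias_gap, objective
    n_sim_trials: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "lambda_hat": self.lambda_hat,
            "sigma_hat": self.sigma_hat,
            "objective_value": self.objective_value,
            "n_sim_trials": self.n_sim_trials,
            "seed": self.seed,
            "grid": self.grid.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _moments_from_masks(
    correct: np.ndarray, labels: np.ndarray, different_only: bool = False,
    truth_is_diff: Optional[np.ndarray] = None,
) -> Moments:
    labeled = labels != BiasLabel.EXCLUDED.value
    plus = labels == BiasLabel.PLUS.value
    minus = labels == BiasLabel.MINUS.value
    if different_only:
        if truth_is_diff is None:
            raise InputError("different_only requires truth information")
        plus = plus & truth_is_diff
        minus = minus & truth_is_diff
    if plus.sum() == 0:
        raise InputError("no Bias+ trials")
    if minus.sum() == 0:
        raise InputError("no Bias- trials")
    acc = float(correct[labeled].mean())
    gap = float(correct[plus].mean() - correct[minus].mean())
    return Moments(accuracy=acc, bias_gap=gap, n_trials=int(labeled.sum()))


def observed_moments(
    trial_log: pd.DataFrame,
    group: Optional[str] = None,
    subject: Optional[str] = None,
    different_only: bool = False,
) -> Moments:
    """(overall accuracy, Bias+ - Bias- gap) of a labeled trial log.

    Accuracy runs over all labeled (non-excluded) trials; the gap
    contrasts Bias+ against Bias- trials, the latter including same
    trials per the labeling. ``different_only=True`` restricts the gap
    to "different" trials (the observer-property convention).
    """
    df = trial_log
    if group is not None:
        df = df[df["group"] == group]
    if subject is not None:
        df = df[df["subject_id"] == subject]
    df = df[df["response"].isin(["same", "different"])]
    if len(df) == 0:
        raise InputError("no responded trials selected")
    if (df["bias_label"] == "").all():
        raise InputError("trial log is unlabeled; run bias labeling first")
    return _moments_from_masks(
        df["correct"].to_numpy(float),
        df["bias_label"].to_numpy(object),
        different_only=different_only,
        truth_is_diff=(df["truth"] == "different").to_numpy(),
    )


def _batch_design(
    config: TaskConfig, n_sessions: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(f1, f2, truth_is_diff) arrays of shape (n_sessions, n_trials).

    Vectorized equivalent of per-session generation: every block of
    every session is an independent random permutation of the balanced
    (truth x base-frequency) factorial.
    """
    n = config.trials_per_block
    n_same = config.n_same_per_block
    base = np.asarray(config.base_frequencies_hz)
    truth_row = np.zeros(n, dtype=bool)
    truth_row[n_same:] = True  # True = different
    f1_row = np.concatenate([np.resize(base, n_same), np.resize(base, n - n_same)])
    f1_parts, truth_parts, diff_parts = [], [], []
    for d in config.block_diff_percent:
        idx = rng.permuted(np.tile(np.arange(n), (n_sessions, 1)), axis=1)
        truth_parts.append(truth_row[idx])
        f1_parts.append(f1_row[idx])
        diff_parts.append(np.full((n_sessions, n), float(d)))
    truth_is_diff = np.concatenate(truth_parts, axis=1)
    f1 = np.concatenate(f1_parts, axis=1)
    d = np.where(truth_is_diff, np.concatenate(diff_parts, axis=1), 0.0)
    f2 = f1 * (1.0 + d / 100.0)
    return f1, f2, truth_is_diff


def simulate_moments(
    params: ObserverParams,
    config: Optional[TaskConfig] = None,
    n_trials: int = 10**5,
    seed: int = 0,
    different_only: bool = False,
) -> Moments:
    """Monte-Carlo moments of an observer on freshly simulated sessions."""
    config = config or TaskConfig()
    n_sessions = max(1, int(np.ceil(n_trials / config.n_trials)))
    rng = np.random.default_rng(seed)
    f1, f2, truth_is_diff = _batch_design(config, n_sessions, rng)
    labels = label_arrays(f1, f2, truth_is_diff)
    is_diff_resp = simulate_batch(params, f1, f2, rng)
    correct = (is_diff_resp == truth_is_diff).astype(float)
    return _moments_from_masks(
        correct, labels, different_only=different_only, truth_is_diff=truth_is_diff
    )


def fit_lambda_sigma(
    observed: Moments,
    config: Optional[TaskConfig] = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
    n_sim_trials: int = 10**5,
    seed: int = 0,
    base_params: Optional[ObserverParams] = None,
) -> RecoveryResult:
    """Grid-then-refine moment matching for (lambda, sigma).

    Every grid point is simulated with common random numbers (one
    noise draw, rescaled per point), making the whole fit deterministic
    given ``seed``. Raises :class:`NoFitError` when the observed
    moments fall outside the envelope achievable on the grid.
    """
    config = config or TaskConfig()
    base = base_params or ObserverParams()
    if min(lambda_grid) < 0 or max(lambda_grid) > 1:
        raise InputError("lambda_grid must lie within [0, 1]")
    if n_sim_trials < 10**4:
        raise InputError("n_sim_trials must be >= 10^4 per grid point")

    n_sessions = max(1, int(np.ceil(n_sim_trials / config.n_trials)))
    rng = np.random.default_rng(seed)
    f1, f2, truth_is_diff = _batch_design(config, n_sessions, rng)
    labels = label_arrays(f1, f2, truth_is_diff)
    shape = f1.shape
    noise = (
        rng.standard_normal(shape),
        rng.standard_normal(shape),
        rng.random(shape),
        rng.random(shape),
    )

    def point(lam: float, sig: float) -> Moments:
        p = dataclasses.replace(base, lambda_contraction=lam, sigma_encoding=sig)
        resp = simulate_batch(p, f1, f2, rng, noise=noise)
        correct = (resp == truth_is_diff).astype(float)
        return _moments_from_masks(correct, labels)

    rows = []
    for sig in sigma_grid:
        for lam in lambda_grid:
            m = point(lam, sig)
            obj = (m.accuracy - observed.accuracy) ** 2 + (m.bias_gap - observed.bias_gap) ** 2
            rows.append(
                {
                    "lambda": lam,
                    "sigma": sig,
                    "accuracy": m.accuracy,
                    "bias_gap": m.bias_gap,
                    "objective": obj,
                }
            )
    grid = pd.DataFrame(rows)

    gmin, gmax = grid["bias_gap"].min(), grid["bias_gap"].max()
    amin, amax = grid["accuracy"].min(), grid["accuracy"].max()
    if not (gmin <= observed.bias_gap <= gmax) or not (amin <= observed.accuracy <= amax):
        raise NoFitError(
            "observed moments outside the achievable envelope",
            envelope={"bias_gap": (gmin, gmax), "accuracy": (amin, amax)},
        )

    best = grid.loc[grid["objective"].idxmin()]
    lam_hat, sig_hat = float(best["lambda"]), float(best["sigma"])

    # local quadratic refinement on lambda at the best sigma
    lams = sorted(lambda_grid)
    i = lams.index(lam_hat)
    if 0 < i < len(lams) - 1:
        sub = grid[grid["sigma"] == sig_hat].set_index("lambda")["objective"]
        x = np.array([lams[i - 1], lams[i], lams[i + 1]])
        y = sub.loc[x].to_numpy()
        denom = (y[0] - 2 * y[1] + y[2])
        if denom > 0:
            vertex = x[1] + 0.5 * (x[1] - x[0]) * (y[0] - y[2]) / denom
            lam_hat = float(np.clip(vertex, x[0], x[2]))

    final = point(lam_hat, sig_hat)
    obj = (final.accuracy - observed.accuracy) ** 2 + (final.bias_gap - observed.bias_gap) ** 2
    return RecoveryResult(
        lambda_hat=lam_hat,
        sigma_hat=sig_hat,
        objective_value=float(obj),
        grid=grid,
        n_sim_trials=n_sessions * config.n_trials,
        seed=seed,
    )
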