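"""Bias+/Bias- trial classification from the preceding trial.

A trial is Bias+ when contraction of the first-tone memory toward the
previous trial's stimuli stretches the perceived within-pair difference
(aiding a correct "different" response) and Bias- when it shrinks it.
All physically identical ("same") pairs are Bias-: any contraction of
the first tone away from the second creates a spurious perceived
difference and so hurts the correct "same" judgment.

The previous trial's pair is summarized by its log-mean attractor
A = (ln f1_prev + ln f2_prev) / 2; since the pair differs by at most a
few percent, A is a faithful one-number stand-in for "the tones of the
preceding trial". Classification then only compares A with the current
first tone u1 = ln f1 (the design guarantees f2 >= f1):

    same trial                -> Bias-
    different, A < u1 - tol   -> Bias+   (attractor beyond f1, stretches)
    different, A > u1 + tol   -> Bias-   (attractor above f1, shrinks)
    |A - u1| <= tol           -> Neutral (degenerate: no direction)

A strict variant requiring both previous tones to sit on one side of f1
is available via ``strict_flanking=True``.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

import numpy as np
import pandas as pd

from .design import TrialRecord
from .errors import InputError

#: Log-unit tolerance below which the attractor is "at" the first tone.
TOL = 1e-9


class BiasLabel(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"
    NEUTRAL = "neutral"
    EXCLUDED = "excluded"  # no predecessor (first trial of a session)

    def __str__(self) -> str:  # serialize as the bare value
        return self.value


def classify_trial(
    prev: TrialRecord,
    current: TrialRecord,
    tol: float = TOL,
    strict_flanking: bool = False,
) -> BiasLabel:
    """Classify ``current`` given its immediate predecessor ``prev``."""
    if prev.subject_id != current.subject_id:
        raise InputError("prev and current must belong to the same session")
    if current.trial_index != prev.trial_index + 1:
        raise InputError("prev must immediately precede current")
    return _classify(
        prev.f1_hz, prev.f2_hz, current.f1_hz, current.f2_hz, current.truth,
        tol=tol, strict_flanking=strict_flanking,
    )


def _classify(
    f1_prev: float,
    f2_prev: float,
    f1: float,
    f2: float,
    truth: str,
    tol: float = TOL,
    strict_flanking: bool = False,
) -> BiasLabel:
    if min(f1_prev, f2_prev, f1, f2) <= 0:
        raise InputError("tone frequencies must be positive")
    if truth == "same":
        return BiasLabel.MINUS
    u1 = math.log(f1)
    if strict_flanking:
        lo, hi = math.log(min(f1_prev, f2_prev)), math.log(max(f1_prev, f2_prev))
        if hi < u1 - tol:
            return BiasLabel.PLUS
        if lo > u1 + tol:
            return BiasLabel.MINUS
        return BiasLabel.NEUTRAL
    a = 0.5 * (math.log(f1_prev) + math.log(f2_prev))
    if a < u1 - tol:
        return BiasLabel.PLUS
    if a > u1 + tol:
        return BiasLabel.MINUS
    return BiasLabel.NEUTRAL


def label_arrays(
    f1: np.ndarray,
    f2: np.ndarray,
    truth_is_diff: np.ndarray,
    tol: float = TOL,
    first_of_session: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Vectorized labeling along axis -1 of (sessions x trials) arrays.

    Returns an object array of bare label strings. ``first_of_session``
    marks positions labeled "excluded" (default: column 0).
    """
    u1 = np.log(f1)
    a = np.empty_like(u1)
    a[..., 0] = np.nan
    a[..., 1:] = 0.5 * (u1[..., :-1] + np.log(f2)[..., :-1])
    labels = np.full(u1.shape, BiasLabel.MINUS.value, dtype=object)
    is_diff = truth_is_diff.astype(bool)
    plus = is_diff & (a < u1 - tol)
    neutral = is_diff & (np.abs(a - u1) <= tol)
    labels[plus] = BiasLabel.PLUS.value
    labels[neutral] = BiasLabel.NEUTRAL.value
    if first_of_session is None:
        labels[..., 0] = BiasLabel.EXCLUDED.value
    else:
        labels[first_of_session] = BiasLabel.EXCLUDED.value
    return labels


def label_session(
    trials: pd.DataFrame,
    tol: float = TOL,
    strict_flanking: bool = False,
    reset_per_block: bool = False,
) -> pd.DataFrame:
    """Label one session's trials; returns a copy with ``bias_label`` set.

    The first trial has no predecessor and is labeled "excluded". By
    default the predecessor crosses block boundaries (blocks ran
    back-to-back); ``reset_per_block=True`` also excludes the first
    trial of every block. Idempotent: labels depend only on stimuli.
    """
    if trials["subject_id"].nunique() > 1:
        raise InputError("label_session expects a single session")
    idx = trials["trial_index"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise InputError("duplicate trial indices")
    order = np.argsort(idx)
    idx_sorted = idx[order]
    if not np.array_equal(idx_sorted, np.arange(idx_sorted[0], idx_sorted[0] + len(idx))):
        raise InputError("non-contiguous trial indices")

    df = trials.iloc[order].copy()
    records = list(df.itertuples(index=False))
    labels = [BiasLabel.EXCLUDED.value]
    for prev, cur in zip(records[:-1], records[1:]):
        if reset_per_block and cur.block_index != prev.block_index:
            labels.append(BiasLabel.EXCLUDED.value)
            continue
        lab = _classify(
            prev.f1_hz, prev.f2_hz, cur.f1_hz, cur.f2_hz, cur.truth,
            tol=tol, strict_flanking=strict_flanking,
        )
        labels.append(lab.value)
    df["bias_label"] = labels
    return df


def label_cohort(trial_log: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Label every subject's session in a cohort trial log."""
    parts = [
        label_session(g, **kwargs) for _, g in trial_log.groupby("subject_id", sort=False)
    ]
    return pd.concat(parts, ignore_index=True)
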