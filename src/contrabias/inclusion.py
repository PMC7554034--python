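"""Above-chance participant inclusion and its binomial rationale.

Participants are retained only when their accuracy in the physically
easiest condition (the block with the largest frequency difference)
strictly exceeds a threshold, 60% by default -- a cutoff justified by
the tail probability of a fair-coin binomial: a guessing participant
rarely clears it. A 50% robustness variant is exposed through the same
``threshold`` argument.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InputError


def binomial_chance_tail(n_trials: int, k_correct: int) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, 1/2), by integer summation."""
    n, k = int(n_trials), int(k_correct)
    if n <= 0:
        raise InputError("n_trials must be positive")
    if not 0 <= k <= n:
        raise InputError("k_correct must lie in [0, n_trials]")
    total = sum(math.comb(n, i) for i in range(k, n + 1))
    return total / 2**n


def _easiest_block(trials: pd.DataFrame) -> int:
    diff = trials[trials["truth"] == "different"]
    if len(diff) == 0:
        raise InputError("no different-trials; cannot identify the easiest condition")
    hardest = diff.groupby("block_index")["diff_percent"].max()
    return int(hardest.idxmax())


def easiest_condition_accuracy(
    subject_trials: pd.DataFrame,
    n_trials: Optional[int] = None,
    count_missing_as_incorrect: bool = False,
) -> float:
    """Fraction correct in the easiest (largest-difference) block.

    By default the whole block counts (40 trials under the default
    design); ``n_trials`` restricts to the block's first n trials.
    Trials without a response are dropped unless
    ``count_missing_as_incorrect`` is set.
    """
    block = _easiest_block(subject_trials)
    blk = subject_trials[subject_trials["block_index"] == block].sort_values("trial_index")
    if n_trials is not None:
        blk = blk.head(n_trials)
    responded = blk["response"].isin(["same", "different"])
    if count_missing_as_incorrect:
        vals = blk["correct"].fillna(0.0).astype(float)
    else:
        vals = blk.loc[responded, "correct"].astype(float)
    if len(vals) == 0:
        raise InputError("no qualifying trials in the easiest condition")
    return float(vals.mean())


def apply_inclusion(
    trial_log: pd.DataFrame,
    threshold: float = 0.60,
    n_trials: Optional[int] = None,
    count_missing_as_incorrect: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Retain subjects with easiest-condition accuracy strictly > threshold.

    Returns (included trial log, per-subject report). The report lists,
    for every subject: group, the number of qualifying trials, correct
    count, accuracy, and the decision -- plus group-wise inclusion
    fractions are easily derived from it for parity checks.
    """
    rows = []
    for sid, g in trial_log.groupby("subject_id", sort=False):
        block = _easiest_block(g)
        blk = g[g["block_index"] == block].sort_values("trial_index")
        if n_trials is not None:
            blk = blk.head(n_trials)
        acc = easiest_condition_accuracy(
            g, n_trials=n_trials, count_missing_as_incorrect=count_missing_as_incorrect
        )
        rows.append(
            {
                "subject_id": sid,
                "group": g["group"].iloc[0],
                "n_trials": len(blk),
                "n_correct": int(blk["correct"].fillna(0).sum()),
                "accuracy": acc,
                "included": acc > threshold,
            }
        )
    report = pd.DataFrame(rows)
    keep = set(report.loc[report["included"], "subject_id"])
    included = trial_log[trial_log["subject_id"].isin(keep)].reset_index(drop=True)
    return included, report


def inclusion_fractions(report: pd.DataFrame) -> pd.Series:
    """Group-wise fraction of subjects passing the filter."""
    return report.groupby("group")["included"].mean()
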