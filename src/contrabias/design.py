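"""Two-tone same/different task design: generation and validation.

The task presents, on every trial, two brief pure tones; the listener
judges whether their frequencies are identical. A session is organised
in blocks ordered by increasing difficulty (decreasing frequency
difference on "different" trials), with the first-tone base frequency
drawn from a small fixed set and half the trials in every block being
physically identical pairs.

Trial logs are carried as :class:`pandas.DataFrame` objects in a fixed
column schema (:data:`TRIAL_LOG_COLUMNS`); :class:`TrialRecord` is the
scalar view of one row used by the per-trial APIs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

#: Column order of the CSV trial-log schema. Missing response/rt are
#: encoded as empty fields on disk and as NaN/"" in memory.
TRIAL_LOG_COLUMNS = [
    "subject_id",
    "group",
    "block_index",
    "trial_index",
    "f1_hz",
    "f2_hz",
    "diff_percent",
    "truth",
    "response",
    "correct",
    "rt_ms",
    "bias_label",
]

#: Relative tolerance for the f2 = f1 * (1 + diff/100) closure check.
F2_RELTOL = 1e-12


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-tone discrimination session.

    Defaults reproduce the canonical design: 120 trials in three
    40-trial blocks at 3%, 2% and 1% frequency difference, four base
    frequencies, and a 50/50 same:different split per block.
    """

    base_frequencies_hz: tuple = (500.0, 750.0, 1000.0, 1500.0)
    block_diff_percent: tuple = (3.0, 2.0, 1.0)
    trials_per_block: int = 40
    same_fraction: float = 0.5
    tone_duration_ms: float = 100.0
    inter_tone_interval_ms: float = 1000.0
    inter_trial_interval_ms: float = 500.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "base_frequencies_hz", tuple(float(f) for f in self.base_frequencies_hz)
        )
        object.__setattr__(
            self, "block_diff_percent", tuple(float(d) for d in self.block_diff_percent)
        )
        if not self.base_frequencies_hz or any(f <= 0 for f in self.base_frequencies_hz):
            raise ConfigError("base_frequencies_hz must be non-empty and positive")
        if not self.block_diff_percent or any(d <= 0 for d in self.block_diff_percent):
            raise ConfigError("block_diff_percent must be non-empty and positive")
        if list(self.block_diff_percent) != sorted(self.block_diff_percent, reverse=True) or len(
            set(self.block_diff_percent)
        ) != len(self.block_diff_percent):
            raise ConfigError(
                "block_diff_percent must be strictly decreasing "
                "(blocks ordered by increasing difficulty)"
            )
        if self.trials_per_block <= 0:
            raise ConfigError("trials_per_block must be positive")
        if not 0.0 <= self.same_fraction <= 1.0:
            raise ConfigError("same_fraction must lie in [0, 1]")
        n_same = self.same_fraction * self.trials_per_block
        if abs(n_same - round(n_same)) > 1e-9:
            raise ConfigError(
                f"same_fraction * trials_per_block = {n_same} is not an integer; "
                "blocks cannot be balanced"
            )
        for name in ("tone_duration_ms", "inter_tone_interval_ms", "inter_trial_interval_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def n_blocks(self) -> int:
        return len(self.block_diff_percent)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_same_per_block(self) -> int:
        return round(self.same_fraction * self.trials_per_block)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_frequencies_hz"] = list(self.base_frequencies_hz)
        d["block_diff_percent"] = list(self.block_diff_percent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown TaskConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrialRecord:
    """Scalar view of one trial-log row."""

    subject_id: str
    group: str
    block_index: int
    trial_index: int
    f1_hz: float
    f2_hz: float
    diff_percent: float
    truth: str
    response: Optional[str] = None
    correct: Optional[bool] = None
    rt_ms: Optional[float] = None
    bias_label: Optional[str] = None


@dataclass
class SessionDesign:
    """One subject's ordered trial sequence before responses."""

    config: TaskConfig
    trials: pd.DataFrame

    def __len__(self) -> int:
        return len(self.trials)

    def records(self) -> Iterable[TrialRecord]:
        for row in self.trials.itertuples(index=False):
            yield TrialRecord(
                subject_id=row.subject_id,
                group=row.group,
                block_index=int(row.block_index),
                trial_index=int(row.trial_index),
                f1_hz=float(row.f1_hz),
                f2_hz=float(row.f2_hz),
                diff_percent=float(row.diff_percent),
                truth=row.truth,
            )


def _spread(values: Sequence[float], n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws from ``values`` with counts as equal as possible (balanced cells)."""
    reps = np.resize(np.asarray(values, dtype=float), n)
    return rng.permutation(reps)


def _block_frame(
    config: TaskConfig,
    diff_percent: float,
    rng: np.random.Generator,
    iid_frequencies: bool,
) -> pd.DataFrame:
    n = config.trials_per_block
    n_same = config.n_same_per_block
    truth = np.array(["same"] * n_same + ["different"] * (n - n_same), dtype=object)
    if iid_frequencies:
        f1 = rng.choice(np.asarray(config.base_frequencies_hz), size=n)
    else:
        # balanced factorial: frequencies spread evenly within each truth level
        f1 = np.concatenate(
            [
                _spread(config.base_frequencies_hz, n_same, rng),
                _spread(config.base_frequencies_hz, n - n_same, rng),
            ]
        )
    order = rng.permutation(n)
    truth, f1 = truth[order], f1[order]
    d = np.where(truth == "different", float(diff_percent), 0.0)
    f2 = f1 * (1.0 + d / 100.0)
    return pd.DataFrame(
        {"f1_hz": f1, "f2_hz": f2, "diff_percent": d, "truth": truth}
    )


def _assemble(
    config: TaskConfig,
    blocks: Sequence[pd.DataFrame],
    subject_id: str,
    group: str,
    block_indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    frames = []
    offset = 0
    for k, blk in enumerate(blocks):
        blk = blk.copy()
        blk.insert(0, "subject_id", subject_id)
        blk.insert(1, "group", group)
        blk.insert(2, "block_index", block_indices[k] if block_indices else k + 1)
        blk.insert(3, "trial_index", np.arange(offset + 1, offset + 1 + len(blk)))
        offset += len(blk)
        frames.append(blk)
    df = pd.concat(frames, ignore_index=True)
    df["response"] = ""
    df["correct"] = np.nan
    df["rt_ms"] = np.nan
    df["bias_label"] = ""
    return df[TRIAL_LOG_COLUMNS]


def generate_session(
    config: TaskConfig,
    subject_id: str = "S01",
    group: str = "TD",
    seed: Optional[int] = None,
    iid_frequencies: bool = False,
) -> SessionDesign:
    """Generate one session: blocks in decreasing-difference order.

    Within each block the (truth, f1) sequence is a seeded random
    permutation of a balanced factorial (each base frequency appears
    equally often within each truth level); pass ``iid_frequencies=True``
    for independent sampling of f1 instead. Deterministic for a fixed
    seed (``config.seed`` unless overridden).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    blocks = [
        _block_frame(config, d, rng, iid_frequencies) for d in config.block_diff_percent
    ]
    return SessionDesign(config, _assemble(config, blocks, subject_id, group))


def generate_training_block(
    config: TaskConfig,
    subject_id: str = "S01",
    group: str = "TD",
    seed: Optional[int] = None,
    n_trials: int = 16,
    diff_levels: tuple = (4.0, 1.0),
    same_fraction: float = 0.0,
) -> SessionDesign:
    """Generate the feedback training block: 16 trials, 8 at 4% and 8 at 1%.

    All training trials are "different" trials by default (the level
    counts refer to trials actually carrying that frequency difference);
    ``same_fraction`` > 0 swaps that fraction of each level's trials for
    physically identical pairs while keeping the level assignment of the
    remainder.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    per_level = n_trials // len(diff_levels)
    frames = []
    for level in diff_levels:
        n_same = round(same_fraction * per_level)
        truth = np.array(["same"] * n_same + ["different"] * (per_level - n_same), dtype=object)
        f1 = _spread(config.base_frequencies_hz, per_level, rng)
        d = np.where(truth == "different", float(level), 0.0)
        frames.append(
            pd.DataFrame(
                {"f1_hz": f1, "f2_hz": f1 * (1 + d / 100.0), "diff_percent": d, "truth": truth}
            )
        )
    merged = pd.concat(frames, ignore_index=True)
    merged = merged.iloc[rng.permutation(len(merged))].reset_index(drop=True)
    return SessionDesign(config, _assemble(config, [merged], subject_id, group, block_indices=[0]))


def training_passed(n_correct: int, n_trials: int = 16, threshold: float = 0.75) -> bool:
    """Repeat-until criterion for the training block (75% accuracy meets it)."""
    if not 0 <= n_correct <= n_trials:
        raise InputError("n_correct out of range")
    return n_correct / n_trials >= threshold


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str


@dataclass
class ValidationReport:
    checks: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append(ValidationCheck(name, bool(passed), detail))

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            lines.append(f"[{'PASS' if c.passed else 'FAIL'}] {c.name}: {c.detail}")
        return "\n".join(lines)


def validate_session(design: SessionDesign) -> ValidationReport:
    """Check a session against the design invariants; never raises."""
    cfg, df = design.config, design.trials
    rep = ValidationReport()

    expected_len = cfg.n_trials
    rep.add("length", len(df) == expected_len, f"{len(df)} trials, expected {expected_len}")

    if len(df) == 0:
        return rep

    balanced = True
    details = []
    for k, d in enumerate(cfg.block_diff_percent, start=1):
        blk = df[df["block_index"] == k]
        n_same = int((blk["truth"] == "same").sum())
        want = cfg.n_same_per_block
        ok = len(blk) == cfg.trials_per_block and n_same == want
        balanced &= ok
        details.append(f"block {k}: {n_same}/{len(blk)} same")
    rep.add("block_balance", balanced, "; ".join(details))

    diffs_ok = True
    for k, d in enumerate(cfg.block_diff_percent, start=1):
        blk = df[(df["block_index"] == k) & (df["truth"] == "different")]
        diffs_ok &= bool(np.all(np.isclose(blk["diff_percent"], d)))
    rep.add("block_differences", diffs_ok, f"different-trial levels {cfg.block_diff_percent}")

    same_zero = bool(np.all((df["truth"] == "same") == (df["diff_percent"] == 0)))
    rep.add("truth_diff_consistency", same_zero, "truth == same iff diff_percent == 0")

    f2_expected = df["f1_hz"] * (1 + df["diff_percent"] / 100.0)
    closure = bool(np.allclose(df["f2_hz"], f2_expected, rtol=F2_RELTOL, atol=0))
    rep.add("frequency_closure", closure, "f2 = f1 * (1 + diff/100)")

    member = bool(df["f1_hz"].isin(cfg.base_frequencies_hz).all())
    rep.add("f1_membership", member, f"f1 in {cfg.base_frequencies_hz}")

    contiguous = bool((df["trial_index"].to_numpy() == np.arange(1, len(df) + 1)).all())
    rep.add("trial_index_contiguity", contiguous, "1..N in order")

    return rep
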