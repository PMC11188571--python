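"""Trial-level behavioral data model, file I/O, and preprocessing.

A :class:`SessionLog` is an ordered sequence of :class:`TrialRecord`
objects concatenated across sessions for one animal (real or synthetic),
together with the task it was collected under. Preprocessing follows the
behavioral-analysis conventions of the paradigm: early-pull trials are
dropped from all modelling, each session is truncated at the trial before
60% of the planned reward was collected, and choice is summarised per
tone as a lever-pull rate or a 10-trial moving average.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "SessionLog",
    "TrialValidationError",
    "UndefinedRateError",
    "read_trials",
    "write_trials",
    "exclude_early_pulls",
    "truncate_at_reward_fraction",
    "lever_pull_rate",
    "moving_average_choice",
    "per_tone_moving_average",
    "threshold_sessions_met",
]

FIELD_NAMES = ("trial_index", "session_id", "tone", "action",
               "reward", "punishment", "early_pull")

TONES = ("A", "B")
ACTIONS = ("pull", "non_pull")


class TrialValidationError(ValueError):
    """A trial record violates the data-model invariants."""


class UndefinedRateError(ValueError):
    """A rate was requested over an empty set of trials."""


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    ``reward`` and ``punishment`` are the *physical* events (water drop,
    air-puff). An animal that does not pull receives neither, so
    ``action == "non_pull"`` forces both to 0. ``early_pull`` marks
    trials where the lever moved before the response window; such trials
    are excluded from all analysis and modelling.
    """

    trial_index: int
    session_id: int
    tone: str
    action: str
    reward: int
    punishment: int
    early_pull: bool = False

    def __post_init__(self) -> None:
        if self.trial_index < 0 or self.session_id < 0:
            raise TrialValidationError(
                f"trial_index/session_id must be >= 0 "
                f"(got {self.trial_index}, {self.session_id})")
        if self.tone not in TONES:
            raise TrialValidationError(f"tone must be one of {TONES}, "
                                       f"got {self.tone!r}")
        if self.action not in ACTIONS:
            raise TrialValidationError(f"action must be one of {ACTIONS}, "
                                       f"got {self.action!r}")
        if self.reward not in (0, 1) or self.punishment not in (0, 1):
            raise TrialValidationError("reward and punishment must be 0/1")
        if self.action == "non_pull" and (self.reward or self.punishment):
            raise TrialValidationError(
                "non_pull trials cannot carry a reward or punishment")


@dataclass
class SessionLog:
    """Ordered trials for one animal under one task.

    Invariants: ``trial_index`` strictly increasing and ``session_id``
    non-decreasing across the sequence.
    """

    trials: list[TrialRecord] = field(default_factory=list)
    task_label: str = "air_puff"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_idx, prev_sess = -1, 0
        for rec in self.trials:
            if rec.trial_index <= prev_idx:
                raise TrialValidationError(
                    f"trial_index not strictly increasing at "
                    f"{rec.trial_index}")
            if rec.session_id < prev_sess:
                raise TrialValidationError(
                    f"session_id decreases at trial {rec.trial_index}")
            prev_idx, prev_sess = rec.trial_index, rec.session_id

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def session_ids(self) -> list[int]:
        return sorted({t.session_id for t in self.trials})

    def session(self, sid: int) -> "SessionLog":
        return SessionLog([t for t in self.trials if t.session_id == sid],
                          self.task_label)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(t) for t in self.trials],
                          columns=list(FIELD_NAMES))
        if len(df):
            df["early_pull"] = df["early_pull"].astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, task_label: str) -> "SessionLog":
        missing = set(FIELD_NAMES) - set(df.columns)
        if missing:
            raise TrialValidationError(
                f"missing columns: {sorted(missing)}")
        trials = []
        for pos, row in enumerate(df.itertuples(index=False)):
            try:
                trials.append(TrialRecord(
                    trial_index=int(row.trial_index),
                    session_id=int(row.session_id),
                    tone=str(row.tone),
                    action=str(row.action),
                    reward=int(row.reward),
                    punishment=int(row.punishment),
                    early_pull=bool(int(row.early_pull)),
                ))
            except (TrialValidationError, TypeError, ValueError) as exc:
                raise TrialValidationError(
                    f"row {pos + 2} (1-based, after header): {exc}") from exc
        return cls(trials, task_label)


def read_trials(path: str | Path, format: str | None = None,
                task_label: str = "air_puff") -> SessionLog:
    """Read a trial log from CSV or JSON.

    The CSV dialect is comma-separated UTF-8 with a header row naming the
    ``TrialRecord`` fields exactly; booleans are written as 0/1. The JSON
    mirror is ``{"task_label": ..., "trials": [{field: value, ...}, ...]}``.
    Malformed rows raise :class:`TrialValidationError` naming the line.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise TrialValidationError(f"{path}: no header row") from exc
        return SessionLog.from_frame(df, task_label)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["trials"], columns=list(FIELD_NAMES))
        return SessionLog.from_frame(df,
                                     payload.get("task_label", task_label))
    raise ValueError(f"unknown format {fmt!r}")


def write_trials(log: SessionLog, path: str | Path,
                 format: str | None = None) -> None:
    """Write a trial log as CSV or JSON (round-trips with read_trials)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        log.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        payload = {"task_label": log.task_label,
                   "trials": [asdict(t) | {"early_pull": int(t.early_pull)}
                              for t in log.trials]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def exclude_early_pulls(log: SessionLog) -> SessionLog:
    """Drop early-pull trials; order preserved. Idempotent."""
    return SessionLog([t for t in log.trials if not t.early_pull],
                      log.task_label)


def truncate_at_reward_fraction(log: SessionLog, planned_rewards: int,
                                fraction: float = 0.6) -> SessionLog:
    """Truncate each session where the reward-fraction criterion is hit.

    Motivation within a session wanes once the animal has collected most
    of its water, so each session is kept only from its first trial to
    the last trial *before* the cumulative rewarded-trial count reaches
    ``ceil(fraction * planned_rewards)``. Sessions that never reach the
    threshold are kept whole.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if planned_rewards <= 0:
        raise ValueError("planned_rewards must be positive")
    threshold = math.ceil(fraction * planned_rewards)
    kept: list[TrialRecord] = []
    for sid in log.session_ids:
        session = [t for t in log.trials if t.session_id == sid]
        cum = 0
        for t in session:
            cum += t.reward
            if cum >= threshold:
                break
            kept.append(t)
        else:
            continue
    # preserve original global order
    kept.sort(key=lambda t: t.trial_index)
    return SessionLog(kept, log.task_label)


def lever_pull_rate(log: SessionLog, tone: str) -> float:
    """Fraction of the tone's non-early trials on which the lever was pulled."""
    trials = [t for t in log.trials if not t.early_pull and t.tone == tone]
    if not trials:
        raise UndefinedRateError(f"no tone-{tone} trials in log")
    return sum(t.action == "pull" for t in trials) / len(trials)


def moving_average_choice(choices: Sequence[int] | np.ndarray,
                          window: int = 10) -> np.ndarray:
    """Trailing moving average of a 0/1 pull-choice sequence.

    Output aligns 1:1 with the input: the first ``window - 1`` entries
    average over the available prefix, later entries over the trailing
    ``window`` trials.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(choices, dtype=float)
    if x.size == 0:
        return x
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


def per_tone_moving_average(log: SessionLog, window: int = 10
                            ) -> dict[str, np.ndarray]:
    """Moving-average pull choice computed separately per tone sequence."""
    out = {}
    for tone in TONES:
        seq = [int(t.action == "pull") for t in log.trials
               if not t.early_pull and t.tone == tone]
        out[tone] = moving_average_choice(seq, window)
    return out


def threshold_sessions_met(per_session_rates: Sequence[tuple[float, float]]
                           ) -> tuple[bool, int | None]:
    """Learning criterion: tone-A rate < 0.5 and tone-B rate > 0.5 on two
    consecutive sessions (strict inequalities).

    Returns ``(True, i)`` with ``i`` the index of the second qualifying
    session, else ``(False, None)``.
    """
    if not per_session_rates:
        raise ValueError("need at least one session")
    prev_ok = False
    for i, (rate_a, rate_b) in enumerate(per_session_rates):
        ok = rate_a < 0.5 and rate_b > 0.5
        if ok and prev_ok:
            return True, i
        prev_ok = ok
    return False, None
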