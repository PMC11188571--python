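"""Generative task environments for the two-tone lever-pull paradigms.

Two head-fixed go/no-go task structures are modelled. In the *air-puff*
(positive punishment) task, tone A sounds on 20% of trials and tone B on
80%; a lever pull is always rewarded with water, but is simultaneously
punished with an air-puff at 90% (tone A) or 10% (tone B). In the
*omission* (negative punishment) task, tone A sounds on 40% of trials and
tone B on 60%; a pull is rewarded at only 10% (tone A) versus 90%
(tone B), and no air-puff is ever delivered. Withholding the pull yields
neither water nor air-puff in either task.

The environment emits only *physical* events (water, air-puff). The
model-level punishment indicator for the omission task (pull without
water) is derived in :mod:`forgetq.core`.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = [
    "TaskConfig",
    "OutcomeDraw",
    "air_puff_task",
    "omission_task",
    "get_preset",
    "PRESET_NAMES",
    "draw_tone",
    "resolve_outcome",
    "generate_session_schedule",
]

TONES = ("A", "B")
PRESET_NAMES = ("air_puff", "omission")


@dataclass(frozen=True)
class TaskConfig:
    """Generative structure of one task.

    Parameters
    ----------
    task_label : {"air_puff", "omission"}
        Which punishment regime the configuration describes.
    p_tone_a : float
        Marginal probability of a tone-A trial; tone B fills the rest.
    reward_prob : mapping of tone -> float
        Probability of water delivery given a lever pull.
    punish_prob : mapping of tone -> float
        Probability of a physical air-puff given a lever pull.
    """

    task_label: str
    p_tone_a: float
    reward_prob: Mapping[str, float]
    punish_prob: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.task_label not in PRESET_NAMES:
            raise ValueError(f"unknown task_label {self.task_label!r}")
        if not 0.0 <= self.p_tone_a <= 1.0:
            raise ValueError("p_tone_a must lie in [0, 1]")
        for name, probs in (("reward_prob", self.reward_prob),
                            ("punish_prob", self.punish_prob)):
            for tone in TONES:
                if tone not in probs:
                    raise ValueError(f"{name} missing tone {tone!r}")
                if not 0.0 <= probs[tone] <= 1.0:
                    raise ValueError(f"{name}[{tone!r}] outside [0, 1]")
        if self.task_label == "omission" and any(
                self.punish_prob[t] != 0.0 for t in TONES):
            raise ValueError("omission task never delivers an air-puff")
        # freeze the mappings so configs are safely shareable
        object.__setattr__(self, "reward_prob",
                           MappingProxyType(dict(self.reward_prob)))
        object.__setattr__(self, "punish_prob",
                           MappingProxyType(dict(self.punish_prob)))

    @property
    def is_omission(self) -> bool:
        return self.task_label == "omission"

    def to_dict(self) -> dict:
        return {
            "task_label": self.task_label,
            "p_tone_a": self.p_tone_a,
            "reward_prob": dict(self.reward_prob),
            "punish_prob": dict(self.punish_prob),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskConfig":
        return cls(task_label=d["task_label"], p_tone_a=d["p_tone_a"],
                   reward_prob=dict(d["reward_prob"]),
                   punish_prob=dict(d["punish_prob"]))


@dataclass(frozen=True)
class OutcomeDraw:
    """Physical outcome of a single trial (water drop, air-puff)."""

    reward: int
    punishment: int


def air_puff_task() -> TaskConfig:
    """Positive-punishment preset: rare risky tone, certain reward."""
    return TaskConfig(
        task_label="air_puff",
        p_tone_a=0.2,
        reward_prob={"A": 1.0, "B": 1.0},
        punish_prob={"A": 0.9, "B": 0.1},
    )


def omission_task() -> TaskConfig:
    """Negative-punishment preset: reward withheld, never an air-puff."""
    return TaskConfig(
        task_label="omission",
        p_tone_a=0.4,
        reward_prob={"A": 0.1, "B": 0.9},
        punish_prob={"A": 0.0, "B": 0.0},
    )


def get_preset(name: str) -> TaskConfig:
    """Return a named task preset (``air_puff`` or ``omission``)."""
    if name == "air_puff":
        return air_puff_task()
    if name == "omission":
        return omission_task()
    raise ValueError(f"unknown task preset {name!r}; choose from {PRESET_NAMES}")


def draw_tone(cfg: TaskConfig, rng: np.random.Generator) -> str:
    """Draw one tone cue: Bernoulli(p_tone_a) gives A, otherwise B."""
    return "A" if rng.random() < cfg.p_tone_a else "B"


def resolve_outcome(cfg: TaskConfig, tone: str, action: str,
                    rng: np.random.Generator) -> OutcomeDraw:
    """Resolve the physical outcome of one trial.

    A non-pull yields neither water nor air-puff. A pull draws reward and
    air-puff independently at the tone-specific probabilities.
    """
    if action != "pull":
        return OutcomeDraw(0, 0)
    reward = int(rng.random() < cfg.reward_prob[tone])
    punishment = int(rng.random() < cfg.punish_prob[tone])
    return OutcomeDraw(reward, punishment)


def generate_session_schedule(cfg: TaskConfig, n_trials: int,
                              rng: np.random.Generator) -> list[str]:
    """Draw an i.i.d. tone schedule of ``n_trials`` cues.

    Fixed schedules are reused across generative-simulation repetitions,
    mirroring how real sessions present one tone sequence to every model
    run. Deterministic given the generator state.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    draws = rng.random(n_trials) < cfg.p_tone_a
    return ["A" if d else "B" for d in draws]
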