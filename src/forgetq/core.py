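"""Forgetting Q-learning model family: values, updates, choice rule.

The learner maintains four action values: Q_pull and Q_non_pull for each
tone cue (A, B). The two tones are learned as independent sequences — a
tone-A trial never touches tone-B values. On a pull, Q_pull moves toward
``kappa_r * r - kappa_p * p`` at learning rate ``alpha_l`` while the
unchosen Q_non_pull decays by the forgetting rate ``alpha_f``; on a
non-pull, Q_non_pull moves toward the covert "saving" reward ``psi``
while Q_pull decays. The pull probability is the logistic function of
``Q_pull - Q_non_pull`` (no inverse-temperature parameter).

Seven model variants arise from switching the punishment term (kappa_p),
the saving term (psi), and the forgetting rate (alpha_f) on or off;
``kappa_r`` and ``alpha_l`` are always free, so variants carry 2–5 free
parameters.

The punishment indicator ``p`` is task-dependent: in the air-puff task it
is the physical air-puff on a pull trial; in the omission task it is 1
exactly when the animal pulled and water was withheld.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

from .tasks import TaskConfig

__all__ = [
    "Params",
    "ModelSpec",
    "QState",
    "PARAM_NAMES",
    "MODEL_NAMES",
    "model_family",
    "derive_punishment_indicator",
    "update_q",
    "choice_probability",
    "steady_state_q",
]

PARAM_NAMES = ("alpha_l", "alpha_f", "kappa_r", "kappa_p", "psi")


@dataclass(frozen=True)
class Params:
    """The five learner parameters.

    alpha_l : learning rate, in (0, 1)
    alpha_f : forgetting rate of the unchosen action, in [0, 1)
        (0 when the forgetting term is disabled)
    kappa_r : subjective reward value, >= 0
    kappa_p : subjective aversion to punishment, >= 0
    psi     : covert reward for withholding the pull, >= 0
    """

    alpha_l: float
    alpha_f: float = 0.0
    kappa_r: float = 1.0
    kappa_p: float = 0.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_l <= 1.0:
            raise ValueError("alpha_l must lie in [0, 1]")
        if not 0.0 <= self.alpha_f <= 1.0:
            raise ValueError("alpha_f must lie in [0, 1]")
        for name in ("kappa_r", "kappa_p", "psi"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], float)

    @classmethod
    def from_array(cls, arr) -> "Params":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "Params":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelSpec:
    """One of the seven model variants.

    ``kappa_r`` and ``alpha_l`` are always free; the three flags say
    whether ``kappa_p``, ``psi`` and ``alpha_f`` are free or pinned at 0.
    """

    name: str
    use_punishment: bool
    use_saving: bool
    use_forgetting: bool

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return 2 + self.use_punishment + self.use_saving + self.use_forgetting

    @property
    def free_params(self) -> tuple[str, ...]:
        names = ["alpha_l"]
        if self.use_forgetting:
            names.append("alpha_f")
        names.append("kappa_r")
        if self.use_punishment:
            names.append("kappa_p")
        if self.use_saving:
            names.append("psi")
        return tuple(names)

    def constrain(self, params: Params) -> Params:
        """Zero out parameters this variant does not use."""
        kw = {}
        if not self.use_punishment:
            kw["kappa_p"] = 0.0
        if not self.use_saving:
            kw["psi"] = 0.0
        if not self.use_forgetting:
            kw["alpha_f"] = 0.0
        return params.replace(**kw) if kw else params

    def admits(self, params: Params) -> bool:
        """True if disabled parameters are exactly 0 in ``params``."""
        return self.constrain(params) == params

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return _FAMILY[name]
        except KeyError:
            raise ValueError(
                f"unknown model {name!r}; choose from {MODEL_NAMES}") from None


def _build_family() -> dict[str, ModelSpec]:
    combos = {
        "simple": (False, False, False),
        "punishment": (True, False, False),
        "saving": (False, True, False),
        "forgetting": (False, False, True),
        "P-F": (True, False, True),
        "S-F": (False, True, True),
        "P-S-F": (True, True, True),
    }
    return {name: ModelSpec(name, p, s, f)
            for name, (p, s, f) in combos.items()}


_FAMILY = _build_family()
MODEL_NAMES = tuple(_FAMILY)


def model_family() -> dict[str, ModelSpec]:
    """The seven constructible variants, keyed by canonical name."""
    return dict(_FAMILY)


@dataclass(frozen=True)
class QState:
    """The four latent action values (pull / non-pull x tone A / B)."""

    q_pull: tuple[float, float] = (0.0, 0.0)
    q_non_pull: tuple[float, float] = (0.0, 0.0)

    def pull(self, tone: str) -> float:
        return self.q_pull[_tone_idx(tone)]

    def non_pull(self, tone: str) -> float:
        return self.q_non_pull[_tone_idx(tone)]

    def to_array(self) -> np.ndarray:
        """2x2 array indexed [tone (0=A, 1=B), action (0=pull, 1=non-pull)]."""
        return np.array([[self.q_pull[0], self.q_non_pull[0]],
                         [self.q_pull[1], self.q_non_pull[1]]], float)

    @classmethod
    def from_array(cls, arr) -> "QState":
        a = np.asarray(arr, float)
        return cls(q_pull=(float(a[0, 0]), float(a[1, 0])),
                   q_non_pull=(float(a[0, 1]), float(a[1, 1])))

    @classmethod
    def zeros(cls) -> "QState":
        return cls()


def _tone_idx(tone: str) -> int:
    if tone == "A":
        return 0
    if tone == "B":
        return 1
    raise ValueError(f"tone must be 'A' or 'B', got {tone!r}")


def derive_punishment_indicator(task_label: str, action: str, reward: int,
                                physical_punishment: int) -> int:
    """Model-level punishment indicator p(t) for one trial.

    Air-puff task: the physical air-puff, on pull trials only.
    Omission task: 1 exactly when the lever was pulled but no water came.
    Non-pull trials are never punished in either task.
    """
    if action != "pull":
        return 0
    if task_label == "omission":
        return int(reward == 0)
    return int(physical_punishment)


def update_q(state: QState, tone: str, action: str, r: int, p: int,
             params: Params) -> QState:
    """One trial's value update; only the presented tone's pair changes.

    ``p`` must already be the task-appropriate punishment indicator (see
    :func:`derive_punishment_indicator`).
    """
    i = _tone_idx(tone)
    q_pull = list(state.q_pull)
    q_np = list(state.q_non_pull)
    if action == "pull":
        q_pull[i] += params.alpha_l * (params.kappa_r * r
                                       - params.kappa_p * p - q_pull[i])
        q_np[i] *= 1.0 - params.alpha_f
    elif action == "non_pull":
        q_pull[i] *= 1.0 - params.alpha_f
        q_np[i] += params.alpha_l * (params.psi - q_np[i])
    else:
        raise ValueError(f"unknown action {action!r}")
    return QState(q_pull=tuple(q_pull), q_non_pull=tuple(q_np))


def choice_probability(state: QState, tone: str) -> float:
    """Pull probability: logistic of Q_pull - Q_non_pull for the tone."""
    diff = state.pull(tone) - state.non_pull(tone)
    # expit without the scipy import; diff is always finite here
    if diff >= 0:
        return 1.0 / (1.0 + np.exp(-diff))
    e = np.exp(diff)
    return e / (1.0 + e)


def steady_state_q(params: Params, cfg: TaskConfig) -> QState:
    """Steady-state initial values under constant expected outcomes.

    Treating the pull update and the non-pull update as being at their
    fixed points with expected reward R_x and punishment P_x taken from
    the task configuration gives Q_pull = kappa_r*R_x - kappa_p*P_x and
    Q_non_pull = psi. Intended for the air-puff preset, where R_A = R_B =
    1, P_A = 0.9, P_B = 0.1.
    """
    q_pull = tuple(params.kappa_r * cfg.reward_prob[t]
                   - params.kappa_p * cfg.punish_prob[t] for t in ("A", "B"))
    return QState(q_pull=q_pull, q_non_pull=(params.psi, params.psi))
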