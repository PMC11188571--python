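"""Generative (posterior-predictive) simulation and RMSE scoring.

A fitted parameter set is replayed through the real session's tone
sequence: each repetition walks the trials in order, draws a pull or
non-pull from the model's current choice probability, resolves outcomes
(reusing the real trial's outcomes when both the simulated and the real
animal pulled, drawing fresh ones from the task probabilities when only
the simulated agent pulled), and updates the values. Generative fit is
scored as the root-mean-square error between the real binary choices and
the simulated ones, averaged across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import rmse_per_rep_kernel, simulate_kernel
from .core import ModelSpec, Params, QState
from .model import encode_log
from .tasks import TaskConfig
from .trials import SessionLog, exclude_early_pulls

__all__ = ["SimResult", "simulate_choices", "rmse", "bin_average_choices",
           "BIN_COUNTS"]

# Display bin counts per task and tone, proportional to the tone
# presentation probabilities (tone A : tone B = 20:80 in the air-puff
# task, 40:60 in the omission task, over a 50-bin total).
BIN_COUNTS = {("air_puff", "A"): 10, ("air_puff", "B"): 40,
              ("omission", "A"): 20, ("omission", "B"): 30}


@dataclass
class SimResult:
    """Outcome of a generative replay.

    ``mean_choice[t]`` is the across-repetition mean of the simulated
    binary pull choice at trial t. ``rmse_mean`` averages the
    per-repetition RMSE values.
    """

    mean_choice: np.ndarray
    rmse_per_rep: np.ndarray
    rmse_mean: float
    n_reps: int
    seed: int | None
    choices: np.ndarray | None = None

    def to_dict(self, include_choices: bool = False) -> dict:
        d = {"mean_choice": self.mean_choice.tolist(),
             "rmse_per_rep": self.rmse_per_rep.tolist(),
             "rmse_mean": self.rmse_mean,
             "n_reps": self.n_reps, "seed": self.seed}
        if include_choices and self.choices is not None:
            d["choices"] = self.choices.tolist()
        return d


def _uniforms(n_reps: int, n_trials: int,
              seed: int | None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.random((n_reps, n_trials, 3))


def simulate_choices(log: SessionLog, cfg: TaskConfig, params: Params,
                     spec: ModelSpec | str,
                     initial_state: QState | None = None,
                     n_reps: int = 1000, seed: int | None = None,
                     keep_choices: bool = False,
                     pred_mode: str = "binary",
                     _uniform_draws: np.ndarray | None = None) -> SimResult:
    """Replay a session generatively ``n_reps`` times.

    Parameters
    ----------
    pred_mode : {"binary", "mean"}
        How the RMSE treats the simulated choice: ``"binary"`` scores
        each repetition's 0/1 choices against the real ones and averages
        the per-repetition RMSEs (default); ``"mean"`` scores the
        across-repetition mean choice probability against the real
        binary choices once.
    _uniform_draws : ndarray, optional
        Pre-drawn uniforms of shape (n_reps, n_trials, 3); used by the
        perturbation grid search to share common random numbers across
        candidate parameter values.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    if cfg.task_label != log.task_label:
        raise ValueError(
            f"task mismatch: log is {log.task_label!r}, "
            f"config is {cfg.task_label!r}")
    if pred_mode not in ("binary", "mean"):
        raise ValueError("pred_mode must be 'binary' or 'mean'")
    params = spec.constrain(params)
    log = exclude_early_pulls(log)
    a = encode_log(log)
    n = len(log)
    if n == 0:
        raise ValueError("cannot simulate an empty log")
    u = _uniform_draws
    if u is None:
        u = _uniforms(n_reps, n, seed)
    elif u.shape != (n_reps, n, 3):
        raise ValueError("uniform draw array has the wrong shape")
    q0 = (initial_state or QState.zeros()).to_array()
    reward_prob = np.array([cfg.reward_prob["A"], cfg.reward_prob["B"]])
    punish_prob = np.array([cfg.punish_prob["A"], cfg.punish_prob["B"]])
    choices = simulate_kernel(a["tone"], a["action"], a["reward"],
                              a["punish"], reward_prob, punish_prob,
                              cfg.is_omission,
                              params.alpha_l, params.alpha_f, params.kappa_r,
                              params.kappa_p, params.psi, q0, u)
    mean_choice = choices.mean(axis=0)
    if pred_mode == "binary":
        per_rep = rmse_per_rep_kernel(choices, a["action"])
        rmse_mean = float(per_rep.mean())
    else:
        per_rep = np.array([rmse(a["action"], mean_choice)])
        rmse_mean = float(per_rep[0])
    return SimResult(mean_choice=mean_choice, rmse_per_rep=per_rep,
                     rmse_mean=rmse_mean, n_reps=n_reps, seed=seed,
                     choices=choices if keep_choices else None)


def rmse(actual, predicted) -> float:
    """Root-mean-square error between two equal-length choice sequences.

    N counts every trial of both tones.
    """
    act = np.asarray(actual, float)
    pred = np.asarray(predicted, float)
    if act.shape != pred.shape:
        raise ValueError("sequences must have equal length")
    if act.size < 1:
        raise ValueError("need at least one trial")
    return float(np.sqrt(np.mean((pred - act) ** 2)))


def bin_average_choices(values, task_label: str, tone: str) -> np.ndarray:
    """Average a per-trial tone sequence into the display bins.

    Bin counts follow the tone presentation probabilities (see
    ``BIN_COUNTS``). When the trial count does not divide evenly, the
    leading bins take one extra trial.
    """
    x = np.asarray(values, float)
    try:
        n_bins = BIN_COUNTS[(task_label, tone)]
    except KeyError:
        raise ValueError(
            f"no bin rule for task {task_label!r}, tone {tone!r}") from None
    if x.size < n_bins:
        raise ValueError(f"need at least {n_bins} trials, got {x.size}")
    base, extra = divmod(x.size, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:extra] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return np.array([x[edges[i]:edges[i + 1]].mean() for i in range(n_bins)])
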