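"""Single-parameter perturbation attribution for injection sessions.

After a pharmacological injection (e.g. muscimol inactivation of the
medial prefrontal cortex), the question is which *one* model parameter
best explains the behavioral change. Starting from the parameters fitted
to the training sessions, each parameter in turn is scanned over an
exhaustive grid (learning/forgetting rates 0–1 in steps of 0.01; value
parameters 0–20 in steps of 0.1) with every other parameter held at its
fitted value; each candidate is scored by the mean RMSE of a generative
replay of the post-injection session. The parameter whose best grid
value attains the lowest RMSE is the *injection-related parameter*.

Initial values for the replay come either from the training fit's final
values (``carryover``) or, for the air-puff task, from the steady-state
values recomputed with the candidate parameter (``steady_state`` — the
injection precedes the session, so the starting values may already
reflect the modulated parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelSpec, Params, QState, steady_state_q
from .simulate import simulate_choices, _uniforms
from .tasks import TaskConfig
from .trials import SessionLog, exclude_early_pulls

__all__ = ["ParameterScan", "PerturbResult", "parameter_grid",
           "optimize_single_parameter", "identify_injection_parameter",
           "SCAN_ORDER"]

# Fixed scan (and tie-break) order across parameters.
SCAN_ORDER = ("alpha_l", "alpha_f", "kappa_r", "kappa_p", "psi")


def parameter_grid(name: str) -> np.ndarray:
    """The exhaustive search grid for one parameter."""
    if name in ("alpha_l", "alpha_f"):
        return np.round(np.arange(0, 101) * 0.01, 2)
    if name in ("kappa_r", "kappa_p", "psi"):
        return np.round(np.arange(0, 201) * 0.1, 1)
    raise ValueError(f"unknown parameter {name!r}")


@dataclass
class ParameterScan:
    """Grid scan of one parameter: candidate values and their RMSEs."""

    name: str
    grid: np.ndarray
    rmse_curve: np.ndarray
    best_value: float
    min_rmse: float


@dataclass
class PerturbResult:
    """Outcome of the five-parameter attribution analysis.

    ``delta_rmse[name]`` is baseline RMSE minus the parameter's
    optimised RMSE (improvement, >= 0 up to Monte-Carlo noise since the
    grids cover the baseline values). ``injection_related_parameter`` is
    the scanned parameter attaining the overall minimum RMSE.
    """

    baseline_rmse: float
    scans: dict[str, ParameterScan]
    delta_rmse: dict[str, float]
    injection_related_parameter: str
    initial_q_mode: str
    n_reps: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "baseline_rmse": self.baseline_rmse,
            "injection_related_parameter": self.injection_related_parameter,
            "initial_q_mode": self.initial_q_mode,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "delta_rmse": dict(self.delta_rmse),
            "optimized": {n: {"best_value": s.best_value,
                              "min_rmse": s.min_rmse}
                          for n, s in self.scans.items()},
        }


def _scan_one(log_post, cfg, base_params, spec, target, initial_state,
              initial_q_mode, n_reps, u, grid, pred_mode) -> ParameterScan:
    rmses = np.empty(grid.size)
    for i, value in enumerate(grid):
        cand = spec.constrain(base_params.replace(**{target: float(value)}))
        if initial_q_mode == "steady_state":
            q0 = steady_state_q(cand, cfg)
        else:
            q0 = initial_state
        sim = simulate_choices(log_post, cfg, cand, spec,
                               initial_state=q0, n_reps=n_reps,
                               _uniform_draws=u, pred_mode=pred_mode)
        rmses[i] = sim.rmse_mean
    min_rmse = rmses.min()
    # ties: prefer the smallest move away from the training-fit value
    base_value = getattr(base_params, target)
    tied = np.flatnonzero(rmses == min_rmse)
    best = grid[tied[np.argmin(np.abs(grid[tied] - base_value))]]
    return ParameterScan(name=target, grid=grid, rmse_curve=rmses,
                         best_value=float(best), min_rmse=float(min_rmse))


def optimize_single_parameter(log_post: SessionLog, cfg: TaskConfig,
                              base_params: Params, spec: ModelSpec | str,
                              target: str,
                              initial_state: QState | None = None,
                              initial_q_mode: str = "carryover",
                              n_reps: int = 1000,
                              seed: int | None = None,
                              grid: np.ndarray | None = None,
                              pred_mode: str = "mean"
                              ) -> tuple[float, float]:
    """Grid-optimise one parameter against the post-injection session.

    Returns ``(best_value, min_rmse)``. All other parameters stay at
    their training-fit values. ``initial_q_mode="carryover"`` replays
    from ``initial_state`` (the training fit's final values);
    ``"steady_state"`` (air-puff task only) recomputes the starting
    values from the candidate parameter set.

    Candidates are scored by the RMSE of the repetition-averaged
    simulated choice against the real binary choices
    (``pred_mode="mean"``). Scoring each repetition's binary choices
    instead (``"binary"``) adds a sampling-variance term that rewards
    whichever candidate makes behavior most deterministic — a degenerate
    objective for attribution, where a saturated learning rate can then
    outscore the truly perturbed parameter.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    if target not in spec.free_params:
        raise ValueError(
            f"parameter {target!r} is not free in model {spec.name!r}")
    _check_mode(initial_q_mode, cfg)
    log_post = exclude_early_pulls(log_post)
    u = _uniforms(n_reps, len(log_post), seed)
    scan = _scan_one(log_post, cfg, base_params, spec, target,
                     initial_state or QState.zeros(), initial_q_mode,
                     n_reps, u, parameter_grid(target) if grid is None
                     else np.asarray(grid, float), pred_mode)
    return scan.best_value, scan.min_rmse


def identify_injection_parameter(log_post: SessionLog, cfg: TaskConfig,
                                 base_params: Params,
                                 spec: ModelSpec | str,
                                 initial_state: QState | None = None,
                                 initial_q_mode: str = "carryover",
                                 n_reps: int = 1000,
                                 seed: int | None = None,
                                 pred_mode: str = "mean") -> PerturbResult:
    """Scan every free parameter and name the injection-related one.

    The same pre-drawn random numbers are reused across all grid values
    and parameters (common random numbers), so RMSE differences between
    candidates reflect the parameter change rather than Monte-Carlo
    noise. Ties across parameters break in the fixed scan order.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    _check_mode(initial_q_mode, cfg)
    log_post = exclude_early_pulls(log_post)
    if len(log_post) == 0:
        raise ValueError("post-injection log is empty")
    initial_state = initial_state or QState.zeros()
    u = _uniforms(n_reps, len(log_post), seed)

    base_q0 = (steady_state_q(spec.constrain(base_params), cfg)
               if initial_q_mode == "steady_state" else initial_state)
    baseline = simulate_choices(log_post, cfg, base_params, spec,
                                initial_state=base_q0, n_reps=n_reps,
                                _uniform_draws=u,
                                pred_mode=pred_mode).rmse_mean

    scans: dict[str, ParameterScan] = {}
    for name in SCAN_ORDER:
        if name not in spec.free_params:
            continue
        scans[name] = _scan_one(log_post, cfg, base_params, spec, name,
                                initial_state, initial_q_mode, n_reps, u,
                                parameter_grid(name), pred_mode)
    best_param = None
    best_rmse = np.inf
    for name in SCAN_ORDER:
        if name in scans and scans[name].min_rmse < best_rmse:
            best_rmse = scans[name].min_rmse
            best_param = name
    delta = {n: baseline - s.min_rmse for n, s in scans.items()}
    return PerturbResult(baseline_rmse=float(baseline), scans=scans,
                         delta_rmse=delta,
                         injection_related_parameter=best_param,
                         initial_q_mode=initial_q_mode, n_reps=n_reps,
                         seed=seed)


def _check_mode(mode: str, cfg: TaskConfig) -> None:
    if mode not in ("carryover", "steady_state"):
        raise ValueError("initial_q_mode must be 'carryover' or "
                         "'steady_state'")
    if mode == "steady_state" and cfg.task_label != "air_puff":
        raise ValueError(
            "steady_state initial values are defined for the air-puff "
            "task only")
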