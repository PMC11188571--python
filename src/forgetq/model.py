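"""Maximum-likelihood fitting of the forgetting Q-learning family.

The entry point is :class:`ForgettingQModel`, built from a
:class:`~forgetq.trials.SessionLog` and a model variant, whose ``fit``
runs bounded multi-start maximum likelihood and returns a
:class:`ForgettingQResults` carrying the estimates, the maximised log
likelihood, AIC/BIC, and the per-trial value and choice-probability
trajectories. ``compare_models`` fits the whole seven-variant family and
reports z-scored information criteria with the best variant per
criterion.

The likelihood is the product over trials of z(t), where z(t) is the
model's pull probability when the animal pulled and its complement when
it did not; the objective is the negative log likelihood, minimised by a
bounded local optimiser from many uniform-random starting points, of
which the best is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._kernels import P_CLAMP_EPS, nll_kernel, trajectory_kernel
from .core import (MODEL_NAMES, PARAM_NAMES, ModelSpec, Params, QState,
                   derive_punishment_indicator)
from .trials import SessionLog, exclude_early_pulls

__all__ = [
    "ForgettingQModel",
    "ForgettingQResults",
    "ModelComparison",
    "FittingError",
    "PARAM_BOUNDS",
    "negative_log_likelihood",
    "fit_model",
    "information_criteria",
    "compare_models",
]

# Optimiser box constraints. The learning/forgetting rates live strictly
# inside (0, 1); the value-scale parameters share the 0-20 range that the
# perturbation grid search also spans.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_l": (1e-6, 1.0 - 1e-6),
    "alpha_f": (1e-6, 1.0 - 1e-6),
    "kappa_r": (0.0, 20.0),
    "kappa_p": (0.0, 20.0),
    "psi": (0.0, 20.0),
}


class FittingError(RuntimeError):
    """No optimisation restart produced a usable optimum."""


def encode_log(log: SessionLog) -> dict[str, np.ndarray]:
    """Encode a (early-pull-free) log as kernel-ready arrays.

    ``punish`` is the model-level punishment indicator, derived from the
    task semantics (air-puff: physical puff; omission: pull without
    water).
    """
    tone = np.array([0 if t.tone == "A" else 1 for t in log], np.int8)
    action = np.array([1 if t.action == "pull" else 0 for t in log], np.int8)
    reward = np.array([t.reward for t in log], np.float64)
    punish = np.array(
        [derive_punishment_indicator(log.task_label, t.action, t.reward,
                                     t.punishment) for t in log],
        np.float64)
    return {"tone": tone, "action": action, "reward": reward,
            "punish": punish}


def negative_log_likelihood(log: SessionLog, params: Params,
                            spec: ModelSpec,
                            initial_state: QState | None = None) -> float:
    """-log L of the choice sequence under one parameter set.

    Computed in log space; choice probabilities are clamped to
    ``[eps, 1-eps]`` (eps = 1e-12) so the objective stays finite at
    boundary parameter values. An empty log gives 0 (empty product).
    """
    params = spec.constrain(params)
    arrays = encode_log(log)
    q0 = (initial_state or QState.zeros()).to_array()
    return float(nll_kernel(arrays["tone"], arrays["action"],
                            arrays["reward"], arrays["punish"],
                            params.alpha_l, params.alpha_f, params.kappa_r,
                            params.kappa_p, params.psi, q0, P_CLAMP_EPS))


def information_criteria(log_likelihood_max: float, k: int,
                         n_trials: int) -> tuple[float, float]:
    """AIC and BIC from the maximised log likelihood.

    AIC = -2 log L_max + 2K; BIC = -2 log L_max + K log T_n.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    aic = -2.0 * log_likelihood_max + 2.0 * k
    bic = -2.0 * log_likelihood_max + k * np.log(n_trials)
    return aic, bic


class ForgettingQModel:
    """Forgetting Q-learning likelihood model for one animal's log.

    Parameters
    ----------
    log : SessionLog
        Concatenated trials; early-pull trials are dropped on entry.
    spec : ModelSpec or str
        Which of the seven variants to fit (e.g. ``"P-S-F"``).
    initial_state : QState, optional
        Values before the first trial; defaults to all zeros, the
        value-neutral start (and the fixed point of every disabled
        term).
    """

    def __init__(self, log: SessionLog, spec: ModelSpec | str = "P-S-F",
                 initial_state: QState | None = None):
        if isinstance(spec, str):
            spec = ModelSpec.from_name(spec)
        self.spec = spec
        self.log = exclude_early_pulls(log)
        self.initial_state = initial_state or QState.zeros()
        self._arrays = encode_log(self.log)
        self._q0 = self.initial_state.to_array()
        self._free_idx = np.array([PARAM_NAMES.index(n)
                                   for n in self.spec.free_params])

    @classmethod
    def from_dataframe(cls, df, task_label: str,
                       spec: ModelSpec | str = "P-S-F",
                       **kw) -> "ForgettingQModel":
        return cls(SessionLog.from_frame(df, task_label), spec, **kw)

    @property
    def nobs(self) -> int:
        return len(self.log)

    def nll(self, params: Params) -> float:
        """Negative log likelihood at one parameter set."""
        params = self.spec.constrain(params)
        return self._nll_vector(params.to_array())

    def loglike(self, params: Params) -> float:
        return -self.nll(params)

    def _nll_vector(self, theta: np.ndarray) -> float:
        a = self._arrays
        return float(nll_kernel(a["tone"], a["action"], a["reward"],
                                a["punish"], theta[0], theta[1], theta[2],
                                theta[3], theta[4], self._q0, P_CLAMP_EPS))

    def _pack(self, free: np.ndarray) -> np.ndarray:
        theta = np.zeros(5)
        theta[self._free_idx] = free
        return theta

    def fit(self, n_restarts: int = 5000, seed: int | None = None,
            method: str = "L-BFGS-B") -> "ForgettingQResults":
        """Best-of-``n_restarts`` bounded local optimisation.

        Starting points are uniform over the parameter box; one RNG
        stream per fit, so the result is reproducible from ``seed``.
        Each restart runs the bounded optimiser at a loose tolerance to
        locate its basin; the best restart is then polished at the
        optimiser's tight default tolerance.
        """
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.nobs == 0:
            raise ValueError("cannot fit an empty log")
        rng = np.random.default_rng(seed)
        free_names = self.spec.free_params
        lo = np.array([PARAM_BOUNDS[n][0] for n in free_names])
        hi = np.array([PARAM_BOUNDS[n][1] for n in free_names])
        bounds = list(zip(lo, hi))
        starts = rng.uniform(lo, hi, size=(n_restarts, len(free_names)))

        objective = lambda free: self._nll_vector(self._pack(free))
        coarse = {"ftol": 1e-6, "gtol": 1e-4, "maxfun": 300}
        best_fun = np.inf
        best_x = None
        n_failed = 0
        for x0 in starts:
            res = minimize(objective, x0, method=method, bounds=bounds,
                           options=coarse)
            if not np.isfinite(res.fun):
                n_failed += 1
                continue
            if res.fun < best_fun:
                best_fun = res.fun
                best_x = res.x
        if best_x is None:
            raise FittingError(
                f"all {n_restarts} restarts failed for model "
                f"{self.spec.name} ({n_failed} non-finite objectives)")
        polish = minimize(objective, best_x, method=method, bounds=bounds)
        if np.isfinite(polish.fun) and polish.fun <= best_fun:
            best_fun, best_x = polish.fun, polish.x

        params = self.spec.constrain(Params.from_array(self._pack(best_x)))
        llf = -best_fun
        aic, bic = information_criteria(llf, self.spec.k, self.nobs)
        a = self._arrays
        q_traj, p_traj, q_final = trajectory_kernel(
            a["tone"], a["action"], a["reward"], a["punish"],
            params.alpha_l, params.alpha_f, params.kappa_r, params.kappa_p,
            params.psi, self._q0)
        return ForgettingQResults(
            model=self, spec=self.spec, params=params,
            log_likelihood_max=llf, n_trials_fit=self.nobs,
            aic=aic, bic=bic, n_restarts=n_restarts, seed=seed,
            q_trajectory=q_traj, p_trajectory=p_traj,
            final_state=QState.from_array(q_final))


@dataclass
class ForgettingQResults:
    """Fit results: estimates, information criteria, trajectories.

    ``q_trajectory[t]`` is the 2x2 value array (tone x pull/non-pull)
    *before* trial t's update — the state that produced the pull
    probability ``p_trajectory[t]``; ``final_state`` is the state after
    the last trial (the carryover initial state for post-injection
    analyses).
    """

    model: ForgettingQModel
    spec: ModelSpec
    params: Params
    log_likelihood_max: float
    n_trials_fit: int
    aic: float
    bic: float
    n_restarts: int
    seed: int | None
    q_trajectory: np.ndarray
    p_trajectory: np.ndarray
    final_state: QState

    @property
    def llf(self) -> float:
        return self.log_likelihood_max

    @property
    def nobs(self) -> int:
        return self.n_trials_fit

    @property
    def k_params(self) -> int:
        return self.spec.k

    def simulate(self, cfg, n_reps: int = 1000, seed: int | None = None,
                 **kw):
        """Generative replay of the fitted log (see forgetq.simulate)."""
        from .simulate import simulate_choices
        return simulate_choices(self.model.log, cfg, self.params, self.spec,
                                initial_state=self.model.initial_state,
                                n_reps=n_reps, seed=seed, **kw)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "params": self.params.to_dict(),
            "log_likelihood_max": self.log_likelihood_max,
            "n_trials_fit": self.n_trials_fit,
            "aic": self.aic,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "final_state": self.final_state.to_array().tolist(),
        }

    def summary(self) -> str:
        lines = [
            "Forgetting Q-learning fit",
            "=" * 46,
            f"model:          {self.spec.name}  (K = {self.spec.k})",
            f"trials fit:     {self.n_trials_fit}",
            f"log L_max:      {self.log_likelihood_max:.4f}",
            f"AIC:            {self.aic:.4f}",
            f"BIC:            {self.bic:.4f}",
            f"restarts:       {self.n_restarts} (seed {self.seed})",
            "-" * 46,
        ]
        for name in PARAM_NAMES:
            value = getattr(self.params, name)
            status = "free" if name in self.spec.free_params else "fixed 0"
            lines.append(f"{name:>10}: {value:10.4f}   [{status}]")
        return "\n".join(lines)


def fit_model(log: SessionLog, spec: ModelSpec | str,
              n_restarts: int = 5000, seed: int | None = None,
              initial_state: QState | None = None) -> ForgettingQResults:
    """Convenience wrapper: build a model and fit it."""
    return ForgettingQModel(log, spec, initial_state).fit(
        n_restarts=n_restarts, seed=seed)


@dataclass
class ModelComparison:
    """AIC/BIC comparison across fitted variants.

    z-scores are taken across the fitted models (mean 0, sd 1), matching
    how model scores are displayed across a family; the best model per
    criterion is the argmin of the raw score, ties broken by the
    canonical model order.
    """

    results: dict[str, ForgettingQResults]
    aic_z: dict[str, float]
    bic_z: dict[str, float]
    best_by_aic: str
    best_by_bic: str

    def to_frame(self):
        import pandas as pd
        rows = []
        for name, res in self.results.items():
            rows.append({"model": name, "K": res.spec.k,
                         "logL_max": res.log_likelihood_max,
                         "aic": res.aic, "bic": res.bic,
                         "aic_z": self.aic_z[name],
                         "bic_z": self.bic_z[name]})
        return pd.DataFrame(rows).set_index("model")


def _zscores(values: dict[str, float]) -> dict[str, float]:
    arr = np.array(list(values.values()))
    sd = arr.std()
    if sd == 0:
        return {k: 0.0 for k in values}
    mean = arr.mean()
    return {k: (v - mean) / sd for k, v in values.items()}


def compare_models(log: SessionLog, n_restarts: int = 5000,
                   seed: int | None = None,
                   model_names: tuple[str, ...] = MODEL_NAMES
                   ) -> ModelComparison:
    """Fit every requested variant and rank them by AIC and BIC.

    Each variant gets its own restart stream (derived from ``seed``) so
    the comparison is reproducible as a whole.
    """
    if len(model_names) < 2:
        raise ValueError("comparison needs at least two models")
    ss = np.random.SeedSequence(seed).spawn(len(model_names))
    results: dict[str, ForgettingQResults] = {}
    for sub_seed, name in zip(ss, model_names):
        results[name] = fit_model(log, name, n_restarts=n_restarts,
                                  seed=int(sub_seed.generate_state(1)[0]
                                           % (2 ** 31)))
    aic = {n: r.aic for n, r in results.items()}
    bic = {n: r.bic for n, r in results.items()}
    best_aic = min(model_names, key=lambda n: aic[n])
    best_bic = min(model_names, key=lambda n: bic[n])
    return ModelComparison(results=results, aic_z=_zscores(aic),
                           bic_z=_zscores(bic), best_by_aic=best_aic,
                           best_by_bic=best_bic)
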