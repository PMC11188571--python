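"""Numba-compiled inner loops.

The likelihood and generative-simulation loops are strictly sequential
(each trial's choice probability depends on the values left by the
previous trial of the same tone), so they are compiled with numba rather
than vectorised. Arrays are encoded as: tone 0=A / 1=B; action 1=pull /
0=non-pull; Q as a 2x2 array indexed [tone, 0=pull / 1=non-pull].
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_CLAMP_EPS = 1e-12  # keeps log z(t) finite at boundary parameter values


@njit(cache=True, fastmath=True)
def _sigmoid(d):
    if d >= 0.0:
        return 1.0 / (1.0 + np.exp(-d))
    e = np.exp(d)
    return e / (1.0 + e)


@njit(cache=True, fastmath=True)
def nll_kernel(tone, action, reward, punish,
               alpha_l, alpha_f, kappa_r, kappa_p, psi, q0, eps):
    """Negative log likelihood of the choice sequence, in log space.

    ``punish`` must already be the model-level punishment indicator.
    """
    q = q0.copy()
    nll = 0.0
    for t in range(tone.shape[0]):
        x = tone[t]
        pr = _sigmoid(q[x, 0] - q[x, 1])
        if pr < eps:
            pr = eps
        elif pr > 1.0 - eps:
            pr = 1.0 - eps
        if action[t] == 1:
            nll -= np.log(pr)
            q[x, 0] += alpha_l * (kappa_r * reward[t]
                                  - kappa_p * punish[t] - q[x, 0])
            q[x, 1] *= 1.0 - alpha_f
        else:
            nll -= np.log(1.0 - pr)
            q[x, 0] *= 1.0 - alpha_f
            q[x, 1] += alpha_l * (psi - q[x, 1])
    return nll


@njit(cache=True, fastmath=True)
def trajectory_kernel(tone, action, reward, punish,
                      alpha_l, alpha_f, kappa_r, kappa_p, psi, q0):
    """Per-trial value and pull-probability trajectories.

    Returns (q_traj, p_traj): q_traj[t] is the state *before* trial t's
    update (the state the choice probability p_traj[t] was computed
    from); the state after the last trial is returned separately.
    """
    n = tone.shape[0]
    q = q0.copy()
    q_traj = np.empty((n, 2, 2))
    p_traj = np.empty(n)
    for t in range(n):
        x = tone[t]
        q_traj[t] = q
        p_traj[t] = _sigmoid(q[x, 0] - q[x, 1])
        if action[t] == 1:
            q[x, 0] += alpha_l * (kappa_r * reward[t]
                                  - kappa_p * punish[t] - q[x, 0])
            q[x, 1] *= 1.0 - alpha_f
        else:
            q[x, 0] *= 1.0 - alpha_f
            q[x, 1] += alpha_l * (psi - q[x, 1])
    return q_traj, p_traj, q


@njit(cache=True, fastmath=True)
def simulate_kernel(tone, actual_action, actual_reward, actual_punish,
                    reward_prob, punish_prob, is_omission,
                    alpha_l, alpha_f, kappa_r, kappa_p, psi,
                    q0, u):
    """Generative replay of a session, one Bernoulli walk per repetition.

    The tone order is the real session's. Per trial the simulated action
    is drawn from the model's pull probability; outcomes follow the
    replay rule: if both the simulated and the real animal pulled, the
    real trial's outcomes are reused; if only the simulated agent
    pulled, outcomes are drawn from the task probabilities (with the
    omission-task punishment indicator derived as pull-without-water);
    a simulated non-pull yields no outcome.

    ``u`` has shape (n_reps, n_trials, 3): uniforms for the action draw,
    the reward draw and the air-puff draw. Returns the int8 choice
    matrix (n_reps, n_trials).
    """
    n_reps = u.shape[0]
    n = tone.shape[0]
    choices = np.empty((n_reps, n), np.int8)
    for rep in range(n_reps):
        q = q0.copy()
        for t in range(n):
            x = tone[t]
            pr = _sigmoid(q[x, 0] - q[x, 1])
            if u[rep, t, 0] < pr:
                choices[rep, t] = 1
                if actual_action[t] == 1:
                    r = actual_reward[t]
                    p = actual_punish[t]
                else:
                    r = 1.0 if u[rep, t, 1] < reward_prob[x] else 0.0
                    if is_omission:
                        p = 1.0 - r
                    else:
                        p = 1.0 if u[rep, t, 2] < punish_prob[x] else 0.0
                q[x, 0] += alpha_l * (kappa_r * r - kappa_p * p - q[x, 0])
                q[x, 1] *= 1.0 - alpha_f
            else:
                choices[rep, t] = 0
                q[x, 0] *= 1.0 - alpha_f
                q[x, 1] += alpha_l * (psi - q[x, 1])
    return choices


@njit(cache=True, fastmath=True)
def rmse_per_rep_kernel(choices, actual_action):
    """Root-mean-square error of each rep's binary choices vs the real ones."""
    n_reps, n = choices.shape
    out = np.empty(n_reps)
    for rep in range(n_reps):
        acc = 0.0
        for t in range(n):
            d = choices[rep, t] - actual_action[t]
            acc += d * d
        out[rep] = np.sqrt(acc / n)
    return out


@njit(cache=True, fastmath=True)
def generate_kernel(tone, reward_prob, punish_prob, is_omission,
                    alpha_l, alpha_f, kappa_r, kappa_p, psi, q0, u):
    """Forward-simulate an agent through a tone schedule.

    ``u`` has shape (n_trials, 3). Returns (action, physical_reward,
    physical_punish, q_traj, p_traj, final_q); the value trajectory
    holds the pre-update state for each trial.
    """
    n = tone.shape[0]
    action = np.empty(n, np.int8)
    rew = np.empty(n, np.int8)
    pun = np.empty(n, np.int8)
    q_traj = np.empty((n, 2, 2))
    p_traj = np.empty(n)
    q = q0.copy()
    for t in range(n):
        x = tone[t]
        q_traj[t] = q
        pr = _sigmoid(q[x, 0] - q[x, 1])
        p_traj[t] = pr
        if u[t, 0] < pr:
            action[t] = 1
            r = 1 if u[t, 1] < reward_prob[x] else 0
            phys_p = 1 if u[t, 2] < punish_prob[x] else 0
            rew[t] = r
            pun[t] = phys_p
            if is_omission:
                model_p = 1.0 - r
            else:
                model_p = float(phys_p)
            q[x, 0] += alpha_l * (kappa_r * r - kappa_p * model_p - q[x, 0])
            q[x, 1] *= 1.0 - alpha_f
        else:
            action[t] = 0
            rew[t] = 0
            pun[t] = 0
            q[x, 0] *= 1.0 - alpha_f
            q[x, 1] += alpha_l * (psi - q[x, 1])
    return action, rew, pun, q_traj, p_traj, q
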