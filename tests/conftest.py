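"""Shared fixtures and pure-Python oracles.

The oracles re-implement the sequential value-update / likelihood /
replay arithmetic in plain Python, independently of the package's
compiled kernels, so kernel results can be checked against a
transparent reference.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from forgetq import (Params, QState, SessionLog, TrialRecord, air_puff_task,
                     omission_task)


def make_log(rows, task_label="air_puff"):
    """Build a SessionLog from (tone, action, reward, punishment[, early])
    tuples; indices are assigned sequentially in one session."""
    trials = []
    for i, row in enumerate(rows):
        tone, action, reward, punishment = row[:4]
        early = bool(row[4]) if len(row) > 4 else False
        trials.append(TrialRecord(trial_index=i, session_id=0, tone=tone,
                                  action=action, reward=reward,
                                  punishment=punishment, early_pull=early))
    return SessionLog(trials, task_label)


def oracle_punishment(task_label, action, reward, physical):
    if action != "pull":
        return 0
    if task_label == "omission":
        return 1 if reward == 0 else 0
    return physical


def oracle_update(q_pull, q_np, tone, action, r, p, params):
    """One update step on plain dicts {tone: value}; returns new dicts."""
    q_pull, q_np = dict(q_pull), dict(q_np)
    if action == "pull":
        q_pull[tone] = q_pull[tone] + params.alpha_l * (
            params.kappa_r * r - params.kappa_p * p - q_pull[tone])
        q_np[tone] = (1 - params.alpha_f) * q_np[tone]
    else:
        q_pull[tone] = (1 - params.alpha_f) * q_pull[tone]
        q_np[tone] = q_np[tone] + params.alpha_l * (params.psi - q_np[tone])
    return q_pull, q_np


def oracle_likelihood(log, params, initial=None):
    """Likelihood as the naive sequential product of z(t) terms."""
    q_pull = {"A": 0.0, "B": 0.0}
    q_np = {"A": 0.0, "B": 0.0}
    if initial is not None:
        q_pull = {"A": initial.pull("A"), "B": initial.pull("B")}
        q_np = {"A": initial.non_pull("A"), "B": initial.non_pull("B")}
    L = 1.0
    for t in log:
        p_pull = 1.0 / (1.0 + math.exp(-(q_pull[t.tone] - q_np[t.tone])))
        z = p_pull if t.action == "pull" else 1.0 - p_pull
        z = min(max(z, 1e-12), 1 - 1e-12)
        L *= z
        p_ind = oracle_punishment(log.task_label, t.action, t.reward,
                                  t.punishment)
        q_pull, q_np = oracle_update(q_pull, q_np, t.tone, t.action,
                                     t.reward, p_ind, params)
    return L


def random_log(rng, n, task_label="air_puff"):
    """A structurally valid random log (respecting the outcome invariants)."""
    rows = []
    for _ in range(n):
        tone = "A" if rng.random() < 0.3 else "B"
        if rng.random() < 0.6:
            reward = int(rng.random() < 0.7)
            punishment = (int(rng.random() < 0.3)
                          if task_label == "air_puff" else 0)
            rows.append((tone, "pull", reward, punishment))
        else:
            rows.append((tone, "non_pull", 0, 0))
    return make_log(rows, task_label)


def random_params(rng):
    return Params(alpha_l=rng.uniform(0.05, 0.95),
                  alpha_f=rng.uniform(0.0, 0.5),
                  kappa_r=rng.uniform(0.0, 8.0),
                  kappa_p=rng.uniform(0.0, 8.0),
                  psi=rng.uniform(0.0, 4.0))


@pytest.fixture
def air_cfg():
    return air_puff_task()


@pytest.fixture
def omi_cfg():
    return omission_task()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
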