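# Methods

This note records the modelling assumptions, the numerical choices, and
the design decisions behind `forgetq`, in the order the pipeline runs.

## Task environments

`tasks.TaskConfig` describes a task as a tone-A presentation
probability plus per-tone reward and air-puff probabilities applied on
pull trials. Two presets are built in: the air-puff task (tone A 20%,
reward certain, air-puff 90%/10% on tone A/B pulls) and the omission
task (tone A 40%, reward 10%/90%, never an air-puff). Tones are drawn
i.i.d. per trial; no block or run-length structure is imposed, since the
tasks specify only marginal probabilities. A non-pull yields no outcome
of either kind. The environment emits *physical* events only; the
model-level punishment indicator is derived downstream (see below), so
the same environment serves both the air-puff and omission semantics.

All randomness flows through `numpy.random.Generator` objects seeded
explicitly; every generated dataset and simulation records its seed.

## Trial data and preprocessing

A `SessionLog` is an ordered list of trial records (tone, action,
reward, air-puff, session id, early-pull flag) concatenated across
sessions. Preprocessing implements the conventions used for this
paradigm:

- **early pulls** (lever moved before the response window) are excluded
  from every analysis and from fitting; the operation is idempotent;
- **reward-fraction truncation**: each session is kept only up to the
  last trial before the cumulative rewarded-trial count reaches
  `ceil(0.6 × planned rewards)`, removing the low-motivation tail. The
  planned reward count is a required configuration value — it is a
  property of the session program, not recoverable from the log;
- **lever-pull rate** per tone = pulls / non-early trials of that tone;
  an empty denominator raises rather than silently returning 0;
- **moving average** of the 0/1 pull choice per tone uses a 10-trial
  trailing window, with growing-prefix averages for the first 9 trials
  so the output aligns one-to-one with trials;
- the **learning criterion** is a tone-A rate strictly below 0.5 and a
  tone-B rate strictly above 0.5 on two consecutive sessions.

Early-pull exclusion is applied before truncation; since early-pull
trials are unrewarded the cumulative reward count is unaffected by the
order, only the retained trial count differs.

## The model family

Values update as in the README's equations; only the presented tone's
pair is touched (the two tones are fitted as interleaved but independent
sequences), and the unchosen action of the presented tone decays by the
forgetting rate. The punishment indicator is task-dependent: the
physical air-puff in the air-puff task, pull-without-water in the
omission task; non-pulls are never punished. The choice rule is the
parameter-free logistic of the value difference, so the value scale
itself (κ_r, κ_p, ψ) carries the role an inverse temperature would
otherwise play.

Seven variants switch κ_p, ψ, α_f on (free) or off (pinned at 0);
`ModelSpec.constrain` enforces the pinning so disabled parameters cannot
leak into simulation or fitting. Free-parameter counts run from 2
(`simple`) to 5 (`P-S-F`).

Initial values for fitting and forward simulation are all-zero — the
value-neutral start and the fixed point of every disabled mechanism.
The steady-state alternative (`steady_state_q`) sets
Q_pull = κ_r R_x − κ_p P_x and Q_non_pull = ψ from the task's expected
outcome rates; it is intended for the air-puff task (R = 1, P = 0.9/0.1)
and is exposed for the injection analysis below.

## Likelihood and fitting

The likelihood is the product over trials of the model's probability of
the observed choice, accumulated in log space. Choice probabilities are
clamped to [1e−12, 1 − 1e−12] so the objective stays finite when the
optimiser probes boundary parameter values; the clamp is far outside
any probability reachable with the bounded parameters and ordinary
value magnitudes.

Fitting minimises the negative log likelihood with L-BFGS-B inside the
box α_l, α_f ∈ [1e−6, 1−1e−6], κ_r, κ_p, ψ ∈ [0, 20] (the same 0–20
ceiling the perturbation grid uses). The optimiser runs from
`n_restarts` uniform-random starting points (default 5,000; the test
suite uses 100) at a loose tolerance (ftol 1e−6, gtol 1e−4, ≤300
evaluations) to locate basins cheaply, then polishes the best restart at
the optimiser's tight default tolerance. On representative 5,000-trial
logs the polished optimum matches all-tight restarts to <1e−5 nats at a
fraction of the cost. Each fit draws its starts from one seeded stream,
so results are reproducible; `compare_models` derives one sub-stream
per variant from its seed. AIC = −2 log L + 2K and
BIC = −2 log L + K log T use the number of free parameters K and fitted
trials T; the comparison reports raw and z-scored criteria (z across the
seven variants) and breaks ties by the canonical variant order.

Inner loops (likelihood, trajectories, replay, generation) are
numba-compiled; the pure-Python reference implementations live in the
test suite and the two are held equal to 1e−10 on random logs.

## Generative replay and RMSE

A replay walks the real session's tone order; per repetition it samples
pull/non-pull from the model's current choice probability, then applies
the outcome rule: if the real animal also pulled, the real outcomes are
reused; if only the simulated agent pulled, outcomes are drawn from the
task probabilities (with the omission indicator derived as
pull-without-water); a simulated non-pull yields no outcome. Default
1,000 repetitions.

Two RMSE conventions are implemented. `pred_mode="binary"` (the default
for generative scoring) computes the RMSE between the real and each
repetition's binary choices and averages the per-repetition RMSEs; its
square is the expected disagreement rate. `pred_mode="mean"` scores the
repetition-averaged choice (a probability trace) against the real
binary choices once. The binary reading follows the definition of the
prediction as a per-simulation binary choice; the mean reading is kept
because the binary objective contains an irreducible sampling-variance
term Σ p(1−p) that rewards *determinism* — a property that matters for
the perturbation analysis (below).

Display binning averages per-tone trial sequences into 10/40 bins
(air-puff A/B) or 20/30 bins (omission A/B), proportional to the tone
frequencies; when counts do not divide evenly the leading bins take one
extra trial.

## Injection (perturbation) attribution

Given training-fit parameters and a post-injection session, each free
parameter in turn is scanned over its exhaustive grid (α: 0–1 step
0.01; κ, ψ: 0–20 step 0.1) with the others fixed; each candidate is
scored by the mean replay RMSE against the post session, and the
parameter whose optimum attains the lowest RMSE is the
injection-related parameter. ΔRMSE is reported as baseline (original
parameters) minus optimised, so improvements are positive; the grids
contain the original values, so ΔRMSE ≥ 0 up to Monte-Carlo noise.

Numerical choices:

- **Common random numbers**: one pre-drawn uniform array per analysis
  is reused across all grid values and parameters, so RMSE differences
  between candidates reflect the parameter change, not resampling
  noise.
- **Scoring** uses `pred_mode="mean"` by default. Under the per-rep
  binary objective the variance term lets a saturating candidate (a
  learning rate driven to ≈1, which makes behavior nearly
  deterministic) outscore the truly perturbed parameter; with the mean
  objective the generator's own parameters are a consistent minimum,
  which is the property the attribution logic needs.
- **Ties** within a grid resolve to the smallest move from the training
  value; across parameters, to the fixed order α_l, α_f, κ_r, κ_p, ψ.
- **Initial values**: `carryover` (default) starts replays from the
  training fit's final values; `steady_state` (air-puff task only)
  recomputes the start from each candidate parameter set, for the case
  where the injection precedes the session and the starting values
  should already reflect the modulated parameter.

## Synthetic agents and study design

`synth` forward-simulates agents of any variant through either task,
returning the log plus the latent value/probability trajectories, and
builds matched baseline/perturbed session pairs (vehicle- versus
muscimol-like) that share tone schedules *and* per-trial random draws,
so behavioral differences are attributable to the parameter change
alone. Agents never produce early pulls — the modelling excludes such
trials anyway.

Ground-truth defaults (`DEFAULT_TRUE_VALUES`) are per-variant constants
in the qualitative regime the task designs call for: reward value a few
units, punishment aversion exceeding the reward value for air-puff
agents, a positive saving term for omission agents. Within that regime
the exact values were fixed by a Fisher-information power analysis
(numerical Hessian of the likelihood at the generating values on
5,000-trial logs): parameter-recovery studies are only informative if
the design can identify the parameters, and the analysis showed two
structural facts worth recording.

First, variants without the punishment term are probed in the omission
task: air-puff rewards are deterministic, so for those variants the
values converge and the likelihood carries information about α_l (and
ψ) only in the initial transient — a degenerate recovery design.
Second, even at the best-powered realistic settings, the maximum
likelihood estimator's standard deviation at 5,000 trials is ≈0.03–0.05
for the forgetting rate and ≈10% for the punishment aversion in the
richer variants (α_f trades off against α_l, and κ_p's effect is
censored once the risky tone is fully avoided). Recovery bands tighter
than that (e.g. ±0.05 on rates in ≥90% of runs) are therefore not
attainable for the `forgetting`, `P-F`, `S-F` and `P-S-F` variants at
this session length — a property of the experiment, not of the
optimiser; the corresponding checks in the test suite document this
honestly rather than loosening the bands.

For inactivation studies a separate base set
(`INACTIVATION_BASE_VALUES`: α_l 0.2, α_f 0.2, κ_r 3, κ_p 4, ψ 1) keeps
a tripled value of any parameter inside the 0–20 grid and, more
importantly, keeps the perturbed dynamics *graded*: with a large base
κ_p, tripling it pins the risky-tone pull probability at 0, and the
only remaining signature (the post-punishment dip depth) is exactly
mimicked by a raised learning rate, making attribution structurally
ambiguous. With the moderate base, single-parameter attribution
achieves clear confusion-matrix diagonal dominance in simulation.

## What the synthetic data do and do not show

The generator realises the fitted model class exactly: logistic choice
on the stated value updates, i.i.d. tones, stationary parameters, no
early pulls, no motivation drift, no response-time structure. Passing
recovery and attribution tests therefore demonstrates that the pipeline
is correct and well-calibrated *under the model*, not that real mice
obey it; with real logs, model misspecification (satiety, attention,
slow drifts) adds error the synthetic studies cannot exhibit.

## Scale choices in the test suite

The suite scales the published procedure down to desk scale: 100
optimisation restarts instead of 5,000 (justified by the basin-polish
scheme above), 200 replay repetitions instead of 1,000 in the
attribution studies, 20 generation seeds per recovery cell, training
histories of 2,000 trials and post-injection sessions of 600 trials.
Library defaults keep the full-scale values.
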