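"""Arbitration between Pavlovian and instrumental control.

Two Beta-Bernoulli reward predictors learn in parallel: a stimulus-only
predictor (posterior means ``theta_s``) and a stimulus-action predictor
(``theta_sa``). Both use the same incremental rule — a counter ``eta``
starts at the prior confidence ``eta0`` and increments on every encounter,
and the posterior mean moves by the prediction error divided by the counter,
which is exactly the running average seeded with ``eta0`` pseudo-observations
of the prior mean ``theta0``.

A log-odds accumulator ``L`` tracks the posterior belief that outcomes are
uncontrollable: each trial adds the log ratio of the two predictors'
one-step predictive probabilities for the observed reward. The Pavlovian
weight ``w = sigmoid(L)`` mixes the two action values; the fixed-weight
variant instead holds ``w`` constant as a free parameter. Choices are
softmax in the integrated values with inverse temperature ``beta``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from pavarb._rng import substream
from pavarb.task import (
    Action,
    Stimulus,
    TaskConfig,
    TrialRecord,
    sample_outcome,
    sample_trial_sequence,
)

#: Clip bound applied to predictive means before taking logs. Unreachable
#: with eta0 > 0 and theta0 in (0, 1); guards degenerate configurations.
CLIP_EPS = 1e-6


class Variant(str, enum.Enum):
    ADAPTIVE = "adaptive"
    FIXED = "fixed"


@dataclass(frozen=True)
class PriorParams:
    """Prior mean and prior confidence of one Beta-Bernoulli predictor."""

    theta0: float
    eta0: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 < 1.0:
            raise ValueError(f"theta0 must be in (0, 1), got {self.theta0}")
        if not self.eta0 > 0.0:
            raise ValueError(f"eta0 must be positive, got {self.eta0}")


@dataclass(frozen=True)
class ModelSpec:
    """Which arbitration variant to run, plus its free parameters.

    ``prior_uncontrollable`` seeds the stimulus-only predictor,
    ``prior_controllable`` the stimulus-action predictor. ``w_fixed`` is
    required by the FIXED variant and forbidden for ADAPTIVE. ``L0`` is the
    initial log-odds of the uncontrollable environment (default 0.5, i.e.
    initial weight sigmoid(0.5) ~= 0.6225); it is held fixed, not fitted.
    """

    variant: Variant
    beta: float
    prior_uncontrollable: PriorParams
    prior_controllable: PriorParams
    w_fixed: float | None = None
    L0: float = 0.5

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.variant is Variant.FIXED:
            if self.w_fixed is None or not 0.0 <= self.w_fixed <= 1.0:
                raise ValueError("FIXED variant requires w_fixed in [0, 1]")
        elif self.w_fixed is not None:
            raise ValueError("ADAPTIVE variant takes no w_fixed")

    @property
    def n_params(self) -> int:
        return 6 if self.variant is Variant.FIXED else 5

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant.value,
            "beta": self.beta,
            "prior_uncontrollable": {
                "theta0": self.prior_uncontrollable.theta0,
                "eta0": self.prior_uncontrollable.eta0,
            },
            "prior_controllable": {
                "theta0": self.prior_controllable.theta0,
                "eta0": self.prior_controllable.eta0,
            },
            "L0": self.L0,
        }
        if self.w_fixed is not None:
            d["w_fixed"] = self.w_fixed
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            variant=Variant(d["variant"]),
            beta=float(d["beta"]),
            prior_uncontrollable=PriorParams(**d["prior_uncontrollable"]),
            prior_controllable=PriorParams(**d["prior_controllable"]),
            w_fixed=d.get("w_fixed"),
            L0=float(d.get("L0", 0.5)),
        )


@dataclass
class LearnerState:
    """Evolving beliefs of one agent within one block."""

    theta_s: dict[Stimulus, float]
    theta_sa: dict[tuple[Stimulus, Action], float]
    eta_s: dict[Stimulus, float]
    eta_sa: dict[tuple[Stimulus, Action], float]
    L: float


def sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def _log_sigmoid(x: float) -> float:
    if x >= 0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


def init_state(model_spec: ModelSpec, stimuli: Iterable[Stimulus]) -> LearnerState:
    """Fresh learner state: predictor tables at their prior means, L at L0."""
    stimuli = list(stimuli)
    if not stimuli:
        raise ValueError("stimulus set must be non-empty")
    pu, pc = model_spec.prior_uncontrollable, model_spec.prior_controllable
    return LearnerState(
        theta_s={s: pu.theta0 for s in stimuli},
        theta_sa={(s, a): pc.theta0 for s in stimuli for a in Action},
        eta_s={s: pu.eta0 for s in stimuli},
        eta_sa={(s, a): pc.eta0 for s in stimuli for a in Action},
        L=model_spec.L0,
    )


def pavlovian_weight(state: LearnerState, model_spec: ModelSpec) -> float:
    """Current mixing weight: sigmoid(L) for ADAPTIVE, w_fixed for FIXED."""
    if model_spec.variant is Variant.FIXED:
        return float(model_spec.w_fixed)  # type: ignore[arg-type]
    return sigmoid(state.L)


def update_means(state: LearnerState, s: Stimulus, a: Action, r: int) -> LearnerState:
    """Incremental posterior-mean update after observing reward ``r``.

    The stimulus-only mean updates on every trial of ``s``; only the chosen
    (s, a) entry of the stimulus-action table updates. Counters increment
    first, then the mean moves by prediction-error / counter.
    """
    if r not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {r!r}")
    state.eta_s[s] += 1
    state.theta_s[s] += (r - state.theta_s[s]) / state.eta_s[s]
    state.eta_sa[(s, a)] += 1
    state.theta_sa[(s, a)] += (r - state.theta_sa[(s, a)]) / state.eta_sa[(s, a)]
    return state


def update_logodds(state: LearnerState, s: Stimulus, a: Action, r: int) -> LearnerState:
    """Accumulate the predictive log-odds of the uncontrollable environment.

    Uses the PRE-update predictive means for this trial: the increment is the
    log ratio of the two predictors' probabilities of the observed reward.
    """
    if r not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {r!r}")
    th_s = min(max(state.theta_s[s], CLIP_EPS), 1.0 - CLIP_EPS)
    th_sa = min(max(state.theta_sa[(s, a)], CLIP_EPS), 1.0 - CLIP_EPS)
    if r:
        state.L += math.log(th_s / th_sa)
    else:
        state.L += math.log((1.0 - th_s) / (1.0 - th_sa))
    return state


def action_values(
    state: LearnerState, s: Stimulus, model_spec: ModelSpec
) -> tuple[float, float]:
    """Integrated (V_go, V_nogo): weighted mix of the two predictors.

    The Pavlovian value invigorates Go (value theta_s) and contributes 0 to
    No-Go; the instrumental values are the stimulus-action means.
    """
    w = pavlovian_weight(state, model_spec)
    v_go = w * state.theta_s[s] + (1.0 - w) * state.theta_sa[(s, Action.GO)]
    v_nogo = (1.0 - w) * state.theta_sa[(s, Action.NOGO)]
    return v_go, v_nogo


def choice_probability(values: tuple[float, float], beta: float) -> float:
    """Softmax probability of Go given (V_go, V_nogo)."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return sigmoid(beta * (values[0] - values[1]))


def step(
    state: LearnerState, s: Stimulus, a: Action, r: int, model_spec: ModelSpec
) -> LearnerState:
    """One learning step: log-odds from pre-update means (ADAPTIVE only),
    then the mean updates. FIXED skips the log-odds dynamics entirely."""
    if model_spec.variant is Variant.ADAPTIVE:
        update_logodds(state, s, a, r)
    return update_means(state, s, a, r)


def simulate_agent(
    model_spec: ModelSpec,
    task_config: TaskConfig,
    seed: int,
    participant_id: str = "sim",
) -> tuple[list[TrialRecord], list[float]]:
    """Simulate one full session; returns trials and the per-trial weight.

    Actions are softmax draws, outcomes Bernoulli draws from the task
    contingencies. The recorded weight is the one in force when the trial's
    choice was made. Learner state (including L) resets at block boundaries:
    each block presents new stimuli and its own controllability regime.
    """
    rng = substream(seed, "simulate", participant_id)
    trials: list[TrialRecord] = []
    weights: list[float] = []
    sequence = sample_trial_sequence(task_config)
    state: LearnerState | None = None
    current_block = -1
    for trial_index, (stimulus, block) in enumerate(sequence):
        if block != current_block:
            state = init_state(model_spec, task_config.block_stimuli(block))
            current_block = block
        assert state is not None
        w = pavlovian_weight(state, model_spec)
        p_go = choice_probability(action_values(state, stimulus, model_spec), model_spec.beta)
        action = Action.GO if rng.random() < p_go else Action.NOGO
        spec = task_config.spec_for(stimulus)
        reward = sample_outcome(spec, action, rng)
        step(state, stimulus, action, reward, model_spec)
        weights.append(w)
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                experiment=task_config.experiment,
                condition=task_config.block_order[block],
                block_index=block,
                trial_index=trial_index,
                stimulus=stimulus,
                action=action,
                reward=reward,
                optimal_action=spec.optimal_action,
            )
        )
    return trials, weights


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _validate_session(trials: Sequence[TrialRecord]) -> None:
    if not trials:
        raise ValueError("empty trial list")
    pids = {t.participant_id for t in trials}
    if len(pids) > 1:
        raise ValueError(f"trials mix participants: {sorted(pids)}")
    idx = [t.trial_index for t in trials]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("trials not sorted by trial_index")


def compile_session(
    trials: Sequence[TrialRecord],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, int]]:
    """Pre-encode a session into per-block integer arrays for fast likelihood.

    Each entry is (stimulus codes, action codes with GO=0, rewards,
    n distinct stimuli) for one block, in presentation order.
    """
    _validate_session(trials)
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]] = []
    for block in sorted({t.block_index for t in trials}):
        sub = [t for t in trials if t.block_index == block]
        stim_ids = sorted({t.stimulus for t in sub}, key=lambda s: s.value)
        code = {s: i for i, s in enumerate(stim_ids)}
        blocks.append(
            (
                np.array([code[t.stimulus] for t in sub], dtype=np.int64),
                np.array([0 if t.action is Action.GO else 1 for t in sub], dtype=np.int64),
                np.array([t.reward for t in sub], dtype=np.int64),
                len(stim_ids),
            )
        )
    return blocks


def _loglik_compiled(
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]],
    beta: float,
    theta0_u: float,
    eta0_u: float,
    theta0_c: float,
    eta0_c: float,
    w_fixed: float | None,
    L0: float,
) -> float:
    """Session log-likelihood on pre-encoded blocks (hot path: plain floats)."""
    adaptive = w_fixed is None
    lo, hi = CLIP_EPS, 1.0 - CLIP_EPS
    ll = 0.0
    for stim, act, rew, n_stim in blocks:
        th_s = [theta0_u] * n_stim
        eta_s = [eta0_u] * n_stim
        th_sa = [[theta0_c, theta0_c] for _ in range(n_stim)]
        eta_sa = [[eta0_c, eta0_c] for _ in range(n_stim)]
        L = L0
        stim_l = stim.tolist()
        act_l = act.tolist()
        rew_l = rew.tolist()
        for s, a, r in zip(stim_l, act_l, rew_l):
            if adaptive:
                w = sigmoid(L)
            else:
                w = w_fixed
            row = th_sa[s]
            dv = beta * (w * th_s[s] + (1.0 - w) * row[0] - (1.0 - w) * row[1])
            ll += _log_sigmoid(dv if a == 0 else -dv)
            if adaptive:
                ths = th_s[s]
                ths = lo if ths < lo else (hi if ths > hi else ths)
                thsa = row[a]
                thsa = lo if thsa < lo else (hi if thsa > hi else thsa)
                if r:
                    L += math.log(ths / thsa)
                else:
                    L += math.log((1.0 - ths) / (1.0 - thsa))
            eta_s[s] += 1
            th_s[s] += (r - th_s[s]) / eta_s[s]
            era = eta_sa[s]
            era[a] += 1
            row[a] += (r - row[a]) / era[a]
    return ll


def session_loglik(model_spec: ModelSpec, trials: Sequence[TrialRecord]) -> float:
    """Total log-likelihood of one participant's choices under a model.

    State evolves exactly as in :func:`simulate_agent` (reset per block);
    each trial contributes log P(chosen action | stimulus) with the weight
    and values in force before that trial's update.
    """
    blocks = compile_session(trials)
    return _loglik_compiled(
        blocks,
        beta=model_spec.beta,
        theta0_u=model_spec.prior_uncontrollable.theta0,
        eta0_u=model_spec.prior_uncontrollable.eta0,
        theta0_c=model_spec.prior_controllable.theta0,
        eta0_c=model_spec.prior_controllable.eta0,
        w_fixed=model_spec.w_fixed if model_spec.variant is Variant.FIXED else None,
        L0=model_spec.L0,
    )


def weight_timeseries(
    model_spec: ModelSpec, trials: Sequence[TrialRecord]
) -> list[float]:
    """Per-trial Pavlovian weight implied by a model for observed trials.

    Replays the learner over the participant's actual (s, a, r) history and
    records the weight in force on each trial.
    """
    _validate_session(trials)
    weights: list[float] = []
    state: LearnerState | None = None
    current_block = -1
    for t in trials:
        if t.block_index != current_block:
            stimuli = sorted(
                {u.stimulus for u in trials if u.block_index == t.block_index},
                key=lambda s: s.value,
            )
            state = init_state(model_spec, stimuli)
            current_block = t.block_index
        assert state is not None
        weights.append(pavlovian_weight(state, model_spec))
        step(state, t.stimulus, t.action, t.reward, model_spec)
    return weights


def simulate_cohort(
    model_spec: ModelSpec,
    experiment,
    n_agents: int,
    seed: int,
    condition=None,
    id_prefix: str = "agent",
) -> tuple[list[TrialRecord], "np.ndarray"]:
    """Simulate ``n_agents`` independent sessions; returns pooled trials and
    an (n_agents, n_trials) weight matrix. Agent i uses substream (seed, i)."""
    from pavarb.task import build_task_config  # local import to avoid cycle

    all_trials: list[TrialRecord] = []
    all_weights = []
    for i in range(n_agents):
        pid = f"{id_prefix}{i:03d}"
        config = build_task_config(experiment, condition, seed=int(seed) * 100003 + i)
        trials, weights = simulate_agent(model_spec, config, seed=seed, participant_id=pid)
        all_trials.extend(trials)
        all_weights.append(weights)
    return all_trials, np.array(all_weights)
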