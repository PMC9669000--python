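"""Generative agents for synthetic cohorts.

The agent couples a Rescorla–Wagner learner over cards with a second,
*outcome-irrelevant* learner over response keys: after each offer the
obtained reward updates both the chosen card's value Q and the pressed
key's value V, and the next choice follows a softmax over the sum
Q(card) + V(key-on-that-side).  A nonzero key learning rate ``alpha_key``
therefore produces the behavioural signature measured downstream — a
reward-dependent tendency to repeat the response key across the two offers
of a trial.  Memory probes are answered by a slot model: ``min(kappa, N)``
of the N array items are encoded; unencoded probes are guessed.

This module is a data generator with known ground truth, not a model fitted
to data; the downstream analysis is regression-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InputError
from .io import validate_probe_log, validate_trial_log
from .task_env import (
    TaskConfig,
    generate_walk,
    plan_capacity_session,
    plan_trial,
    sample_outcome,
)

RT_MIN_MS = 200.0
RT_MAX_MS = 4000.0


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated subject."""

    alpha_card: float = 0.3
    alpha_key: float = 0.3
    beta: float = 3.0
    kappa: float = 3.0
    guess: float = 0.5  # P(respond 'same') when the probed item is unencoded
    rt_meanlog: float = 6.55
    rt_sdlog: float = 0.35
    p_fast: float = 0.01
    p_slow: float = 0.008
    lapse_no_load: float = 0.06

    def __post_init__(self) -> None:
        for name in ("alpha_card", "alpha_key", "guess", "p_fast", "p_slow", "lapse_no_load"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.beta < 0 or self.kappa < 0:
            raise ConfigurationError("beta and kappa must be >= 0")


@dataclass
class AgentState:
    """Card values Q and response-key values V for the current block."""

    Q: dict[int, float]
    V: dict[str, float]


def init_state(block_cards, q0: float = 0.5, v0: float = 0.0) -> AgentState:
    """Fresh block state: cards at the reward midpoint, keys neutral."""
    return AgentState(Q={int(c): q0 for c in block_cards}, V={"left": v0, "right": v0})


def choice_prob_left(state: AgentState, offer, beta: float) -> float:
    """P(choose the left card) under the additive card+key softmax."""
    cl, cr = offer
    if cl not in state.Q or cr not in state.Q:
        raise InputError(f"offer {offer} contains cards outside the block state {sorted(state.Q)}")
    diff = (state.Q[cl] + state.V["left"]) - (state.Q[cr] + state.V["right"])
    return 1.0 / (1.0 + math.exp(-beta * diff))


def choose(state: AgentState, offer, beta: float, rng: np.random.Generator):
    """Sample a choice; returns ``(chosen_card, chosen_key)``."""
    p_left = choice_prob_left(state, offer, beta)
    if rng.random() < p_left:
        return offer[0], "left"
    return offer[1], "right"


def update(
    state: AgentState,
    chosen_card: int,
    chosen_key: str,
    reward: int,
    alpha_card: float,
    alpha_key: float,
) -> AgentState:
    """Delta-rule credit assignment to the chosen card *and* pressed key."""
    if reward not in (0, 1):
        raise InputError(f"reward must be 0 or 1, got {reward}")
    state.Q[chosen_card] += alpha_card * (reward - state.Q[chosen_card])
    state.V[chosen_key] += alpha_key * (reward - state.V[chosen_key])
    return state


def respond_probe(
    kappa: float,
    set_size: int,
    probe_is_same: bool,
    guess: float,
    rng: np.random.Generator,
):
    """Slot-model probe response; returns ``(response_same, correct)``.

    The probed item is encoded with probability ``min(kappa, N) / N`` and
    then answered correctly; otherwise the agent responds 'same' with
    probability ``guess``.  With balanced probes and guess = 0.5 the
    accuracy is ``kappa/N + (1 - kappa/N)/2``, whose inversion is exactly
    the K = N(2·accuracy − 1) capacity formula.
    """
    if set_size < 1:
        raise InputError("set_size must be >= 1")
    p_encoded = min(kappa, set_size) / set_size
    if rng.random() < p_encoded:
        response_same = bool(probe_is_same)
    else:
        response_same = bool(rng.random() < guess)
    return int(response_same), int(response_same == bool(probe_is_same))


@dataclass(frozen=True)
class CohortSpec:
    """Population the cohort is drawn from.

    ``alpha_key_link`` is the slope of the capacity→alpha_key relation in
    units of alpha_key per memory item; a negative value makes low-capacity
    agents stronger outcome-irrelevant learners.  All draws are clipped into
    their parameter domains.
    """

    n_subjects: int = 40
    kappa_mean: float = 3.0
    kappa_sd: float = 1.0
    alpha_key_mean: float = 0.3
    alpha_key_link: float = -0.08
    alpha_key_resid_sd: float = 0.05
    alpha_card_mean: float = 0.3
    alpha_card_sd: float = 0.1
    beta_mean: float = 3.0
    beta_sd: float = 1.0
    guess: float = 0.5
    rt_meanlog: float = 6.55
    rt_sdlog: float = 0.35
    p_fast: float = 0.01
    p_slow: float = 0.008
    lapse_no_load: float = 0.06
    capacity_trials: int = 120
    reset_key_values_per_block: bool = True
    integer_slots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.kappa_sd < 0 or self.alpha_card_sd < 0 or self.beta_sd < 0 or self.alpha_key_resid_sd < 0:
            raise ConfigurationError("spread parameters must be >= 0")


def draw_agent_params(spec: CohortSpec, rng: np.random.Generator) -> list[AgentParams]:
    """Sample per-subject parameters; the capacity→alpha_key link acts here."""
    kappa = np.clip(rng.normal(spec.kappa_mean, spec.kappa_sd, spec.n_subjects), 0.25, 7.5)
    if spec.integer_slots:
        kappa = np.round(kappa)
    alpha_key = np.clip(
        spec.alpha_key_mean
        + spec.alpha_key_link * (kappa - spec.kappa_mean)
        + rng.normal(0.0, spec.alpha_key_resid_sd, spec.n_subjects),
        0.0,
        1.0,
    )
    alpha_card = np.clip(rng.normal(spec.alpha_card_mean, spec.alpha_card_sd, spec.n_subjects), 0.01, 0.99)
    beta = np.clip(rng.normal(spec.beta_mean, spec.beta_sd, spec.n_subjects), 0.1, 12.0)
    return [
        AgentParams(
            alpha_card=float(alpha_card[i]),
            alpha_key=float(alpha_key[i]),
            beta=float(beta[i]),
            kappa=float(kappa[i]),
            guess=spec.guess,
            rt_meanlog=spec.rt_meanlog,
            rt_sdlog=spec.rt_sdlog,
            p_fast=spec.p_fast,
            p_slow=spec.p_slow,
            lapse_no_load=spec.lapse_no_load,
        )
        for i in range(spec.n_subjects)
    ]


def _draw_rt(params: AgentParams, rng: np.random.Generator, contaminate: bool = True) -> float:
    """Lognormal RT clipped into the plausible band, with optional
    fast/slow contamination that the downstream filter must catch."""
    if contaminate:
        u = rng.random()
        if u < params.p_fast:
            return float(rng.uniform(80.0, RT_MIN_MS - 1.0))
        if u < params.p_fast + params.p_slow:
            return float(rng.uniform(RT_MAX_MS + 1.0, 5500.0))
    rt = float(rng.lognormal(params.rt_meanlog, params.rt_sdlog))
    return float(np.clip(rt, RT_MIN_MS, RT_MAX_MS))


_DUAL_SET_SIZE = {"low": 1, "high": 4}


def _simulate_subject(
    subject_id: str,
    params: AgentParams,
    task: TaskConfig,
    spec: CohortSpec,
    rng: np.random.Generator,
):
    trial_rows, probe_rows = [], []
    blocks_per_session = max(1, task.n_blocks // 2) if task.n_blocks > 1 else 1
    state = None
    for b, load in enumerate(task.load_schedule):
        cards = [b * task.cards_per_block + i for i in range(task.cards_per_block)]
        walk = generate_walk(task.walk, task.cards_per_block, task.trials_per_block, rng)
        fixed_color = int(rng.integers(task.n_colors))
        if state is None or spec.reset_key_values_per_block:
            v_carry = {"left": 0.0, "right": 0.0}
        else:
            v_carry = state.V
        state = init_state(cards)
        state.V = dict(v_carry)
        session = 1 + (b // blocks_per_session if task.n_blocks > 1 else 0)
        session = min(session, 2)
        for t in range(task.trials_per_block):
            plan = plan_trial(cards, load, fixed_color, rng)
            for oi, offer in enumerate(plan.offers):
                card, key = choose(state, offer, params.beta, rng)
                reward = sample_outcome(walk, card - cards[0], t, rng)
                update(state, card, key, reward, params.alpha_card, params.alpha_key)
                trial_rows.append(
                    {
                        "subject_id": subject_id,
                        "session": session,
                        "block": b + 1,
                        "trial": t + 1,
                        "offer_index": oi + 1,
                        "load": load,
                        "card_left": offer.card_left,
                        "card_right": offer.card_right,
                        "chosen_card": card,
                        "chosen_key": key,
                        "rt_ms": round(_draw_rt(params, rng), 1),
                        "reward": reward,
                        "true_p_left": round(float(walk.probs[offer.card_left - cards[0], t]), 4),
                        "true_p_right": round(float(walk.probs[offer.card_right - cards[0], t]), 4),
                    }
                )
            if load == "none":
                correct = int(rng.random() >= params.lapse_no_load)
                response_same = int(plan.probe.is_same if correct else not plan.probe.is_same)
                set_size = 1
            else:
                set_size = _DUAL_SET_SIZE[load]
                response_same, correct = respond_probe(
                    params.kappa, set_size, plan.probe.is_same, params.guess, rng
                )
            probe_rows.append(
                {
                    "subject_id": subject_id,
                    "task": "dual",
                    "block": b + 1,
                    "trial": t + 1,
                    "set_size": set_size,
                    "load": load,
                    "probe_same": int(plan.probe.is_same),
                    "response_same": response_same,
                    "correct": correct,
                    "rt_ms": round(_draw_rt(params, rng, contaminate=False), 1),
                }
            )
    for i, cap_plan in enumerate(plan_capacity_session(spec.capacity_trials, rng)):
        response_same, correct = respond_probe(
            params.kappa, cap_plan.set_size, cap_plan.probe.is_same, params.guess, rng
        )
        probe_rows.append(
            {
                "subject_id": subject_id,
                "task": "standalone",
                "block": 0,
                "trial": i + 1,
                "set_size": cap_plan.set_size,
                "load": "none",
                "probe_same": int(cap_plan.probe.is_same),
                "response_same": response_same,
                "correct": correct,
                "rt_ms": round(_draw_rt(params, rng, contaminate=False), 1),
            }
        )
    return trial_rows, probe_rows


def simulate_cohort(cohort: CohortSpec, task: TaskConfig):
    """Simulate a full cohort through the dual task and the capacity session.

    Returns ``(trial_log, probe_log, ground_truth)`` DataFrames, all
    schema-validated before being handed downstream.  All randomness flows
    from ``(cohort.seed, task.seed)`` through named substreams, so identical
    specs reproduce identical tables.
    """
    root = np.random.SeedSequence([int(cohort.seed), int(task.seed), 0x01EA])
    param_ss, *subject_ss = root.spawn(1 + cohort.n_subjects)
    params = draw_agent_params(cohort, np.random.default_rng(param_ss))
    trial_rows, probe_rows, truth_rows = [], [], []
    for i, (p, ss) in enumerate(zip(params, subject_ss)):
        sid = f"S{i + 1:03d}"
        t_rows, p_rows = _simulate_subject(sid, p, task, cohort, np.random.default_rng(ss))
        trial_rows.extend(t_rows)
        probe_rows.extend(p_rows)
        truth_rows.append(
            {
                "subject_id": sid,
                "alpha_card": p.alpha_card,
                "alpha_key": p.alpha_key,
                "beta": p.beta,
                "kappa": p.kappa,
            }
        )
    trial_log = pd.DataFrame(trial_rows)
    probe_log = pd.DataFrame(probe_rows)
    truth = pd.DataFrame(truth_rows)
    try:
        validate_trial_log(trial_log)
        validate_probe_log(probe_log)
    except Exception as exc:  # pragma: no cover - generation bug guard
        raise DataError(f"generated cohort failed schema validation: {exc}") from exc
    if set(truth["subject_id"]) != set(trial_log["subject_id"]) or set(truth["subject_id"]) != set(
        probe_log["subject_id"]
    ):
        raise DataError("ground truth and logs disagree on subject ids")
    return trial_log, probe_log, truth


def null_cohort(spec: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A cohort with no outcome-irrelevant learning and no capacity link."""
    base = spec or CohortSpec()
    return replace(base, alpha_key_mean=0.0, alpha_key_link=0.0, alpha_key_resid_sd=0.0, **overrides)
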