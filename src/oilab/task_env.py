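"""Structure of the dual reinforcement-learning / change-detection experiment.

The experiment is a restless four-card bandit: on every trial the computer
deals the block's four cards, without replacement, into two successive
two-card offers, and the chosen card pays 0 or 1 with a probability that
drifts across trials as a reflected Gaussian random walk.  Each bandit trial
is sandwiched between the encoding and probe phases of a change-detection
task whose memory array depends on the block's load condition (a fixed
colour, one random colour, or four random colours out of nine).  A separate
single-probe change-detection session with set sizes four and eight measures
working-memory capacity.

Everything here is deterministic given a :class:`numpy.random.Generator`;
no wall-clock or pixel-level timing is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError, InputError
from .io import LOAD_LEVELS

CARDS_PER_BLOCK = 4
N_COLORS = 9


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the per-card reward-probability random walk.

    ``step_sd`` is in probability units per trial.  Values stepping outside
    ``bounds`` are reflected back inside (default) or clipped.
    """

    step_sd: float = 0.025
    bounds: tuple[float, float] = (0.2, 0.8)
    init_range: tuple[float, float] = (0.3, 0.7)
    reflect: bool = True

    def __post_init__(self) -> None:
        low, high = self.bounds
        ilow, ihigh = self.init_range
        if not (0.0 <= low < high <= 1.0):
            raise ConfigurationError(f"walk bounds must satisfy 0 <= low < high <= 1, got {self.bounds}")
        if self.step_sd < 0:
            raise ConfigurationError(f"step_sd must be >= 0, got {self.step_sd}")
        if not (low <= ilow <= ihigh <= high):
            raise ConfigurationError("init_range must lie within bounds")


@dataclass
class RewardWalk:
    """Latent reward probabilities, indexed ``probs[card, trial]``."""

    probs: np.ndarray
    config: WalkConfig

    @property
    def n_cards(self) -> int:
        return self.probs.shape[0]

    @property
    def n_trials(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class TaskConfig:
    """Block/trial structure of the dual task."""

    n_blocks: int = 6
    trials_per_block: int = 50
    cards_per_block: int = CARDS_PER_BLOCK
    load_schedule: tuple[str, ...] = ("none", "low", "high", "none", "low", "high")
    n_colors: int = N_COLORS
    walk: WalkConfig = field(default_factory=WalkConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cards_per_block != CARDS_PER_BLOCK:
            raise ConfigurationError(f"cards_per_block is fixed at {CARDS_PER_BLOCK}")
        if self.n_colors != N_COLORS:
            raise ConfigurationError(f"n_colors is fixed at {N_COLORS}")
        if len(self.load_schedule) != self.n_blocks:
            raise ConfigurationError("load_schedule length must equal n_blocks")
        bad = [l for l in self.load_schedule if l not in LOAD_LEVELS]
        if bad:
            raise ConfigurationError(f"unknown load conditions: {bad}")
        if self.n_blocks < 1 or self.trials_per_block < 2:
            raise ConfigurationError("need >= 1 block and >= 2 trials per block")


class Offer(NamedTuple):
    card_left: int
    card_right: int


class Probe(NamedTuple):
    position: int
    color: int
    is_same: bool


@dataclass
class TrialPlan:
    """One dual-task trial: memory array, two card offers, and the probe."""

    load: str
    memory_items: tuple[tuple[int, int], ...]  # (position, color)
    offers: tuple[Offer, Offer]
    probe: Probe
    block: int = -1
    trial: int = -1

    @property
    def offer1_cards(self) -> frozenset[int]:
        return frozenset(self.offers[0])

    @property
    def offer2_cards(self) -> frozenset[int]:
        return frozenset(self.offers[1])


@dataclass
class CapacityTrialPlan:
    """One standalone change-detection trial."""

    set_size: int
    array_items: tuple[tuple[int, int], ...]  # (position, color)
    probe: Probe


def _reflect_into(x: np.ndarray, low: float, high: float) -> np.ndarray:
    """Fold values into [low, high] by reflection at both bounds."""
    span = high - low
    y = np.mod(x - low, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return low + y


def generate_walk(
    config: WalkConfig, n_cards: int, n_trials: int, rng: np.random.Generator
) -> RewardWalk:
    """Simulate reflected Gaussian random walks of reward probabilities.

    Column 0 is drawn uniformly from ``config.init_range``; each subsequent
    column adds an independent N(0, step_sd^2) increment, reflecting (or
    clipping, if ``reflect`` is false) at the bounds.
    """
    if n_cards < 1 or n_trials < 1:
        raise InputError("n_cards and n_trials must be >= 1")
    low, high = config.bounds
    probs = np.empty((n_cards, n_trials))
    probs[:, 0] = rng.uniform(*config.init_range, size=n_cards)
    if n_trials > 1:
        steps = rng.normal(0.0, config.step_sd, size=(n_cards, n_trials - 1))
        for t in range(1, n_trials):
            raw = probs[:, t - 1] + steps[:, t - 1]
            if config.reflect:
                probs[:, t] = _reflect_into(raw, low, high)
            else:
                probs[:, t] = np.clip(raw, low, high)
    return RewardWalk(probs=probs, config=config)


def _memory_array(load: str, block_fixed_color: int, rng: np.random.Generator):
    if load == "none":
        return ((0, int(block_fixed_color)),)
    if load == "low":
        return ((0, int(rng.integers(N_COLORS))),)
    if load == "high":
        colors = rng.choice(N_COLORS, size=4, replace=False)
        return tuple((pos, int(c)) for pos, c in enumerate(colors))
    raise InputError(f"unknown load condition {load!r}")


def _plan_probe(items, rng: np.random.Generator) -> Probe:
    positions = [p for p, _ in items]
    colors = {c for _, c in items}
    idx = int(rng.integers(len(items)))
    position, shown = items[idx]
    if rng.random() < 0.5:
        return Probe(position=position, color=shown, is_same=True)
    unused = [c for c in range(N_COLORS) if c not in colors]
    return Probe(position=position, color=int(rng.choice(unused)), is_same=False)


def plan_trial(
    block_cards, load: str, block_fixed_color: int, rng: np.random.Generator
) -> TrialPlan:
    """Plan one dual-task trial.

    The four block cards are partitioned uniformly at random into two
    unordered offer pairs (each of the three pairings has probability 1/3),
    left/right sides are assigned independently and uniformly within each
    offer, and the probe is 'same' with probability 1/2 (otherwise a colour
    absent from the memory array).
    """
    cards = list(block_cards)
    if len(cards) != CARDS_PER_BLOCK or len(set(cards)) != CARDS_PER_BLOCK:
        raise InputError(f"plan_trial needs exactly {CARDS_PER_BLOCK} distinct cards, got {block_cards}")
    if load not in LOAD_LEVELS:
        raise InputError(f"unknown load condition {load!r}")
    order = rng.permutation(CARDS_PER_BLOCK)
    pairs = [(cards[order[0]], cards[order[1]]), (cards[order[2]], cards[order[3]])]
    offers = []
    for a, b in pairs:
        if rng.random() < 0.5:
            offers.append(Offer(card_left=a, card_right=b))
        else:
            offers.append(Offer(card_left=b, card_right=a))
    items = _memory_array(load, block_fixed_color, rng)
    probe = _plan_probe(items, rng)
    return TrialPlan(load=load, memory_items=items, offers=(offers[0], offers[1]), probe=probe)


def sample_outcome(walk: RewardWalk, card: int, trial: int, rng: np.random.Generator) -> int:
    """Bernoulli reward draw for ``card`` at ``trial`` under the walk."""
    if not (0 <= card < walk.n_cards) or not (0 <= trial < walk.n_trials):
        raise InputError(f"card/trial indices ({card}, {trial}) outside walk dimensions {walk.probs.shape}")
    return int(rng.random() < walk.probs[card, trial])


def plan_capacity_session(n_trials: int = 120, rng: np.random.Generator | None = None):
    """Plan a standalone change-detection session.

    Set sizes 4 and 8 and same/different probes are fully balanced (so
    ``n_trials`` must be divisible by 4), then shuffled.
    """
    if rng is None:
        raise InputError("an explicit rng is required")
    if n_trials % 4 != 0:
        raise InputError("n_trials must be divisible by 4 for a balanced session")
    conditions = [(s, same) for s in (4, 8) for same in (True, False) for _ in range(n_trials // 4)]
    order = rng.permutation(len(conditions))
    plans = []
    for i in order:
        set_size, want_same = conditions[i]
        colors = rng.choice(N_COLORS, size=set_size, replace=False)
        items = tuple((pos, int(c)) for pos, c in enumerate(colors))
        idx = int(rng.integers(set_size))
        position, shown = items[idx]
        if want_same:
            probe = Probe(position=position, color=shown, is_same=True)
        else:
            unused = [c for c in range(N_COLORS) if c not in set(colors.tolist())]
            probe = Probe(position=position, color=int(rng.choice(unused)), is_same=False)
        plans.append(CapacityTrialPlan(set_size=set_size, array_items=items, probe=probe))
    return plans
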