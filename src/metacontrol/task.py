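"""Two-step space-treasure task environment.

Four spaceships, shown in two fixed pairs, deterministically transport the
player to one of two planets ("red", "purple"); each pair contains exactly one
spaceship per planet.  Each planet pays out 0-9 pieces of treasure according
to an independent drifting (reflected Gaussian random walk) reward series.
On a random ~50% of trials a stake amplifier multiplies treasure into points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

PLANETS = ("red", "purple")

DEFAULT_TRANSITIONS: dict[str, str] = {
    "dark_blue": "red",
    "green": "purple",
    "orange": "red",
    "pink": "purple",
}

DEFAULT_PAIRS: dict[str, tuple[str, str]] = {
    "pairA": ("dark_blue", "green"),
    "pairB": ("orange", "pink"),
}


class TaskConfigError(ValueError):
    """Raised for invalid task configuration values."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the task environment.

    Attributes
    ----------
    n_trials : int
        Session length.
    reward_low, reward_high : float
        Bounds of the treasure scale (inclusive).
    walk_sd : float
        SD of the Gaussian step of the latent per-planet reward walks.
    stake_prob : float
        Probability a trial is high-stake.
    stake_multiplier : int
        Points per treasure piece on high-stake trials.
    transition_map : mapping spaceship -> planet.
    pairs : mapping pair label -> tuple of 2 spaceships.
    seed : int
        Base RNG seed for environment sampling.
    """

    n_trials: int = 200
    reward_low: float = 0.0
    reward_high: float = 9.0
    walk_sd: float = 2.0
    stake_prob: float = 0.5
    stake_multiplier: int = 5
    transition_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS)
    )
    pairs: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PAIRS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise TaskConfigError("n_trials must be >= 1")
        if self.reward_low >= self.reward_high:
            raise TaskConfigError("reward_low must be < reward_high")
        if self.walk_sd < 0:
            raise TaskConfigError("walk_sd must be nonnegative")
        if not 0.0 <= self.stake_prob <= 1.0:
            raise TaskConfigError("stake_prob must lie in [0, 1]")
        if self.stake_multiplier < 1:
            raise TaskConfigError("stake_multiplier must be a positive integer")
        planets = set(self.transition_map.values())
        if planets != set(PLANETS):
            raise TaskConfigError(f"transition_map must cover planets {PLANETS}")
        if len(self.pairs) != 2:
            raise TaskConfigError("exactly two spaceship pairs required")
        for label, members in self.pairs.items():
            if len(members) != 2:
                raise TaskConfigError(f"pair {label!r} must contain 2 spaceships")
            dests = {self.transition_map.get(s) for s in members}
            if dests != set(PLANETS):
                raise TaskConfigError(
                    f"pair {label!r} must contain one spaceship per planet"
                )

    @property
    def pair_labels(self) -> tuple[str, ...]:
        return tuple(self.pairs)

    def spaceship_for(self, pair: str, planet: str) -> str:
        """The spaceship in `pair` that travels to `planet`."""
        for s in self.pairs[pair]:
            if self.transition_map[s] == planet:
                return s
        raise KeyError(f"no spaceship in {pair!r} reaches {planet!r}")


@dataclass(frozen=True)
class RewardWalk:
    """Latent per-planet treasure series, shape (n_trials, 2) in planet order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise TaskConfigError("RewardWalk values must have shape (n_trials, 2)")
        object.__setattr__(self, "values", v)

    def treasure(self, trial: int, planet: str) -> int:
        """Displayed whole-treasure payout (nearest integer of the latent walk)."""
        return int(np.rint(self.values[trial, PLANETS.index(planet)]))


@dataclass(frozen=True)
class StakeSchedule:
    """Per-trial stake values, entries in {1, stake_multiplier}."""

    stakes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "stakes", np.asarray(self.stakes, dtype=int))


def reflect(x: float, lo: float, hi: float) -> float:
    """Fold `x` back into [lo, hi] by reflection at the boundaries.

    Reflection is iterated (period 2*(hi - lo)), so arbitrarily large steps
    remain valid — necessary for large step SDs relative to the box.
    """
    if not math.isfinite(x):
        raise TaskConfigError(f"cannot reflect non-finite value {x}")
    span = hi - lo
    y = (x - lo) % (2.0 * span)
    if y > span:
        y = 2.0 * span - y
    return lo + y


def generate_reward_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalk:
    """Independent reflected Gaussian walks, one per planet.

    Initial values are uniform on [reward_low, reward_high]; each step adds
    Gaussian noise with SD ``walk_sd`` and reflects once at the bounds.
    """
    lo, hi = config.reward_low, config.reward_high
    values = np.empty((config.n_trials, 2))
    values[0] = rng.uniform(lo, hi, size=2)
    steps = rng.normal(0.0, config.walk_sd, size=(config.n_trials - 1, 2))
    for t in range(1, config.n_trials):
        for j in range(2):
            values[t, j] = reflect(values[t - 1, j] + steps[t - 1, j], lo, hi)
    return RewardWalk(values)


def sample_stakes(config: TaskConfig, rng: np.random.Generator) -> StakeSchedule:
    """i.i.d. Bernoulli(stake_prob) high-stake draws mapped to {multiplier, 1}."""
    high = rng.random(config.n_trials) < config.stake_prob
    return StakeSchedule(np.where(high, config.stake_multiplier, 1))


def transition(spaceship: str, config: TaskConfig) -> str:
    """Deterministic spaceship -> planet lookup."""
    return config.transition_map[spaceship]


def points_awarded(treasure: int, stake: int, config: TaskConfig | None = None) -> int:
    """Points won on a trial: treasure pieces times the stake amplifier."""
    multiplier = config.stake_multiplier if config is not None else 5
    lo = config.reward_low if config is not None else 0
    hi = config.reward_high if config is not None else 9
    if not lo <= treasure <= hi:
        raise TaskConfigError(f"treasure {treasure} outside [{lo}, {hi}]")
    if stake not in (1, multiplier):
        raise TaskConfigError(f"stake {stake} not in {{1, {multiplier}}}")
    return int(treasure) * int(stake)
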