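"""Dual-systems agent: model-free TD values, model-based planning values, and
a stake-conditioned softmax mixture with choice and response-key stickiness.

The model-free system caches a value per (pair, spaceship) and so cannot
generalize reward experience across pairs; the model-based system values a
spaceship by the current value of the planet it deterministically reaches and
therefore generalizes instantly.  The mixture weight ``w`` is selected per
trial by the stake condition (``w_low`` vs ``w_high``); their difference
``w_high - w_low`` is the metacontrol score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TRIAL_COLUMNS
from .task import (
    PLANETS,
    TaskConfig,
    generate_reward_walks,
    points_awarded,
    sample_stakes,
    transition,
)

KEYS = ("left", "right")


class ParamError(ValueError):
    """Raised for out-of-bounds agent parameters."""


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the dual-systems model.

    alpha : learning rate in [0, 1]
    beta : softmax inverse temperature >= 0 (rewards scaled to [0, 1])
    lam : eligibility-trace weight in [0, 1]
    w_low / w_high : model-based weight on low-/high-stake trials, in [0, 1]
    pi : stickiness toward repeating the previously visited planet
    rho : stickiness toward repeating the previous response key
    """

    alpha: float
    beta: float
    lam: float
    w_low: float
    w_high: float
    pi: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "w_low", "w_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ParamError(f"beta={self.beta} must be nonnegative")
        for name in ("pi", "rho"):
            if not np.isfinite(getattr(self, name)):
                raise ParamError(f"{name} must be finite")

    @property
    def metacontrol(self) -> float:
        return self.w_high - self.w_low

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta, "lam": self.lam,
            "w_low": self.w_low, "w_high": self.w_high,
            "pi": self.pi, "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(**{k: float(d[k]) for k in
                      ("alpha", "beta", "lam", "w_low", "w_high", "pi", "rho")})


@dataclass
class AgentState:
    """Mutable learner state.

    ``q_mf`` caches one value per (pair, spaceship); ``v_planet`` one value per
    planet.  Both start at the midpoint (0.5) of the scaled reward range so the
    first trial is unbiased.  ``prev_planet``/``prev_key`` drive stickiness.
    """

    q_mf: dict = field(default_factory=dict)
    v_planet: dict = field(default_factory=lambda: {p: 0.5 for p in PLANETS})
    prev_planet: str | None = None
    prev_key: str | None = None

    @classmethod
    def initial(cls, config: TaskConfig) -> "AgentState":
        q = {(pair, s): 0.5 for pair, members in config.pairs.items()
             for s in members}
        return cls(q_mf=q)


def mb_values(state: AgentState, config: TaskConfig, pair: str) -> np.ndarray:
    """Model-based values for the two spaceships of `pair` (in pair order)."""
    return np.array([state.v_planet[transition(s, config)]
                     for s in config.pairs[pair]])


def mf_values(state: AgentState, config: TaskConfig, pair: str) -> np.ndarray:
    return np.array([state.q_mf[(pair, s)] for s in config.pairs[pair]])


def mf_update(
    state: AgentState,
    config: TaskConfig,
    pair: str,
    chosen: str,
    reward_scaled: float,
    alpha: float,
    lam: float,
) -> AgentState:
    """Two-step TD update with an eligibility trace, in place.

    delta1 = V(planet) - Q(pair, a);      Q += alpha * delta1
    delta2 = r - V(planet);               V += alpha * delta2
                                          Q += alpha * lam * delta2
    Unchosen options are untouched.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParamError(f"alpha={alpha} outside [0, 1]")
    if not 0.0 <= lam <= 1.0:
        raise ParamError(f"lam={lam} outside [0, 1]")
    dest = transition(chosen, config)
    delta1 = state.v_planet[dest] - state.q_mf[(pair, chosen)]
    state.q_mf[(pair, chosen)] += alpha * delta1
    delta2 = reward_scaled - state.v_planet[dest]
    state.v_planet[dest] += alpha * delta2
    state.q_mf[(pair, chosen)] += alpha * lam * delta2
    state.prev_planet = dest
    return state


def choice_probabilities(
    state: AgentState,
    config: TaskConfig,
    pair: str,
    stake: int,
    params: AgentParams,
    sides: dict[str, str] | None = None,
) -> np.ndarray:
    """Softmax choice probabilities over the two spaceships of `pair`.

    Q_net = w * Q_MB + (1 - w) * Q_MF with w picked by the stake condition;
    the logit of each option additionally gains ``pi`` if it leads to the
    previously visited planet, and ``rho`` if its response key repeats the
    previous key (requires `sides`, a spaceship -> key mapping).
    """
    w = params.w_high if stake != 1 else params.w_low
    q_net = w * mb_values(state, config, pair) + (1 - w) * mf_values(
        state, config, pair)
    logits = params.beta * q_net
    members = config.pairs[pair]
    if state.prev_planet is not None and params.pi != 0.0:
        rep = np.array([transition(s, config) == state.prev_planet
                        for s in members], dtype=float)
        logits = logits + params.pi * rep
    if sides is not None and state.prev_key is not None and params.rho != 0.0:
        rep_key = np.array([sides[s] == state.prev_key for s in members],
                           dtype=float)
        logits = logits + params.rho * rep_key
    logits = logits - logits.max()  # shift-invariant
    ex = np.exp(logits)
    return ex / ex.sum()


def simulate_subject(
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    miss_prob: float = 0.0,
) -> pd.DataFrame:
    """Play one full session and return a schema-complete trial table.

    Per trial: draw the stake, show a uniformly random pair with randomized
    left/right placement, sample a choice from the softmax policy, resolve the
    deterministic transition, read the treasure from the drifting reward walk,
    award points, and run the TD update.  Missed trials (probability
    ``miss_prob``) yield no reward and no learning.
    """
    walks = generate_reward_walks(config, rng)
    stakes = sample_stakes(config, rng).stakes
    state = AgentState.initial(config)
    pair_labels = config.pair_labels
    rows = []
    for t in range(config.n_trials):
        pair = pair_labels[rng.integers(len(pair_labels))]
        members = list(config.pairs[pair])
        order = rng.permutation(2)
        left, right = members[order[0]], members[order[1]]
        sides = {left: "left", right: "right"}
        missed = bool(rng.random() < miss_prob)
        red, purple = walks.values[t]
        if missed:
            rows.append((subject_id, t + 1, pair, int(stakes[t]), left, right,
                         "", "", np.nan, 0, True, red, purple))
            continue
        probs = choice_probabilities(state, config, pair, int(stakes[t]),
                                     params, sides=sides)
        choice = members[0] if rng.random() < probs[0] else members[1]
        planet = transition(choice, config)
        treasure = walks.treasure(t, planet)
        points = points_awarded(treasure, int(stakes[t]), config)
        rows.append((subject_id, t + 1, pair, int(stakes[t]), left, right,
                     choice, planet, float(treasure), points, False,
                     red, purple))
        mf_update(state, config, pair, choice,
                  treasure / config.reward_high, params.alpha, params.lam)
        state.prev_key = sides[choice]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
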