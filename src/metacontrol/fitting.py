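"""Per-subject maximum-likelihood fitting of the dual-systems model.

The likelihood walks the observed session trial by trial, updating values with
the subject's observed choices and rewards and scoring each non-missed choice
under the stake-conditioned softmax mixture.  Missed trials contribute nothing
and do not update values.  Fitting is bounded quasi-Newton optimization over
transformed parameters (logit for the unit-interval parameters, log for the
inverse temperature) with multiple seeded restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .agent import AgentParams
from .io import SchemaError
from .task import PLANETS, TaskConfig

BETA_MAX = 20.0
BETA_MIN = 1e-6
STICKY_BOUND = 5.0
LOGIT_BOUND = 10.0

_PARAM_NAMES = ("alpha", "beta", "lam", "w_low", "w_high", "pi", "rho")


class FitDataError(SchemaError):
    """Raised when a trial table cannot be scored."""


@dataclass(frozen=True)
class FitResult:
    params_hat: AgentParams
    nll: float
    n_restarts: int
    converged: bool
    n_trials_used: int
    w_low_identified: bool = True
    w_high_identified: bool = True

    @property
    def metacontrol(self) -> float:
        return self.params_hat.metacontrol

    def to_dict(self) -> dict:
        d = self.params_hat.to_dict()
        d.update(nll=self.nll, n_restarts=self.n_restarts,
                 converged=self.converged, n_trials_used=self.n_trials_used,
                 metacontrol=metacontrol_score(self))
        return d


def metacontrol_score(fit: FitResult) -> float:
    """w_high - w_low; NaN when either weight is unidentified."""
    if not (fit.w_low_identified and fit.w_high_identified):
        return float("nan")
    return fit.params_hat.metacontrol


# ---------------------------------------------------------------------------
# parameter transforms (unconstrained optimization space <-> model space)

def pack_params(p: AgentParams) -> np.ndarray:
    return np.array([
        special.logit(np.clip(p.alpha, 1e-12, 1 - 1e-12)),
        math.log(max(p.beta, BETA_MIN)),
        special.logit(np.clip(p.lam, 1e-12, 1 - 1e-12)),
        special.logit(np.clip(p.w_low, 1e-12, 1 - 1e-12)),
        special.logit(np.clip(p.w_high, 1e-12, 1 - 1e-12)),
        p.pi,
        p.rho,
    ])


def unpack_params(x: np.ndarray) -> AgentParams:
    return AgentParams(
        alpha=float(special.expit(x[0])),
        beta=float(math.exp(x[1])),
        lam=float(special.expit(x[2])),
        w_low=float(special.expit(x[3])),
        w_high=float(special.expit(x[4])),
        pi=float(x[5]),
        rho=float(x[6]),
    )


_BOUNDS = [
    (-LOGIT_BOUND, LOGIT_BOUND),
    (math.log(BETA_MIN), math.log(BETA_MAX)),
    (-LOGIT_BOUND, LOGIT_BOUND),
    (-LOGIT_BOUND, LOGIT_BOUND),
    (-LOGIT_BOUND, LOGIT_BOUND),
    (-STICKY_BOUND, STICKY_BOUND),
    (-STICKY_BOUND, STICKY_BOUND),
]


# ---------------------------------------------------------------------------
# likelihood

def _prepare_arrays(trials: pd.DataFrame, config: TaskConfig):
    """Flatten a trial table into integer arrays for the likelihood core.

    Within each pair, options are indexed by their position in
    ``config.pairs[pair]``; model-free values live at flat index
    pair_index * 2 + option_index.  Stickiness indicators are data-determined
    (they depend only on the previous non-missed trial's outcome) and are
    precomputed here.
    """
    pair_idx = {p: i for i, p in enumerate(config.pair_labels)}
    planet_idx = {p: i for i, p in enumerate(PLANETS)}
    opt_planet = np.array(
        [[planet_idx[config.transition_map[s]] for s in config.pairs[p]]
         for p in config.pair_labels], dtype=np.int64)

    pairs, chosens, dests, rewards, highs = [], [], [], [], []
    rep_planet, rep_key = [], []
    prev_planet = -1
    prev_key = -1  # 0=left, 1=right
    for idx, row in trials.iterrows():
        if bool(row["missed"]):
            continue
        pair = row["pair"]
        if pair not in pair_idx:
            raise FitDataError(f"row {idx}: unknown pair {pair!r}")
        members = config.pairs[pair]
        choice = row["choice"]
        if choice not in members:
            raise FitDataError(f"row {idx}: unknown spaceship {choice!r}")
        treasure = float(row["treasure"])
        if not np.isfinite(treasure):
            raise FitDataError(f"row {idx}: non-finite treasure")
        pi_ = pair_idx[pair]
        ci = members.index(choice)
        sides = {row["option_left"]: 0, row["option_right"]: 1}
        try:
            opt_sides = [sides[s] for s in members]
        except KeyError as exc:
            raise FitDataError(f"row {idx}: options do not match pair "
                               f"{pair!r}") from exc
        pairs.append(pi_)
        chosens.append(ci)
        dests.append(opt_planet[pi_, ci])
        rewards.append(treasure / config.reward_high)
        highs.append(1 if int(row["stake"]) != 1 else 0)
        rep_planet.append([1.0 if opt_planet[pi_, j] == prev_planet else 0.0
                           for j in range(2)])
        rep_key.append([1.0 if opt_sides[j] == prev_key else 0.0
                        for j in range(2)])
        prev_planet = int(opt_planet[pi_, ci])
        prev_key = opt_sides[ci]
    return (np.array(pairs, dtype=np.int64), np.array(chosens, dtype=np.int64),
            np.array(dests, dtype=np.int64), np.array(rewards),
            np.array(highs, dtype=np.int64), opt_planet,
            np.array(rep_planet), np.array(rep_key))


def _nll_core(pairs, chosens, dests, rewards, highs, opt_planet,
              rep_planet, rep_key,
              alpha, beta, lam, w_low, w_high, pi, rho) -> float:
    """Scalar likelihood loop over the flattened session."""
    q = [0.5, 0.5, 0.5, 0.5]
    v = [0.5, 0.5]
    op = opt_planet.tolist()
    nll = 0.0
    for t in range(len(pairs)):
        p = pairs[t]
        c = chosens[t]
        w = w_high if highs[t] else w_low
        base = 2 * p
        pl0, pl1 = op[p][0], op[p][1]
        l0 = beta * (w * v[pl0] + (1 - w) * q[base]) \
            + pi * rep_planet[t, 0] + rho * rep_key[t, 0]
        l1 = beta * (w * v[pl1] + (1 - w) * q[base + 1]) \
            + pi * rep_planet[t, 1] + rho * rep_key[t, 1]
        # -log softmax of the chosen option
        if c == 0:
            nll += math.log1p(math.exp(min(l1 - l0, 700.0)))
        else:
            nll += math.log1p(math.exp(min(l0 - l1, 700.0)))
        d = dests[t]
        qi = base + c
        q[qi] += alpha * (v[d] - q[qi])
        delta2 = rewards[t] - v[d]
        v[d] += alpha * delta2
        q[qi] += alpha * lam * delta2
    return nll


def negative_log_likelihood(
    params: AgentParams, trials: pd.DataFrame, config: TaskConfig
) -> float:
    """Sum of -ln P(observed choice) over non-missed trials."""
    arrays = _prepare_arrays(trials, config)
    return _nll_core(*arrays, params.alpha, params.beta, params.lam,
                     params.w_low, params.w_high, params.pi, params.rho)


# ---------------------------------------------------------------------------
# fitting

def _sample_start(rng: np.random.Generator, fit_pi: bool, fit_rho: bool
                  ) -> np.ndarray:
    x = np.empty(7)
    x[[0, 2, 3, 4]] = rng.uniform(-2.0, 2.0, size=4)    # logit-scale
    x[1] = rng.uniform(math.log(0.5), math.log(15.0))   # log beta
    x[5] = rng.uniform(-1.0, 1.0) if fit_pi else 0.0
    x[6] = rng.uniform(-1.0, 1.0) if fit_rho else 0.0
    return x


def fit_subject(
    trials: pd.DataFrame,
    config: TaskConfig,
    n_restarts: int = 20,
    seed: int = 0,
    fit_pi: bool = True,
    fit_rho: bool = True,
) -> FitResult:
    """Maximum-likelihood fit with seeded multi-start L-BFGS-B.

    The best (lowest-NLL) restart wins; ties break toward the earlier restart.
    If no restart reports convergence the best point is still returned with
    ``converged=False``.
    """
    arrays = _prepare_arrays(trials, config)
    highs = arrays[4]
    n_used = len(highs)
    if n_used == 0:
        raise FitDataError("no usable (non-missed) trials")
    w_high_ident = bool((highs == 1).any())
    w_low_ident = bool((highs == 0).any())

    fixed = []
    if not fit_pi:
        fixed.append(5)
    if not fit_rho:
        fixed.append(6)

    def objective(x: np.ndarray) -> float:
        return _nll_core(
            *arrays,
            special.expit(x[0]), math.exp(x[1]), special.expit(x[2]),
            special.expit(x[3]), special.expit(x[4]), x[5], x[6])

    rng = np.random.default_rng(seed)
    best_x, best_nll, any_converged = None, math.inf, False
    for _ in range(n_restarts):
        x0 = _sample_start(rng, fit_pi, fit_rho)
        bounds = list(_BOUNDS)
        for i in fixed:
            bounds[i] = (0.0, 0.0)
            x0[i] = 0.0
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-6, "maxiter": 500})
        if res.success:
            any_converged = True
        if res.fun < best_nll - 1e-12:
            best_nll, best_x = float(res.fun), res.x.copy()
    params_hat = unpack_params(best_x)
    return FitResult(params_hat=params_hat, nll=best_nll,
                     n_restarts=n_restarts, converged=any_converged,
                     n_trials_used=n_used,
                     w_low_identified=w_low_ident,
                     w_high_identified=w_high_ident)
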