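"""Model-agnostic behavioral markers.

Corrected reward rate benchmarks a subject against the drifting rewards that
were actually available (zero = chance); the exclusion rule drops subjects
missing more than 30% of trials; the stay-probability analysis regresses
planet-level staying on the previous trial's reward, separately for same- and
different-pair transitions — the previous-reward effect on different-pair
trials indexes model-based generalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

MISSED_PCT_CUTOFF = 30.0


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    corrected_reward_rate: float
    pct_missed: float
    included: bool
    generalization_index: float
    stay_degenerate: bool

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "corrected_reward_rate": self.corrected_reward_rate,
            "pct_missed": self.pct_missed,
            "included": self.included,
            "generalization_index": self.generalization_index,
            "stay_degenerate": self.stay_degenerate,
        }


def corrected_reward_rate(trials: pd.DataFrame, correction: str = "mean") -> float:
    """Mean obtained-minus-available treasure per non-missed trial.

    ``correction="mean"`` subtracts the across-planet mean of the displayed
    reward walks (zero = chance under a uniform-random policy);
    ``correction="max"`` subtracts the best available planet instead.
    Stakes are ignored: the metric lives on the treasure scale.
    """
    ok = trials.loc[~trials["missed"].astype(bool)]
    if len(ok) == 0:
        return float("nan")
    avail = ok[["reward_red", "reward_purple"]].to_numpy(dtype=float)
    if correction == "mean":
        baseline = avail.mean(axis=1)
    elif correction == "max":
        baseline = avail.max(axis=1)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float((ok["treasure"].to_numpy(dtype=float) - baseline).mean())


def pct_missed(trials: pd.DataFrame) -> float:
    return 100.0 * float(trials["missed"].astype(bool).mean())


def apply_exclusions(trials: pd.DataFrame) -> bool:
    """True (included) iff the subject missed at most 30% of trials."""
    return pct_missed(trials) <= MISSED_PCT_CUTOFF


def stay_probability_analysis(
    trials: pd.DataFrame, reward_high: float = 9.0, min_pairs: int = 30
) -> tuple[dict, bool]:
    """Logistic regression of staying with the previous planet.

    Model: stay ~ prev_reward * same_pair, over consecutive non-missed trial
    pairs.  ``stay`` is 1 when the current choice leads to the previously
    visited planet.  Returns (coefficients, degenerate); the ``prev_reward``
    main effect (same_pair coded 0 = different pair) is the model-based
    generalization index.
    """
    ok = trials.loc[~trials["missed"].astype(bool)].reset_index(drop=True)
    if len(ok) < 2:
        raise ValueError("need at least 2 usable trials")
    consecutive = (ok["trial"].to_numpy()[1:] - ok["trial"].to_numpy()[:-1]) == 1
    stay = (ok["planet"].to_numpy()[1:] == ok["planet"].to_numpy()[:-1])
    prev_reward = ok["treasure"].to_numpy(dtype=float)[:-1] / reward_high
    same_pair = (ok["pair"].to_numpy()[1:] == ok["pair"].to_numpy()[:-1])

    stay = stay[consecutive].astype(float)
    prev_reward = prev_reward[consecutive]
    same_pair = same_pair[consecutive].astype(float)
    if len(stay) < min_pairs:
        raise ValueError(f"need >= {min_pairs} consecutive-trial pairs, "
                         f"got {len(stay)}")

    nan_coefs = {"intercept": np.nan, "prev_reward": np.nan,
                 "same_pair": np.nan, "prev_reward:same_pair": np.nan}
    if stay.min() == stay.max():
        return nan_coefs, True
    X = sm.add_constant(np.column_stack(
        [prev_reward, same_pair, prev_reward * same_pair]))
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(stay, X, family=sm.families.Binomial()).fit(maxiter=200)
        params = res.params
    except Exception:
        return nan_coefs, True
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        return nan_coefs, True
    coefs = {"intercept": float(params[0]), "prev_reward": float(params[1]),
             "same_pair": float(params[2]),
             "prev_reward:same_pair": float(params[3])}
    return coefs, False


def summarize_subject(trials: pd.DataFrame, reward_high: float = 9.0,
                      correction: str = "mean") -> SubjectSummary:
    subject_id = str(trials["subject_id"].iloc[0])
    try:
        coefs, degenerate = stay_probability_analysis(trials, reward_high)
        gen = coefs["prev_reward"]
    except ValueError:
        gen, degenerate = float("nan"), True
    return SubjectSummary(
        subject_id=subject_id,
        corrected_reward_rate=corrected_reward_rate(trials, correction),
        pct_missed=pct_missed(trials),
        included=apply_exclusions(trials),
        generalization_index=gen,
        stay_degenerate=degenerate,
    )
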