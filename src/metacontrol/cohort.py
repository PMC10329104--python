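"""Synthetic cohort generator.

Individual differences are imposed on latent jointly-Gaussian scores (a
Gaussian copula) and pushed through monotone links into observable scales:
uniform ages, logistic-bounded model weights, and standardized executive
function and cortical-thickness proxy scores.  Because the links attenuate
Pearson correlations, the latent correlation matrix is self-calibrated
against a large internal pilot sample so that the *realized* correlations hit
the requested targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special

from .agent import AgentParams, simulate_subject
from .task import TaskConfig

_LATENTS = ["age", "w", "meta", "flanker", "stroop", "wm", "thickL", "thickR"]
_CALIBRATION_N = 40_000
_CALIBRATION_SEED = 987_654_321


class CohortSpecError(ValueError):
    """Raised for an infeasible cohort specification."""


@dataclass(frozen=True)
class CohortSpec:
    """Targets for the cohort's individual-difference structure.

    Correlation targets are *realized-scale* (observed Pearson) targets; the
    thickness targets are calibration values back-converted from the original
    ROI statistics and are not treated as ground truth.
    """

    n_subjects: int = 69
    age_range: tuple[float, float] = (6.19, 12.61)
    r_age_w: float = 0.25
    r_age_metacontrol: float = 0.0
    r_flanker_metacontrol: float = 0.42
    r_thickness_metacontrol_left: float = 0.37
    r_thickness_metacontrol_right: float = 0.42
    r_thickness_lr: float = 0.5
    female_prob: float = 35 / 69
    comprehension_prob: float = 0.96
    # population hyperparameters for the agent (calibration choices)
    w_loc: float = 0.0
    w_scale: float = 1.0
    meta_scale: float = 1.4
    alpha_loc: float = 0.0
    alpha_scale: float = 0.7
    beta_log_mean: float = 1.6
    beta_log_sd: float = 0.3
    lam_loc: float = 0.5
    lam_scale: float = 0.8
    pi_mean: float = 0.3
    pi_sd: float = 0.3
    rho_mean: float = 0.0
    rho_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise CohortSpecError("n_subjects must be >= 4")
        for name in ("r_age_w", "r_age_metacontrol", "r_flanker_metacontrol",
                     "r_thickness_metacontrol_left",
                     "r_thickness_metacontrol_right", "r_thickness_lr"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise CohortSpecError(f"{name}={v} must lie in (-1, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise CohortSpecError("age_range must be increasing")

    def target_pairs(self) -> dict[tuple[str, str], float]:
        return {
            ("age", "w"): self.r_age_w,
            ("age", "meta"): self.r_age_metacontrol,
            ("flanker", "meta"): self.r_flanker_metacontrol,
            ("thickL", "meta"): self.r_thickness_metacontrol_left,
            ("thickR", "meta"): self.r_thickness_metacontrol_right,
            ("thickL", "thickR"): self.r_thickness_lr,
        }


@dataclass(frozen=True)
class Cohort:
    """One synthetic sample: a per-subject table plus the generating spec."""

    table: pd.DataFrame
    spec: CohortSpec

    def agent_params(self, subject_id: str) -> AgentParams:
        row = self.table.set_index("subject_id").loc[subject_id]
        return AgentParams(alpha=row["alpha"], beta=row["beta"],
                           lam=row["lam"], w_low=row["w_low"],
                           w_high=row["w_high"], pi=row["pi"], rho=row["rho"])


def _latent_corr(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    k = len(_LATENTS)
    R = np.eye(k)
    idx = {name: i for i, name in enumerate(_LATENTS)}
    for (a, b), r in pairs.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


def _check_psd(R: np.ndarray, pairs: dict[tuple[str, str], float]) -> None:
    if np.linalg.eigvalsh(R).min() < -1e-10:
        worst = max(pairs, key=lambda p: abs(pairs[p]))
        raise CohortSpecError(
            "correlation targets are jointly infeasible (matrix not positive "
            f"semi-definite); largest requested target is {worst}")


def _observe(z: np.ndarray, spec: CohortSpec) -> pd.DataFrame:
    """Map latent Gaussian scores to the observed columns."""
    cols = dict(zip(_LATENTS, z.T))
    lo, hi = spec.age_range
    age = lo + (hi - lo) * stats.norm.cdf(cols["age"])
    a = spec.w_loc + spec.w_scale * cols["w"]
    b = 0.5 * spec.meta_scale * cols["meta"]
    w_low = special.expit(a - b)
    w_high = special.expit(a + b)
    return pd.DataFrame({
        "age": age,
        "w_low": w_low,
        "w_high": w_high,
        "metacontrol_true": w_high - w_low,
        "flanker": cols["flanker"],
        "stroop": cols["stroop"],
        "wm_span": cols["wm"],
        "thickness_left": cols["thickL"],
        "thickness_right": cols["thickR"],
    })


_OBSERVED_FOR_LATENT = {
    "age": "age", "w": "w_low", "meta": "metacontrol_true",
    "flanker": "flanker", "stroop": "stroop", "wm": "wm_span",
    "thickL": "thickness_left", "thickR": "thickness_right",
}


from functools import lru_cache


@lru_cache(maxsize=64)
def _calibrate_latent_targets(spec: CohortSpec) -> dict[tuple[str, str], float]:
    """Inflate latent correlations so realized observed correlations hit spec.

    One fixed-seed pilot sample estimates the attenuation of each targeted
    pair through the observation links; each latent target is the requested
    value divided by its attenuation factor.
    """
    pairs = spec.target_pairs()
    R = _latent_corr(pairs)
    _check_psd(R, pairs)
    if all(v == 0.0 for v in pairs.values()):
        return {k: 0.0 for k in pairs}
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z = rng.multivariate_normal(np.zeros(len(_LATENTS)), R,
                                size=_CALIBRATION_N, method="cholesky")
    obs = _observe(z, spec)
    adjusted: dict[tuple[str, str], float] = {}
    for (a, b), target in pairs.items():
        if target == 0.0:
            adjusted[(a, b)] = 0.0
            continue
        realized = float(np.corrcoef(obs[_OBSERVED_FOR_LATENT[a]],
                                     obs[_OBSERVED_FOR_LATENT[b]])[0, 1])
        atten = realized / R[_LATENTS.index(a), _LATENTS.index(b)]
        if not np.isfinite(atten) or atten <= 0.05:
            raise CohortSpecError(f"target {(a, b)} is unreachable through "
                                  "the observation links")
        adjusted[(a, b)] = float(np.clip(target / atten, -0.99, 0.99))
    return adjusted


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw one cohort from the calibrated Gaussian copula."""
    seed = spec.seed if seed is None else seed
    adjusted = _calibrate_latent_targets(spec)
    R = _latent_corr(adjusted)
    _check_psd(R, adjusted)
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(len(_LATENTS)), R,
                                size=spec.n_subjects, method="cholesky")
    table = _observe(z, spec)
    n = spec.n_subjects
    table.insert(0, "subject_id", [f"s{i:03d}" for i in range(n)])
    table["sex"] = np.where(rng.random(n) < spec.female_prob, "F", "M")
    table["comprehension"] = rng.random(n) < spec.comprehension_prob
    table["alpha"] = special.expit(
        rng.normal(spec.alpha_loc, spec.alpha_scale, size=n))
    table["beta"] = np.clip(
        np.exp(rng.normal(spec.beta_log_mean, spec.beta_log_sd, size=n)),
        0.1, 15.0)
    table["lam"] = special.expit(
        rng.normal(spec.lam_loc, spec.lam_scale, size=n))
    table["pi"] = rng.normal(spec.pi_mean, spec.pi_sd, size=n)
    table["rho"] = rng.normal(spec.rho_mean, spec.rho_sd, size=n)
    return Cohort(table=table, spec=spec)


def simulate_cohort_behavior(
    cohort: Cohort, config: TaskConfig, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """One simulated session per subject; per-subject RNG streams spawned
    deterministically from the master seed."""
    streams = np.random.SeedSequence(seed).spawn(len(cohort.table))
    tables: dict[str, pd.DataFrame] = {}
    for stream, (_, row) in zip(streams, cohort.table.iterrows()):
        sid = row["subject_id"]
        params = cohort.agent_params(sid)
        tables[sid] = simulate_subject(params, config,
                                       np.random.default_rng(stream),
                                       subject_id=sid)
    return tables
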