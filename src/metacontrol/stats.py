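"""Inferential toolkit: correlations with Fisher-z CIs, t-tests with effect
sizes, Bonferroni control, exact correlation power / sample size, and
percentile-bootstrap mediation."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

P_FLOOR = 1e-15


class DegenerateInputError(ValueError):
    """Raised when inputs have no usable variance (or are collinear)."""


@dataclass(frozen=True)
class StatResult:
    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    df: float
    p: float
    effect_size_d: float
    kind: str = ""

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "statistic": self.statistic,
                "df": self.df, "p": self.p,
                "effect_size_d": self.effect_size_d, "kind": self.kind}


@dataclass(frozen=True)
class MediationResult:
    path_a: float
    path_b: float
    path_c_total: float
    path_c_prime_direct: float
    indirect: float
    indirect_ci: tuple[float, float]
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {"path_a": self.path_a, "path_b": self.path_b,
                "path_c_total": self.path_c_total,
                "path_c_prime_direct": self.path_c_prime_direct,
                "indirect": self.indirect,
                "indirect_ci_low": self.indirect_ci[0],
                "indirect_ci_high": self.indirect_ci[1],
                "n_boot": self.n_boot, "seed": self.seed}


def format_p(p: float) -> str:
    """Report very small p-values as a bound, journal-style."""
    if p < 0.001:
        return "p < .001"
    return f"p = {p:.3f}"


def _as_clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("non-finite values in input")
    return x


def pearson_test(x, y) -> StatResult:
    """Pearson r with Fisher-z 95% CI and the t-based two-sided p-value."""
    x, y = _as_clean(x), _as_clean(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * math.sqrt(df / max(1.0 - r * r, 1e-300))
    zcrit = stats.norm.ppf(0.975)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = zcrit / math.sqrt(n - 3)
    lo, hi = math.tanh(z - half), math.tanh(z + half)
    return StatResult(estimate=r, ci_low=lo, ci_high=hi, statistic=float(t),
                      df=float(df), p=float(p), effect_size_d=float("nan"),
                      kind="pearson")


def one_sample_t(x, mu0: float = 0.0) -> StatResult:
    x = _as_clean(x)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance in input")
    res = stats.ttest_1samp(x, mu0)
    d = float((x.mean() - mu0) / sd)
    ci = res.confidence_interval(0.95)
    return StatResult(estimate=float(x.mean() - mu0), ci_low=float(ci.low - mu0),
                      ci_high=float(ci.high - mu0), statistic=float(res.statistic),
                      df=float(res.df), p=float(res.pvalue), effect_size_d=d,
                      kind="one_sample_t")


def welch_t(x1, x2) -> StatResult:
    """Welch two-sample t-test with Satterthwaite df and Cohen's d."""
    x1, x2 = _as_clean(x1), _as_clean(x2)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise DegenerateInputError("zero variance in both groups")
    n1, n2 = len(x1), len(x2)
    res = stats.ttest_ind(x1, x2, equal_var=False)
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    diff = float(x1.mean() - x2.mean())
    d = diff / sp if sp > 0 else float("inf")
    se = math.sqrt(v1 / n1 + v2 / n2)
    tcrit = stats.t.ppf(0.975, df)
    return StatResult(estimate=diff, ci_low=diff - tcrit * se,
                      ci_high=diff + tcrit * se,
                      statistic=float(res.statistic), df=float(df),
                      p=float(res.pvalue), effect_size_d=float(d),
                      kind="welch_t")


def bonferroni_threshold(alpha_family: float, m: int) -> float:
    """Per-comparison alpha under Bonferroni family-wise control."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must lie in (0, 1)")
    return alpha_family / m


# ---------------------------------------------------------------------------
# correlation power

def _r_log_density(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    lognum = (math.log(n - 2) + special.gammaln(n - 1)
              + (n - 1) / 2 * math.log1p(-rho * rho)
              + (n - 4) / 2 * np.log1p(-r * r))
    logden = (0.5 * math.log(2 * math.pi) + special.gammaln(n - 0.5)
              + (n - 1.5) * np.log1p(-rho * r))
    return lognum - logden


def _r_density(r, rho: float, n: int):
    """Sampling density of the Pearson correlation under a bivariate normal."""
    r = np.asarray(r, dtype=float)
    return np.exp(_r_log_density(r, rho, n)) * special.hyp2f1(
        0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def _critical_r(n: int, alpha: float, tails: str) -> float:
    a = alpha if tails == "one" else alpha / 2
    tstar = stats.t.ppf(1 - a, n - 2)
    return float(tstar / math.sqrt(n - 2 + tstar * tstar))


def correlation_power(n: int, rho: float, alpha: float = 0.05,
                      tails: str = "one") -> float:
    """Exact power of the test of rho=0 at sample size n (bivariate normal)."""
    if n < 4:
        raise ValueError("n must be >= 4")
    rc = _critical_r(n, alpha, tails)
    sgn = 1.0 if rho >= 0 else -1.0
    upper, _ = integrate.quad(_r_density, sgn * rc, sgn * 1.0,
                              args=(abs(rho), n))
    if tails == "one":
        return float(upper)
    lower, _ = integrate.quad(_r_density, -1.0, -rc, args=(abs(rho), n))
    return float(upper + lower)


def correlation_power_mc(n: int, rho: float, alpha: float = 0.05,
                         tails: str = "one", n_reps: int = 100_000,
                         seed: int = 0) -> float:
    """Monte Carlo oracle for `correlation_power` (vectorized simulation)."""
    rng = np.random.default_rng(seed)
    rc = _critical_r(n, alpha, tails)
    power_hits = 0
    chunk = max(1, min(n_reps, int(2e7) // n))
    done = 0
    while done < n_reps:
        k = min(chunk, n_reps - done)
        x = rng.standard_normal((k, n))
        e = rng.standard_normal((k, n))
        y = rho * x + math.sqrt(1 - rho * rho) * e
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
        if tails == "one":
            power_hits += int((np.sign(rho) * r > rc).sum()) if rho != 0 \
                else int((r > rc).sum())
        else:
            power_hits += int((np.abs(r) > rc).sum())
        done += k
    return power_hits / n_reps


def correlation_sample_size(rho1: float, alpha: float = 0.05,
                            power: float = 0.9, tails: str = "one",
                            method: str = "exact", n_max: int = 100_000,
                            **mc_kwargs) -> int:
    """Smallest N at which the test of rho=0 reaches the requested power.

    ``method="exact"`` integrates the sampling distribution of r;
    ``"fisher"`` uses the Fisher-z normal approximation (labeled, may differ
    by a couple of subjects); ``"montecarlo"`` uses the simulation oracle.
    """
    if not 0.0 < abs(rho1) < 1.0:
        raise ValueError("rho1 must satisfy 0 < |rho1| < 1")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if method == "fisher":
        a = alpha if tails == "one" else alpha / 2
        za, zb = stats.norm.ppf(1 - a), stats.norm.ppf(power)
        n = math.ceil(((za + zb) / math.atanh(abs(rho1))) ** 2 + 3)
        return max(n, 4)
    power_fn = {
        "exact": lambda n: correlation_power(n, rho1, alpha, tails),
        "montecarlo": lambda n: correlation_power_mc(
            n, rho1, alpha, tails, **mc_kwargs),
    }[method]
    # bracket with the Fisher approximation, then scan
    guess = correlation_sample_size(rho1, alpha, power, tails, method="fisher")
    n = max(4, guess - 10)
    while n <= n_max:
        if power_fn(n) >= power:
            break
        n += 1
    else:
        raise ValueError(f"requested power not attainable below n_max={n_max}")
    while n > 4 and power_fn(n - 1) >= power:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# mediation

def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xd = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise DegenerateInputError("collinear predictors in OLS path")
    return coef


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray
           ) -> tuple[float, float, float, float]:
    a = _ols(x[:, None], m)[1]
    bc = _ols(np.column_stack([x, m]), y)
    c_prime, b = bc[1], bc[2]
    c = _ols(x[:, None], y)[1]
    return float(a), float(b), float(c), float(c_prime)


def mediation(x, m, y, n_boot: int = 5000, seed: int = 0) -> MediationResult:
    """Simple mediation via OLS paths and a paired-case percentile bootstrap.

    a: x -> m; b and c': y ~ x + m; c: y ~ x. Indirect effect = a*b with a
    95% percentile bootstrap CI. The decomposition c = c' + a*b is exact for
    OLS fits on the same sample.
    """
    x, m, y = _as_clean(x), _as_clean(m), _as_clean(y)
    if not len(x) == len(m) == len(y):
        raise ValueError("x, m, y must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    a, b, c, c_prime = _paths(x, m, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ab, bb, _, _ = _paths(x[idx], m[idx], y[idx])
        except DegenerateInputError:
            boots[i] = np.nan
            continue
        boots[i] = ab * bb
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MediationResult(path_a=a, path_b=b, path_c_total=c,
                           path_c_prime_direct=c_prime, indirect=a * b,
                           indirect_ci=(float(lo), float(hi)),
                           n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# correlation battery

def correlation_battery(table: pd.DataFrame, x_cols: list[str],
                        y_cols: list[str], alpha_family: float = 0.05,
                        m_tests: int | None = None) -> pd.DataFrame:
    """All x-by-y Pearson correlations with a Bonferroni significance flag.

    ``m_tests`` defaults to the number of tests actually run but may be set
    to an externally defined family size.
    """
    rows = []
    n_tests = m_tests if m_tests is not None else len(x_cols) * len(y_cols)
    thresh = bonferroni_threshold(alpha_family, n_tests)
    for xc in x_cols:
        for yc in y_cols:
            res = pearson_test(table[xc], table[yc])
            rows.append({"pair": f"{xc}~{yc}", "x": xc, "y": yc,
                         "r": res.estimate, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "t": res.statistic,
                         "df": res.df, "p": res.p,
                         "p_bonferroni_flag": res.p < thresh})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thresh
    out.attrs["m_tests"] = n_tests
    return out


def render_battery(battery: pd.DataFrame) -> str:
    """Plain-text table of a correlation battery."""
    lines = [f"{'pair':<34}{'r':>8}{'95% CI':>20}{'p':>12}  sig"]
    for _, row in battery.iterrows():
        ci = f"[{row['ci_low']:+.2f}, {row['ci_high']:+.2f}]"
        flag = "*" if row["p_bonferroni_flag"] else ""
        lines.append(f"{row['pair']:<34}{row['r']:>+8.2f}{ci:>20}"
                     f"{format_p(row['p']):>12}  {flag}")
    thresh = battery.attrs.get("bonferroni_threshold")
    if thresh is not None:
        lines.append(f"* Bonferroni-corrected threshold p < {thresh:.4g} "
                     f"({battery.attrs.get('m_tests')} tests)")
    return "\n".join(lines)
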