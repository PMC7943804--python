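"""Effect summaries: per-lag, cumulative, and average percentage changes.

Coefficients are log rate ratios; reported effects are percentage
changes 100*(exp(beta) - 1) with Wald confidence intervals formed on
the log scale and then exponentiated.  Confidence levels are Bonferroni
adjusted for the number of outcome causes D (alpha = 0.05 / D); a
step-down Holm procedure is available separately for hypothesis flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelFit

__all__ = [
    "AdjustedAlpha",
    "CumulativeEffect",
    "AverageEffect",
    "adjusted_alpha",
    "lag_effects",
    "cumulative_and_average_effects",
    "holm_adjusted_pvalues",
]


@dataclass(frozen=True)
class AdjustedAlpha:
    """Bonferroni-adjusted two-sided level and its normal quantile."""

    alpha: float
    z: float


def adjusted_alpha(n_causes: int) -> AdjustedAlpha:
    """Bonferroni level alpha = 0.05 / D and matching normal quantile."""
    if n_causes < 1:
        raise ValueError("n_causes must be >= 1")
    alpha = 0.05 / n_causes
    return AdjustedAlpha(alpha=alpha, z=float(stats.norm.ppf(1.0 - alpha / 2.0)))


def _pct(b):
    return 100.0 * np.expm1(b)


def _lag_names(fit: ModelFit, block: str) -> list[str]:
    names = [c for c in fit.beta.index if c.startswith(f"{block}_lag")]
    names.sort(key=lambda c: int(c.rsplit("lag", 1)[1]))
    return names


def lag_effects(fit: ModelFit, n_causes: int = 13, block: str = "exposure") -> pd.DataFrame:
    """Per-lag percentage changes with multiplicity-adjusted Wald CIs.

    Returns one row per lag with columns (lag, beta, se, pct_change,
    ci_low, ci_high, alpha).  ``block`` selects the lag block
    ("exposure" for binary, "gale"/"hurricane" for three-category
    fits).  A zero standard error yields a degenerate interval equal to
    the point estimate and sets the ``degenerate`` flag.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    names = _lag_names(fit, block)
    if not names:
        raise ValueError(f"no lag coefficients found for block {block!r}")
    adj = adjusted_alpha(n_causes)
    se = fit.se()
    rows = []
    for name in names:
        b, s = float(fit.beta[name]), float(se[name])
        rows.append(
            {
                "lag": int(name.rsplit("lag", 1)[1]),
                "beta": b,
                "se": s,
                "pct_change": _pct(b),
                "ci_low": _pct(b - adj.z * s),
                "ci_high": _pct(b + adj.z * s),
                "alpha": adj.alpha,
                "degenerate": s == 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CumulativeEffect:
    """Cumulative log rate ratio over the lag window (sum of beta_l)."""

    sum_beta: float
    se: float
    alpha: float
    z: float

    @property
    def pct_change(self) -> float:
        return _pct(self.sum_beta)

    @property
    def ci_low_log(self) -> float:
        return self.sum_beta - self.z * self.se

    @property
    def ci_high_log(self) -> float:
        return self.sum_beta + self.z * self.se

    @property
    def ci_low(self) -> float:
        return _pct(self.ci_low_log)

    @property
    def ci_high(self) -> float:
        return _pct(self.ci_high_log)


@dataclass(frozen=True)
class AverageEffect:
    """Average per-day effect over the lag window (sum of beta_l / 8)."""

    avg_beta: float
    se: float
    alpha: float
    z: float

    @property
    def pct_change(self) -> float:
        return _pct(self.avg_beta)

    @property
    def ci_low(self) -> float:
        return _pct(self.avg_beta - self.z * self.se)

    @property
    def ci_high(self) -> float:
        return _pct(self.avg_beta + self.z * self.se)


def cumulative_and_average_effects(
    fit: ModelFit, n_causes: int = 13, block: str = "exposure"
) -> tuple[CumulativeEffect, AverageEffect]:
    """Cumulative (sum) and average (sum / n_lags) effects with Wald CIs.

    The cumulative variance is 1' Sigma 1 over the lag-coefficient
    covariance block; the average simply rescales both the point
    estimate and its standard error by the number of lags.  Note the
    average percentage change transforms (sum beta)/n, which differs
    from the mean of the per-lag percentage changes.
    """
    names = _lag_names(fit, block)
    if not names:
        raise ValueError(f"no lag coefficients found for block {block!r}")
    cov = fit.covariance.loc[names, names].to_numpy()
    eig_min = float(np.linalg.eigvalsh(cov).min())
    if eig_min < -1e-8 * max(1.0, abs(cov).max()):
        raise ValueError("lag covariance block is not positive semi-definite")
    k = len(names)
    total = float(fit.beta[names].sum())
    var = float(np.ones(k) @ cov @ np.ones(k))
    se = float(np.sqrt(max(var, 0.0)))
    adj = adjusted_alpha(n_causes)
    cum = CumulativeEffect(sum_beta=total, se=se, alpha=adj.alpha, z=adj.z)
    avg = AverageEffect(avg_beta=total / k, se=se / k, alpha=adj.alpha, z=adj.z)
    return cum, avg


def holm_adjusted_pvalues(pvalues) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def effects_table(
    fit: ModelFit, n_causes: int = 13, block: str = "exposure", cause: str = ""
) -> pd.DataFrame:
    """Tidy table of per-lag, cumulative, and average effects."""
    lag = lag_effects(fit, n_causes, block)
    cum, avg = cumulative_and_average_effects(fit, n_causes, block)
    rows = lag.assign(term=[f"lag{int(l)}" for l in lag["lag"]])[
        ["term", "pct_change", "ci_low", "ci_high", "alpha"]
    ]
    extra = pd.DataFrame(
        [
            {
                "term": "cumulative",
                "pct_change": cum.pct_change,
                "ci_low": cum.ci_low,
                "ci_high": cum.ci_high,
                "alpha": cum.alpha,
            },
            {
                "term": "average",
                "pct_change": avg.pct_change,
                "ci_low": avg.ci_low,
                "ci_high": avg.ci_high,
                "alpha": avg.alpha,
            },
        ]
    )
    out = pd.concat([rows, extra], ignore_index=True)
    out.insert(0, "block", block)
    if cause:
        out.insert(0, "cause", cause)
    return out
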