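"""Conditional quasi-Poisson fitting via profiled stratum intercepts.

The model is Poisson regression with one intercept per matched stratum
(county x calendar day).  Rather than instantiating thousands of dummy
columns, the stratum intercepts are profiled out analytically: at any
slope vector beta the maximizing intercept of stratum s is

    alpha_s(beta) = log( Y_s+ / sum_{i in s} exp(o_i + x_i' beta) ),

where o_i is the log-population offset.  Substituting alpha_s(beta)
gives the conditional (multinomial-equivalent) log-likelihood, which is
maximized by Newton iterations whose Hessian is the within-stratum
weighted-centered information.  Inference is quasi-likelihood: the Wald
covariance is scaled by a Pearson dispersion whose residual degrees of
freedom count the profiled intercepts as spent parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AssembledDesign

__all__ = ["ModelFit", "fit_conditional_quasipoisson", "estimate_dispersion"]


class ConvergenceError(RuntimeError):
    """Raised when the profiled Newton iteration fails to converge."""


@dataclass
class ModelFit:
    """Result of a conditional quasi-Poisson fit.

    ``beta`` holds log rate ratios for every retained design column;
    ``covariance`` is the dispersion-scaled inverse information;
    ``stratum_intercepts`` are the profiled alpha-hats (derived
    quantities, not free parameters).
    """

    beta: pd.Series
    covariance: pd.DataFrame
    dispersion: float
    dispersion_kind: str
    stratum_intercepts: pd.Series
    n_obs: int
    n_strata_used: int
    residual_df: int
    converged: bool
    iterations: int
    loglik: float
    fitted_mean: np.ndarray = field(repr=False)
    dropped_columns: list[str] = field(default_factory=list)

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance.to_numpy())), index=self.beta.index
        )

    def report(self) -> str:
        """Plain-text coefficient report."""
        lines = [
            f"conditional quasi-Poisson fit: n={self.n_obs}, "
            f"strata={self.n_strata_used}, residual df={self.residual_df}",
            f"dispersion ({self.dispersion_kind}) = {self.dispersion:.6g}",
            f"converged = {self.converged} in {self.iterations} iterations; "
            f"profiled loglik = {self.loglik:.6f}",
        ]
        if self.dropped_columns:
            lines.append(f"dropped columns: {', '.join(self.dropped_columns)}")
        se = self.se()
        lines.append(f"{'term':<16}{'beta':>12}{'se':>12}")
        for name in self.beta.index:
            lines.append(f"{name:<16}{self.beta[name]:>12.6f}{se[name]:>12.6f}")
        return "\n".join(lines)


def _group_logsumexp(eta: np.ndarray, s: np.ndarray, n_strata: int) -> np.ndarray:
    gmax = np.full(n_strata, -np.inf)
    np.maximum.at(gmax, s, eta)
    return gmax + np.log(np.bincount(s, weights=np.exp(eta - gmax[s]), minlength=n_strata))


def _centered(X: np.ndarray, w: np.ndarray, s: np.ndarray, n_strata: int) -> np.ndarray:
    """X minus its within-stratum weighted mean (the profiled information core)."""
    wsum = np.bincount(s, weights=w, minlength=n_strata)
    Xc = np.empty_like(X)
    for j in range(X.shape[1]):
        m = np.bincount(s, weights=w * X[:, j], minlength=n_strata) / wsum
        Xc[:, j] = X[:, j] - m[s]
    return Xc


def estimate_dispersion(mu: np.ndarray, y: np.ndarray, residual_df: int) -> float:
    """Pearson quasi-likelihood dispersion phi.

    phi = sum((y - mu)^2 / mu) / residual_df, with residual_df counting
    both slope coefficients and profiled stratum intercepts as spent.
    Floored at machine epsilon so a degenerate exact fit stays positive.
    """
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y, dtype=float)
    if residual_df <= 0:
        raise ValueError("residual_df must be positive")
    if np.any(mu <= 0):
        raise ValueError("fitted means must be positive")
    pearson = float(np.sum((y - mu) ** 2 / mu))
    return max(pearson / residual_df, np.finfo(float).eps)


def _deviance_dispersion(mu: np.ndarray, y: np.ndarray, residual_df: int) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    dev = 2.0 * float(np.sum(term - (y - mu)))
    return max(dev / residual_df, np.finfo(float).eps)


def fit_conditional_quasipoisson(
    design: AssembledDesign,
    tol: float = 1e-8,
    max_iter: int = 50,
    dispersion_kind: str = "pearson",
) -> ModelFit:
    """Fit the matched-stratum quasi-Poisson model by profiled Newton.

    Starting from beta = 0 (safe: the strata absorb all baseline
    levels), each iteration profiles the stratum intercepts in closed
    form, takes a Newton step on the profiled log-likelihood with
    step-halving on any decrease, and stops when the relative change in
    log-likelihood falls below ``tol``.  Columns that do not vary within
    any stratum (within-stratum variance < 1e-12) are non-identifiable
    and dropped with a warning, as are exactly collinear columns.
    Non-convergence raises :class:`ConvergenceError`.
    """
    if dispersion_kind not in {"pearson", "deviance"}:
        raise ValueError("dispersion_kind must be 'pearson' or 'deviance'")
    y = np.asarray(design.y, dtype=float)
    X = np.asarray(design.X, dtype=float)
    offset = np.asarray(design.offset, dtype=float)
    s = np.asarray(design.stratum)
    n, p_all = X.shape
    n_strata = int(s.max()) + 1
    ysum = np.bincount(s, weights=y, minlength=n_strata)
    if np.any(ysum <= 0):
        raise ValueError("strata with zero total count must be dropped upstream")

    names = list(design.columns)
    dropped: list[str] = []

    # identifiability: within-stratum variance (unweighted; beta=0 start)
    ones = np.ones(n)
    Xc0 = _centered(X, ones, s, n_strata)
    wvar = (Xc0**2).mean(axis=0)
    keep = wvar >= 1e-12
    if not keep.all():
        dropped += [nm for nm, k in zip(names, keep) if not k]
        warnings.warn(
            f"dropping non-identifiable columns (constant within strata): {dropped}",
            stacklevel=2,
        )
        X, Xc0 = X[:, keep], Xc0[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]

    # exact collinearity among centered columns: pivoted QR
    if X.shape[1]:
        _, R, piv = _pivoted_qr(Xc0)
        diag = np.abs(np.diag(R))
        rank_ok = diag > max(Xc0.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
        bad = sorted(piv[np.flatnonzero(~rank_ok)])
        if bad:
            badnames = [names[j] for j in bad]
            warnings.warn(f"dropping collinear columns: {badnames}", stacklevel=2)
            dropped += badnames
            keep2 = np.ones(X.shape[1], bool)
            keep2[bad] = False
            X = X[:, keep2]
            names = [nm for nm, k in zip(names, keep2) if k]
    p = X.shape[1]
    if p == 0:
        raise ValueError("no identifiable covariate columns remain")

    beta = np.zeros(p)

    def profile(b: np.ndarray):
        eta = offset + X @ b
        lse = _group_logsumexp(eta, s, n_strata)
        alpha = np.log(ysum) - lse
        mu = np.exp(eta + alpha[s])
        # profiled Poisson loglik up to constants; sum(mu)=sum(y) per stratum
        ll = float(np.sum(y * (eta + alpha[s]))) - float(ysum.sum())
        return alpha, mu, ll

    alpha, mu, ll = profile(beta)
    converged = False
    it = 0
    H = None
    for it in range(1, max_iter + 1):
        g = X.T @ (y - mu)
        Xc = _centered(X, mu, s, n_strata)
        H = (Xc * mu[:, None]).T @ Xc
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information at iteration {it}") from exc
        # step-halving on likelihood decrease
        lam, ll_new = 1.0, -np.inf
        for _ in range(30):
            cand = beta + lam * step
            alpha_new, mu_new, ll_new = profile(cand)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        else:
            raise ConvergenceError(f"step-halving failed at iteration {it}")
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, alpha, mu, ll = cand, alpha_new, mu_new, ll_new
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (last rel change {rel:.3g})"
        )

    # information at the optimum (one more centering at final weights)
    Xc = _centered(X, mu, s, n_strata)
    H = (Xc * mu[:, None]).T @ Xc
    residual_df = n - p - n_strata
    if residual_df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    if dispersion_kind == "pearson":
        phi = estimate_dispersion(mu, y, residual_df)
    else:
        phi = _deviance_dispersion(mu, y, residual_df)
    cov = phi * np.linalg.inv(H)
    cov = 0.5 * (cov + cov.T)

    return ModelFit(
        beta=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        dispersion=phi,
        dispersion_kind=dispersion_kind,
        stratum_intercepts=pd.Series(alpha, index=design.stratum_labels),
        n_obs=n,
        n_strata_used=n_strata,
        residual_df=residual_df,
        converged=converged,
        iterations=it,
        loglik=ll,
        fitted_mean=mu,
        dropped_columns=dropped,
    )


def _pivoted_qr(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv
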