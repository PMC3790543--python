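"""Phylogenetic GLS regression, OLS, and the quadratic-term check.

PGLS fits y = X beta + e with residual covariance sigma2 * V(lambda),
where V is the tree's Brownian covariance matrix and lambda scales its
off-diagonals. beta has the usual GLS form (X' V^-1 X)^-1 X' V^-1 y;
lambda can be fixed or estimated jointly by maximum likelihood. With
lambda = 0 (or on a star tree) the fit reduces to OLS.

r2 is defined on the whitened scale: 1 - RSS / TSS, where TSS is the
residual sum of squares of the whitened intercept-only (GLS grand mean)
model. This is stated explicitly because there is no unique r2 for GLS;
reported values are unadjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._gls import GLSFitResult, LambdaProfile
from .phylo_core import Phylogeny, vcv_matrix
from .signal import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = ["PGLSFit", "fit_pgls", "fit_ols", "quadratic_check", "eliminate_predictors"]


@dataclass
class PGLSFit:
    """A fitted (phylogenetic) least-squares regression."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    lambda_used: float
    lambda_mode: str               # "fixed" | "estimated" | "ols"
    r2: float
    loglik: float
    n: int
    predictor_names: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.predictor_names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.predictor_names.index(name)])


def _design(X, names: list[str] | None, n: int) -> tuple[np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("predictor rows do not match response length")
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    full = np.column_stack([np.ones(n), X])
    return full, ["intercept"] + list(names)


def _finalize(res: GLSFitResult, names: list[str], mode: str) -> PGLSFit:
    n, p = res.n, res.p
    if n <= p:
        raise ValueError("not enough observations for the number of predictors")
    sigma2_unbiased = res.rss / (n - p)
    cov = sigma2_unbiased * np.linalg.inv(res.xtvix)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = res.beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - p)
    r2 = 1.0 - res.rss / res.tss if res.tss > 0 else 0.0
    return PGLSFit(
        coefficients=res.beta,
        std_errors=se,
        t_stats=t,
        p_values=pvals,
        lambda_used=float(res.lam),
        lambda_mode=mode,
        r2=float(np.clip(r2, 0.0, 1.0)),
        loglik=float(res.loglik),
        n=n,
        predictor_names=names,
    )


def fit_pgls(
    tree: Phylogeny,
    y,
    X,
    lambda_mode: float | str = "estimate",
    *,
    predictor_names: list[str] | None = None,
) -> PGLSFit:
    """Regress y on X under phylogenetic covariance V(lambda).

    ``lambda_mode`` is either a fixed value in [0, 1] or ``"estimate"``,
    in which case lambda is found by ML jointly with beta and sigma2.
    An intercept is always added. Rows with missing values are dropped
    listwise (with a logged count) before fitting.
    """
    y = np.asarray(y, dtype=float).ravel()
    n_all = y.size
    if n_all != tree.n_tips:
        raise ValueError("response length does not match tree tips")
    full, names = _design(X, predictor_names, n_all)
    keep = np.isfinite(y) & np.all(np.isfinite(full), axis=1)
    if not keep.all():
        logger.info("listwise deletion removed %d rows", int((~keep).sum()))
    if np.ptp(y[keep]) == 0:
        raise DegenerateInputError("response is constant")
    V = vcv_matrix(tree).matrix[np.ix_(keep, keep)]
    n = int(keep.sum())
    if n < full.shape[1] + 1:
        raise ValueError("need n >= p + 2 observations")
    prof = LambdaProfile(V, full[keep], y[keep])
    try:
        if lambda_mode == "estimate":
            res = prof.maximize() if prof.identifiable else prof.fit(0.0)
            mode = "estimated"
        else:
            lam = float(lambda_mode)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("fixed lambda must be in [0, 1]")
            res = prof.fit(lam)
            mode = "fixed"
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"collinear or degenerate design: {exc}") from exc
    if not np.isfinite(res.loglik):
        raise ValueError("covariance matrix V(lambda) is not positive definite")
    return _finalize(res, names, mode)


def fit_ols(y, X, *, predictor_names: list[str] | None = None) -> PGLSFit:
    """Ordinary least squares: the nonphylogenetic arm of the assessment."""
    y = np.asarray(y, dtype=float).ravel()
    full, names = _design(X, predictor_names, y.size)
    keep = np.isfinite(y) & np.all(np.isfinite(full), axis=1)
    if not keep.all():
        logger.info("listwise deletion removed %d rows", int((~keep).sum()))
    y, full = y[keep], full[keep]
    if np.ptp(y) == 0:
        raise DegenerateInputError("response is constant")
    if y.size < full.shape[1] + 1:
        raise ValueError("need n >= p + 2 observations")
    prof = LambdaProfile(np.eye(y.size), full, y)
    try:
        res = prof.fit(0.0)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"collinear or degenerate design: {exc}") from exc
    return _finalize(res, names, "ols")


def quadratic_check(tree: Phylogeny | None, y, x, phylogenetic: bool = True) -> float:
    """p-value of the squared term in y ~ x + x^2.

    x is centered before squaring to decorrelate the linear and quadratic
    columns. Used to verify that an apparently negligible linear SEF-SRF
    association is not hiding a curved one.
    """
    x = np.asarray(x, dtype=float).ravel()
    xc = x - np.nanmean(x)
    X = np.column_stack([xc, xc**2])
    names = ["x", "x_squared"]
    if phylogenetic:
        if tree is None:
            raise ValueError("phylogenetic quadratic check needs a tree")
        fit = fit_pgls(tree, y, X, "estimate", predictor_names=names)
    else:
        fit = fit_ols(y, X, predictor_names=names)
    return fit.p_value("x_squared")


def eliminate_predictors(
    tree: Phylogeny,
    y,
    X,
    predictor_names: list[str],
    alpha: float = 0.05,
    lambda_mode: float | str = "estimate",
) -> tuple[PGLSFit, list[str]]:
    """Single-step backward elimination of nonsignificant effect traits.

    Fits the full PGLS model once, drops every predictor whose p-value
    exceeds ``alpha``, and refits once with the survivors. Returns the
    final fit and the dropped names. Not a stepwise search: mirrors the
    practice of discarding traits that explain no significant additional
    variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    full = fit_pgls(tree, y, X, lambda_mode, predictor_names=predictor_names)
    drop = [
        nm for nm in predictor_names
        if full.p_value(nm) > alpha
    ]
    keep_idx = [i for i, nm in enumerate(predictor_names) if nm not in drop]
    if not keep_idx or not drop:
        return full, drop
    refit = fit_pgls(
        tree, y, X[:, keep_idx], lambda_mode,
        predictor_names=[predictor_names[i] for i in keep_idx],
    )
    return refit, drop
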