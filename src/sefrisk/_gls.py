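"""Shared GLS / lambda-profile likelihood machinery.

Both Pagel's-lambda estimation and PGLS maximize the same multivariate
normal likelihood with mean X @ beta and covariance sigma2 * V(lambda),
where V(lambda) scales off-diagonal covariances by lambda. beta and
sigma2 have closed-form GLS/ML solutions at each lambda, so lambda is
found by maximizing the profile likelihood on [0, 1].

On ultrametric trees the diagonal of V is constant, so
V(lambda) = lambda * V + (1 - lambda) * depth * I shares V's eigenvectors:
one symmetric eigendecomposition makes every profile evaluation O(n).
Non-ultrametric trees fall back to a Cholesky factorization per lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GLSFitResult:
    lam: float
    beta: np.ndarray
    sigma2_ml: float          # ML estimate, RSS_w / n
    loglik: float
    rss: float                # whitened residual sum of squares
    tss: float                # whitened TSS about the GLS intercept-only fit
    xtvix: np.ndarray         # X' V(lam)^-1 X
    n: int
    p: int


class LambdaProfile:
    """Profile likelihood over Pagel's lambda for fixed design X and response y."""

    def __init__(self, V: np.ndarray, X: np.ndarray, y: np.ndarray):
        V = np.asarray(V, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        self.n, self.p = self.X.shape
        if V.shape != (self.n, self.n):
            raise ValueError("V shape does not match data length")
        self.V = V
        self.diag = np.diag(V).copy()
        dmax = self.diag.max()
        self._ultrametric = dmax > 0 and (dmax - self.diag.min()) <= 1e-8 * dmax
        off = V - np.diag(self.diag)
        self.identifiable = np.abs(off).max() > 1e-10 * max(dmax, 1e-300)
        if self._ultrametric:
            w, Q = np.linalg.eigh(V)
            self._w = np.clip(w, 0.0, None)
            self._depth = dmax
            self._Xr = Q.T @ self.X
            self._yr = Q.T @ self.y

    # -- core evaluation ---------------------------------------------

    def fit(self, lam: float) -> GLSFitResult:
        """GLS fit of y on X under covariance V(lam); ML profile loglik."""
        if self._ultrametric:
            vals = lam * self._w + (1.0 - lam) * self._depth
            if vals.min() <= 1e-12 * vals.max():
                return self._degenerate(lam)
            s = 1.0 / np.sqrt(vals)
            Xw = self._Xr * s[:, None]
            yw = self._yr * s
            logdet = float(np.log(vals).sum())
        else:
            Vl = self.V * lam
            np.fill_diagonal(Vl, self.diag)
            try:
                L = np.linalg.cholesky(Vl)
            except np.linalg.LinAlgError:
                return self._degenerate(lam)
            Xw = linalg.solve_triangular(L, self.X, lower=True)
            yw = linalg.solve_triangular(L, self.y, lower=True)
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < self.p:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        # whitened TSS about the GLS-estimated grand mean (intercept-only fit)
        ones_w = Xw[:, 0] if _is_intercept(self.X[:, 0]) else None
        if ones_w is not None and abs(ones_w @ ones_w) > 0:
            mu = float(ones_w @ yw) / float(ones_w @ ones_w)
            dev = yw - mu * ones_w
        else:
            dev = yw
        tss = float(dev @ dev)
        n = self.n
        sigma2 = rss / n
        if sigma2 <= 0:
            sigma2 = np.finfo(float).tiny
        loglik = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)
        return GLSFitResult(
            lam=lam, beta=beta, sigma2_ml=sigma2, loglik=loglik,
            rss=rss, tss=tss, xtvix=Xw.T @ Xw, n=n, p=self.p,
        )

    def _degenerate(self, lam: float) -> GLSFitResult:
        return GLSFitResult(
            lam=lam, beta=np.full(self.p, np.nan), sigma2_ml=np.nan,
            loglik=-np.inf, rss=np.nan, tss=np.nan,
            xtvix=np.full((self.p, self.p), np.nan), n=self.n, p=self.p,
        )

    def loglik(self, lam: float) -> float:
        return self.fit(lam).loglik

    # -- optimization ------------------------------------------------

    def maximize(self, *, tie_tol: float = 1e-7) -> GLSFitResult:
        """ML lambda on [0, 1], robust to multimodal profiles.

        The profile is maximized separately on four subintervals (plus
        both endpoints); near-ties are broken toward the lower lambda.
        """
        candidates = [0.0, 1.0]
        intervals = [(0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0)]
        # coarse scan guards against multiple local maxima within one
        # subinterval (common on small trees); refine around the best point
        coarse = np.linspace(0.0, 1.0, 51)
        lls = np.array([self.loglik(lam) for lam in coarse])
        best_coarse = float(coarse[int(np.argmax(lls))])
        intervals.append(
            (max(0.0, best_coarse - 0.04), min(1.0, best_coarse + 0.04))
        )
        for lo, hi in intervals:
            res = optimize.minimize_scalar(
                lambda lam: -self.loglik(lam),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            candidates.append(float(np.clip(res.x, 0.0, 1.0)))
        fits = [self.fit(lam) for lam in candidates]
        best = max(f.loglik for f in fits)
        eligible = [f for f in fits if f.loglik >= best - tie_tol]
        return min(eligible, key=lambda f: f.lam)


def _is_intercept(col: np.ndarray) -> bool:
    return bool(np.all(col == col[0]) and col[0] != 0)
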