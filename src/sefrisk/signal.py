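"""Phylogenetic signal statistics: Pagel's lambda and Fritz-Purvis D.

Lambda measures signal in a continuous variable as the off-diagonal
multiplier of the Brownian covariance matrix that maximizes a
multivariate-normal likelihood: 0 means tip values are phylogenetically
random, 1 means full Brownian structure. D measures dispersion of a
binary variable from the sum of sister-clade differences, scaled between
two simulated expectations so that a randomly shuffled trait gives
D ~ 1 and a Brownian-threshold trait gives D ~ 0; it is reported
alongside 1 - D, which runs in the same direction as lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._gls import LambdaProfile
from .phylo_core import Phylogeny, vcv_matrix

__all__ = [
    "LambdaFit",
    "DResult",
    "DegenerateInputError",
    "fit_lambda",
    "sum_sister_differences",
    "fit_D",
]


class DegenerateInputError(ValueError):
    """Input data cannot support the requested estimate."""


@dataclass
class LambdaFit:
    """Maximum-likelihood Pagel's lambda for one continuous variable."""

    lambda_hat: float
    sigma2_hat: float      # Brownian rate, trait-units^2 per branch-length unit
    mu_hat: float          # ancestral (GLS grand) mean, trait units
    loglik: float
    p_vs_zero: float       # LRT against lambda = 0 (chi2, 1 df)
    p_vs_one: float        # LRT against lambda = 1
    n: int
    unidentifiable: bool = False


@dataclass
class DResult:
    """Fritz-Purvis D with its two Monte-Carlo nulls."""

    d: float
    one_minus_d: float
    sum_d_obs: float
    p_random: float        # P(shuffle-null sum <= observed)
    p_brownian: float      # P(Brownian-null sum >= observed)
    n_perm: int
    seed: int


def _aligned_values(tree: Phylogeny, values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size != tree.n_tips:
        raise ValueError(
            f"values length {v.size} does not match {tree.n_tips} tips"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return v


def fit_lambda(tree: Phylogeny, values) -> LambdaFit:
    """ML estimate of Pagel's lambda for a continuous tip variable.

    mu and sigma2 are concentrated out analytically at each lambda; the
    profile likelihood is maximized on [0, 1]. Likelihood-ratio p-values
    against the lambda = 0 and lambda = 1 boundaries use the chi2(1)
    reference distribution (anti-conservative at a boundary).
    """
    y = _aligned_values(tree, values)
    n = y.size
    if n < 4:
        raise DegenerateInputError("lambda estimation needs at least 4 tips")
    if np.ptp(y) == 0:
        raise DegenerateInputError("trait is constant across tips")
    V = vcv_matrix(tree).matrix
    prof = LambdaProfile(V, np.ones((n, 1)), y)
    if not prof.identifiable:
        # star phylogeny: V(lambda) does not depend on lambda
        f0 = prof.fit(0.0)
        return LambdaFit(
            lambda_hat=0.0, sigma2_hat=f0.sigma2_ml / V[0, 0],
            mu_hat=float(f0.beta[0]), loglik=f0.loglik,
            p_vs_zero=1.0, p_vs_one=1.0, n=n, unidentifiable=True,
        )
    best = prof.maximize()
    ll0 = prof.loglik(0.0)
    ll1 = prof.loglik(1.0)
    p0 = float(stats.chi2.sf(max(0.0, 2.0 * (best.loglik - ll0)), df=1))
    p1 = float(stats.chi2.sf(max(0.0, 2.0 * (best.loglik - ll1)), df=1))
    # sigma2 is a rate per unit branch length; V carries the depths
    return LambdaFit(
        lambda_hat=float(best.lam),
        sigma2_hat=float(best.sigma2_ml),
        mu_hat=float(best.beta[0]),
        loglik=float(best.loglik),
        p_vs_zero=p0,
        p_vs_one=p1,
        n=n,
    )


# ---------------------------------------------------------------------------
# Fritz-Purvis D
# ---------------------------------------------------------------------------


class _SisterSums:
    """Vectorized sister-difference sums for many tip-state columns at once.

    Precomputes, for a fully bifurcating tree, a postorder schedule of
    (left, right, parent) row indices into a work matrix whose first
    n rows hold tip values. Each internal node gets the unweighted mean
    of its two daughters; the statistic is the sum over internal nodes of
    the absolute daughter difference. Branch lengths play no role here.
    """

    def __init__(self, tree: Phylogeny):
        if not tree.is_binary:
            raise ValueError(
                "the D statistic requires a binary tree; resolve polytomies "
                "first (Phylogeny.resolve_polytomies)"
            )
        n = tree.n_tips
        order: list[tuple[int, int, int]] = []
        row_of: dict[int, int] = {}
        next_row = n
        for i, leaf in enumerate(tree._leaves):
            row_of[id(leaf)] = i
        for node in tree._tree.postorder_internal_node_iter():
            kids = node.child_nodes()
            row_of[id(node)] = next_row
            order.append((row_of[id(kids[0])], row_of[id(kids[1])], next_row))
            next_row += 1
        self.n_tips = n
        self.n_rows = next_row
        self.left = np.array([o[0] for o in order])
        self.right = np.array([o[1] for o in order])
        self.parent = np.array([o[2] for o in order])

    def __call__(self, columns: np.ndarray) -> np.ndarray:
        """columns: (n_tips, k) tip states -> (k,) sister-difference sums."""
        cols = np.atleast_2d(np.asarray(columns, dtype=float))
        if cols.shape[0] != self.n_tips:
            cols = cols.T
        k = cols.shape[1]
        work = np.empty((self.n_rows, k))
        work[: self.n_tips] = cols
        total = np.zeros(k)
        for l, r, p in zip(self.left, self.right, self.parent):
            a = work[l]
            b = work[r]
            total += np.abs(a - b)
            work[p] = 0.5 * (a + b)
        return total


def _check_binary_states(v: np.ndarray) -> np.ndarray:
    if not np.all(np.isin(v, (0.0, 1.0))):
        raise ValueError("states must be 0/1")
    return v


def sum_sister_differences(tree: Phylogeny, values) -> float:
    """Observed sum of sister-clade differences of a 0/1 trait.

    Nodal values are unweighted daughter means computed tip-to-root;
    the return value is the sum over internal nodes of the absolute
    difference between the two daughter values.
    """
    v = _check_binary_states(_aligned_values(tree, values))
    return float(_SisterSums(tree)(v[:, None])[0])


def fit_D(tree: Phylogeny, values, n_perm: int = 1000, seed: int = 0) -> DResult:
    """Fritz-Purvis D for a binary trait, with permutation and Brownian nulls.

    D = (S_obs - mean S_brownian) / (mean S_random - mean S_brownian),
    where S is the sum of sister-clade differences, the random null
    shuffles tip states, and the Brownian null simulates continuous
    Brownian motion on the tree and rank-thresholds it at the observed
    prevalence (so both nulls condition on the observed state counts).
    Monte-Carlo p-values include the observed dataset and so are never 0.
    """
    v = _check_binary_states(_aligned_values(tree, values))
    n = v.size
    n_ones = int(v.sum())
    if n_ones == 0 or n_ones == n:
        raise DegenerateInputError("both binary states must be present")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    sums = _SisterSums(tree)
    s_obs = float(sums(v[:, None])[0])

    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.tile(v, (n_perm, 1)), axis=1).T
    s_rand = sums(shuffled)

    V = vcv_matrix(tree).matrix
    L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / n * np.eye(n))
    sims = L @ rng.standard_normal((n, n_perm))
    # rank-threshold: top n_ones values of each simulated column become 1
    order = np.argsort(sims, axis=0)
    binary = np.zeros_like(sims)
    rows = order[n - n_ones :, :]
    np.put_along_axis(binary, rows, 1.0, axis=0)
    s_brown = sums(binary)

    mean_r = float(s_rand.mean())
    mean_b = float(s_brown.mean())
    denom = mean_r - mean_b
    if abs(denom) < 1e-9:
        raise DegenerateInputError(
            "random and Brownian null expectations coincide; D undefined"
        )
    d = (s_obs - mean_b) / denom
    p_random = (1.0 + float(np.sum(s_rand <= s_obs))) / (n_perm + 1.0)
    p_brownian = (1.0 + float(np.sum(s_brown >= s_obs))) / (n_perm + 1.0)
    return DResult(
        d=float(d),
        one_minus_d=float(1.0 - d),
        sum_d_obs=s_obs,
        p_random=p_random,
        p_brownian=p_brownian,
        n_perm=n_perm,
        seed=seed,
    )
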