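"""Weighted two-parameter latent trait model for binary disease indicators.

The multimorbidity of respondent ``j`` is a latent trait ``z_j ~ N(0, 1)``;
each disease indicator is Bernoulli with

    logit P(X_ij = 1 | z_j) = beta0_i + beta1_i * z_j,

so ``expit(beta0_i)`` is the prevalence of condition ``i`` at average
multimorbidity and ``beta1_i`` its discrimination. Estimation maximises the
weighted marginal likelihood

    sum_j w_j log \\int prod_i pi_i(z)^x (1-pi_i(z))^(1-x) dPhi(z)

by an EM algorithm in the Bock-Aitkin tradition: the integral is replaced by
a fixed quadrature grid, the E-step distributes each (weighted) response
pattern over the nodes by its posterior, and the M-step solves one weighted
logistic regression per item by Newton iterations. Respondents are scored by
the posterior mean (EAP) of the trait, and scores are affinely rescaled to
[0, 1] for the downstream regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.special import logsumexp

from .disability_index import DISEASES

__all__ = [
    "ItemParams",
    "QuadratureGrid",
    "LatentFit",
    "item_probability",
    "fit_weighted_2pl",
    "eap_scores",
    "item_information",
    "m2_degrees_of_freedom",
    "rescale_unit",
]


@dataclass(frozen=True)
class ItemParams:
    """Intercepts and slopes of the 2PL measurement model, one pair per item."""

    items: tuple[str, ...]
    beta0: np.ndarray
    beta1: np.ndarray

    def __post_init__(self) -> None:
        b0 = np.asarray(self.beta0, dtype=float)
        b1 = np.asarray(self.beta1, dtype=float)
        if b0.shape != (len(self.items),) or b1.shape != (len(self.items),):
            raise ValueError("beta0/beta1 must have one entry per item")
        if not (np.isfinite(b0).all() and np.isfinite(b1).all()):
            raise ValueError("item parameters must be finite")
        object.__setattr__(self, "beta0", b0)
        object.__setattr__(self, "beta1", b1)

    @classmethod
    def from_dict(cls, params: dict[str, tuple[float, float]]) -> "ItemParams":
        items = tuple(params)
        return cls(
            items=items,
            beta0=np.array([params[i][0] for i in items]),
            beta1=np.array([params[i][1] for i in items]),
        )


@dataclass(frozen=True)
class QuadratureGrid:
    """Nodes and prior masses approximating the standard-normal latent prior."""

    nodes: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        if np.any(masses < 0) or not np.isclose(masses.sum(), 1.0, atol=1e-10):
            raise ValueError("masses must be nonnegative and sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "masses", masses)

    @classmethod
    def bock_aitkin(cls, n_nodes: int = 61, span: float = 6.0) -> "QuadratureGrid":
        """Equally spaced nodes on [-span, span] with renormalised N(0,1) masses."""
        nodes = np.linspace(-span, span, n_nodes)
        masses = np.exp(-0.5 * nodes**2)
        return cls(nodes=nodes, masses=masses / masses.sum())

    @classmethod
    def gauss_hermite(cls, n_nodes: int = 21) -> "QuadratureGrid":
        """Gauss-Hermite nodes/weights transformed to the N(0,1) prior."""
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        return cls(nodes=np.sqrt(2.0) * x, masses=w / np.sqrt(np.pi))


@dataclass
class LatentFit:
    """Result of the weighted 2PL fit."""

    params: ItemParams
    se_beta0: np.ndarray
    se_beta1: np.ndarray
    z: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    grid: QuadratureGrid


def item_probability(beta0: float, beta1: float, z: float | np.ndarray) -> np.ndarray:
    """P(X=1 | z) = expit(beta0 + beta1 * z)."""
    return expit(beta0 + beta1 * np.asarray(z, dtype=float))


def item_information(beta0: float, beta1: float, z: float | np.ndarray) -> np.ndarray:
    """Fisher information of one item at trait level z: beta1^2 p(1-p)."""
    p = item_probability(beta0, beta1, z)
    return beta1**2 * p * (1.0 - p)


def m2_degrees_of_freedom(n_items: int) -> int:
    """Degrees of freedom of the limited-information fit statistic for a 2PL.

    Univariate plus bivariate margins minus the 2 free parameters per item;
    positive only from 4 items on (3 items is the identifiability boundary).
    """
    if n_items < 3:
        raise ValueError("need at least 3 items for a nonnegative df")
    return n_items + n_items * (n_items - 1) // 2 - 2 * n_items


def _collapse_patterns(X: np.ndarray, w: np.ndarray):
    codes = X @ (1 << np.arange(X.shape[1], dtype=np.int64))
    _, first, inverse = np.unique(codes, return_index=True, return_inverse=True)
    patterns = X[first]
    weights = np.bincount(inverse, weights=w, minlength=len(first))
    return patterns, weights, inverse


def _pattern_loglik(patterns: np.ndarray, grid: QuadratureGrid, params: ItemParams):
    """(P, Q) log-likelihood of each pattern at each node."""
    eta = params.beta0[:, None] + params.beta1[:, None] * grid.nodes[None, :]  # (I, Q)
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    return patterns @ logp + (1 - patterns) @ log1mp


def fit_weighted_2pl(
    X: np.ndarray,
    w: np.ndarray | None = None,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> LatentFit:
    """Fit the weighted 2PL by EM with fixed-grid quadrature.

    Parameters
    ----------
    X : (N, I) binary matrix of disease indicators.
    w : strictly positive sampling weights (default: all ones).
    grid : quadrature grid; defaults to 61 Bock-Aitkin nodes on [-6, 6].
    tol : stop when the max absolute parameter change falls below this.
    max_iter : EM iteration cap; exceeding it flags the fit as unconverged.
    """
    X = np.asarray(X)
    n, n_items = X.shape
    if not np.isin(X, (0, 1)).all():
        raise ValueError("X must be binary")
    items = tuple(DISEASES) if n_items == len(DISEASES) else tuple(
        f"item{i}" for i in range(n_items)
    )
    for i in range(n_items):
        if X[:, i].min() == X[:, i].max():
            raise ValueError(f"item {items[i]!r} has zero variance")
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if grid is None:
        grid = QuadratureGrid.bock_aitkin()

    patterns, pat_w, _ = _collapse_patterns(X.astype(np.int64), w)
    log_mass = np.log(grid.masses)
    nodes = grid.nodes

    # start at observed (weighted) prevalences, unit slopes
    prev = (pat_w @ patterns) / pat_w.sum()
    beta0 = logit(np.clip(prev, 1e-6, 1 - 1e-6))
    beta1 = np.ones(n_items)

    loglik_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        params = ItemParams(items=items, beta0=beta0, beta1=beta1)
        ll_pq = _pattern_loglik(patterns, grid, params) + log_mass[None, :]
        ll_p = logsumexp(ll_pq, axis=1)
        loglik_path.append(float(pat_w @ ll_p))
        post = np.exp(ll_pq - ll_p[:, None])  # (P, Q)

        nq = pat_w @ post  # expected weighted count per node
        rq = (patterns * pat_w[:, None]).T @ post  # (I, Q) expected successes

        new0, new1 = beta0.copy(), beta1.copy()
        Z = np.column_stack([np.ones_like(nodes), nodes])
        for i in range(n_items):
            b = np.array([new0[i], new1[i]])
            for _ in range(50):  # inner Newton for the weighted logistic fit
                p = expit(Z @ b)
                g = Z.T @ (rq[i] - nq * p)
                h = (Z * (nq * p * (1 - p))[:, None]).T @ Z
                step = np.linalg.solve(h, g)
                b = b + step
                if np.max(np.abs(step)) < 1e-10:
                    break
            new0[i], new1[i] = b

        delta = max(np.max(np.abs(new0 - beta0)), np.max(np.abs(new1 - beta1)))
        beta0, beta1 = new0, new1
        if delta < tol:
            converged = True
            break

    # sign identification: the trait points toward more disease
    if beta1.mean() < 0:
        beta1 = -beta1
    params = ItemParams(items=items, beta0=beta0, beta1=beta1)

    ll_pq = _pattern_loglik(patterns, grid, params) + log_mass[None, :]
    ll_p = logsumexp(ll_pq, axis=1)
    loglik = float(pat_w @ ll_p)
    loglik_path.append(loglik)
    post = np.exp(ll_pq - ll_p[:, None])

    # empirical cross-product of per-pattern score contributions
    pi_q = expit(beta0[:, None] + beta1[:, None] * nodes[None, :])  # (I, Q)
    resid = patterns[:, :, None] - pi_q[None, :, :]  # (P, I, Q)
    g0 = np.einsum("pq,piq->pi", post, resid)
    g1 = np.einsum("pq,piq,q->pi", post, resid, nodes)
    scores = np.concatenate([g0, g1], axis=1)  # (P, 2I): all beta0 then all beta1
    info = (scores * pat_w[:, None]).T @ scores
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    z = eap_scores(X, params, grid)
    return LatentFit(
        params=params,
        se_beta0=se[:n_items],
        se_beta1=se[n_items:],
        z=z,
        loglik=loglik,
        loglik_path=np.asarray(loglik_path),
        n_iter=it,
        converged=converged,
        grid=grid,
    )


def eap_scores(
    X: np.ndarray, params: ItemParams, grid: QuadratureGrid | None = None
) -> np.ndarray:
    """Posterior-mean (EAP) trait score per respondent; equal patterns score equally."""
    if grid is None:
        grid = QuadratureGrid.bock_aitkin()
    X = np.asarray(X).astype(np.int64)
    patterns, _, inverse = _collapse_patterns(X, np.ones(len(X)))
    ll_pq = _pattern_loglik(patterns, grid, params) + np.log(grid.masses)[None, :]
    post = np.exp(ll_pq - logsumexp(ll_pq, axis=1)[:, None])
    return (post @ grid.nodes)[inverse]


def rescale_unit(z: np.ndarray) -> np.ndarray:
    """Affine map of scores onto [0, 1]: sample min -> 0, sample max -> 1."""
    z = np.asarray(z, dtype=float)
    lo, hi = z.min(), z.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant score vector")
    return (z - lo) / (hi - lo)
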