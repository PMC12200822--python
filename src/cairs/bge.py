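"""Bayesian Gaussian equivalent (BGe) marginal-likelihood score.

The ordinal panel codes (poor=0 < fair=1 < healthy=2) are scored as
Gaussian observations under a conjugate normal-Wishart prior, which keeps
the ordering information while giving a closed-form, decomposable and
Markov-equivalent score.  Columns are standardized (mean 0, sd 1) before
scoring so the identity prior scale is not arbitrary in the coding units.

The per-family score is the ratio of two subset marginal likelihoods,

    score(j | Pa) = log p(D_{Pa ∪ {j}}) - log p(D_{Pa}),

where the marginal likelihood of a subset W of the d variables, with
|W| = w, sample size N, precision-scale hyperparameter ``alpha_mu``,
degrees of freedom ``alpha_w`` and prior scale matrix T, is

    p(D_W) = pi^(-wN/2) * (alpha_mu / (N + alpha_mu))^(w/2)
             * prod_{i=1..w} Gamma((N + l - i + 1)/2) / Gamma((l - i + 1)/2)
             * |T_W|^(l/2) / |R_W|^((N + l)/2),       l = alpha_w - d + w,

with posterior scale ``R = T + S_N + N*alpha_mu/(N+alpha_mu) *
(xbar - mu0)(xbar - mu0)'`` (S_N the centered scatter matrix).  The
``- d + w`` degrees-of-freedom shift is the determinant correction that
makes subset marginals consistent with the full joint, and hence makes the
total DAG score identical across Markov-equivalent structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, pi

import numpy as np

from .graphs import Dag, bits

__all__ = ["BgeHyper", "BgeScorer", "bge_node_score", "dag_score", "ordinal_encode"]


@dataclass(frozen=True)
class BgeHyper:
    """Hyperparameters of the normal-Wishart prior behind the BGe score.

    ``alpha_mu`` weights the prior mean (default 1); ``alpha_w`` is the
    Wishart degrees of freedom and must exceed ``d - 1`` (default ``d + 2``
    when left as None).  The prior mean is zero and the prior scale matrix
    is ``t * I`` with ``t = alpha_mu * (alpha_w - d - 1) / (alpha_mu + 1)``,
    the standard literature default, unless an explicit scale is given.
    """

    alpha_mu: float = 1.0
    alpha_w: float | None = None
    prior_mean: np.ndarray | None = None
    prior_scale: np.ndarray | None = None

    def resolve(self, d: int) -> tuple[float, float, np.ndarray, np.ndarray]:
        if self.alpha_mu <= 0:
            raise ValueError("alpha_mu must be positive")
        aw = float(self.alpha_w) if self.alpha_w is not None else d + 2.0
        if aw <= d - 1:
            raise ValueError(f"alpha_w must exceed d-1 = {d - 1}, got {aw}")
        mu0 = (
            np.zeros(d)
            if self.prior_mean is None
            else np.asarray(self.prior_mean, dtype=float)
        )
        if self.prior_scale is None:
            t = self.alpha_mu * (aw - d - 1.0) / (self.alpha_mu + 1.0)
            T = t * np.eye(d)
        else:
            T = np.asarray(self.prior_scale, dtype=float)
            if T.shape != (d, d) or not np.allclose(T, T.T):
                raise ValueError("prior_scale must be a symmetric (d, d) matrix")
            if np.linalg.eigvalsh(T).min() <= 0:
                raise ValueError("prior_scale must be positive definite")
        return self.alpha_mu, aw, mu0, T


class BgeScorer:
    """Caching per-family BGe scorer for one data matrix.

    Parameters
    ----------
    data : (n, d) array of ordinal codes (or any real values).
    hyper : prior hyperparameters.
    standardize : center and scale columns before scoring (default True).
        Constant columns are rejected — the score is undefined for them.
    """

    def __init__(
        self, data: np.ndarray, hyper: BgeHyper | None = None, standardize: bool = True
    ):
        X = np.asarray(data, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be a 2-d matrix")
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        sd = X.std(axis=0)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0).tolist()
            raise ValueError(
                f"columns {bad} are constant; the BGe score is undefined for "
                "constant columns — drop or perturb them"
            )
        if standardize:
            X = (X - X.mean(axis=0)) / sd
        self.n, self.d = n, d
        self.hyper = hyper or BgeHyper()
        am, aw, mu0, T = self.hyper.resolve(d)
        self.alpha_mu, self.alpha_w = am, aw
        xbar = X.mean(axis=0)
        centered = X - xbar
        scatter = centered.T @ centered
        dev = xbar - mu0
        self.R = T + scatter + (n * am / (n + am)) * np.outer(dev, dev)
        self.T = T
        self._subset_cache: dict[int, float] = {0: 0.0}
        self._family_cache: dict[tuple[int, int], float] = {}

    def subset_logml(self, mask: int) -> float:
        """Log marginal likelihood of the columns selected by ``mask``."""
        cached = self._subset_cache.get(mask)
        if cached is not None:
            return cached
        idx = list(bits(mask))
        w = len(idx)
        n, d, am, aw = self.n, self.d, self.alpha_mu, self.alpha_w
        l = aw - d + w
        sub_T = self.T[np.ix_(idx, idx)]
        sub_R = self.R[np.ix_(idx, idx)]
        sign_T, logdet_T = np.linalg.slogdet(sub_T)
        sign_R, logdet_R = np.linalg.slogdet(sub_R)
        if sign_T <= 0 or sign_R <= 0:
            raise np.linalg.LinAlgError(
                f"non-positive-definite scale submatrix for columns {idx}"
            )
        val = (
            -0.5 * w * n * log(pi)
            + 0.5 * w * log(am / (n + am))
            + sum(
                lgamma((n + l - i + 1) / 2.0) - lgamma((l - i + 1) / 2.0)
                for i in range(1, w + 1)
            )
            + 0.5 * l * logdet_T
            - 0.5 * (n + l) * logdet_R
        )
        self._subset_cache[mask] = val
        return val

    def node_score(self, node: int, parent_mask: int) -> float:
        """Log marginal-likelihood contribution of one (child, parents) family."""
        if parent_mask & (1 << node):
            raise ValueError(f"node {node} cannot be its own parent")
        key = (node, parent_mask)
        cached = self._family_cache.get(key)
        if cached is not None:
            return cached
        val = self.subset_logml(parent_mask | (1 << node)) - self.subset_logml(
            parent_mask
        )
        self._family_cache[key] = val
        return val

    def dag_score(self, dag: Dag) -> float:
        """Total log score: sum of per-family contributions (decomposable)."""
        if dag.n != self.d:
            raise ValueError(f"dag has {dag.n} nodes but data has {self.d} columns")
        return sum(self.node_score(j, m) for j, m in enumerate(dag.parents))


def bge_node_score(
    node: int,
    parents: set[int] | frozenset[int] | tuple[int, ...],
    data: np.ndarray,
    hyper: BgeHyper | None = None,
) -> float:
    """One-shot per-family BGe score (builds a scorer; prefer BgeScorer in loops)."""
    mask = 0
    for p in parents:
        mask |= 1 << p
    return BgeScorer(data, hyper).node_score(node, mask)


def dag_score(dag: Dag, data: np.ndarray, hyper: BgeHyper | None = None) -> float:
    """One-shot total DAG score."""
    return BgeScorer(data, hyper).dag_score(dag)


def ordinal_encode(panel) -> np.ndarray:
    """Panel -> (n, 2k) real matrix of ordinal codes in canonical node order.

    Column order is baseline domains (registry order) then follow-up
    domains; values are the level codes 0/1/2 as floats, preserving the
    poor < fair < healthy ordering.
    """
    codes = panel.codes()
    if codes.shape[0] < 2:
        raise ValueError("need at least 2 records to score structures")
    return codes.astype(float)
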