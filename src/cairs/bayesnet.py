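"""Categorical Bayesian networks over the two-slice temporal graph.

Each sampled DAG is turned into a categorical Bayesian network by fitting
one conditional probability table (CPT) per node with a Dirichlet-MAP
(add-pseudocount) estimate.  Follow-up outcomes given a fixed baseline
profile are computed exactly: baseline nodes are clamped to the observed
state and the joint over follow-up nodes is the product of their CPT rows.
An idealized intervention on a domain is the do-operation: the domain's
*follow-up* node loses all incoming edges and its CPT becomes a point mass
on "healthy", leaving every other CPT untouched.

Inference paths: :func:`followup_distribution` enumerates the full joint
(3^k states, the reference path) while :func:`followup_marginals` sums each
node over its within-follow-up ancestor set only, vectorized across many
baseline states; both are exact and tested against each other.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .domains import HEALTHY, DomainRegistry, ProfileState
from .graphs import Dag, bits
from .panel import PanelDataset

__all__ = [
    "Cpt",
    "CategoricalBn",
    "FollowupDistribution",
    "fit_cpts",
    "followup_distribution",
    "followup_marginals",
    "mutilate",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table of one node given its ordered parents.

    ``table`` has one leading axis per parent (level codes 0..2, in
    ascending parent-node order) and a trailing axis of length 3 for the
    child level; every row sums to 1.
    """

    child: int
    parents: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        expected = (3,) * len(self.parents) + (3,)
        if self.table.shape != expected:
            raise ValueError(
                f"CPT for node {self.child}: table shape {self.table.shape} "
                f"!= expected {expected}"
            )
        if np.any(self.table < 0):
            raise ValueError(f"CPT for node {self.child} has negative entries")
        sums = self.table.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > _ROW_TOL):
            raise ValueError(f"CPT rows for node {self.child} do not sum to 1")

    def flat_rows(self) -> np.ndarray:
        """(3^p, 3) view; rows in lexicographic parent-code order."""
        return self.table.reshape(-1, 3)


@dataclass(frozen=True)
class CategoricalBn:
    """A DAG over the 2k temporal nodes plus one CPT per node."""

    registry: DomainRegistry
    dag: Dag
    cpts: tuple[Cpt, ...]
    n_fitted: int = 0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        k = len(self.registry)
        if self.dag.n != 2 * k:
            raise ValueError(
                f"dag has {self.dag.n} nodes; registry implies {2 * k}"
            )
        if len(self.cpts) != self.dag.n:
            raise ValueError("need exactly one CPT per node")
        for j, cpt in enumerate(self.cpts):
            if cpt.child != j:
                raise ValueError("CPTs must be listed in node order")
            if cpt.parents != tuple(sorted(bits(self.dag.parents[j]))):
                raise ValueError(
                    f"CPT parents for node {j} do not match the DAG"
                )

    @property
    def k(self) -> int:
        return len(self.registry)

    def followup_node(self, domain: str) -> int:
        return self.k + self.registry.index(domain)

    def to_dict(self) -> dict:
        return {
            "domains": list(self.registry.names),
            "parents": [list(c.parents) for c in self.cpts],
            "tables": [c.flat_rows().tolist() for c in self.cpts],
            "n_fitted": self.n_fitted,
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoricalBn":
        registry = DomainRegistry(tuple(d["domains"]))
        n = 2 * len(registry)
        cpts = []
        for j in range(n):
            parents = tuple(d["parents"][j])
            table = np.asarray(d["tables"][j], dtype=float).reshape(
                (3,) * len(parents) + (3,)
            )
            cpts.append(Cpt(j, parents, table))
        dag = Dag.from_edges(
            n, [(p, j) for j in range(n) for p in d["parents"][j]]
        )
        return cls(
            registry,
            dag,
            tuple(cpts),
            n_fitted=d.get("n_fitted", 0),
            pseudocount=d.get("pseudocount", 1.0),
        )


def fit_cpts(
    dag: Dag, panel: PanelDataset, pseudocount: float = 1.0
) -> CategoricalBn:
    """Dirichlet-MAP CPT fit: cell = (count + pc) / (row total + 3 pc).

    With the default ``pseudocount=1`` this is the mode of a symmetric
    Dirichlet(2) posterior; unobserved parent configurations yield uniform
    rows, so every table is well defined however sparse the panel.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    k = len(panel.registry)
    if dag.n != 2 * k:
        raise ValueError(f"dag has {dag.n} nodes; panel implies {2 * k}")
    codes = panel.codes()
    cpts = []
    for j in range(dag.n):
        parents = tuple(sorted(bits(dag.parents[j])))
        p = len(parents)
        counts = np.zeros((3,) * p + (3,))
        idx = tuple(codes[:, q] for q in parents) + (codes[:, j],)
        np.add.at(counts, idx, 1.0)
        table = (counts + pseudocount) / (
            counts.sum(axis=-1, keepdims=True) + 3.0 * pseudocount
        )
        cpts.append(Cpt(j, parents, table))
    return CategoricalBn(
        panel.registry, dag, tuple(cpts), n_fitted=panel.n, pseudocount=pseudocount
    )


@dataclass(frozen=True)
class FollowupDistribution:
    """Exact joint over all 3^k follow-up profiles given a clamped baseline.

    ``probs[i]`` is the probability of the i-th profile in lexicographic
    level-code order over registry domains (last domain varies fastest).
    """

    registry: DomainRegistry
    probs: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.registry)
        if self.probs.shape != (3**k,):
            raise ValueError("probability vector has wrong length")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError("follow-up distribution does not sum to 1")

    def prob_of(self, state: ProfileState) -> float:
        idx = 0
        for code in state.levels:
            idx = idx * 3 + code
        return float(self.probs[idx])

    def marginal(self, domain: str) -> np.ndarray:
        """Length-3 marginal distribution of one domain's follow-up level."""
        k = len(self.registry)
        i = self.registry.index(domain)
        cube = self.probs.reshape((3,) * k)
        axes = tuple(a for a in range(k) if a != i)
        return cube.sum(axis=axes)

    def marginals(self) -> np.ndarray:
        """(k, 3) matrix of per-domain marginals."""
        return np.stack([self.marginal(d) for d in self.registry])


def _followup_topo(bn: CategoricalBn) -> list[int]:
    """Follow-up nodes in a topological order of the within-follow-up graph."""
    k = bn.k
    order = [j for j in bn.dag.topological_order() if j >= k]
    return order


def followup_distribution(
    bn: CategoricalBn, baseline: ProfileState
) -> FollowupDistribution:
    """Exact enumeration of the follow-up joint with the baseline clamped.

    This is the "doing nothing" simulation: baseline nodes are set to the
    observed state (their CPTs are not evaluated) and the joint over
    follow-up nodes is the product of their CPT entries.
    """
    k = bn.k
    if baseline.registry != bn.registry:
        raise ValueError("baseline state registry does not match the network")
    configs = np.array(
        list(itertools.product(range(3), repeat=k)), dtype=np.int64
    )  # (3^k, k), canonical lexicographic order
    probs = np.ones(len(configs))
    base = np.asarray(baseline.levels, dtype=np.int64)
    for j in range(k, 2 * k):
        cpt = bn.cpts[j]
        ix = []
        for p in cpt.parents:
            if p < k:
                ix.append(base[p])
            else:
                ix.append(configs[:, p - k])
        ix.append(configs[:, j - k])
        probs = probs * cpt.table[tuple(ix)]
    return FollowupDistribution(bn.registry, probs)


def followup_marginals(
    bn: CategoricalBn, baselines: np.ndarray | Sequence[ProfileState]
) -> np.ndarray:
    """Per-domain follow-up marginals for many baseline states at once.

    Parameters
    ----------
    baselines : (n_states, k) integer code matrix or a sequence of
        :class:`ProfileState`.

    Returns
    -------
    (n_states, k, 3) array; ``out[s, i, l]`` is P(domain i at level l at
    follow-up | baseline state s).  Exact: each domain is summed over its
    within-follow-up ancestor set only, which matches the full enumeration.
    """
    k = bn.k
    if not isinstance(baselines, np.ndarray):
        baselines = np.array([s.levels for s in baselines], dtype=np.int64)
    S = np.asarray(baselines, dtype=np.int64)
    if S.ndim != 2 or S.shape[1] != k:
        raise ValueError(f"baselines must be (n_states, {k})")
    n_states = S.shape[0]
    topo = _followup_topo(bn)
    out = np.empty((n_states, k, 3))
    for i, d in enumerate(bn.registry):
        j = k + i
        anc = _followup_ancestors(bn, j)
        order = [a for a in topo if a in anc]
        pos = {a: t for t, a in enumerate(order)}
        configs = np.array(
            list(itertools.product(range(3), repeat=len(order))), dtype=np.int64
        )
        weight = np.ones((len(configs), n_states))
        for a in order:
            cpt = bn.cpts[a]
            ix = []
            for p in cpt.parents:
                if p < k:
                    ix.append(S[:, p][None, :])
                else:
                    ix.append(configs[:, pos[p]][:, None])
            ix.append(configs[:, pos[a]][:, None])
            weight = weight * cpt.table[tuple(ix)]
        child_levels = configs[:, pos[j]]
        for l in range(3):
            out[:, i, l] = weight[child_levels == l].sum(axis=0)
    return out


def _followup_ancestors(bn: CategoricalBn, j: int) -> set[int]:
    """Within-follow-up ancestors of follow-up node j, including j."""
    k = bn.k
    anc = {j}
    frontier = [j]
    while frontier:
        v = frontier.pop()
        for p in bits(bn.dag.parents[v]):
            if p >= k and p not in anc:
                anc.add(p)
                frontier.append(p)
    return anc


def mutilate(bn: CategoricalBn, target: str) -> CategoricalBn:
    """do-operation: clamp a domain's follow-up node to "healthy".

    Removes every edge into the target's follow-up node and replaces its
    CPT with a point mass on the healthy level; all other CPTs and the
    original network are unchanged.  Idempotent.
    """
    j = bn.followup_node(target)
    point = np.zeros(3)
    point[HEALTHY] = 1.0
    new_parents = list(bn.dag.parents)
    new_parents[j] = 0
    new_dag = Dag(bn.dag.n, tuple(new_parents), bn.dag.labels)
    new_cpts = list(bn.cpts)
    new_cpts[j] = Cpt(j, (), point)
    return replace(bn, dag=new_dag, cpts=tuple(new_cpts))
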