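"""Temporal variables, DAGs and ordered node partitions.

The causal structure lives on ``2k`` nodes: every domain appears once in the
baseline slice and once in the follow-up slice.  Node order is fixed —
baseline nodes in registry order first, then follow-up nodes — and parent
sets are stored as integer bitmasks over that order, which keeps structure
enumeration and MCMC scoring cheap.

The hard temporal constraint forbids edges from any follow-up node into any
baseline node ("no arrows backwards in time"); edges within either slice
and from baseline into follow-up are permitted.

An ordered partition (weakly ordered node blocks) represents an equivalence
set of DAGs: a DAG is *compatible* with a partition when every node's
parents lie in strictly earlier blocks and every node outside the first
block has at least one parent in the immediately preceding block.  That
second condition makes the map DAG -> partition unique, so summing DAG
scores within partitions covers every DAG exactly once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .domains import DomainRegistry

__all__ = [
    "TemporalVariable",
    "temporal_nodes",
    "temporal_allowed_masks",
    "unconstrained_allowed_masks",
    "Dag",
    "Partition",
    "compatible_dags",
    "enumerate_dags",
    "iter_submasks",
]

SLICES = ("baseline", "followup")


@dataclass(frozen=True)
class TemporalVariable:
    """A (domain, time-slice) pair; the node identity in the temporal graph."""

    domain: str
    slice: str

    def __post_init__(self) -> None:
        if self.slice not in SLICES:
            raise ValueError(f"slice must be one of {SLICES}, got {self.slice!r}")

    @property
    def name(self) -> str:
        return f"{self.domain}_t{SLICES.index(self.slice)}"


def temporal_nodes(registry: DomainRegistry) -> list[TemporalVariable]:
    """The 2k nodes in canonical order: baseline slice then follow-up slice."""
    return [TemporalVariable(d, s) for s in SLICES for d in registry]


def temporal_allowed_masks(k: int) -> list[int]:
    """Per-node admissible-parent bitmasks under the temporal constraint.

    Baseline nodes (indices ``0..k-1``) may only have baseline parents;
    follow-up nodes (``k..2k-1``) may have any parents.  Self-loops are
    always excluded.
    """
    baseline_mask = (1 << k) - 1
    full_mask = (1 << (2 * k)) - 1
    out = []
    for j in range(2 * k):
        allowed = baseline_mask if j < k else full_mask
        out.append(allowed & ~(1 << j))
    return out


def unconstrained_allowed_masks(n: int) -> list[int]:
    """Admissible-parent masks with no temporal constraint (tests, toys)."""
    full = (1 << n) - 1
    return [full & ~(1 << j) for j in range(n)]


def iter_submasks(mask: int) -> Iterator[int]:
    """All submasks of ``mask``, including 0 and ``mask`` itself."""
    sub = mask
    while True:
        yield sub
        if sub == 0:
            return
        sub = (sub - 1) & mask


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph stored as one parent bitmask per node."""

    n: int
    parents: tuple[int, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.parents) != self.n:
            raise ValueError("need one parent mask per node")
        for j, mask in enumerate(self.parents):
            if mask & (1 << j):
                raise ValueError(f"node {j} lists itself as a parent")
            if mask >> self.n:
                raise ValueError(f"parent mask of node {j} references unknown nodes")
        if not self._acyclic():
            raise ValueError("graph contains a directed cycle")

    def _acyclic(self) -> bool:
        indeg = [bin(m).count("1") for m in self.parents]
        children: list[list[int]] = [[] for _ in range(self.n)]
        for j, mask in enumerate(self.parents):
            for p in bits(mask):
                children[p].append(j)
        stack = [j for j in range(self.n) if indeg[j] == 0]
        seen = 0
        while stack:
            v = stack.pop()
            seen += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        return seen == self.n

    @classmethod
    def from_edges(
        cls, n: int, edges: Iterable[tuple[int, int]], labels: Sequence[str] | None = None
    ) -> "Dag":
        parents = [0] * n
        for u, v in edges:
            parents[v] |= 1 << u
        return cls(n, tuple(parents), tuple(labels) if labels else None)

    def edges(self) -> list[tuple[int, int]]:
        """Directed edges as (parent, child) index pairs."""
        return [(p, j) for j, mask in enumerate(self.parents) for p in bits(mask)]

    def parent_indices(self, j: int) -> tuple[int, ...]:
        return tuple(bits(self.parents[j]))

    def has_edge(self, u: int, v: int) -> bool:
        return bool(self.parents[v] & (1 << u))

    def reachable_from(self, src: int) -> int:
        """Bitmask of nodes reachable from ``src`` by a directed path."""
        children: list[int] = [0] * self.n
        for j, mask in enumerate(self.parents):
            for p in bits(mask):
                children[p] |= 1 << j
        seen = 0
        frontier = children[src]
        while frontier:
            seen |= frontier
            nxt = 0
            for v in bits(frontier):
                nxt |= children[v] & ~seen
            frontier = nxt
        return seen

    def has_path(self, src: int, dst: int) -> bool:
        return bool(self.reachable_from(src) & (1 << dst))

    def descendants(self, src: int) -> tuple[int, ...]:
        return tuple(bits(self.reachable_from(src)))

    def topological_order(self) -> list[int]:
        order: list[int] = []
        placed = 0
        remaining = set(range(self.n))
        while remaining:
            ready = [j for j in remaining if (self.parents[j] & ~placed) == 0]
            for j in sorted(ready):
                order.append(j)
                placed |= 1 << j
                remaining.remove(j)
        return order

    def respects(self, allowed: Sequence[int]) -> bool:
        """True when every node's parents fall inside its admissible mask."""
        return all((m & ~a) == 0 for m, a in zip(self.parents, allowed))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        names = self.labels or tuple(str(i) for i in range(self.n))
        g.add_nodes_from(names)
        g.add_edges_from((names[u], names[v]) for u, v in self.edges())
        return g


def bits(mask: int) -> Iterator[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


@dataclass(frozen=True)
class Partition:
    """Ordered sequence of disjoint, non-empty node blocks covering all nodes."""

    n: int
    blocks: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        union: set[int] = set()
        for b in self.blocks:
            if not b:
                raise ValueError("empty block in partition")
            if union & b:
                raise ValueError("blocks are not disjoint")
            union |= b
        if union != set(range(self.n)):
            raise ValueError("blocks must cover exactly the node set")

    @classmethod
    def single_block(cls, n: int) -> "Partition":
        return cls(n, (frozenset(range(n)),))

    @classmethod
    def from_lists(cls, n: int, blocks: Sequence[Iterable[int]]) -> "Partition":
        return cls(n, tuple(frozenset(b) for b in blocks))

    def block_masks(self) -> list[int]:
        return [sum(1 << v for v in b) for b in self.blocks]

    def __len__(self) -> int:
        return len(self.blocks)


def _admissible_parent_masks(
    partition: Partition,
    node: int,
    allowed: Sequence[int],
    max_parents: int | None = None,
) -> list[int]:
    """Parent masks admissible for ``node`` under the partition semantics."""
    masks = partition.block_masks()
    block_index = next(i for i, m in enumerate(masks) if m & (1 << node))
    if block_index == 0:
        return [0]
    earlier = 0
    for m in masks[:block_index]:
        earlier |= m
    prev = masks[block_index - 1]
    pool = earlier & allowed[node]
    out = []
    for sub in iter_submasks(pool):
        if not (sub & prev):
            continue
        if max_parents is not None and bin(sub).count("1") > max_parents:
            continue
        out.append(sub)
    return out


def compatible_dags(
    partition: Partition,
    allowed: Sequence[int] | None = None,
    max_parents: int | None = None,
) -> list[Dag]:
    """Enumerate every DAG compatible with an ordered partition.

    Compatibility: each node's parents lie in strictly earlier blocks, and
    each node outside the first block has at least one parent in the
    immediately preceding block.  Guarded to at most 8 nodes — the count is
    combinatorial and this enumeration exists for small problems and tests.
    """
    n = partition.n
    if n > 8:
        raise ValueError(f"compatible_dags is limited to 8 nodes, got {n}")
    if allowed is None:
        allowed = unconstrained_allowed_masks(n)
    per_node = [
        _admissible_parent_masks(partition, j, allowed, max_parents) for j in range(n)
    ]
    dags = []
    for combo in itertools.product(*per_node):
        dags.append(Dag(n, tuple(combo)))
    return dags


def enumerate_dags(
    n: int,
    allowed: Sequence[int] | None = None,
    max_parents: int | None = None,
) -> Iterator[Dag]:
    """All DAGs on ``n`` nodes whose parents respect ``allowed`` masks.

    Guarded to 5 nodes (29,281 DAGs unconstrained); used as an exact
    posterior oracle.
    """
    if n > 5:
        raise ValueError(f"enumerate_dags is limited to 5 nodes, got {n}")
    if allowed is None:
        allowed = unconstrained_allowed_masks(n)
    per_node = []
    for j in range(n):
        opts = [
            m
            for m in iter_submasks(allowed[j])
            if max_parents is None or bin(m).count("1") <= max_parents
        ]
        per_node.append(opts)
    for combo in itertools.product(*per_node):
        try:
            yield Dag(n, tuple(combo))
        except ValueError:
            continue  # cyclic combination
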