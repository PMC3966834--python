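"""Labeled directed acyclic graphs: counting, exhaustive enumeration,
and Markov-equivalence bookkeeping.

The number of labeled DAGs on ``n`` nodes satisfies Robinson's
alternating-sign recurrence

    f(n) = sum_{i=1}^{n} (-1)^(i+1) C(n, i) 2^(i(n-i)) f(n-i),   f(0) = 1,

which grows super-exponentially (f(10) is about 4.2e18), so exact integer
arithmetic is mandatory.  Exhaustive enumeration is supported for n <= 5:
all 2^(n(n-1)) ordered-pair subsets are generated in a fixed bitmask order
and filtered for acyclicity, giving every structure a stable canonical
index that downstream score tables and reports refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Iterator, Sequence

from .errors import ArgumentError, CapabilityError, FormatError

#: Enumeration is deliberately capped here; the structure space on 6 nodes
#: already holds 3,781,503 DAGs out of 2^30 candidate arc sets.
MAX_ENUM_NODES = 5


def arc_order(n_nodes: int) -> list[tuple[int, int]]:
    """Fixed ordering of the n(n-1) possible arcs used for bitmask encoding.

    Arc (parent, child) at list position b corresponds to bit b of a
    structure's arc mask. Order is lexicographic on (parent, child).
    """
    return [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]


@dataclass(frozen=True)
class DagStructure:
    """A labeled DAG on nodes 0..n_nodes-1, the unit of enumeration and scoring.

    Parameters
    ----------
    n_nodes
        Number of nodes.
    arcs
        Set of ordered (parent, child) pairs. Must be acyclic, with no
        self-arcs.
    """

    n_nodes: int
    arcs: frozenset[tuple[int, int]]

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ArgumentError("n_nodes must be >= 1")
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        for (p, c) in self.arcs:
            if not (0 <= p < self.n_nodes and 0 <= c < self.n_nodes):
                raise ArgumentError(f"arc ({p},{c}) references a node outside 0..{self.n_nodes - 1}")
            if p == c:
                raise ArgumentError(f"self-arc on node {p}")
        if not is_acyclic(self.arcs, self.n_nodes):
            raise ArgumentError("arc set contains a directed cycle")

    @property
    def parent_sets(self) -> list[frozenset[int]]:
        """Per-node parent sets, index i holding {j : (j, i) in arcs}."""
        ps: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for (p, c) in self.arcs:
            ps[c].add(p)
        return [frozenset(s) for s in ps]

    @property
    def arc_mask(self) -> int:
        """Bitmask of this structure under :func:`arc_order`."""
        order = {a: b for b, a in enumerate(arc_order(self.n_nodes))}
        m = 0
        for a in self.arcs:
            m |= 1 << order[a]
        return m

    def is_connected(self) -> bool:
        """Weak connectivity of the underlying undirected skeleton."""
        if self.n_nodes == 1:
            return True
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for (p, c) in self.arcs:
            adj[p].add(c)
            adj[c].add(p)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_nodes


@dataclass(frozen=True)
class EquivalenceKey:
    """Skeleton plus v-structures: equal keys iff the DAGs are Markov equivalent."""

    skeleton: frozenset[tuple[int, int]]
    v_structures: frozenset[tuple[int, int, int]]


def is_acyclic(arcs, n_nodes: int) -> bool:
    """True iff the arc set admits a topological order.

    Self-arcs are rejected as malformed input rather than reported as cycles.
    """
    parents = [0] * n_nodes
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for (p, c) in arcs:
        if p == c:
            raise ArgumentError(f"self-arc on node {p}")
        parents[c] += 1
        children[p].append(c)
    # Kahn's algorithm
    queue = [i for i in range(n_nodes) if parents[i] == 0]
    removed = 0
    while queue:
        u = queue.pop()
        removed += 1
        for v in children[u]:
            parents[v] -= 1
            if parents[v] == 0:
                queue.append(v)
    return removed == n_nodes


@lru_cache(maxsize=None)
def count_dags(n: int) -> int:
    """Exact number of labeled DAGs on n nodes (Robinson's recurrence)."""
    if n < 0:
        raise ArgumentError("node count must be non-negative")
    if n == 0:
        return 1
    return sum(
        (-1) ** (i + 1) * comb(n, i) * 2 ** (i * (n - i)) * count_dags(n - i)
        for i in range(1, n + 1)
    )


def _mask_is_acyclic(child_masks: list[int], n: int) -> bool:
    # Kahn on bitset representation: repeatedly strip nodes with no
    # remaining parents. At most n rounds for n nodes.
    alive = (1 << n) - 1
    while alive:
        parented = 0
        for u in range(n):
            if alive & (1 << u):
                parented |= child_masks[u] & alive
        removable = alive & ~parented
        if removable == 0:
            return False
        alive &= ~removable
    return True


def enumerate_dags(n: int) -> Iterator[DagStructure]:
    """Yield every labeled DAG on n nodes exactly once, in canonical order.

    Canonical order is ascending on the arc-set bitmask of :func:`arc_order`;
    the position of a structure in this sequence is its stable structure id.
    Bounded at n <= 5 (2^20 candidate arc sets, filtered for acyclicity).
    """
    if n < 1:
        raise ArgumentError("node count must be >= 1")
    if n > MAX_ENUM_NODES:
        raise CapabilityError(
            f"exhaustive enumeration is limited to n <= {MAX_ENUM_NODES} nodes (got n={n})"
        )
    order = arc_order(n)
    n_bits = len(order)
    for mask in range(1 << n_bits):
        child_masks = [0] * n
        arcs = []
        m = mask
        while m:
            b = (m & -m).bit_length() - 1
            p, c = order[b]
            child_masks[p] |= 1 << c
            arcs.append((p, c))
            m &= m - 1
        if _mask_is_acyclic(child_masks, n):
            yield DagStructure(n, frozenset(arcs))


def equivalence_key(dag: DagStructure) -> EquivalenceKey:
    """Markov-equivalence class key: skeleton edges + v-structures.

    Two DAGs encode the same set of conditional-independence relations iff
    they share the same skeleton and the same colliders with non-adjacent
    parents (v-structures); score-equivalent metrics are constant on each
    class.
    """
    skeleton = frozenset((min(p, c), max(p, c)) for (p, c) in dag.arcs)
    adjacent = {(a, b) for (a, b) in skeleton} | {(b, a) for (a, b) in skeleton}
    vs = set()
    parent_sets = dag.parent_sets
    for child in range(dag.n_nodes):
        ps = sorted(parent_sets[child])
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                a, b = ps[i], ps[j]
                if (a, b) not in adjacent:
                    vs.add((a, b, child))
    return EquivalenceKey(skeleton=skeleton, v_structures=frozenset(vs))


# ---------------------------------------------------------------------------
# Edge-list text format: one "parent<TAB>child" line per arc, labels X1..Xn.


def write_dag(dag: DagStructure, path) -> None:
    """Write a DAG as tab-separated "X<p+1>\\tX<c+1>" lines (canonical arc order)."""
    order = arc_order(dag.n_nodes)
    with open(path, "w") as fh:
        for (p, c) in order:
            if (p, c) in dag.arcs:
                fh.write(f"X{p + 1}\tX{c + 1}\n")


def read_dag(path, n_nodes: int) -> DagStructure:
    """Read an edge-list file; a blank file denotes the empty graph on n_nodes."""
    arcs = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("expected 'parent<TAB>child'", line=lineno)
            try:
                p, c = (_parse_label(tok, n_nodes, lineno) for tok in parts)
            except FormatError:
                raise
            if (p, c) in arcs:
                raise FormatError(f"duplicate arc X{p + 1}->X{c + 1}", line=lineno)
            arcs.add((p, c))
    try:
        return DagStructure(n_nodes, frozenset(arcs))
    except ArgumentError as exc:
        raise FormatError(str(exc)) from exc


def _parse_label(token: str, n_nodes: int, lineno: int) -> int:
    if not token.startswith("X"):
        raise FormatError(f"node label {token!r} must look like 'X1'..'X{n_nodes}'", line=lineno)
    try:
        idx = int(token[1:]) - 1
    except ValueError:
        raise FormatError(f"node label {token!r} is not of the form X<k>", line=lineno) from None
    if not (0 <= idx < n_nodes):
        raise FormatError(f"node label {token!r} outside X1..X{n_nodes}", line=lineno)
    return idx
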