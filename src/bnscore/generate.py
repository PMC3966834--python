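"""Synthetic gold-standard Bayesian networks.

A gold standard is a structure plus parameters: a uniformly distributed
multi-connected DAG (sampled by an add/remove Markov chain over connected
acyclic digraphs, after Ide & Cozman) and one conditional probability
table per node. CPT rows are either uniform random points on the
probability simplex ("random" regime) or fixed extreme rows (p, 1-p)
("low-entropy" regime: p = 0.1 or 0.9 yields highly compressible data).

Parent-configuration rows of every CPT are ordered mixed-radix over the
node's parents sorted ascending, with the highest-indexed parent varying
fastest; the forward sampler and the scoring module use the same
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dag import DagStructure
from .errors import ArgumentError, CapabilityError, FormatError

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table of one node.

    ``probabilities`` has shape (q, r): one row per configuration of the
    node's parents (mixed-radix order, highest-indexed parent fastest),
    one column per value of the node. Rows sum to 1 within 1e-12.
    """

    node: int
    parents: tuple[int, ...]  # sorted ascending
    probabilities: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if probs.ndim != 2:
            raise ArgumentError("CPT probabilities must be a 2-D (q, r) matrix")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ArgumentError("CPT entries must lie in [0, 1]")
        if np.max(np.abs(probs.sum(axis=1) - 1.0)) > _ROW_SUM_TOL:
            raise ArgumentError("every CPT row must sum to 1 within 1e-12")


@dataclass(frozen=True)
class BayesNet:
    """Structure + arities + CPTs; the generating model of a synthetic study."""

    structure: DagStructure
    arities: tuple[int, ...]
    cpts: tuple[Cpt, ...]

    def __post_init__(self):
        object.__setattr__(self, "arities", tuple(int(a) for a in self.arities))
        object.__setattr__(self, "cpts", tuple(self.cpts))
        n = self.structure.n_nodes
        if len(self.arities) != n or len(self.cpts) != n:
            raise ArgumentError("arities and cpts must have one entry per node")
        if any(a < 2 for a in self.arities):
            raise ArgumentError("arities must be >= 2")
        parent_sets = self.structure.parent_sets
        for i, cpt in enumerate(self.cpts):
            if cpt.node != i:
                raise ArgumentError("cpts must be listed in node order")
            if tuple(sorted(parent_sets[i])) != cpt.parents:
                raise ArgumentError(f"CPT of node {i} disagrees with the structure's parent set")
            q = int(np.prod([self.arities[p] for p in cpt.parents], dtype=object)) if cpt.parents else 1
            if cpt.probabilities.shape != (q, self.arities[i]):
                raise ArgumentError(
                    f"CPT of node {i} must have shape ({q}, {self.arities[i]})"
                )

    def joint(self) -> np.ndarray:
        """Full joint distribution, shape ``arities`` (tiny for n <= 5)."""
        return joint_distribution(self)


def _cpt_joint_factor(bn: BayesNet, cpt: Cpt) -> np.ndarray:
    """CPT broadcast to the full joint shape (helper for :func:`joint_distribution`)."""
    n = bn.structure.n_nodes
    involved = list(cpt.parents) + [cpt.node]
    table = cpt.probabilities.reshape([bn.arities[v] for v in involved])
    # permute axes into ascending node order, then insert singleton axes
    perm = sorted(range(len(involved)), key=lambda a: involved[a])
    table = np.transpose(table, axes=perm)
    full_shape = [bn.arities[v] if v in involved else 1 for v in range(n)]
    return table.reshape(full_shape)


def joint_distribution(bn: BayesNet) -> np.ndarray:
    """Exact joint P(X_1..X_n) as the product of the local conditionals."""
    n = bn.structure.n_nodes
    joint = np.ones([bn.arities[v] for v in range(n)], dtype=float)
    for cpt in bn.cpts:
        joint = joint * _cpt_joint_factor(bn, cpt)
    return joint


# ---------------------------------------------------------------------------
# Structure generation


def random_dag(n: int, rng, steps: int) -> DagStructure:
    """Sample a weakly connected DAG on n nodes, approximately uniformly.

    Starts from a random ordered tree (node i's parent drawn uniformly from
    0..i-1) and runs ``steps`` moves of an add/remove chain over connected
    acyclic digraphs: pick an ordered node pair; if the arc exists, remove
    it only when the skeleton stays connected; if absent, add it only when
    the graph stays acyclic. The chain's stationary distribution is uniform
    over connected DAGs; with steps = 0 the initial tree is returned.
    """
    if n < 2:
        raise ArgumentError("random_dag requires n >= 2")
    if steps < 0:
        raise ArgumentError("steps must be >= 0")
    arcs: set[tuple[int, int]] = set()
    for i in range(1, n):
        arcs.add((rng.integer(i), i))
    for _ in range(steps):
        u = rng.integer(n)
        v = rng.integer(n - 1)
        if v >= u:
            v += 1
        if (u, v) in arcs:
            arcs.remove((u, v))
            if not _connected(arcs, n):
                arcs.add((u, v))
        else:
            arcs.add((u, v))
            from .dag import is_acyclic

            if not is_acyclic(arcs, n):
                arcs.remove((u, v))
    return DagStructure(n, frozenset(arcs))


def _connected(arcs, n: int) -> bool:
    adj: list[set[int]] = [set() for _ in range(n)]
    for (p, c) in arcs:
        adj[p].add(c)
        adj[c].add(p)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


# ---------------------------------------------------------------------------
# Parameter generation


def _parent_config_count(structure: DagStructure, arities, node: int) -> int:
    parents = sorted(structure.parent_sets[node])
    q = 1
    for p in parents:
        q *= arities[p]
    return q


def _simplex_point(r: int, rng) -> np.ndarray:
    """Uniform point on the (r-1)-simplex from r-1 independent draws.

    Uses sorted uniform cut points (order statistics), whose successive
    differences are uniformly distributed on the simplex. For binary nodes
    this reduces to a single draw u giving the row (u, 1-u).
    """
    cuts = sorted(rng.uniform() for _ in range(r - 1))
    points = [0.0] + list(cuts) + [1.0]
    return np.diff(points)


def random_cpts(structure: DagStructure, arities: Sequence[int], rng) -> BayesNet:
    """Attach uniformly random CPTs to a structure (the "random" regime)."""
    arities = tuple(int(a) for a in arities)
    if any(a < 2 for a in arities):
        raise ArgumentError("arities must be >= 2")
    cpts = []
    for node in range(structure.n_nodes):
        parents = tuple(sorted(structure.parent_sets[node]))
        q = _parent_config_count(structure, arities, node)
        rows = np.vstack([_simplex_point(arities[node], rng) for _ in range(q)])
        cpts.append(Cpt(node=node, parents=parents, probabilities=rows))
    return BayesNet(structure=structure, arities=arities, cpts=tuple(cpts))


def low_entropy_cpts(
    structure: DagStructure,
    arities: Sequence[int],
    p: float,
    flip_rng=None,
) -> BayesNet:
    """Attach extreme-parameter CPTs: every row is (p, 1-p), binary nodes only.

    With p = 0.1 each local conditional carries about 0.469 bits of entropy
    per case, so the sampled data are highly compressible. When ``flip_rng``
    is given, each row is independently flipped to (1-p, p) with probability
    one half (a sensitivity variant; the default applies p to the first
    value of every row uniformly).
    """
    arities = tuple(int(a) for a in arities)
    if any(a != 2 for a in arities):
        raise CapabilityError("low-entropy CPTs are defined for binary variables only")
    if not (0.0 < p < 1.0):
        raise ArgumentError("p must lie strictly between 0 and 1")
    cpts = []
    for node in range(structure.n_nodes):
        parents = tuple(sorted(structure.parent_sets[node]))
        q = _parent_config_count(structure, arities, node)
        rows = np.empty((q, 2), dtype=float)
        for j in range(q):
            if flip_rng is not None and flip_rng.uniform() < 0.5:
                rows[j] = (1.0 - p, p)
            else:
                rows[j] = (p, 1.0 - p)
        cpts.append(Cpt(node=node, parents=parents, probabilities=rows))
    return BayesNet(structure=structure, arities=arities, cpts=tuple(cpts))


# ---------------------------------------------------------------------------
# Plain-text model serialization


def write_model(bn: BayesNet, path) -> None:
    """Write a BayesNet as a plain-text model file (round-trip exact to 17 s.f.)."""
    from .dag import arc_order

    with open(path, "w") as fh:
        fh.write(f"nodes\t{bn.structure.n_nodes}\n")
        fh.write("arities\t" + " ".join(str(a) for a in bn.arities) + "\n")
        fh.write("[arcs]\n")
        for (p, c) in arc_order(bn.structure.n_nodes):
            if (p, c) in bn.structure.arcs:
                fh.write(f"X{p + 1}\tX{c + 1}\n")
        fh.write("[cpts]\n")
        for cpt in bn.cpts:
            for j, row in enumerate(cpt.probabilities):
                vals = " ".join(format(x, ".17g") for x in row)
                fh.write(f"X{cpt.node + 1}\t{j}\t{vals}\n")


def read_model(path) -> BayesNet:
    """Read a model file written by :func:`write_model`."""
    n = None
    arities: tuple[int, ...] | None = None
    arcs: set[tuple[int, int]] = set()
    cpt_rows: dict[int, dict[int, np.ndarray]] = {}
    section = "header"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line == "[arcs]":
                section = "arcs"
                continue
            if line == "[cpts]":
                section = "cpts"
                continue
            parts = line.split("\t")
            if section == "header":
                if parts[0] == "nodes":
                    n = int(parts[1])
                elif parts[0] == "arities":
                    arities = tuple(int(x) for x in parts[1].split())
                else:
                    raise FormatError(f"unknown header field {parts[0]!r}", line=lineno)
            elif section == "arcs":
                if len(parts) != 2:
                    raise FormatError("expected 'parent<TAB>child'", line=lineno)
                p = int(parts[0][1:]) - 1
                c = int(parts[1][1:]) - 1
                arcs.add((p, c))
            else:
                if len(parts) != 3:
                    raise FormatError("expected 'node<TAB>config<TAB>probs'", line=lineno)
                node = int(parts[0][1:]) - 1
                j = int(parts[1])
                row = np.array([float(x) for x in parts[2].split()])
                cpt_rows.setdefault(node, {})[j] = row
    if n is None or arities is None:
        raise FormatError("model file must declare 'nodes' and 'arities'")
    structure = DagStructure(n, frozenset(arcs))
    cpts = []
    for node in range(n):
        parents = tuple(sorted(structure.parent_sets[node]))
        rows = cpt_rows.get(node, {})
        q = _parent_config_count(structure, arities, node)
        if sorted(rows) != list(range(q)):
            raise FormatError(f"CPT of node X{node + 1} must have configs 0..{q - 1}")
        probs = np.vstack([rows[j] for j in range(q)])
        cpts.append(Cpt(node=node, parents=parents, probabilities=probs))
    return BayesNet(structure=structure, arities=arities, cpts=tuple(cpts))
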