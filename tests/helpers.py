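"""Independent oracles used by the tests.

These deliberately avoid the package's own computational paths: the
brute-force likelihood oracle tallies cases with plain Python scans, and
the Markov-equivalence oracle enumerates d-separation statements on the
moralized ancestral graph. Both are only feasible at toy sizes, which is
exactly where they are used.
"""

from __future__ import annotations

from itertools import chain, combinations
from math import log2


def powerset(iterable):
    s = list(iterable)
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))


def d_separated(n_nodes, arcs, x, y, z) -> bool:
    """d-separation of x and y given set z, via the moral ancestral graph."""
    z = set(z)
    parents = {v: set() for v in range(n_nodes)}
    for (p, c) in arcs:
        parents[c].add(p)
    # ancestors of {x, y} | z (inclusive)
    anc = set()
    frontier = {x, y} | z
    while frontier:
        v = frontier.pop()
        if v in anc:
            continue
        anc.add(v)
        frontier |= parents[v] - anc
    # moralize the induced subgraph: connect co-parents, drop directions
    und = {v: set() for v in anc}
    for c in anc:
        ps = sorted(parents[c] & anc)
        for p in ps:
            und[p].add(c)
            und[c].add(p)
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                und[ps[i]].add(ps[j])
                und[ps[j]].add(ps[i])
    # remove z and test reachability x -> y
    seen = {x}
    stack = [x]
    while stack:
        u = stack.pop()
        for v in und[u]:
            if v in z or v in seen:
                continue
            if v == y:
                return False
            seen.add(v)
            stack.append(v)
    return True


def ci_signature(n_nodes, arcs) -> frozenset:
    """All conditional-independence statements the DAG encodes.

    Two DAGs are Markov equivalent iff their signatures are equal.
    """
    stmts = set()
    for x in range(n_nodes):
        for y in range(x + 1, n_nodes):
            rest = [v for v in range(n_nodes) if v not in (x, y)]
            for z in powerset(rest):
                if d_separated(n_nodes, arcs, x, y, set(z)):
                    stmts.add((x, y, frozenset(z)))
    return frozenset(stmts)


def brute_force_ll(values, arities, parent_sets) -> float:
    """Per-case maximum-likelihood log-likelihood in bits, by naive scans.

    For every case, multiply each node's ML conditional probability
    (matching-count ratios tallied directly from the raw rows).
    """
    rows = [tuple(int(v) for v in row) for row in values]
    total = 0.0
    for row in rows:
        for node, parents in enumerate(parent_sets):
            pa = tuple(sorted(parents))
            n_match_pa = sum(1 for r in rows if all(r[p] == row[p] for p in pa))
            n_match_full = sum(
                1
                for r in rows
                if r[node] == row[node] and all(r[p] == row[p] for p in pa)
            )
            total += log2(n_match_full / n_match_pa)
    return total
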