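"""Forward (ancestral) sampling of discrete Bayesian networks and the
delimited-text dataset format.

A case is generated by visiting nodes in a topological order and sampling
each variable from the CPT row selected by its already-sampled parents.
Datasets are complete (no missing entries) N x n integer matrices; the
on-disk form is a comma-delimited file with header "X1,...,Xn" and
0-based integer codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dag import DagStructure
from .errors import ArgumentError, FormatError
from .generate import BayesNet


@dataclass(frozen=True)
class Dataset:
    """N x n matrix of discrete values with per-variable arities."""

    values: np.ndarray
    arities: tuple[int, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "arities", tuple(int(a) for a in self.arities))
        if vals.ndim != 2:
            raise ArgumentError("dataset values must be a 2-D matrix")
        if vals.shape[1] != len(self.arities):
            raise ArgumentError("one arity per column is required")
        for i, a in enumerate(self.arities):
            col = vals[:, i]
            if col.size and (col.min() < 0 or col.max() >= a):
                raise ArgumentError(f"column {i} holds values outside 0..{a - 1}")

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]


def topological_order(structure: DagStructure) -> list[int]:
    """A node order in which every node follows all of its parents.

    Deterministic: among nodes simultaneously available, the lowest index
    comes first, so the empty graph yields (0, 1, ..., n-1).
    """
    n = structure.n_nodes
    parent_sets = [set(s) for s in structure.parent_sets]
    remaining = set(range(n))
    order: list[int] = []
    while remaining:
        ready = sorted(v for v in remaining if not (parent_sets[v] & remaining))
        if not ready:
            raise ArgumentError("structure contains a directed cycle")
        order.append(ready[0])
        remaining.remove(ready[0])
    return order


def _config_index(case: np.ndarray, parents: tuple[int, ...], arities) -> int:
    """Mixed-radix parent-configuration index, highest-indexed parent fastest."""
    j = 0
    for p in parents:  # parents sorted ascending
        j = j * arities[p] + int(case[p])
    return j


def forward_sample(bn: BayesNet, n_cases: int, rng) -> Dataset:
    """Draw ``n_cases`` complete cases from the network by ancestral sampling."""
    if n_cases < 1:
        raise ArgumentError("n_cases must be >= 1")
    n = bn.structure.n_nodes
    order = topological_order(bn.structure)
    cum = [np.cumsum(cpt.probabilities, axis=1) for cpt in bn.cpts]
    values = np.empty((n_cases, n), dtype=np.int64)
    for row in range(n_cases):
        case = values[row]
        for node in order:
            cpt = bn.cpts[node]
            j = _config_index(case, cpt.parents, bn.arities)
            u = rng.uniform()
            case[node] = int(np.searchsorted(cum[node][j], u, side="right"))
    return Dataset(values=values, arities=bn.arities)


def write_dataset(dataset: Dataset, path) -> None:
    """Write as CSV: header "X1,...,Xn", one case per line, 0-based integers."""
    n = dataset.n_vars
    with open(path, "w") as fh:
        fh.write(",".join(f"X{i + 1}" for i in range(n)) + "\n")
        for row in dataset.values:
            fh.write(",".join(str(int(v)) for v in row) + "\n")


def read_dataset(path, arities=None) -> Dataset:
    """Read a dataset CSV; arities default to 1 + per-column maximum (min 2).

    Raises :class:`FormatError` with the offending line number on ragged
    rows, non-integer cells, or values outside the declared arity.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError("empty file: header row 'X1,...,Xn' required", line=1)
        names = header.strip().split(",")
        n = len(names)
        rows: list[list[int]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != n:
                raise FormatError(f"expected {n} columns, found {len(cells)}", line=lineno)
            try:
                row = [int(c) for c in cells]
            except ValueError:
                raise FormatError("non-integer cell", line=lineno) from None
            if any(v < 0 for v in row):
                raise FormatError("negative value", line=lineno)
            rows.append(row)
    values = np.array(rows, dtype=np.int64).reshape(len(rows), n)
    if arities is None:
        arities = tuple(max(2, int(values[:, i].max()) + 1 if len(rows) else 2) for i in range(n))
    else:
        arities = tuple(int(a) for a in arities)
        for i, a in enumerate(arities):
            bad = np.nonzero(values[:, i] >= a)[0]
            if bad.size:
                raise FormatError(
                    f"value {int(values[bad[0], i])} in column {i} outside declared arity {a}",
                    line=int(bad[0]) + 2,
                )
    return Dataset(values=values, arities=arities)
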