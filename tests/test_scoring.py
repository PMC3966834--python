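"""Sufficient statistics, log-likelihood, model dimension, and the five metrics."""

from math import e, log2

import numpy as np
import pytest

from bnscore import (
    DagStructure,
    Dataset,
    dimension_k,
    enumerate_dags,
    equivalence_key,
    log_likelihood,
    score_all,
    score_metrics,
    sufficient_stats,
)
from bnscore.errors import ArgumentError
from bnscore.scoring import read_score_table, write_score_table
from conftest import random_binary_dataset
from helpers import brute_force_ll


def _single_column(counts):
    """Dataset with one binary column realizing the given (zeros, ones) counts."""
    values = np.array([[0]] * counts[0] + [[1]] * counts[1])
    return Dataset(values=values, arities=(2,))


def test_sufficient_stats_marginal_tally():
    rng = np.random.default_rng(1)
    col0 = np.array([0] * 7 + [1] * 3)
    values = np.column_stack([col0, rng.integers(0, 2, 10)])
    ds = Dataset(values=values, arities=(2, 2))
    stats = sufficient_stats(ds, DagStructure(2, frozenset()))
    np.testing.assert_array_equal(stats.counts[0], [[7, 3]])


def test_sufficient_stats_conservation(data4, gold4):
    stats = sufficient_stats(data4, gold4)
    for tab in stats.counts:
        assert tab.sum() == data4.n_cases
        assert np.all(tab >= 0)


def test_sufficient_stats_single_case():
    ds = Dataset(values=np.array([[1, 0, 1]]), arities=(2, 2, 2))
    chain = DagStructure(3, frozenset({(0, 1), (1, 2)}))
    stats = sufficient_stats(ds, chain)
    for tab in stats.counts:
        assert tab.sum() == 1
        assert (tab == 1).sum() == 1


def test_sufficient_stats_dimension_mismatch(data4):
    with pytest.raises(ArgumentError):
        sufficient_stats(data4, DagStructure(3, frozenset()))


def test_parent_config_order_is_mixed_radix_highest_parent_fastest():
    # node 2 with parents (0, 1): rows ordered (x0,x1) = 00,01,10,11
    values = np.array([[0, 1, 1], [1, 0, 0], [1, 1, 1], [0, 1, 1]])
    ds = Dataset(values=values, arities=(2, 2, 2))
    collider = DagStructure(3, frozenset({(0, 2), (1, 2)}))
    tab = sufficient_stats(ds, collider).counts[2]
    np.testing.assert_array_equal(tab, [[0, 0], [0, 2], [1, 0], [0, 1]])


def test_log_likelihood_deterministic_column_is_zero():
    stats = sufficient_stats(_single_column((10, 0)), DagStructure(1, frozenset()))
    assert log_likelihood(stats) == 0.0


def test_log_likelihood_balanced_column():
    stats = sufficient_stats(_single_column((5, 5)), DagStructure(1, frozenset()))
    assert log_likelihood(stats) == pytest.approx(-10.0, abs=1e-12)


def test_log_likelihood_copied_child_adds_nothing():
    # Y identical to X: the conditional term of Y is exactly 0
    col = np.array([0, 0, 0, 1, 1, 0, 1, 1])
    ds = Dataset(values=np.column_stack([col, col]), arities=(2, 2))
    arc = DagStructure(2, frozenset({(0, 1)}))
    ll = log_likelihood(sufficient_stats(ds, arc))
    marginal = log_likelihood(
        sufficient_stats(Dataset(values=col[:, None], arities=(2,)), DagStructure(1, frozenset()))
    )
    assert ll == pytest.approx(marginal, abs=1e-12)


@pytest.mark.parametrize(
    "arcs,n,expected",
    [
        (set(), 4, 4),  # empty graph: one free parameter per root
        ({(0, 1), (1, 2)}, 3, 5),  # chain: 1 + 2 + 2
        ({(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)}, 4, 15),  # complete: 1+2+4+8
    ],
)
def test_dimension_k(arcs, n, expected):
    assert dimension_k(DagStructure(n, frozenset(arcs)), (2,) * n) == expected


def test_score_metrics_closed_form():
    # balanced single binary column: -LL = 10 bits, k = 1, n = 10
    mdl, mdl2, aic, aic2, bic = score_metrics(-10.0, k=1, n_cases=10)
    assert mdl == pytest.approx(10 + 0.5 * log2(10), abs=1e-9)
    assert mdl == pytest.approx(11.66096, abs=5e-6)
    assert bic == -mdl  # exact negation
    assert mdl2 == mdl / 10  # exact
    assert aic == pytest.approx(11.0, abs=1e-12)
    assert aic2 == pytest.approx(10 + log2(e), abs=1e-12)


def test_score_metrics_guards():
    with pytest.raises(ArgumentError):
        score_metrics(-1.0, k=1, n_cases=0)
    with pytest.raises(ArgumentError):
        score_metrics(-1.0, k=0, n_cases=10)
    with pytest.raises(ArgumentError):
        score_metrics(1.0, k=1, n_cases=10)


def test_penalty_ordering_mdl_hardest():
    # per parameter: (1/2) log2 n > log2 e > 1 once n >= 8
    for n in (8, 1000, 3000, 5000, 10000):
        assert 0.5 * log2(n) > log2(e) > 1.0


def test_score_all_exhaustive_n4(data4):
    records = score_all(data4, list(enumerate_dags(4)))
    assert len(records) == 543
    assert [r.structure_id for r in records] == list(range(543))
    for r in records:
        assert r.bic == -r.mdl  # bitwise identity
        assert r.mdl2 == r.mdl / data4.n_cases
        assert r.log_lik <= 0.0
    # empty structure: k = 4, likelihood factorizes over columns
    empty = records[0]
    assert empty.k == 4
    marg = sum(
        log_likelihood(
            sufficient_stats(
                Dataset(values=data4.values[:, [i]], arities=(2,)),
                DagStructure(1, frozenset()),
            )
        )
        for i in range(4)
    )
    assert empty.log_lik == pytest.approx(marg, abs=1e-9)


def test_markov_equivalent_chains_score_identically(data4):
    chain = DagStructure(4, frozenset({(0, 1), (1, 2), (2, 3)}))
    reverse = DagStructure(4, frozenset({(3, 2), (2, 1), (1, 0)}))
    assert equivalence_key(chain) == equivalence_key(reverse)
    a, b = score_all(data4, [chain, reverse])
    for field in ("log_lik", "mdl", "mdl2", "aic", "aic2", "bic"):
        assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-9)


def test_score_all_agrees_with_direct_stats_path(data4):
    """The cached-family fast path must equal sufficient_stats + log_likelihood."""
    dags = list(enumerate_dags(3))
    ds = Dataset(values=data4.values[:, :3], arities=(2, 2, 2))
    records = score_all(ds, dags)
    for d, r in zip(dags, records):
        ll = log_likelihood(sufficient_stats(ds, d))
        assert r.log_lik == pytest.approx(ll, abs=1e-9)
        assert r.k == dimension_k(d, ds.arities)


@pytest.mark.parametrize("seed", range(6))
def test_decomposable_ll_matches_bruteforce_oracle(seed):
    """On tiny datasets the factorized ML log-likelihood equals the naive
    per-case product of matching-count ratios."""
    rng = np.random.default_rng(seed)
    n_cases = int(rng.integers(4, 17))
    ds = random_binary_dataset(seed + 100, n_cases, 3)
    dags = list(enumerate_dags(3))
    for d in [dags[int(rng.integers(len(dags)))] for _ in range(5)]:
        ll = log_likelihood(sufficient_stats(ds, d))
        oracle = brute_force_ll(ds.values, ds.arities, [set(s) for s in d.parent_sets])
        assert ll == pytest.approx(oracle, abs=1e-9)


def test_loglik_monotone_under_arc_addition(data4):
    """A structure whose arc set contains another's never fits worse."""
    rng = np.random.default_rng(0)
    dags = list(enumerate_dags(4))
    records = score_all(data4, dags)
    by_mask = {d.arc_mask: r for d, r in zip(dags, records)}
    for _ in range(200):
        b = dags[int(rng.integers(len(dags)))]
        if not b.arcs:
            continue
        arcs = sorted(b.arcs)
        keep = [a for a in arcs if rng.random() < 0.5]
        a = DagStructure(4, frozenset(keep))  # any arc subset of a DAG is a DAG
        assert by_mask[b.arc_mask].log_lik >= by_mask[a.arc_mask].log_lik - 1e-9


def test_score_table_tsv_round_trip(tmp_path, data4):
    records = score_all(data4, list(enumerate_dags(4))[:10])
    path = tmp_path / "scores.tsv"
    write_score_table(records, path, n_cases=data4.n_cases, seed=1)
    back = read_score_table(path)
    assert len(back) == len(records)
    assert back[0].structure_id == records[0].structure_id
    assert back[3].mdl == pytest.approx(records[3].mdl, rel=1e-10)
    assert path.read_text().startswith("# n_cases=1000 seed=1 log_base=2")
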