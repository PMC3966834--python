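"""End-to-end synthetic studies of score-based structure selection.

A run draws a gold-standard network (random connected DAG + CPTs from the
chosen regime), forward-samples one dataset per requested sample size,
scores every structure in the DAG space, and summarizes each score
landscape three ways:

* the lower envelope — the best attainable score at each model dimension
  k, which traces the empirical bias-variance curve;
* the global optimum tie set — every structure achieving the best score;
* a comparison to the gold standard — the log2 ratio of the gold
  standard's score to the optimal score (0 means the gold standard is
  itself optimal; positive means the selected network beats it).

All randomness flows from a single master seed through independent
sub-seeds (one per artifact), so any dataset of a run can be regenerated
in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from math import log2
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .dag import DagStructure, count_dags, enumerate_dags
from .errors import ArgumentError
from .generate import BayesNet, low_entropy_cpts, random_cpts, random_dag, write_model
from .rng import make_rng
from .sample import Dataset, forward_sample, write_dataset
from .scoring import (
    METRIC_NAMES,
    MINIMIZED,
    ScoreRecord,
    metric_value,
    score_all,
    write_score_table,
)

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one synthetic study."""

    n_nodes: int = 4
    regime: str = "random"  # "random" or "low_entropy"
    low_entropy_p: float = 0.1
    sample_sizes: tuple[int, ...] = (1000, 3000, 5000)
    seed: int = 0
    metrics: tuple[str, ...] = METRIC_NAMES
    rng_kind: str = "numpy"  # "numpy" or "ran3"
    dag_steps: int | None = None  # default 10 * n_nodes**2 chain moves

    def __post_init__(self):
        if self.n_nodes > 5:
            raise ArgumentError("exhaustive experiments are limited to n_nodes <= 5")
        if self.n_nodes < 2:
            raise ArgumentError("n_nodes must be >= 2")
        if self.regime not in ("random", "low_entropy"):
            raise ArgumentError("regime must be 'random' or 'low_entropy'")
        if not (0.0 < self.low_entropy_p < 1.0):
            raise ArgumentError("low_entropy_p must lie strictly between 0 and 1")
        if any(s < 1 for s in self.sample_sizes):
            raise ArgumentError("sample sizes must all be >= 1")
        object.__setattr__(self, "sample_sizes", tuple(int(s) for s in self.sample_sizes))
        object.__setattr__(self, "metrics", tuple(self.metrics))
        for m in self.metrics:
            if m not in METRIC_NAMES:
                raise ArgumentError(f"unknown metric {m!r}")

    @property
    def steps(self) -> int:
        return self.dag_steps if self.dag_steps is not None else 10 * self.n_nodes**2


@dataclass(frozen=True)
class EnvelopePoint:
    """Best score over all structures of one exact model dimension k."""

    k: int
    best_value: float
    structure_ids: tuple[int, ...]


@dataclass(frozen=True)
class ComparisonReport:
    """Gold-standard score vs the landscape optimum, per metric.

    ``distance`` is log2(gold / best) on the minimized positive form of the
    metric (BIC is negated back to MDL first), so it is >= 0 whenever the
    optimum is global and 0 exactly when the gold standard ties it.
    """

    metric: str
    gold_structure_id: int
    gold_value: float
    best_structure_ids: tuple[int, ...]
    best_value: float
    distance: float
    gold_in_tie_set: bool


@dataclass
class SampleSizeResult:
    n_cases: int
    dataset: Dataset
    records: list[ScoreRecord]
    envelopes: dict[str, list[EnvelopePoint]]
    optima: dict[str, tuple[tuple[int, ...], float]]
    reports: dict[str, ComparisonReport]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    gold: BayesNet
    gold_id: int
    sub_seeds: dict[str, int]
    by_size: dict[int, SampleSizeResult]


@lru_cache(maxsize=None)
def _dag_list(n: int) -> tuple[DagStructure, ...]:
    return tuple(enumerate_dags(n))


@lru_cache(maxsize=None)
def _mask_to_id(n: int) -> dict[int, int]:
    return {d.arc_mask: i for i, d in enumerate(_dag_list(n))}


def structure_id_of(dag: DagStructure) -> int:
    """Canonical index of a structure within the enumeration of its DAG space."""
    return _mask_to_id(dag.n_nodes)[dag.arc_mask]


def derive_sub_seeds(master_seed: int, labels: Sequence[str]) -> dict[str, int]:
    """One independent sub-seed (< 2^31) per named random artifact."""
    state = np.random.SeedSequence(master_seed).generate_state(len(labels))
    return {lab: int(s % (2**31)) for lab, s in zip(labels, state)}


def make_gold_standard(config: ExperimentConfig) -> tuple[BayesNet, dict[str, int]]:
    """Draw the gold-standard network (structure + CPTs) for a configuration."""
    labels = ["structure", "cpts"] + [f"dataset_{s}" for s in config.sample_sizes]
    seeds = derive_sub_seeds(config.seed, labels)
    structure = random_dag(config.n_nodes, make_rng(seeds["structure"], config.rng_kind), config.steps)
    arities = (2,) * config.n_nodes
    if config.regime == "random":
        gold = random_cpts(structure, arities, make_rng(seeds["cpts"], config.rng_kind))
    else:
        gold = low_entropy_cpts(structure, arities, config.low_entropy_p)
    return gold, seeds


def lower_envelope(records: Sequence[ScoreRecord], metric: str) -> list[EnvelopePoint]:
    """Per-dimension optimum: one point per distinct k present in the table."""
    if not records:
        raise ArgumentError("score table is empty")
    minimize = _direction(metric)
    by_k: dict[int, list[ScoreRecord]] = {}
    for r in records:
        by_k.setdefault(r.k, []).append(r)
    points = []
    for k in sorted(by_k):
        vals = [metric_value(r, metric) for r in by_k[k]]
        best = min(vals) if minimize else max(vals)
        ties = tuple(
            r.structure_id for r, v in zip(by_k[k], vals) if abs(v - best) <= _TIE_TOL
        )
        points.append(EnvelopePoint(k=k, best_value=best, structure_ids=ties))
    return points


def global_optimum(records: Sequence[ScoreRecord], metric: str) -> tuple[tuple[int, ...], float]:
    """All structures achieving the optimal value (within 1e-9), plus the value."""
    if not records:
        raise ArgumentError("score table is empty")
    minimize = _direction(metric)
    vals = [metric_value(r, metric) for r in records]
    best = min(vals) if minimize else max(vals)
    ties = tuple(r.structure_id for r, v in zip(records, vals) if abs(v - best) <= _TIE_TOL)
    return ties, best


def _direction(metric: str) -> bool:
    try:
        return MINIMIZED[metric]
    except KeyError:
        raise ArgumentError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}") from None


def compare_to_gold(
    records: Sequence[ScoreRecord], gold: DagStructure, metric: str
) -> ComparisonReport:
    """Score distance between the gold standard and the landscape optimum.

    The distance is computed on the minimized positive form of the metric;
    for BIC that form is -BIC = MDL, so the BIC report always carries the
    same distance as the MDL report.
    """
    _direction(metric)
    gold_id = structure_id_of(gold)
    by_id = {r.structure_id: r for r in records}
    if gold_id not in by_id:
        raise ArgumentError("gold-standard structure is not present in the score table")
    best_ids, best_value = global_optimum(records, metric)
    positive = "MDL" if metric == "BIC" else metric
    gold_pos = metric_value(by_id[gold_id], positive)
    best_pos = metric_value(by_id[best_ids[0]], positive)
    distance = log2(gold_pos / best_pos)
    return ComparisonReport(
        metric=metric,
        gold_structure_id=gold_id,
        gold_value=metric_value(by_id[gold_id], metric),
        best_structure_ids=best_ids,
        best_value=best_value,
        distance=distance,
        gold_in_tie_set=gold_id in best_ids,
    )


def plot_landscape(
    records: Sequence[ScoreRecord],
    envelope: Sequence[EnvelopePoint],
    gold_id: int,
    metric: str,
    path,
) -> None:
    """Scatter of model dimension k vs score, with the per-k envelope, the
    global optimum (red) and the gold standard (green).

    A TSV sidecar (``<path>.tsv``) records the plotted coordinates so runs
    can be compared without pixel-level image diffs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = [r.k for r in records]
    vals = [metric_value(r, metric) for r in records]
    best_ids, best_value = global_optimum(records, metric)
    by_id = {r.structure_id: r for r in records}
    gold_rec = by_id[gold_id]

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(ks, vals, s=12, color="tab:blue", alpha=0.5, label="all structures")
    ax.plot(
        [p.k for p in envelope],
        [p.best_value for p in envelope],
        color="black",
        lw=1,
        marker=".",
        label="per-k optimum",
    )
    ax.scatter(
        [by_id[best_ids[0]].k], [best_value], color="red", zorder=5, label="global optimum"
    )
    ax.scatter(
        [gold_rec.k],
        [metric_value(gold_rec, metric)],
        color="green",
        zorder=5,
        label="gold standard",
    )
    ax.set_xlabel("model dimension k")
    ax.set_ylabel(f"{metric} (bits, base-2 logs)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    with open(str(path) + ".tsv", "w") as fh:
        fh.write("series\tstructure_id\tk\tvalue\n")
        for r in records:
            fh.write(f"all\t{r.structure_id}\t{r.k}\t{metric_value(r, metric):.12g}\n")
        for p in envelope:
            fh.write(f"envelope\t{p.structure_ids[0]}\t{p.k}\t{p.best_value:.12g}\n")
        fh.write(f"optimum\t{best_ids[0]}\t{by_id[best_ids[0]].k}\t{best_value:.12g}\n")
        fh.write(
            f"gold\t{gold_id}\t{gold_rec.k}\t{metric_value(gold_rec, metric):.12g}\n"
        )


def run_experiment(
    config: ExperimentConfig,
    out_dir=None,
    plots: bool = False,
) -> ExperimentResult:
    """Run the full pipeline; write the output bundle when ``out_dir`` is given."""
    gold, seeds = make_gold_standard(config)
    gold_id = structure_id_of(gold.structure)
    structures = _dag_list(config.n_nodes)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_model(gold, out / "gold_model.txt")

    by_size: dict[int, SampleSizeResult] = {}
    for size in config.sample_sizes:
        rng = make_rng(seeds[f"dataset_{size}"], config.rng_kind)
        dataset = forward_sample(gold, size, rng)
        records = score_all(dataset, structures)
        envelopes = {m: lower_envelope(records, m) for m in config.metrics}
        optima = {m: global_optimum(records, m) for m in config.metrics}
        reports = {m: compare_to_gold(records, gold.structure, m) for m in config.metrics}
        by_size[size] = SampleSizeResult(
            n_cases=size,
            dataset=dataset,
            records=records,
            envelopes=envelopes,
            optima=optima,
            reports=reports,
        )
        if out is not None:
            write_dataset(dataset, out / f"dataset_{size}.csv")
            write_score_table(records, out / f"scores_{size}.tsv", size, seed=config.seed)
            _write_envelopes(envelopes, out / f"envelope_{size}.tsv")
            _write_reports(reports, out / f"comparison_{size}.tsv")
            if plots:
                for m in config.metrics:
                    plot_landscape(
                        records, envelopes[m], gold_id, m, out / f"landscape_{m}_{size}.png"
                    )

    result = ExperimentResult(
        config=config, gold=gold, gold_id=gold_id, sub_seeds=seeds, by_size=by_size
    )
    if out is not None:
        _write_manifest(result, out / "manifest.yaml")
    return result


def _write_envelopes(envelopes: dict[str, list[EnvelopePoint]], path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tk\tbest_value\ttie_count\trepresentative\n")
        for metric, points in envelopes.items():
            for p in points:
                fh.write(
                    f"{metric}\t{p.k}\t{p.best_value:.12g}\t"
                    f"{len(p.structure_ids)}\t{p.structure_ids[0]}\n"
                )


def _write_reports(reports: dict[str, ComparisonReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tgold_value\tbest_value\tdistance\tgold_in_tie_set\n")
        for metric, rep in reports.items():
            fh.write(
                f"{metric}\t{rep.gold_value:.12g}\t{rep.best_value:.12g}\t"
                f"{rep.distance:.12g}\t{int(rep.gold_in_tie_set)}\n"
            )


def _write_manifest(result: ExperimentResult, path) -> None:
    cfg = dataclasses.asdict(result.config)
    cfg["sample_sizes"] = list(result.config.sample_sizes)
    cfg["metrics"] = list(result.config.metrics)
    doc = {
        "package": "bnscore",
        "version": __version__,
        "config": cfg,
        "sub_seeds": result.sub_seeds,
        "structure_count": count_dags(result.config.n_nodes),
        "gold_structure_id": result.gold_id,
        "gold_arcs": sorted(f"X{p + 1}>X{c + 1}" for (p, c) in result.gold.structure.arcs),
        "optima": {
            size: {
                m: {"value": float(v), "tie_count": len(ids), "representative": ids[0]}
                for m, (ids, v) in res.optima.items()
            }
            for size, res in result.by_size.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
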