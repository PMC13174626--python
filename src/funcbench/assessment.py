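"""Orchestration: evaluate methods, pick team bests, bootstrap CIs, rank.

A team may enter up to three methods; on each benchmark the team is
represented by its best-scoring method.  Confidence intervals resample the
benchmark proteins with replacement (the unit of evaluation), re-sweep the
thresholds on every resample, and report the 2.5th-97.5th percentile band.
Team-best selection is fixed before bootstrapping.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .benchmarks import BenchmarkSet
from .metrics import EvaluationCurve, MetricResult, fmax, smin, summarize, sweep
from .ontology import OntologyGraph, TermInformation
from .predictions import (PredictionSet, parse_predictions, propagate_scores,
                          validate_terms)

logger = logging.getLogger(__name__)

METRICS = ("fmax_macro", "fmax_micro", "smin")
#: metrics where smaller is better
ASCENDING_METRICS = frozenset({"smin"})


@dataclass
class MethodRecord:
    """One evaluated method: identity, prepared predictions, and its summary."""

    team: str
    model_index: int
    method_id: str
    pred: Optional[PredictionSet] = None
    result: Optional[MetricResult] = None
    curve: Optional[EvaluationCurve] = None
    ci: dict[str, "BootstrapCI"] = field(default_factory=dict)

    def value(self, metric: str) -> float:
        return getattr(self.result, metric)


@dataclass
class BootstrapCI:
    """Percentile bootstrap interval for one metric."""

    point: float
    lo: float
    hi: float
    n_iter: int
    seed: int


def evaluate_method(pred, bench: BenchmarkSet, onto: OntologyGraph,
                    ia: Optional[TermInformation], mode: str = "complete",
                    team: Optional[str] = None) -> MethodRecord:
    """Full per-method pipeline: parse, validate, propagate, sweep, summarize.

    ``pred`` may be a path to a submission file or an in-memory
    :class:`PredictionSet` (validated and propagated internally either way).
    """
    if not isinstance(pred, PredictionSet):
        pred = parse_predictions(pred)
    prepared = propagate_scores(validate_terms(pred, onto, bench.aspect), onto)
    curve = sweep(prepared, bench, ia, mode=mode)
    result = summarize(curve, prepared, bench)
    logger.info("evaluated %s on %s/%s: FmaxM=%.3f Fmaxu=%.3f Smin=%.3f C=%.3f",
                pred.method_id, bench.aspect, bench.setting,
                result.fmax_macro, result.fmax_micro, result.smin, result.coverage)
    return MethodRecord(team=pred.author or pred.method_id,
                        model_index=pred.model_index or 1,
                        method_id=pred.method_id, pred=prepared,
                        result=result, curve=curve)


def select_team_best(records: Iterable[MethodRecord], metric: str) -> list[MethodRecord]:
    """One record per team: best by the metric's direction; ties -> lowest model index."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    ascending = metric in ASCENDING_METRICS
    best: dict[str, MethodRecord] = {}
    for rec in sorted(records, key=lambda r: r.model_index):
        cur = best.get(rec.team)
        if cur is None:
            best[rec.team] = rec
            continue
        better = rec.value(metric) < cur.value(metric) if ascending \
            else rec.value(metric) > cur.value(metric)
        if better:
            best[rec.team] = rec
    return [best[t] for t in sorted(best)]


def method_stream_seed(master_seed: int, method_id: str, aspect: str, setting: str) -> int:
    """A stable per-(method, aspect, setting) seed derived from a master seed.

    Adding or removing other methods does not perturb an existing method's
    resampling stream.
    """
    tag = zlib.crc32(f"{method_id}|{aspect}|{setting}".encode())
    return (master_seed * 0x9E3779B1 + tag) % (2 ** 31)


def bootstrap_ci(pred: PredictionSet, bench: BenchmarkSet,
                 ia: Optional[TermInformation], metric: str,
                 n_iter: int = 1000, seed: int = 0, mode: str = "complete",
                 return_samples: bool = False):
    """Percentile bootstrap over benchmark proteins.

    Proteins are resampled with replacement ``n_iter`` times; the metric is
    recomputed (thresholds re-swept) on each resample; the 2.5th and 97.5th
    percentiles use linear interpolation between order statistics.
    Deterministic given ``seed``.  ``pred`` must already be validated and
    propagated.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    proteins = sorted(bench.proteins)
    n = len(proteins)

    def compute(plist: Sequence[str]) -> float:
        curve = sweep(pred, bench, ia, mode=mode, proteins=plist)
        if metric == "smin":
            return smin(curve)[0]
        return fmax(curve, metric.split("_")[1])[0]

    point = compute(proteins)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_iter)
    for k in range(n_iter):
        idx = rng.integers(0, n, n)
        samples[k] = compute([proteins[j] for j in idx])
    lo, hi = np.percentile(samples, [2.5, 97.5])
    ci = BootstrapCI(point=point, lo=float(lo), hi=float(hi), n_iter=n_iter, seed=seed)
    if return_samples:
        return ci, samples
    return ci


@dataclass
class LeaderboardRow:
    rank: int
    team: str
    method_id: str
    metric: str
    value: float
    coverage: float
    ci_lo: Optional[float] = None
    ci_hi: Optional[float] = None
    baseline: bool = False


def rank_methods(records: Sequence[MethodRecord], metric: str, top_k: int = 10,
                 baseline_teams: Iterable[str] = ("naive", "blast")) -> list[LeaderboardRow]:
    """Order team-best records by a metric and truncate to the top k.

    Smin ranks ascending, Fmax descending; ties break by higher coverage, then
    lexicographic team name.  Baseline methods keep their computed rank but are
    always appended even when outside the top k.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    ascending = metric in ASCENDING_METRICS
    baseline_teams = set(baseline_teams)

    def key(rec: MethodRecord):
        v = rec.value(metric)
        return (v if ascending else -v, -rec.result.coverage, rec.team)

    ordered = sorted(records, key=key)
    rows = []
    for rank, rec in enumerate(ordered, start=1):
        ci = rec.ci.get(metric)
        rows.append(LeaderboardRow(
            rank=rank, team=rec.team, method_id=rec.method_id, metric=metric,
            value=rec.value(metric), coverage=rec.result.coverage,
            ci_lo=ci.lo if ci else None, ci_hi=ci.hi if ci else None,
            baseline=rec.team in baseline_teams,
        ))
    kept = [r for r in rows if not r.baseline][:top_k]
    kept += [r for r in rows if r.baseline]
    return kept


def write_leaderboard(rows: Sequence[LeaderboardRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tteam\tmethod\tmetric\tvalue\tcoverage\tci_lo\tci_hi\tbaseline\n")
        for r in rows:
            lo = "" if r.ci_lo is None else repr(r.ci_lo)
            hi = "" if r.ci_hi is None else repr(r.ci_hi)
            fh.write(f"{r.rank}\t{r.team}\t{r.method_id}\t{r.metric}\t{r.value!r}"
                     f"\t{r.coverage!r}\t{lo}\t{hi}\t{int(r.baseline)}\n")
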