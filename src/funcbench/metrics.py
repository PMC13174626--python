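"""Threshold-sweep evaluation: precision/recall, Fmax, ru/mi, Smin, coverage.

Evaluation is per-protein (structured-output): at a score threshold tau each
protein i contributes its thresholded prediction set P_i(tau), compared with
its propagated truth.  For partial-knowledge proteins the terms already known
at the deadline (the prior T_i^ts) are subtracted from the prediction set
before precision is computed, so a method is not rewarded for repeating known
annotations; recall is measured on the gained truth T_i^tB \\ T_i^ts only.
With empty priors the formulas reduce to the familiar no-knowledge forms.

Definitions, writing E_i(tau) = P_i(tau) \\ T_i^ts and G_i = T_i^tB \\ T_i^ts:

* macro precision: mean over the m(tau) proteins with E_i non-empty of
  |E_i cap T_i^tB| / |E_i|;  macro recall: (1/ne) sum_i |P_i cap G_i| / |G_i|;
* micro versions pool numerators and denominators over proteins first;
* Fmax (macro or micro) is the max over tau of the harmonic mean of
  precision and recall (0 when both are 0);
* remaining uncertainty ru(tau) = (1/ne) sum_i sum_f ia(f) [f not in P_i, f in G_i],
  misinformation mi(tau) = (1/ne) sum_i sum_f ia(f) [f in P_i, f not in T_i^tB];
* Smin = min over tau of sqrt(ru^2 + mi^2), the closest approach of the
  information-weighted curve to the origin;
* coverage C = m(0)/n, the fraction of benchmark proteins predicted at all.

In the "complete" mode ne = n, the benchmark size, so unpredicted proteins
count as zero-recall; in the "incomplete" mode ne = m(0) and recall, ru and mi
are restricted to the proteins the method chose to predict.

The sweep visits every distinct submitted score (plus 1.0) as a threshold, so
the optimum is exact; the historical 101-point grid is available through the
``thresholds`` argument for backward comparability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .benchmarks import BenchmarkSet
from .ontology import TermInformation
from .predictions import PredictionSet

MODES = ("complete", "incomplete")


@dataclass
class EvaluationCurve:
    """Per-threshold evaluation surface for one method on one benchmark."""

    thresholds: np.ndarray      # ascending
    pr_macro: np.ndarray
    rc_macro: np.ndarray
    pr_micro: np.ndarray
    rc_micro: np.ndarray
    ru: np.ndarray              # bits
    mi: np.ndarray              # bits
    m: np.ndarray               # proteins with a non-empty effective set
    mode: str
    ne: int
    n: int


@dataclass
class MetricResult:
    """Summary of a curve: Fmax (both flavors), Smin, coverage, argopt taus."""

    fmax_macro: float
    fmax_macro_tau: float
    fmax_micro: float
    fmax_micro_tau: float
    smin: float
    smin_tau: float
    coverage: float


def sweep(pred: PredictionSet, bench: BenchmarkSet, ia: Optional[TermInformation],
          mode: str = "complete", thresholds: Optional[Sequence[float]] = None,
          strict_novelty: bool = False,
          proteins: Optional[Sequence[str]] = None) -> EvaluationCurve:
    """Compute the full evaluation curve.

    ``pred`` must be validated against the benchmark aspect and propagated.
    ``ia`` supplies the information-accretion weights for ru/mi (None makes
    them zero).  ``strict_novelty`` scores precision against the gained truth
    only, instead of the full tB truth set, for partial-knowledge benchmarks.
    ``proteins`` optionally fixes the evaluated protein list (repeats allowed;
    used by bootstrap resampling); it defaults to the sorted benchmark.
    """
    if mode not in MODES:
        raise ValueError(f"unknown evaluation mode {mode!r}; expected one of {MODES}")
    if bench.n == 0:
        raise ValueError("empty benchmark")
    if proteins is None:
        proteins = sorted(bench.proteins)

    n = len(proteins)
    iaf = ia.ia if ia is not None else {}

    prior: list[set[str]] = []
    gained: list[set[str]] = []
    truth: list[set[str]] = []
    events: list[tuple[float, int, str]] = []
    all_scores: set[float] = set()
    for i, protein in enumerate(proteins):
        p = bench.prior.get(protein, set())
        g = bench.gained_truth.get(protein, set())
        if not g:
            raise ValueError(f"benchmark protein {protein} has empty gained truth")
        prior.append(p)
        gained.append(g)
        truth.append(p | g)
        for term, score in pred.scores.get(protein, {}).items():
            all_scores.add(score)
            if term in p:
                continue  # prior terms affect no quantity (they sit inside T_i^tB)
            events.append((score, i, term))
    events.sort(key=lambda e: -e[0])

    if thresholds is None:
        grid = sorted(all_scores | {1.0}, reverse=True)
    else:
        grid = sorted(set(float(t) for t in thresholds), reverse=True)

    if mode == "complete":
        in_subset = [True] * n
        ne = n
    else:
        predicted = {i for _, i, _ in events}
        in_subset = [i in predicted for i in range(n)]
        ne = len(predicted)

    correct = gained if strict_novelty else truth

    # per-protein counters, updated per event; per-threshold quantities are
    # recomputed from them so ratios stay exact where they are exact
    eff_size = np.zeros(n, dtype=np.int64)      # |E_i|
    eff_tp = np.zeros(n, dtype=np.int64)        # |E_i cap correct_i|
    gained_hit = np.zeros(n, dtype=np.int64)    # |P_i cap G_i|
    gained_len = np.array([len(g) for g in gained], dtype=np.int64)
    miss = gained_len.copy()                    # |G_i \ P_i|
    ru_i = np.array([sum(iaf.get(f, 0.0) for f in sorted(g)) for g in gained])
    mi_i = np.zeros(n)
    sel = np.array(in_subset)

    tot_eff = 0
    tot_eff_tp = 0
    tot_gained_hit = 0
    tot_gained = int(gained_len[sel].sum())

    out_tau: list[float] = []
    out = {k: [] for k in ("pr_macro", "rc_macro", "pr_micro", "rc_micro", "ru", "mi", "m")}

    pos = 0
    n_events = len(events)
    for tau in grid:
        while pos < n_events and events[pos][0] >= tau:
            _, i, term = events[pos]
            pos += 1
            eff_size[i] += 1
            tot_eff += 1
            if term in correct[i]:
                eff_tp[i] += 1
                tot_eff_tp += 1
            if term in gained[i]:
                gained_hit[i] += 1
                miss[i] -= 1
                ru_i[i] = 0.0 if miss[i] == 0 else ru_i[i] - iaf.get(term, 0.0)
                if in_subset[i]:
                    tot_gained_hit += 1
            elif term not in truth[i]:
                mi_i[i] += iaf.get(term, 0.0)

        nz = eff_size > 0
        m_count = int(nz.sum())
        out_tau.append(tau)
        out["m"].append(m_count)
        out["pr_macro"].append(float((eff_tp[nz] / eff_size[nz]).sum()) / m_count
                               if m_count else 0.0)
        out["rc_macro"].append(float((gained_hit[sel] / gained_len[sel]).sum()) / ne
                               if ne else 0.0)
        out["pr_micro"].append(tot_eff_tp / tot_eff if tot_eff else 0.0)
        out["rc_micro"].append(tot_gained_hit / tot_gained if tot_gained else 0.0)
        out["ru"].append(float(ru_i[sel].sum()) / ne if ne else 0.0)
        out["mi"].append(float(mi_i[sel].sum()) / ne if ne else 0.0)

    order = slice(None, None, -1)  # grid was descending; report ascending
    return EvaluationCurve(
        thresholds=np.asarray(out_tau[order]),
        pr_macro=np.asarray(out["pr_macro"][order]),
        rc_macro=np.asarray(out["rc_macro"][order]),
        pr_micro=np.asarray(out["pr_micro"][order]),
        rc_micro=np.asarray(out["rc_micro"][order]),
        ru=np.asarray(out["ru"][order]),
        mi=np.asarray(out["mi"][order]),
        m=np.asarray(out["m"][order]),
        mode=mode, ne=ne, n=n,
    )


def _f1(pr: np.ndarray, rc: np.ndarray) -> np.ndarray:
    denom = pr + rc
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, 2.0 * pr * rc / np.where(denom > 0, denom, 1.0), 0.0)
    return f


def fmax(curve: EvaluationCurve, flavor: str = "macro") -> tuple[float, float]:
    """Max over thresholds of the pr/rc harmonic mean; ties -> smallest tau.

    Returns (fmax, argmax tau).
    """
    if flavor == "macro":
        f = _f1(curve.pr_macro, curve.rc_macro)
    elif flavor == "micro":
        f = _f1(curve.pr_micro, curve.rc_micro)
    else:
        raise ValueError(f"unknown Fmax flavor {flavor!r}")
    idx = int(np.argmax(f))  # first occurrence = smallest tau (ascending grid)
    return float(f[idx]), float(curve.thresholds[idx])


def smin(curve: EvaluationCurve) -> tuple[float, float]:
    """Min over thresholds of sqrt(ru^2 + mi^2); ties -> smallest tau.

    Returns (smin, argmin tau).
    """
    s = np.hypot(curve.ru, curve.mi)
    idx = int(np.argmin(s))
    return float(s[idx]), float(curve.thresholds[idx])


def coverage(pred: PredictionSet, bench: BenchmarkSet) -> float:
    """Fraction of benchmark proteins with at least one stored score."""
    if bench.n == 0:
        raise ValueError("empty benchmark")
    return sum(1 for p in bench.proteins if pred.scores.get(p)) / bench.n


def summarize(curve: EvaluationCurve, pred: PredictionSet,
              bench: BenchmarkSet) -> MetricResult:
    fM, tM = fmax(curve, "macro")
    fU, tU = fmax(curve, "micro")
    s, ts = smin(curve)
    return MetricResult(fmax_macro=fM, fmax_macro_tau=tM,
                        fmax_micro=fU, fmax_micro_tau=tU,
                        smin=s, smin_tau=ts,
                        coverage=coverage(pred, bench))


def write_curve(curve: EvaluationCurve, path) -> None:
    """Write the per-threshold TSV (tau, pr/rc macro+micro, ru, mi, m)."""
    with open(path, "w") as fh:
        fh.write("tau\tpr_macro\trc_macro\tpr_micro\trc_micro\tru\tmi\tm\n")
        for i in range(len(curve.thresholds)):
            row = [float(curve.thresholds[i]), float(curve.pr_macro[i]),
                   float(curve.rc_macro[i]), float(curve.pr_micro[i]),
                   float(curve.rc_micro[i]), float(curve.ru[i]), float(curve.mi[i])]
            fh.write("\t".join(repr(v) for v in row) + f"\t{int(curve.m[i])}\n")
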