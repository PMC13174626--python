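"""Independent brute-force oracles used to check the evaluation machinery.

Everything here recomputes quantities from set primitives at every distinct
threshold, with no shared code with the package's sweep, so agreement is a
genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def brute_curve(scores, prior, gained, ia, mode="complete"):
    """Per-threshold metrics with partial-knowledge prior subtraction.

    ``scores``: protein -> term -> score; ``prior``/``gained``: protein -> set;
    ``ia``: term -> bits.  Returns a list of per-threshold dicts, ascending tau.
    """
    proteins = sorted(gained)
    taus = sorted({s for d in scores.values() for s in d.values()} | {1.0})
    truth = {p: prior.get(p, set()) | gained[p] for p in proteins}
    if mode == "complete":
        sel = list(proteins)
    else:
        sel = [p for p in proteins
               if {t for t, s in scores.get(p, {}).items() if t not in prior.get(p, set())}]
    ne = len(sel)
    rows = []
    for tau in taus:
        P = {p: {t for t, s in scores.get(p, {}).items() if s >= tau} for p in proteins}
        E = {p: P[p] - prior.get(p, set()) for p in proteins}
        withpred = [p for p in proteins if E[p]]
        m = len(withpred)
        pr_macro = (sum(len(E[p] & truth[p]) / len(E[p]) for p in withpred) / m
                    if m else 0.0)
        rc_macro = (sum(len(P[p] & gained[p]) / len(gained[p]) for p in sel) / ne
                    if ne else 0.0)
        eff = sum(len(E[p]) for p in withpred)
        pr_micro = (sum(len(E[p] & truth[p]) for p in withpred) / eff if eff else 0.0)
        tg = sum(len(gained[p]) for p in sel)
        rc_micro = (sum(len(P[p] & gained[p]) for p in sel) / tg if tg else 0.0)
        ru = (sum(ia.get(f, 0.0) for p in sel for f in sorted(gained[p]) if f not in P[p]) / ne
              if ne else 0.0)
        mi = (sum(ia.get(f, 0.0) for p in sel for f in sorted(P[p]) if f not in truth[p]) / ne
              if ne else 0.0)
        rows.append(dict(tau=tau, pr_macro=pr_macro, rc_macro=rc_macro,
                         pr_micro=pr_micro, rc_micro=rc_micro, ru=ru, mi=mi, m=m))
    return rows


def brute_curve_plain(scores, truth, ia, mode="complete"):
    """The no-knowledge formulas: no prior anywhere, truth == gained truth."""
    proteins = sorted(truth)
    taus = sorted({s for d in scores.values() for s in d.values()} | {1.0})
    if mode == "complete":
        sel = list(proteins)
    else:
        sel = [p for p in proteins if scores.get(p)]
    ne = len(sel)
    rows = []
    for tau in taus:
        P = {p: {t for t, s in scores.get(p, {}).items() if s >= tau} for p in proteins}
        withpred = [p for p in proteins if P[p]]
        m = len(withpred)
        pr_macro = (sum(len(P[p] & truth[p]) / len(P[p]) for p in withpred) / m
                    if m else 0.0)
        rc_macro = (sum(len(P[p] & truth[p]) / len(truth[p]) for p in sel) / ne
                    if ne else 0.0)
        eff = sum(len(P[p]) for p in withpred)
        pr_micro = (sum(len(P[p] & truth[p]) for p in withpred) / eff if eff else 0.0)
        tg = sum(len(truth[p]) for p in sel)
        rc_micro = (sum(len(P[p] & truth[p]) for p in sel) / tg if tg else 0.0)
        ru = (sum(ia.get(f, 0.0) for p in sel for f in sorted(truth[p]) if f not in P[p]) / ne
              if ne else 0.0)
        mi = (sum(ia.get(f, 0.0) for p in sel for f in sorted(P[p]) if f not in truth[p]) / ne
              if ne else 0.0)
        rows.append(dict(tau=tau, pr_macro=pr_macro, rc_macro=rc_macro,
                         pr_micro=pr_micro, rc_micro=rc_micro, ru=ru, mi=mi, m=m))
    return rows


def brute_fmax(rows, flavor):
    best = 0.0
    for r in rows:
        pr, rc = r[f"pr_{flavor}"], r[f"rc_{flavor}"]
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def brute_smin(rows):
    return min(math.sqrt(r["ru"] ** 2 + r["mi"] ** 2) for r in rows)


def percentile_linear(values, q):
    """Sort-and-index percentile with linear interpolation between order stats."""
    xs = sorted(values)
    h = (len(xs) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (xs[hi] - xs[lo]) * (h - lo)


def random_raw_fixture(rng, max_proteins=5, max_terms=12, with_prior=True,
                       score_decimals=2):
    """A random flat benchmark: term universe, priors, gained truth, scores, ia.

    Scores are rounded to a coarse grid so threshold ties occur; some proteins
    get no predictions at all so coverage < 1 cases are exercised.
    """
    n_terms = int(rng.integers(3, max_terms + 1))
    terms = [f"X:{i:03d}" for i in range(n_terms)]
    n = int(rng.integers(1, max_proteins + 1))
    prior, gained, scores = {}, {}, {}
    ia = {t: float(np.round(rng.uniform(0.0, 3.0), 3)) for t in terms}
    for i in range(n):
        p = f"P{i}"
        perm = [terms[j] for j in rng.permutation(n_terms)]
        k_gained = int(rng.integers(1, max(2, n_terms // 2 + 1)))
        gained[p] = set(perm[:k_gained])
        prior[p] = set()
        if with_prior and rng.random() < 0.5:
            rest = perm[k_gained:]
            prior[p] = set(rest[:int(rng.integers(0, len(rest) + 1))])
        if rng.random() < 0.9:
            k_scored = int(rng.integers(1, n_terms + 1))
            perm2 = [terms[j] for j in rng.permutation(n_terms)]
            scores[p] = {t: float(np.round(rng.uniform(0.01, 1.0), score_decimals))
                         for t in perm2[:k_scored]}
    return terms, prior, gained, scores, ia


def conditional_frequency_ia(onto, sets_by_aspect, relations=("is_a", "part_of")):
    """Count-based information accretion, walking the graph edges directly."""
    roots = set(onto.roots.values())
    out = {}
    for term in onto.graph.nodes:
        if term in roots:
            out[term] = 0.0
            continue
        aspect = onto.graph.nodes[term]["aspect"]
        parents = {v for _, v, d in onto.graph.out_edges(term, data=True)
                   if (set(d["relations"]) & set(relations))
                   and onto.graph.nodes[v]["aspect"] == aspect} - roots
        den = num = 0
        for s in sets_by_aspect.get(aspect, []):
            if parents <= s:
                den += 1
                if term in s:
                    num += 1
        out[term] = (None if den == 0 or num == 0 else -math.log2(num / den))
    # zero-count terms take the aspect maximum, as the estimator defines
    for term, value in list(out.items()):
        if value is None:
            aspect = onto.graph.nodes[term]["aspect"]
            finite = [v for t, v in out.items()
                      if v is not None and t not in roots
                      and onto.graph.nodes[t]["aspect"] == aspect]
            out[term] = max(finite, default=0.0)
    return out


def make_bench_pred(prior, gained, scores, aspect="MF", setting="PK"):
    """Wrap raw dicts in the package's benchmark/prediction containers."""
    from funcbench.benchmarks import BenchmarkSet
    from funcbench.predictions import PredictionSet

    bench = BenchmarkSet(aspect=aspect, setting=setting,
                         proteins=set(gained), prior=dict(prior),
                         gained_truth=dict(gained))
    pred = PredictionSet(method_id="raw", scores=dict(scores), propagated=True)
    return bench, pred
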