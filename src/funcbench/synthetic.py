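"""Synthetic ontologies, annotation snapshots, and predictors with known truth.

Everything the evaluation pipeline consumes in production -- an OBO ontology,
two annotation snapshots bracketing an accumulation phase, scored submission
files, and a similarity hit table -- can be generated here with planted ground
truth, so the whole package is testable without external downloads.

The generator emulates the structure of the real inputs (a rooted DAG per
aspect, proteins planted in the no/limited/partial-knowledge roles, a tunable
quality knob separating true-term from false-term scores) but not the
statistics of the real Gene Ontology (term counts, depth distribution,
annotation biases).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .annotations import AnnotationSnapshot
from .benchmarks import BenchmarkSet, classify_protein
from .ontology import (ASPECT_TO_NAMESPACE, ASPECTS, OntologyGraph, _build,
                       DEFAULT_PROPAGATION_RELATIONS, propagate)
from .predictions import PredictionSet, write_predictions

ROLES = ("NK", "LK", "PK", "none")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    ``frac_nk/lk/pk`` plant proteins in the three evaluation roles relative to
    ``eval_aspect``; the remainder are planted as "none" (no gained terms, so
    they join no benchmark).  ``gain_rate`` is the mean number of newly drawn
    source terms per protein between the two snapshots; ``predictor_quality``
    in [0, 1] controls how well simulated scores separate true from false
    terms (1 = perfect separation, 0 = exchangeable).
    """

    n_terms: int = 30               # per aspect, including the root
    p_extra_parent: float = 0.3     # chance a term gets a second parent
    p_part_of: float = 0.15         # chance an extra parent uses part_of
    n_proteins: int = 200
    frac_nk: float = 0.25
    frac_lk: float = 0.25
    frac_pk: float = 0.40
    gain_rate: float = 2.0
    predictor_quality: float = 0.8
    eval_aspect: str = "MF"
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("need at least a root and one child per aspect")
        if self.frac_nk + self.frac_lk + self.frac_pk > 1.0 + 1e-9:
            raise ValueError("role fractions must sum to at most 1")
        if not 0.0 <= self.predictor_quality <= 1.0:
            raise ValueError("predictor_quality must lie in [0, 1]")
        if self.eval_aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {self.eval_aspect!r}")


def _term_id(aspect_index: int, i: int) -> str:
    return f"GO:{(aspect_index + 1) * 1000000 + i:07d}"


def random_ontology(spec: FixtureSpec) -> OntologyGraph:
    """A rooted random DAG per aspect; every non-root term has 1-2 parents.

    Parents are drawn among earlier terms of the same aspect, so acyclicity
    and reachability from the root hold by construction.  Deterministic given
    the spec seed.
    """
    rng = np.random.default_rng([spec.seed, 1])
    dg = nx.DiGraph()
    for a, aspect in enumerate(ASPECTS):
        ids = [_term_id(a, i) for i in range(spec.n_terms)]
        for i, term in enumerate(ids):
            dg.add_node(term, aspect=aspect, name=f"{aspect} term {i}")
        for i in range(1, spec.n_terms):
            parents = {int(rng.integers(0, i))}
            if i >= 2 and rng.random() < spec.p_extra_parent:
                extra = int(rng.integers(0, i))
                if extra not in parents:
                    rel = "part_of" if rng.random() < spec.p_part_of else "is_a"
                    dg.add_edge(ids[i], ids[extra], relations={rel})
            for p in parents:
                dg.add_edge(ids[i], ids[p], relations={"is_a"})
    return _build(dg, {}, DEFAULT_PROPAGATION_RELATIONS)


def _closure(onto: OntologyGraph, terms) -> set[str]:
    return propagate(onto, terms)


def _sample_terms(rng, pool: Sequence[str], k: int) -> list[str]:
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[int(i)] for i in np.sort(idx)]


def simulate_snapshots(onto: OntologyGraph, spec: FixtureSpec
                       ) -> tuple[AnnotationSnapshot, AnnotationSnapshot, dict[str, str]]:
    """Plant NK/LK/PK/none roles and build consistent (ts, tB) snapshots.

    Returns the deadline snapshot, the benchmark-time snapshot (a per-protein
    superset), and the planted role of every protein relative to the spec's
    evaluation aspect.  Snapshots are propagated (roots removed) by
    construction, so classification definitions recover the planted roles
    exactly.
    """
    rng = np.random.default_rng([spec.seed, 2])
    eval_aspect = spec.eval_aspect
    other_aspects = [a for a in ASPECTS if a != eval_aspect]
    roots = onto.root_terms
    pool = {a: sorted(t for t in onto.terms if onto.aspect_of(t) == a and t not in roots)
            for a in ASPECTS}

    n = spec.n_proteins
    counts = {
        "NK": int(round(spec.frac_nk * n)),
        "LK": int(round(spec.frac_lk * n)),
        "PK": int(round(spec.frac_pk * n)),
    }
    counts["none"] = n - sum(counts.values())
    if counts["none"] < 0:
        raise ValueError("role fractions exceed 1 after rounding")
    roles = [r for r in ROLES for _ in range(counts[r])]
    rng.shuffle(roles)

    ts = AnnotationSnapshot(label="ts", propagated=True)
    tB = AnnotationSnapshot(label="tB", propagated=True)
    planted: dict[str, str] = {}

    def n_gain() -> int:
        return max(1, int(rng.poisson(spec.gain_rate)))

    for i, role in enumerate(roles):
        protein = f"T{i:05d}"
        planted[protein] = role
        ts_sets: dict[str, set[str]] = {}
        tb_sets: dict[str, set[str]] = {}

        if role in ("LK", "none"):
            # deadline-time knowledge in another aspect
            other = other_aspects[int(rng.integers(0, len(other_aspects)))]
            ts_sets[other] = _closure(onto, _sample_terms(rng, pool[other], 1 + int(rng.poisson(1.0))))
        if role == "PK":
            prior = _closure(onto, _sample_terms(rng, pool[eval_aspect],
                                                 1 + int(rng.integers(0, 2))))
            ts_sets[eval_aspect] = prior
        if role == "none" and rng.random() < 0.5:
            ts_sets[eval_aspect] = _closure(onto, _sample_terms(rng, pool[eval_aspect], 1))

        tb_sets = {a: set(s) for a, s in ts_sets.items()}
        if role in ("NK", "LK"):
            tb_sets[eval_aspect] = _closure(onto, _sample_terms(rng, pool[eval_aspect], n_gain()))
        elif role == "PK":
            prior = ts_sets[eval_aspect]
            novel: list[str] = []
            attempts = 0
            want = n_gain()
            while len(novel) < want and attempts < 200:
                attempts += 1
                t = pool[eval_aspect][int(rng.integers(0, len(pool[eval_aspect])))]
                if not (_closure(onto, [t]) <= prior):
                    novel.append(t)
            if not novel:
                raise ValueError(
                    "could not plant a PK gain; ontology too small for the sampled prior"
                )
            tb_sets[eval_aspect] = prior | _closure(onto, novel)

        ts_sets = {a: s for a, s in ts_sets.items() if s}
        tb_sets = {a: s for a, s in tb_sets.items() if s}
        if ts_sets:
            ts.annotations[protein] = ts_sets
        if tb_sets:
            tB.annotations[protein] = tb_sets

    return ts, tB, planted


def simulate_predictor(bench: BenchmarkSet, onto: OntologyGraph, quality: float,
                       seed: int, coverage: float = 1.0,
                       method_id: str = "sim", team: Optional[str] = None,
                       model_index: int = 1) -> PredictionSet:
    """Score the benchmark with a predictor of tunable quality.

    True terms (the protein's full tB truth) draw scores pushed towards 1 and
    false terms scores pushed towards 0 by a power transform of a common
    uniform base: with u ~ U(0.001, 1), true terms score u^(1/(1+4q)) and
    false terms u^(1+4q), rounded to 3 decimals with a 0.001 floor.  At q=0
    the two are exchangeable; the distributions overlap for 0 < q < 1; at q=1
    true terms score exactly 1.0 and false terms 0.001 (perfect separation,
    so Fmax = 1 is achievable).  ``coverage`` drops whole proteins at random
    to emulate partial submissions.
    """
    if not 0.0 <= quality <= 1.0:
        raise ValueError("quality must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    roots = onto.root_terms
    aspect_terms = sorted(t for t in onto.terms
                          if onto.aspect_of(t) == bench.aspect and t not in roots)

    def draw(true_term: bool) -> float:
        if quality == 1.0:
            return 1.0 if true_term else 0.001
        u = rng.uniform(0.001, 1.0)
        power = 1.0 + 4.0 * quality
        s = u ** (1.0 / power) if true_term else u ** power
        return max(0.001, min(1.0, round(s, 3)))

    scores: dict[str, dict[str, float]] = {}
    for protein in sorted(bench.proteins):
        if rng.random() >= coverage:
            continue
        truth = bench.truth(protein)
        per: dict[str, float] = {}
        for term in sorted(truth):
            per[term] = draw(True)
        false_pool = [t for t in aspect_terms if t not in truth]
        k = min(len(false_pool), max(1, int(rng.poisson(len(bench.gained_truth[protein])))))
        for term in _sample_terms(rng, false_pool, k):
            per[term] = draw(False)
        scores[protein] = per
    return PredictionSet(method_id=method_id, scores=scores, propagated=False,
                         author=team or method_id, model_index=model_index)


def write_obo(onto: OntologyGraph, path) -> None:
    """Write the ontology as an OBO 1.2 flat file (is_a + part_of)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(onto.terms):
            data = onto.graph.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {ASPECT_TO_NAMESPACE[data['aspect']]}\n")
            for _, parent, edata in sorted(onto.graph.out_edges(term, data=True)):
                for rel in sorted(edata["relations"]):
                    if rel == "is_a":
                        fh.write(f"is_a: {parent}\n")
                    else:
                        fh.write(f"relationship: {rel} {parent}\n")


def simulate_hit_table(bench_proteins: Sequence[str], reference: AnnotationSnapshot,
                       seed: int, max_hits: int = 3) -> list[tuple[str, str, float]]:
    """Random similarity hits from targets to annotated reference proteins."""
    rng = np.random.default_rng(seed)
    refs = sorted(reference.annotations)
    rows: list[tuple[str, str, float]] = []
    if not refs:
        return rows
    for target in sorted(bench_proteins):
        for _ in range(1 + int(rng.integers(0, max_hits))):
            ref = refs[int(rng.integers(0, len(refs)))]
            identity = float(np.round(rng.uniform(35.0, 95.0), 1))
            rows.append((target, ref, identity))
    return rows


DEFAULT_PREDICTORS = (
    ("alpha", 1, 0.9),
    ("alpha", 2, 0.6),
    ("beta", 1, 0.7),
    ("gamma", 1, 0.4),
)


def write_fixture(spec: FixtureSpec, out_dir,
                  predictors: Sequence[tuple[str, int, float]] = DEFAULT_PREDICTORS) -> dict:
    """Emit a complete on-disk study: OBO, snapshots, submissions, hits, manifest.

    Prediction files cover every protein with gained truth in the evaluation
    aspect (any role), written in the CAFA submission format so the parsers
    are exercised end to end.  Returns the manifest (also written as JSON).
    """
    from . import annotations as ann

    os.makedirs(out_dir, exist_ok=True)
    onto = random_ontology(spec)
    ts, tB, planted = simulate_snapshots(onto, spec)

    write_obo(onto, os.path.join(out_dir, "ontology.obo"))
    ann.write_snapshot(ts, os.path.join(out_dir, "snapshot_ts.tsv"))
    ann.write_snapshot(tB, os.path.join(out_dir, "snapshot_tb.tsv"))

    # union benchmark over every role with gained truth, used as target list
    union = BenchmarkSet(aspect=spec.eval_aspect, setting="NK+LK")
    for protein in sorted(tB.proteins):
        label = classify_protein(protein, ts, tB, spec.eval_aspect)
        if label == "none":
            continue
        prior = set(ts.terms(protein, spec.eval_aspect))
        union.proteins.add(protein)
        union.prior[protein] = prior
        union.gained_truth[protein] = tB.terms(protein, spec.eval_aspect) - prior

    pred_dir = os.path.join(out_dir, "predictions")
    os.makedirs(pred_dir, exist_ok=True)
    manifest_preds = []
    for k, (team, model, quality) in enumerate(predictors):
        pred = simulate_predictor(union, onto, quality, seed=spec.seed * 1000 + k,
                                  method_id=f"{team}_{model}", team=team,
                                  model_index=model)
        fname = f"{team}_{model}.txt"
        write_predictions(pred, os.path.join(pred_dir, fname))
        manifest_preds.append({"team": team, "model": model, "quality": quality,
                               "file": os.path.join("predictions", fname)})

    hits = simulate_hit_table(sorted(union.proteins), ts, seed=spec.seed * 1000 + 999)
    with open(os.path.join(out_dir, "hits.tsv"), "w") as fh:
        for target, ref, identity in hits:
            fh.write(f"{target}\t{ref}\t{identity}\n")

    manifest = {"spec": asdict(spec), "planted": planted, "predictors": manifest_preds}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
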