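"""Prediction files, validation, score propagation, and the two baselines.

A submission assigns each (protein, term) pair a score in (0,1] interpreted as
the strength of the association.  Before evaluation, predicted terms are
resolved against the ontology and scores are propagated upward so that every
ancestor scores at least as high as its best descendant -- the thresholded
prediction set is then ancestor-closed at any cutoff, matching the propagated
ground truth.

Two reference predictors calibrate the difficulty of a benchmark: the Naive
predictor scores every term by its frequency among annotated reference
proteins (a prior-only method), and the similarity-transfer predictor copies
annotations from sequence-similar reference proteins scored by percent
identity (a BLAST-style baseline consuming a precomputed hit table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotations import AnnotationSnapshot
from .ontology import ASPECTS, OntologyGraph

logger = logging.getLogger(__name__)

MAX_MODELS_PER_TEAM = 3


@dataclass
class PredictionSet:
    """Scored term lists for one method: protein -> term -> score in (0,1]."""

    method_id: str
    scores: dict[str, dict[str, float]] = field(default_factory=dict)
    propagated: bool = False
    author: Optional[str] = None
    model_index: Optional[int] = None
    keywords: tuple[str, ...] = ()

    @property
    def proteins(self) -> set[str]:
        return set(self.scores)

    def terms_above(self, protein: str, tau: float) -> set[str]:
        """The thresholded prediction set P_i(tau)."""
        return {t for t, s in self.scores.get(protein, {}).items() if s >= tau}


def _store(scores: dict[str, dict[str, float]], protein: str, term: str,
           score: float) -> bool:
    """Insert a score, collapsing duplicates to the max. Returns True if duplicate."""
    per = scores.setdefault(protein, {})
    if term in per:
        per[term] = max(per[term], score)
        return True
    per[term] = score
    return False


def parse_predictions(path, method_id: Optional[str] = None) -> PredictionSet:
    """Read a CAFA-format submission or a headerless 3-column TSV.

    The CAFA format carries AUTHOR / MODEL / KEYWORDS header lines, whitespace
    separated (target, term, score) rows, and an END footer.  Scores outside
    (0,1] reject the row (counted); duplicate pairs collapse to the maximum
    score; a MODEL index above 3 is an error since a team may enter at most
    three methods.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]

    author = None
    model_index = None
    keywords: tuple[str, ...] = ()
    rows = lines
    if lines and lines[0].upper().startswith("AUTHOR"):
        body_start = 0
        for i, ln in enumerate(lines):
            upper = ln.upper()
            if upper.startswith("AUTHOR"):
                author = ln.split(None, 1)[1] if len(ln.split(None, 1)) > 1 else ""
            elif upper.startswith("MODEL"):
                model_index = int(ln.split()[1])
                if not 1 <= model_index <= MAX_MODELS_PER_TEAM:
                    raise ValueError(
                        f"{path}: MODEL {model_index} out of range; at most "
                        f"{MAX_MODELS_PER_TEAM} methods per team"
                    )
            elif upper.startswith("KEYWORDS"):
                parts = ln.split(None, 1)
                if len(parts) > 1:
                    keywords = tuple(k.strip() for k in parts[1].rstrip(".").split(","))
            else:
                body_start = i
                break
        else:
            body_start = len(lines)
        rows = lines[body_start:]
        if rows and rows[-1].upper() == "END":
            rows = rows[:-1]

    scores: dict[str, dict[str, float]] = {}
    rejected = 0
    duplicates = 0
    for ln in rows:
        fields = ln.split()
        if len(fields) != 3:
            rejected += 1
            continue
        protein, term, raw = fields
        try:
            score = float(raw)
        except ValueError:
            rejected += 1
            continue
        if not 0.0 < score <= 1.0:
            rejected += 1
            continue
        duplicates += _store(scores, protein, term, score)
    if rejected:
        logger.warning("parse_predictions: rejected %d rows in %s", rejected, path)
    if duplicates:
        logger.warning("parse_predictions: collapsed %d duplicate pairs (max score) in %s",
                       duplicates, path)

    if method_id is None:
        method_id = f"{author}_{model_index}" if author is not None else str(path)
    return PredictionSet(method_id=method_id, scores=scores, author=author,
                         model_index=model_index, keywords=keywords)


def validate_terms(pred: PredictionSet, onto: OntologyGraph,
                   aspect: str) -> PredictionSet:
    """Resolve alternate ids and keep only non-root terms of the given aspect.

    Unresolvable and cross-aspect terms are dropped with counted warnings;
    predictions resolving to the same primary term collapse to the max score.
    """
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}")
    roots = onto.root_terms
    out: dict[str, dict[str, float]] = {}
    dropped_unresolved = dropped_aspect = dropped_root = 0
    for protein, per in pred.scores.items():
        for term, score in per.items():
            resolved = onto.resolve(term)
            if resolved is None:
                dropped_unresolved += 1
                continue
            if resolved in roots:
                dropped_root += 1
                continue
            if onto.aspect_of(resolved) != aspect:
                dropped_aspect += 1
                continue
            _store(out, protein, resolved, score)
    out = {p: per for p, per in out.items() if per}
    if dropped_unresolved or dropped_aspect or dropped_root:
        logger.info(
            "validate_terms[%s/%s]: dropped %d unresolvable, %d cross-aspect, %d root predictions",
            pred.method_id, aspect, dropped_unresolved, dropped_aspect, dropped_root,
        )
    return PredictionSet(method_id=pred.method_id, scores=out, propagated=False,
                         author=pred.author, model_index=pred.model_index,
                         keywords=pred.keywords)


def propagate_scores(pred: PredictionSet, onto: OntologyGraph) -> PredictionSet:
    """Give every ancestor the max score over its scored descendants.

    Keeps scores in (0,1], is idempotent, never lowers a stored score, and
    makes every thresholded set ancestor-closed.  Aspect roots are skipped.
    """
    roots = onto.root_terms
    out: dict[str, dict[str, float]] = {}
    for protein, per in pred.scores.items():
        new: dict[str, float] = {}
        for term, score in per.items():
            for t in (term, *onto.ancestors(term)):
                if t in roots:
                    continue
                if score > new.get(t, 0.0):
                    new[t] = score
        out[protein] = new
    return PredictionSet(method_id=pred.method_id, scores=out, propagated=True,
                         author=pred.author, model_index=pred.model_index,
                         keywords=pred.keywords)


def naive_baseline(reference: AnnotationSnapshot, onto: OntologyGraph,
                   targets: Iterable[str]) -> PredictionSet:
    """The Naive predictor: term frequency in the reference, same for all targets.

    Within each aspect, a term scores the fraction of annotated reference
    proteins that carry it (reference sets are propagated, roots excluded).
    """
    if not reference.propagated:
        raise ValueError("naive baseline requires a propagated reference snapshot")
    template: dict[str, float] = {}
    any_annotated = False
    for aspect in ASPECTS:
        sets = [terms for by_aspect in reference.annotations.values()
                for a, terms in by_aspect.items() if a == aspect and terms]
        if not sets:
            continue
        any_annotated = True
        counts: dict[str, int] = {}
        for s in sets:
            for t in s:
                counts[t] = counts.get(t, 0) + 1
        denom = len(sets)
        for t, c in counts.items():
            template[t] = c / denom
    if not any_annotated:
        raise ValueError("empty reference snapshot: cannot build the naive baseline")
    scores = {target: dict(template) for target in targets}
    return PredictionSet(method_id="naive", scores=scores, propagated=True,
                         author="naive", model_index=1)


def similarity_baseline(hit_table: Iterable[tuple[str, str, float]],
                        reference: AnnotationSnapshot,
                        method_id: str = "blast") -> PredictionSet:
    """Annotation transfer from similar sequences (BLAST-style baseline).

    Each hit row is (target, reference protein, percent identity in (0,100]).
    A target scores each term of a hit reference protein at identity/100,
    keeping the max over hits.  Targets without hits get no predictions,
    which lowers the method's coverage.
    """
    if not reference.propagated:
        raise ValueError("similarity baseline requires a propagated reference snapshot")
    scores: dict[str, dict[str, float]] = {}
    rejected = 0
    for target, ref_protein, identity in hit_table:
        identity = float(identity)
        if not 0.0 < identity <= 100.0:
            rejected += 1
            continue
        score = identity / 100.0
        for terms in reference.annotations.get(ref_protein, {}).values():
            for term in terms:
                _store(scores, target, term, score)
    if rejected:
        logger.warning("similarity_baseline: rejected %d hits with identity outside (0,100]",
                       rejected)
    return PredictionSet(method_id=method_id, scores=scores, propagated=reference.propagated,
                         author=method_id, model_index=1)


def read_hit_table(path) -> list[tuple[str, str, float]]:
    """Read a (target, reference protein, percent identity) TSV."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            target, ref_protein, identity = line.split("\t")[:3]
            rows.append((target, ref_protein, float(identity)))
    return rows


def write_predictions(pred: PredictionSet, path) -> None:
    """Write a CAFA-format submission file (AUTHOR/MODEL/KEYWORDS, rows, END)."""
    with open(path, "w") as fh:
        fh.write(f"AUTHOR {pred.author or pred.method_id}\n")
        fh.write(f"MODEL {pred.model_index or 1}\n")
        if pred.keywords:
            fh.write("KEYWORDS " + ", ".join(pred.keywords) + ".\n")
        for protein in sorted(pred.scores):
            for term in sorted(pred.scores[protein]):
                fh.write(f"{protein}\t{term}\t{pred.scores[protein][term]!r}\n")
        fh.write("END\n")
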