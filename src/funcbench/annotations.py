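"""Reading and cleaning protein annotation records.

A benchmark is built from two *snapshots* of a curated annotation database:
one frozen at the challenge submission deadline (ts) and one at evaluation
time (tB).  Before snapshots are formed, raw records are filtered down to
experimentally supported, positive, non-duplicate annotations, the catch-all
MF term "protein binding" (GO:0005515) is removed, and database accessions
are mapped to challenge target identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .ontology import ASPECTS, OntologyGraph, propagate

logger = logging.getLogger(__name__)

#: Evidence codes treated as experimental for ground-truth purposes.  TAS and
#: IC are curator/author statements in GO's own taxonomy but are retained here
#: as part of the experimental set used for CAFA-style ground truth.
EXPERIMENTAL_EVIDENCE_CODES = frozenset({
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
    "TAS", "IC", "HTP", "HDA", "HMP", "HGI", "HEP",
})

#: The MF "protein binding" term, excluded from ground truth: it is too
#: unspecific to reward and would dominate the MF benchmark.
PROTEIN_BINDING = "GO:0005515"

GAF_ASPECT_LETTER = {"F": "MF", "P": "BP", "C": "CC"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein-term association with its evidence and qualifier."""

    object_id: str
    term: str
    evidence: str
    qualifier: str = ""
    aspect: Optional[str] = None

    @property
    def negated(self) -> bool:
        return "NOT" in self.qualifier.split("|")


@dataclass
class AnnotationSnapshot:
    """Per-protein, per-aspect term sets at a fixed point in time.

    ``annotations`` maps protein -> aspect -> set of terms.  When
    ``propagated`` is true, every set equals its own ancestral closure with
    aspect roots removed.
    """

    label: str
    annotations: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    propagated: bool = False

    @property
    def proteins(self) -> set[str]:
        return set(self.annotations)

    def terms(self, protein: str, aspect: str) -> set[str]:
        return self.annotations.get(protein, {}).get(aspect, set())

    def has_any(self, protein: str, aspects: Iterable[str] = ASPECTS) -> bool:
        return any(self.terms(protein, a) for a in aspects)


def parse_annotations(path, dialect: str = "gaf") -> list[AnnotationRecord]:
    """Read annotation records from a GAF 2.x file or a simple TSV.

    The simple TSV dialect has columns (protein, term, evidence[, qualifier]).
    Comment lines ('!' for GAF, '#' for TSV) are skipped.  Malformed rows are
    skipped with a counted warning; more than 10% malformed rows is a hard
    failure.
    """
    dialect = dialect.lower()
    if dialect not in ("gaf", "tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    comment = "!" if dialect == "gaf" else "#"
    records: list[AnnotationRecord] = []
    malformed = 0
    total = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(comment):
                continue
            total += 1
            fields = line.split("\t")
            try:
                if dialect == "gaf":
                    rec = AnnotationRecord(
                        object_id=fields[1],
                        qualifier=fields[3],
                        term=fields[4],
                        evidence=fields[6],
                        aspect=GAF_ASPECT_LETTER[fields[8]],
                    )
                else:
                    rec = AnnotationRecord(
                        object_id=fields[0],
                        term=fields[1],
                        evidence=fields[2],
                        qualifier=fields[3] if len(fields) > 3 else "",
                    )
                if not rec.object_id or ":" not in rec.term or not rec.evidence:
                    raise ValueError("missing field")
            except (IndexError, KeyError, ValueError):
                malformed += 1
                continue
            records.append(rec)
    if malformed:
        logger.warning("parse_annotations: skipped %d malformed rows in %s", malformed, path)
        if malformed > 0.1 * total:
            raise ValueError(
                f"{path}: {malformed}/{total} rows malformed (>10%); refusing to continue"
            )
    if not records:
        logger.warning("parse_annotations: no records parsed from %s", path)
    return records


def filter_experimental(records: Iterable[AnnotationRecord]) -> list[AnnotationRecord]:
    """Keep experimentally evidenced, positive, non-duplicate records.

    Drops records outside the 13-code experimental evidence list, NOT-qualified
    (negative) records, duplicate (protein, term) pairs, and all annotations to
    the MF "protein binding" term.  Pure filter: idempotent and, up to record
    order, order-independent.
    """
    seen: set[tuple[str, str]] = set()
    out: list[AnnotationRecord] = []
    for rec in records:
        if rec.evidence not in EXPERIMENTAL_EVIDENCE_CODES:
            continue
        if rec.negated:
            continue
        if rec.term == PROTEIN_BINDING:
            continue
        key = (rec.object_id, rec.term)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def map_ids(records: Iterable[AnnotationRecord],
            mapping: Mapping[str, str]) -> list[AnnotationRecord]:
    """Replace database accessions with target IDs; drop unmapped records.

    The mapping must be injective (no two accessions mapped to one target),
    otherwise distinct proteins would be silently merged.
    """
    targets = list(mapping.values())
    if len(set(targets)) != len(targets):
        raise ValueError("ID mapping is not injective: multiple accessions share a target ID")
    out = []
    dropped = 0
    for rec in records:
        target = mapping.get(rec.object_id)
        if target is None:
            dropped += 1
            continue
        out.append(replace(rec, object_id=target))
    if dropped:
        logger.warning("map_ids: dropped %d records with unmapped accessions", dropped)
    return out


def build_snapshot(records: Iterable[AnnotationRecord], onto: OntologyGraph,
                   propagate_terms: bool = True, label: str = "") -> AnnotationSnapshot:
    """Group filtered, mapped records into per-protein per-aspect term sets.

    Terms are resolved through the ontology's alternate-id map (the aspect is
    taken from the ontology, overriding any aspect letter in the record);
    unresolvable terms are dropped with a warning.  With ``propagate_terms``
    each set is replaced by its ancestral closure, roots removed.
    """
    annotations: dict[str, dict[str, set[str]]] = {}
    dropped = 0
    for rec in records:
        term = onto.resolve(rec.term)
        if term is None:
            dropped += 1
            continue
        aspect = onto.aspect_of(term)
        annotations.setdefault(rec.object_id, {}).setdefault(aspect, set()).add(term)
    if dropped:
        logger.warning("build_snapshot: dropped %d records with terms not in the ontology", dropped)
    if propagate_terms:
        for by_aspect in annotations.values():
            for aspect in list(by_aspect):
                by_aspect[aspect] = propagate(onto, by_aspect[aspect])
        for protein in list(annotations):
            annotations[protein] = {a: s for a, s in annotations[protein].items() if s}
            if not annotations[protein]:
                del annotations[protein]
    return AnnotationSnapshot(label=label, annotations=annotations,
                              propagated=propagate_terms)


def superset_violations(ts: AnnotationSnapshot,
                        tB: AnnotationSnapshot) -> list[tuple[str, str, set[str]]]:
    """Report (protein, aspect, terms) present at ts but retracted by tB.

    Nominally the deadline snapshot is a subset of the evaluation snapshot;
    curated databases occasionally retract annotations, so violations are
    reported rather than treated as errors.
    """
    out = []
    for protein, by_aspect in ts.annotations.items():
        for aspect, terms in by_aspect.items():
            missing = terms - tB.terms(protein, aspect)
            if missing:
                out.append((protein, aspect, missing))
    return out


def write_snapshot(snapshot: AnnotationSnapshot, path) -> None:
    """Write the 3-column exchange TSV (protein, term, aspect), sorted."""
    with open(path, "w") as fh:
        fh.write("protein\tterm\taspect\n")
        for protein in sorted(snapshot.annotations):
            for aspect in sorted(snapshot.annotations[protein]):
                for term in sorted(snapshot.annotations[protein][aspect]):
                    fh.write(f"{protein}\t{term}\t{aspect}\n")


def read_snapshot(path, label: str = "", propagated: bool = False) -> AnnotationSnapshot:
    """Read the exchange TSV back; ``propagated`` records the caller's claim."""
    annotations: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "protein\tterm\taspect":
            raise ValueError(f"{path}: not a snapshot TSV (header {header!r})")
        for line in fh:
            protein, term, aspect = line.rstrip("\n").split("\t")
            annotations.setdefault(protein, {}).setdefault(aspect, set()).add(term)
    return AnnotationSnapshot(label=label, annotations=annotations, propagated=propagated)


def read_id_mapping(path) -> dict[str, str]:
    """Read a 2-column (accession, target ID) TSV; '#' lines are comments."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            accession, target = line.split("\t")[:2]
            mapping[accession] = target
    return mapping
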