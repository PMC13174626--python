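"""Time-delayed benchmark construction.

Evaluation proteins are those that gained experimental annotations in an
aspect between the submission deadline (ts) and benchmark time (tB).  They are
split by what was known at the deadline:

* NK (no knowledge): no experimental annotation in any aspect at ts;
* LK (limited knowledge): none in the evaluated aspect, some in another;
* PK (partial knowledge): some in the evaluated aspect, more gained later.

Ground truth is the *gained* propagated term set, tB minus ts, taken after
propagation so that a new leaf under an annotated branch contributes only its
genuinely novel ancestors.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from .annotations import AnnotationSnapshot
from .ontology import ASPECTS, OntologyGraph

SETTINGS = ("NK", "LK", "PK", "NK+LK")


@dataclass
class BenchmarkSet:
    """Evaluation proteins for one (aspect, setting) pair.

    ``prior`` holds each protein's propagated deadline-time term set in the
    evaluated aspect (empty for NK/LK); ``gained_truth`` the propagated terms
    gained by tB.  Invariants: gained_truth is non-empty for every protein and
    disjoint from its prior.
    """

    aspect: str
    setting: str
    proteins: set[str] = field(default_factory=set)
    prior: dict[str, set[str]] = field(default_factory=dict)
    gained_truth: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.proteins)

    def truth(self, protein: str) -> set[str]:
        """Full propagated term set at tB (prior plus gained)."""
        return self.prior.get(protein, set()) | self.gained_truth.get(protein, set())


def classify_protein(protein: str, snapshot_ts: AnnotationSnapshot,
                     snapshot_tB: AnnotationSnapshot, aspect: str) -> str:
    """Assign NK / LK / PK, or "none" when no terms were gained in the aspect.

    Both snapshots must be filtered and propagated; a protein whose deadline
    annotations are all non-experimental is thereby treated as unannotated.
    """
    ts_eval = snapshot_ts.terms(protein, aspect)
    gained = snapshot_tB.terms(protein, aspect) - ts_eval
    if not gained:
        return "none"
    if ts_eval:
        return "PK"
    others = [a for a in ASPECTS if a != aspect]
    if snapshot_ts.has_any(protein, others):
        return "LK"
    return "NK"


def build_benchmark(snapshot_ts: AnnotationSnapshot, snapshot_tB: AnnotationSnapshot,
                    aspect: str, setting: str,
                    onto: Optional[OntologyGraph] = None) -> BenchmarkSet:
    """Assemble the benchmark set for one aspect and evaluation setting."""
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}")
    if not (snapshot_ts.propagated and snapshot_tB.propagated):
        raise ValueError("benchmark construction requires propagated snapshots")
    wanted = {"NK", "LK"} if setting == "NK+LK" else {setting}

    bench = BenchmarkSet(aspect=aspect, setting=setting)
    for protein in snapshot_tB.proteins:
        label = classify_protein(protein, snapshot_ts, snapshot_tB, aspect)
        if label not in wanted:
            continue
        ts_eval = set(snapshot_ts.terms(protein, aspect))
        gained = snapshot_tB.terms(protein, aspect) - ts_eval
        if onto is not None:
            bad = {t for t in gained | ts_eval if t not in onto}
            if bad:
                raise ValueError(f"benchmark terms absent from ontology: {sorted(bad)[:5]}")
        bench.proteins.add(protein)
        bench.prior[protein] = ts_eval
        bench.gained_truth[protein] = gained
    if not bench.proteins:
        raise ValueError(f"empty benchmark for aspect={aspect}, setting={setting}")
    return bench


def write_benchmark(bench: BenchmarkSet, out_dir) -> None:
    """Write the membership list and the (protein, term, role) truth table."""
    os.makedirs(out_dir, exist_ok=True)
    stem = f"{bench.aspect}_{bench.setting.replace('+', '')}"
    with open(os.path.join(out_dir, f"{stem}.members.tsv"), "w") as fh:
        fh.write("protein\n")
        for protein in sorted(bench.proteins):
            fh.write(protein + "\n")
    with open(os.path.join(out_dir, f"{stem}.truth.tsv"), "w") as fh:
        fh.write("protein\tterm\trole\n")
        for protein in sorted(bench.proteins):
            for term in sorted(bench.prior.get(protein, ())):
                fh.write(f"{protein}\t{term}\tprior\n")
            for term in sorted(bench.gained_truth[protein]):
                fh.write(f"{protein}\t{term}\tgained\n")


def read_benchmark(out_dir, aspect: str, setting: str) -> BenchmarkSet:
    stem = f"{aspect}_{setting.replace('+', '')}"
    bench = BenchmarkSet(aspect=aspect, setting=setting)
    with open(os.path.join(out_dir, f"{stem}.members.tsv")) as fh:
        header = fh.readline().rstrip("\n")
        if header != "protein":
            raise ValueError("not a benchmark membership file")
        for line in fh:
            protein = line.strip()
            if protein:
                bench.proteins.add(protein)
                bench.prior[protein] = set()
                bench.gained_truth[protein] = set()
    with open(os.path.join(out_dir, f"{stem}.truth.tsv")) as fh:
        header = fh.readline().rstrip("\n")
        if header != "protein\tterm\trole":
            raise ValueError("not a benchmark truth file")
        for line in fh:
            protein, term, role = line.rstrip("\n").split("\t")
            if role == "prior":
                bench.prior[protein].add(term)
            elif role == "gained":
                bench.gained_truth[protein].add(term)
            else:
                raise ValueError(f"unknown truth role {role!r}")
    return bench
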