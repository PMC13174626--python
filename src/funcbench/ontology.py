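"""Ontology handling for function-prediction evaluation.

The Gene Ontology (GO) is a rooted directed acyclic graph of terms split into
three aspects -- Molecular Function (MF), Biological Process (BP) and Cellular
Component (CC).  Annotations and predictions are interpreted under the *true
path rule*: a protein annotated with a term is implicitly annotated with every
ancestor of that term, so term sets are compared after replacing them by their
ancestral closure ("propagation").

This module parses OBO files, extracts per-aspect subgraphs, propagates term
sets, estimates per-term information accretion (the specificity weight used by
the semantic-distance metrics), and restricts an ontology to the terms shared
by several releases so that predictions made against different GO versions can
be compared on equal footing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, TYPE_CHECKING

import networkx as nx
import obonet

if TYPE_CHECKING:  # pragma: no cover
    from .annotations import AnnotationSnapshot

logger = logging.getLogger(__name__)

ASPECTS = ("MF", "BP", "CC")

NAMESPACE_TO_ASPECT = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
ASPECT_TO_NAMESPACE = {v: k for k, v in NAMESPACE_TO_ASPECT.items()}

#: Relations that carry the true-path rule.  Established CAFA practice
#: propagates over is_a and part_of; regulates-type relations do not imply
#: the parent annotation and are excluded.
DEFAULT_PROPAGATION_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass
class OntologyGraph:
    """A rooted DAG of terms, possibly covering several aspects.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point child -> parent
    and carry a ``relations`` set attribute.  ``roots`` maps each aspect
    present in the graph to its single parentless term.  ``alt_id_map`` routes
    alternate and obsolete identifiers to their primary term, or to ``None``
    (a tombstone) when an obsolete term has no replacement.
    """

    graph: nx.DiGraph
    roots: dict[str, str]
    alt_id_map: dict[str, Optional[str]]
    relations: frozenset = DEFAULT_PROPAGATION_RELATIONS
    _ancestor_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def aspect_of(self, term: str) -> str:
        return self.graph.nodes[term]["aspect"]

    @property
    def root_terms(self) -> set[str]:
        return set(self.roots.values())

    def resolve(self, term: str) -> Optional[str]:
        """Map an identifier to its primary term, or None if unresolvable."""
        if term in self.graph:
            return term
        target = self.alt_id_map.get(term)
        if target is not None and target in self.graph:
            return target
        return None

    def parents(self, term: str) -> list[str]:
        """Direct parents of *term* over the propagation relations, within its aspect."""
        aspect = self.aspect_of(term)
        out = []
        for _, parent, data in self.graph.out_edges(term, data=True):
            if not (data["relations"] & self.relations):
                continue
            if self.graph.nodes[parent]["aspect"] != aspect:
                continue
            out.append(parent)
        return out

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of *term* (up to and including its aspect root)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents(term))
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            cached_t = self._ancestor_cache.get(t)
            if cached_t is not None:
                out |= cached_t
            else:
                stack.extend(self.parents(t))
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result


def _build(graph: nx.DiGraph, alt_id_map: dict[str, Optional[str]],
           relations: frozenset) -> OntologyGraph:
    """Validate acyclicity and single roots, then assemble an OntologyGraph."""
    prop = nx.DiGraph()
    prop.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        if data["relations"] & relations:
            prop.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(prop):
        cycle = nx.find_cycle(prop)
        raise ValueError(f"ontology contains a cycle: {cycle}")

    # tombstone alt ids whose target is not a primary term
    alt = {k: (v if v is not None and v in graph else None) for k, v in alt_id_map.items()}

    onto = OntologyGraph(graph=graph, roots={}, alt_id_map=alt, relations=relations)
    roots: dict[str, list[str]] = {}
    for term in graph.nodes:
        if not onto.parents(term):
            roots.setdefault(onto.aspect_of(term), []).append(term)
    for aspect, cands in roots.items():
        if len(cands) != 1:
            raise ValueError(
                f"aspect {aspect} has {len(cands)} parentless terms {sorted(cands)}; "
                "expected a single root"
            )
    onto.roots = {a: c[0] for a, c in roots.items()}
    return onto


def parse_obo(path, relations: Iterable[str] = DEFAULT_PROPAGATION_RELATIONS) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are removed from the graph and routed through
    ``alt_id_map``: via their ``replaced_by`` target when one is given,
    otherwise to a tombstone (``consider`` suggestions are not auto-applied).
    A cyclic is_a/part_of graph is a hard error naming the cycle.
    """
    multi = obonet.read_obo(path, ignore_obsolete=False)

    dg = nx.DiGraph()
    alt: dict[str, Optional[str]] = {}
    obsolete: set[str] = set()
    for node, data in multi.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            replaced = data.get("replaced_by") or []
            alt[node] = replaced[0] if replaced else None
            obsolete.add(node)
            continue
        namespace = data.get("namespace")
        if namespace not in NAMESPACE_TO_ASPECT:
            raise ValueError(f"term {node} has missing or unknown namespace {namespace!r}")
        dg.add_node(node, aspect=NAMESPACE_TO_ASPECT[namespace], name=data.get("name", ""))
        for a in data.get("alt_id", []):
            alt[a] = node

    for child, parent, rel in multi.edges(keys=True):
        if child in obsolete or parent in obsolete:
            continue
        if dg.has_edge(child, parent):
            dg.edges[child, parent]["relations"].add(rel)
        else:
            dg.add_edge(child, parent, relations={rel})

    return _build(dg, alt, frozenset(relations))


def aspect_subgraph(onto: OntologyGraph, aspect: str) -> OntologyGraph:
    """Induced subgraph of one aspect; cross-aspect edges are dropped."""
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}; expected one of {ASPECTS}")
    nodes = {t for t in onto.graph.nodes if onto.aspect_of(t) == aspect}
    sub = onto.graph.subgraph(nodes).copy()
    alt = {
        k: v
        for k, v in onto.alt_id_map.items()
        if v is None or v in nodes
    }
    roots = {aspect: onto.roots[aspect]} if aspect in onto.roots else {}
    out = OntologyGraph(graph=sub, roots=roots, alt_id_map=alt, relations=onto.relations)
    return out


def propagate(onto: OntologyGraph, terms: Iterable[str],
              include_roots: bool = False) -> set[str]:
    """Ancestral closure of a term set.

    Aspect roots are removed from the result by default: they hold for every
    annotated protein and carry zero information.  Unresolvable terms are
    dropped with a warning rather than failing the whole set.
    """
    out: set[str] = set()
    for term in terms:
        resolved = onto.resolve(term)
        if resolved is None:
            logger.warning("propagate: dropping unresolvable term %s", term)
            continue
        out.add(resolved)
        out |= onto.ancestors(resolved)
    if not include_roots:
        out -= onto.root_terms
    return out


@dataclass
class TermInformation:
    """Per-term information accretion (ia), in bits.

    ia(f) is the negative binary log of the conditional probability that a
    protein carries term f given that it carries all of f's parents, estimated
    by maximum likelihood from a reference corpus of experimentally annotated,
    propagated protein annotations.  Roots have ia = 0.
    """

    ia: dict[str, float]
    reference_size: int

    def __call__(self, term: str) -> float:
        return self.ia.get(term, 0.0)

    def total(self, terms: Iterable[str]) -> float:
        return sum(self.ia.get(t, 0.0) for t in terms)


def information_accretion(onto: OntologyGraph,
                          reference: "AnnotationSnapshot") -> TermInformation:
    """Estimate information accretion for every term from a propagated reference.

    For term f with (non-root) parent set P, ia(f) = -log2(n_{f,P} / n_P) where
    n_P counts reference proteins (in f's aspect) carrying every parent in P
    and n_{f,P} additionally carrying f.  Terms with an undefined or infinite
    estimate (no protein carries the parents, or none carries f given the
    parents) receive the maximum finite ia observed in their aspect, logged.
    """
    if not reference.propagated:
        raise ValueError("information accretion requires a propagated reference snapshot")

    per_aspect_sets: dict[str, list[set[str]]] = {a: [] for a in ASPECTS}
    annotated_proteins: set[str] = set()
    for protein, by_aspect in reference.annotations.items():
        for aspect, terms in by_aspect.items():
            if terms:
                per_aspect_sets[aspect].append(terms)
                annotated_proteins.add(protein)
    if not annotated_proteins:
        raise ValueError("empty reference snapshot: no annotated proteins")

    roots = onto.root_terms
    ia: dict[str, float] = {}
    pending: dict[str, list[str]] = {a: [] for a in ASPECTS}
    for term in onto.graph.nodes:
        if term in roots:
            ia[term] = 0.0
            continue
        aspect = onto.aspect_of(term)
        sets = per_aspect_sets[aspect]
        parents = set(onto.parents(term)) - roots
        den = 0
        num = 0
        for s in sets:
            if parents <= s:
                den += 1
                if term in s:
                    num += 1
        if den == 0 or num == 0:
            pending[aspect].append(term)
        else:
            ia[term] = -math.log2(num / den)

    for aspect, terms in pending.items():
        if not terms:
            continue
        finite = [ia[t] for t in onto.graph.nodes
                  if t in ia and t not in roots and onto.aspect_of(t) == aspect]
        cap = max(finite, default=0.0)
        logger.warning(
            "information_accretion: %d %s terms with zero-count estimates "
            "assigned the aspect maximum ia %.4f", len(terms), aspect, cap,
        )
        for t in terms:
            ia[t] = cap

    return TermInformation(ia=ia, reference_size=len(annotated_proteins))


def common_term_restriction(graphs: list[OntologyGraph]) -> OntologyGraph:
    """Restrict to terms shared by every graph, keeping the newest semantics.

    ``graphs`` is ordered oldest to newest.  The output contains the
    intersection of the term sets; its edges are the transitive reduction of
    the newest graph's ancestor relation over the surviving terms, so a child
    whose intermediate parents were removed is reconnected to its nearest
    retained ancestors and propagation semantics are preserved.
    """
    if len(graphs) < 2:
        raise ValueError("common_term_restriction needs at least two graphs")
    retained = set.intersection(*(g.terms for g in graphs))
    if not retained:
        raise ValueError("no terms are common to all supplied ontologies")
    newest = graphs[-1]

    dg = nx.DiGraph()
    for term in retained:
        dg.add_node(term, aspect=newest.aspect_of(term),
                    name=newest.graph.nodes[term].get("name", ""))
    anc = {t: newest.ancestors(t) & retained for t in retained}
    for u in retained:
        minimal = [v for v in anc[u]
                   if not any(v in anc[w] for w in anc[u] if w != v)]
        for v in minimal:
            if newest.graph.has_edge(u, v):
                rels = set(newest.graph.edges[u, v]["relations"]) & newest.relations
                rels = rels or {"is_a"}
            else:
                rels = {"is_a"}
            dg.add_edge(u, v, relations=rels)

    for aspect, root in newest.roots.items():
        if any(newest.aspect_of(t) == aspect for t in retained) and root not in retained:
            raise ValueError(f"{aspect} root {root} is not common to all ontologies")

    alt = {k: v for k, v in newest.alt_id_map.items() if v is None or v in retained}
    return _build(dg, alt, newest.relations)


def write_term_information(ti: TermInformation, onto: OntologyGraph, path) -> None:
    """Write a (term, aspect, ia) TSV, sorted by term id."""
    with open(path, "w") as fh:
        fh.write("term\taspect\tia\n")
        for term in sorted(ti.ia):
            aspect = onto.aspect_of(term) if term in onto else "NA"
            fh.write(f"{term}\t{aspect}\t{ti.ia[term]!r}\n")


def read_term_information(path) -> TermInformation:
    ia: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("term\t"):
            raise ValueError(f"{path}: not a term-information TSV")
        for line in fh:
            term, _aspect, value = line.rstrip("\n").split("\t")
            ia[term] = float(value)
    return TermInformation(ia=ia, reference_size=0)
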