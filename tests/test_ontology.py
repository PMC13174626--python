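import math
import textwrap

import numpy as np
import pytest

from funcbench.annotations import AnnotationSnapshot
from funcbench.ontology import (aspect_subgraph, common_term_restriction,
                                information_accretion, parse_obo, propagate)
from funcbench.synthetic import FixtureSpec, random_ontology

from _oracles import conditional_frequency_ia
from conftest import (BP_CHILD, BP_ROOT, CC_CHILD, CC_ROOT, MF_A, MF_ALT, MF_B,
                      MF_C, MF_D, MF_OBSOLETE, MF_ROOT)


def _write_obo(tmp_path, text, name="o.obo"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return str(path)


class TestParseObo:
    def test_counts_and_aspects(self, tiny_onto):
        assert len(tiny_onto) == 9  # obsolete term removed
        assert tiny_onto.roots == {"MF": MF_ROOT, "BP": BP_ROOT, "CC": CC_ROOT}
        assert tiny_onto.aspect_of(MF_C) == "MF"
        assert tiny_onto.graph.number_of_edges() == 8

    def test_obsolete_resolves_through_replaced_by(self, tiny_onto):
        assert MF_OBSOLETE not in tiny_onto
        assert tiny_onto.resolve(MF_OBSOLETE) == MF_A

    def test_alt_id_resolves(self, tiny_onto):
        assert tiny_onto.resolve(MF_ALT) == MF_A

    def test_obsolete_without_replacement_is_tombstoned(self, tmp_path):
        path = _write_obo(tmp_path, """\
            format-version: 1.2

            [Term]
            id: GO:0000001
            name: root
            namespace: molecular_function

            [Term]
            id: GO:0000009
            name: dead end
            namespace: molecular_function
            is_obsolete: true
            """)
        onto = parse_obo(path)
        assert onto.resolve("GO:0000009") is None
        assert "GO:0000009" in onto.alt_id_map

    def test_cycle_is_a_hard_error_naming_the_cycle(self, tmp_path):
        path = _write_obo(tmp_path, """\
            format-version: 1.2

            [Term]
            id: GO:0000001
            name: a
            namespace: molecular_function
            is_a: GO:0000002

            [Term]
            id: GO:0000002
            name: b
            namespace: molecular_function
            is_a: GO:0000001
            """)
        with pytest.raises(ValueError, match="cycle"):
            parse_obo(path)


class TestAspectSubgraph:
    def test_partition(self, tiny_onto):
        mf = aspect_subgraph(tiny_onto, "MF")
        assert all(mf.aspect_of(t) == "MF" for t in mf.terms)
        assert BP_CHILD not in mf and CC_CHILD not in mf

    def test_idempotent(self, tiny_onto):
        once = aspect_subgraph(tiny_onto, "BP")
        twice = aspect_subgraph(once, "BP")
        assert once.terms == twice.terms
        assert set(once.graph.edges) == set(twice.graph.edges)

    def test_cross_aspect_part_of_edge_absent_from_both_sides(self, tiny_onto):
        cc = aspect_subgraph(tiny_onto, "CC")
        bp = aspect_subgraph(tiny_onto, "BP")
        assert not cc.graph.has_edge(CC_CHILD, BP_ROOT)
        assert CC_CHILD not in bp
        # and propagation never crosses it either
        assert propagate(tiny_onto, [CC_CHILD]) == {CC_CHILD}

    def test_unknown_aspect(self, tiny_onto):
        with pytest.raises(ValueError):
            aspect_subgraph(tiny_onto, "XX")


class TestPropagate:
    def test_chain_closure_excludes_root(self, tiny_onto):
        assert propagate(tiny_onto, [MF_C]) == {MF_C, MF_A}

    def test_include_roots_flag(self, tiny_onto):
        assert propagate(tiny_onto, [MF_C], include_roots=True) == {MF_C, MF_A, MF_ROOT}

    def test_idempotent(self, tiny_onto):
        once = propagate(tiny_onto, [MF_D])
        assert propagate(tiny_onto, once) == once

    def test_diamond_multi_parent(self, tiny_onto):
        assert propagate(tiny_onto, [MF_D]) == {MF_D, MF_A, MF_B}

    def test_unresolvable_dropped_not_fatal(self, tiny_onto):
        assert propagate(tiny_onto, ["GO:9999999", MF_C]) == {MF_C, MF_A}

    def test_closure_property_on_random_dags(self):
        rng = np.random.default_rng(7)
        for seed in rng.integers(0, 2**31, 20):
            onto = random_ontology(FixtureSpec(n_terms=12, seed=int(seed)))
            terms = sorted(onto.terms - onto.root_terms)
            picked = [terms[int(i)] for i in rng.integers(0, len(terms), 4)]
            closed = propagate(onto, picked)
            for t in closed:
                assert set(onto.parents(t)) - onto.root_terms <= closed


def _snapshot(sets):
    """Propagated MF-only snapshot from protein -> set."""
    return AnnotationSnapshot(label="ref", propagated=True,
                              annotations={p: {"MF": set(s)} for p, s in sets.items()})


class TestInformationAccretion:
    def test_worked_example_one_bit(self, tiny_onto):
        # 4 proteins carry parent A, 2 of them also carry child C
        ref = _snapshot({"P1": {MF_A, MF_C}, "P2": {MF_A, MF_C},
                         "P3": {MF_A}, "P4": {MF_A}})
        ti = information_accretion(tiny_onto, ref)
        assert ti(MF_C) == -math.log2(2 / 4) == 1.0

    def test_always_present_term_is_zero_bits(self, tiny_onto):
        ref = _snapshot({"P1": {MF_A, MF_C}, "P2": {MF_A, MF_C}})
        ti = information_accretion(tiny_onto, ref)
        assert ti(MF_C) == 0.0

    def test_roots_are_zero(self, tiny_onto):
        ref = _snapshot({"P1": {MF_A}})
        ti = information_accretion(tiny_onto, ref)
        assert ti(MF_ROOT) == ti(BP_ROOT) == ti(CC_ROOT) == 0.0

    def test_zero_count_terms_get_aspect_maximum(self, tiny_onto):
        # nobody carries B, so D's parents never co-occur and B is unseen
        ref = _snapshot({"P1": {MF_A, MF_C}, "P2": {MF_A}, "P3": {MF_A}, "P4": {MF_A}})
        ti = information_accretion(tiny_onto, ref)
        cap = ti(MF_C)  # -log2(1/4) = 2 bits, the only finite non-trivial value
        assert cap == 2.0
        assert ti(MF_B) == cap and ti(MF_D) == cap

    def test_empty_reference_rejected(self, tiny_onto):
        with pytest.raises(ValueError, match="empty reference"):
            information_accretion(tiny_onto, _snapshot({}))

    def test_matches_counting_oracle_on_random_reference(self):
        rng = np.random.default_rng(42)
        onto = random_ontology(FixtureSpec(n_terms=6, seed=5))
        terms = sorted(t for t in onto.terms if onto.aspect_of(t) == "MF"
                       and t not in onto.root_terms)
        sets = {}
        for i in range(8):
            picked = [terms[int(j)] for j in rng.integers(0, len(terms), 2)]
            sets[f"P{i}"] = propagate(onto, picked)
        ti = information_accretion(onto, _snapshot(sets))
        oracle = conditional_frequency_ia(onto, {"MF": list(sets.values())})
        for t in terms:
            assert ti(t) == oracle[t]


class TestCommonTermRestriction:
    def test_identical_graphs_give_back_the_graph(self, tiny_onto):
        out = common_term_restriction([tiny_onto, tiny_onto])
        assert out.terms == tiny_onto.terms
        # edges are rebuilt from within-aspect ancestor relations, so the
        # decorative cross-aspect part_of edge is not part of the contract
        within = {(u, v) for u, v in tiny_onto.graph.edges
                  if tiny_onto.aspect_of(u) == tiny_onto.aspect_of(v)}
        assert set(out.graph.edges) == within

    def test_removed_middle_term_reconnects_transitively(self, tmp_path):
        old = parse_obo(_write_obo(tmp_path, """\
            format-version: 1.2

            [Term]
            id: GO:0000001
            name: root
            namespace: molecular_function

            [Term]
            id: GO:0000003
            name: c
            namespace: molecular_function
            is_a: GO:0000001
            """, "old.obo"))
        new = parse_obo(_write_obo(tmp_path, """\
            format-version: 1.2

            [Term]
            id: GO:0000001
            name: root
            namespace: molecular_function

            [Term]
            id: GO:0000002
            name: a
            namespace: molecular_function
            is_a: GO:0000001

            [Term]
            id: GO:0000003
            name: c
            namespace: molecular_function
            is_a: GO:0000002
            """, "new.obo"))
        out = common_term_restriction([old, new])
        assert out.terms == {"GO:0000001", "GO:0000003"}
        # C's ancestors in the restriction match its retained ancestors in the
        # newest graph: reconnected directly under the root
        assert out.graph.has_edge("GO:0000003", "GO:0000001")
        assert propagate(out, ["GO:0000003"], include_roots=True) == \
            {"GO:0000003", "GO:0000001"}

    def test_retained_terms_commutative(self, tiny_onto, tmp_path):
        other = parse_obo(_write_obo(tmp_path, """\
            format-version: 1.2

            [Term]
            id: GO:0000001
            name: root
            namespace: molecular_function

            [Term]
            id: GO:0000002
            name: a
            namespace: molecular_function
            is_a: GO:0000001
            """, "v2.obo"))
        ab = common_term_restriction([other, tiny_onto])
        ba = common_term_restriction([tiny_onto, other])
        assert ab.terms == ba.terms == {"GO:0000001", "GO:0000002"}

    def test_disjoint_term_sets_rejected(self, tiny_onto, tmp_path):
        other = parse_obo(_write_obo(tmp_path, """\
            format-version: 1.2

            [Term]
            id: GO:0000077
            name: lone root
            namespace: molecular_function
            """, "v3.obo"))
        with pytest.raises(ValueError, match="common"):
            common_term_restriction([tiny_onto, other])
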