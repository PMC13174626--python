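import logging
import textwrap

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

logging.getLogger("funcbench").setLevel(logging.ERROR)


#: Three-aspect toy ontology: an MF chain R->A->C, an MF diamond D under A and
#: B, an obsolete term replaced by A, an alt_id on A, a one-child BP and CC,
#: and a cross-aspect part_of from the CC child to the BP root.
TINY_OBO = textwrap.dedent("""\
    format-version: 1.2
    ontology: tiny

    [Term]
    id: GO:0000001
    name: mf root
    namespace: molecular_function

    [Term]
    id: GO:0000002
    name: A
    namespace: molecular_function
    alt_id: GO:0000022
    is_a: GO:0000001

    [Term]
    id: GO:0000003
    name: C
    namespace: molecular_function
    is_a: GO:0000002

    [Term]
    id: GO:0000004
    name: B
    namespace: molecular_function
    is_a: GO:0000001

    [Term]
    id: GO:0000005
    name: D
    namespace: molecular_function
    is_a: GO:0000002
    relationship: part_of GO:0000004

    [Term]
    id: GO:0000006
    name: gone
    namespace: molecular_function
    is_obsolete: true
    replaced_by: GO:0000002

    [Term]
    id: GO:0000011
    name: bp root
    namespace: biological_process

    [Term]
    id: GO:0000012
    name: bp child
    namespace: biological_process
    is_a: GO:0000011

    [Term]
    id: GO:0000021
    name: cc root
    namespace: cellular_component

    [Term]
    id: GO:0000031
    name: cc child
    namespace: cellular_component
    is_a: GO:0000021
    relationship: part_of GO:0000011
    """)

MF_ROOT = "GO:0000001"
MF_A = "GO:0000002"
MF_C = "GO:0000003"
MF_B = "GO:0000004"
MF_D = "GO:0000005"
MF_OBSOLETE = "GO:0000006"
MF_ALT = "GO:0000022"
BP_ROOT = "GO:0000011"
BP_CHILD = "GO:0000012"
CC_ROOT = "GO:0000021"
CC_CHILD = "GO:0000031"


@pytest.fixture(scope="session")
def tiny_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("onto") / "tiny.obo"
    path.write_text(TINY_OBO)
    return path


@pytest.fixture(scope="session")
def tiny_onto(tiny_obo_path):
    from funcbench.ontology import parse_obo

    return parse_obo(str(tiny_obo_path))


@pytest.fixture(scope="session")
def small_study():
    """A moderate synthetic study shared by benchmark/metric tests."""
    from funcbench import benchmarks, ontology, synthetic

    spec = synthetic.FixtureSpec(n_proteins=80, n_terms=18, seed=11)
    onto = synthetic.random_ontology(spec)
    ts, tB, planted = synthetic.simulate_snapshots(onto, spec)
    bench = benchmarks.build_benchmark(ts, tB, "MF", "NK+LK")
    bench_pk = benchmarks.build_benchmark(ts, tB, "MF", "PK")
    ia = ontology.information_accretion(onto, tB)
    return dict(spec=spec, onto=onto, ts=ts, tB=tB, planted=planted,
                bench=bench, bench_pk=bench_pk, ia=ia)
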