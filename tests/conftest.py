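import logging
from pathlib import Path

import pytest

from genesum import (
    FixtureSpec,
    GeneAnnotationStore,
    GeneSet,
    MockBackend,
    Ontology,
    OntologyTerm,
    load_gaf,
    load_gene_set,
    load_narrative_table,
    load_ontology,
    make_fixture,
    make_narrative_table,
)

DATA = Path(__file__).parent / "data"

# silence the deliberately noisy warning paths during tests
logging.getLogger("genesum").setLevel(logging.ERROR)
for name in ("genesum.annotations", "genesum.enrichment", "genesum.grounding",
             "genesum.descriptions", "genesum.prompting", "genesum.llm"):
    logging.getLogger(name).setLevel(logging.ERROR)


def build_toy_ontology(closure_relations=("is_a",)) -> Ontology:
    """The four-term toy DAG: T1 is_a T0; T2 is_a T1; T3 part_of T0."""
    terms = {
        "T0": OntologyTerm(id="T0", label="root"),
        "T1": OntologyTerm(id="T1", label="branch", parents=frozenset({("is_a", "T0")})),
        "T2": OntologyTerm(id="T2", label="leaf", parents=frozenset({("is_a", "T1")})),
        "T3": OntologyTerm(id="T3", label="part", parents=frozenset({("part_of", "T0")})),
    }
    return Ontology(terms, closure_relations=closure_relations)


@pytest.fixture
def toy_ontology():
    return build_toy_ontology()


@pytest.fixture(scope="session")
def mini_ontology():
    return load_ontology(DATA / "mini.obo")


@pytest.fixture(scope="session")
def mini_store(mini_ontology):
    return load_gaf(DATA / "mini.gaf", mini_ontology)


@pytest.fixture(scope="session")
def mini_gene_set():
    return load_gene_set(DATA / "mini_genes.txt")


@pytest.fixture(scope="session")
def mini_narrative():
    return load_narrative_table(DATA / "mini_narrative.tsv")


@pytest.fixture(scope="session")
def default_fixture():
    """One generated fixture under the default study conditions (seed 7)."""
    spec = FixtureSpec(seed=7)
    ontology, store, gene_set = make_fixture(spec)
    narrative = make_narrative_table(store, seed=7)
    return spec, ontology, store, gene_set, narrative


@pytest.fixture
def faithful_backend(default_fixture):
    _, _, store, _, _ = default_fixture
    return MockBackend(store=store, behavior="faithful")
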