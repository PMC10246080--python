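"""Ontology loading and closure semantics."""

import json
import random

import pytest

from genesum import (
    FixtureSpec,
    Ontology,
    OntologyTerm,
    OntologyValidationError,
    UnknownTermError,
    load_ontology,
    make_fixture,
)
from .conftest import build_toy_ontology

TOY_OBO = """format-version: 1.4

[Term]
id: T0
name: root

[Term]
id: T1
name: branch
is_a: T0

[Term]
id: T2
name: leaf
is_a: T1

[Term]
id: T3
name: part
relationship: part_of T0
"""


@pytest.fixture
def toy_obo_path(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


class TestLoading:
    def test_toy_obo_loads_with_is_a_closure_only(self, toy_obo_path):
        o = load_ontology(toy_obo_path, closure_relations={"is_a"})
        assert len(o) == 4
        # T3's only parent edge is part_of, which is outside the closure set
        assert o.ancestors("T3") == frozenset()

    def test_empty_ontology_file(self, tmp_path):
        path = tmp_path / "empty.obo"
        path.write_text("format-version: 1.4\n")
        assert len(load_ontology(path)) == 0

    def test_cycle_is_a_validation_error(self, toy_obo_path):
        text = toy_obo_path.read_text() + "\n[Term]\nid: T4\nname: x\nis_a: T2\n"
        text = text.replace("id: T0\nname: root", "id: T0\nname: root\nis_a: T2")
        path = toy_obo_path.parent / "cyclic.obo"
        path.write_text(text)
        with pytest.raises(OntologyValidationError) as err:
            load_ontology(path)
        assert err.value.cycle  # one offending cycle is reported

    def test_unresolved_parent_rejected(self):
        terms = {"A": OntologyTerm(id="A", parents=frozenset({("is_a", "GHOST")}))}
        with pytest.raises(OntologyValidationError):
            Ontology(terms)

    def test_obographs_json_matches_obo(self, toy_obo_path, tmp_path):
        doc = {
            "graphs": [
                {
                    "nodes": [
                        {"id": "T0", "lbl": "root"},
                        {"id": "T1", "lbl": "branch"},
                        {"id": "T2", "lbl": "leaf"},
                        {"id": "T3", "lbl": "part"},
                    ],
                    "edges": [
                        {"sub": "T1", "pred": "is_a", "obj": "T0"},
                        {"sub": "T2", "pred": "is_a", "obj": "T1"},
                        {"sub": "T3", "pred": "BFO:0000050", "obj": "T0"},
                    ],
                }
            ]
        }
        path = tmp_path / "toy.json"
        path.write_text(json.dumps(doc))
        from_json = load_ontology(path, format="obographs-json")
        from_obo = load_ontology(toy_obo_path)
        assert from_json == from_obo

    def test_obsolete_and_synonyms_loaded(self, mini_ontology):
        term = mini_ontology.terms["MINI:0000006"]
        assert term.obsolete
        assert "myelin sheath maintenance" in term.synonyms
        assert term.replaced_by == "MINI:0000002"


class TestClosure:
    def test_ancestors_nonreflexive(self, toy_ontology):
        assert toy_ontology.ancestors("T2") == {"T1", "T0"}

    def test_root_has_no_ancestors(self, toy_ontology):
        assert toy_ontology.ancestors("T0") == frozenset()

    def test_ancestors_reflexive_adds_self(self, toy_ontology):
        assert toy_ontology.ancestors("T2", reflexive=True) == {"T2", "T1", "T0"}

    def test_descendants_mirror(self, toy_ontology):
        assert toy_ontology.descendants("T0") == {"T1", "T2"}
        assert toy_ontology.descendants("T2") == frozenset()
        assert toy_ontology.descendants("T1", reflexive=True) == {"T1", "T2"}

    def test_unknown_term_lookup_error(self, toy_ontology):
        with pytest.raises(UnknownTermError):
            toy_ontology.ancestors("NOPE")
        with pytest.raises(UnknownTermError):
            toy_ontology.related_by_hierarchy("T0", "NOPE")

    @pytest.mark.parametrize(
        "a, b, expected",
        [("T1", "T2", True), ("T1", "T1", True), ("T1", "T3", False)],
    )
    def test_related_by_hierarchy(self, toy_ontology, a, b, expected):
        assert toy_ontology.related_by_hierarchy(a, b) is expected

    def test_related_by_hierarchy_symmetric_exhaustive(self, mini_ontology):
        ids = sorted(mini_ontology.terms)
        for a in ids:
            for b in ids:
                assert mini_ontology.related_by_hierarchy(
                    a, b
                ) == mini_ontology.related_by_hierarchy(b, a)

    def test_mutual_consistency_of_closures(self, mini_ontology):
        ids = sorted(mini_ontology.terms)
        for a in ids:
            for b in ids:
                assert (b in mini_ontology.ancestors(a)) == (
                    a in mini_ontology.descendants(b)
                )


def brute_force_ancestors(ontology: Ontology, term_id: str) -> set:
    """Fixed point of repeated one-step parent expansion (independent oracle)."""
    term = ontology.terms[term_id]
    if term.obsolete:
        return set()

    def step(ids):
        out = set(ids)
        for t in ids:
            if ontology.terms[t].obsolete:
                continue
            for rel, parent in ontology.terms[t].parents:
                if rel in ontology.closure_relations:
                    out.add(parent)
        return out

    current = step({term_id})
    while True:
        expanded = step(current)
        if expanded == current:
            return current - {term_id}
        current = expanded


@pytest.mark.parametrize("seed", range(5))
def test_closure_matches_brute_force_on_random_dags(seed):
    ontology, _, _ = make_fixture(FixtureSpec(seed=seed, n_terms=40, dag_depth=4))
    assert len(ontology) <= 50
    for t in ontology.terms:
        assert ontology.ancestors(t) == brute_force_ancestors(ontology, t)


def test_widening_closure_relations_never_shrinks_ancestors():
    narrow = build_toy_ontology(closure_relations={"is_a"})
    wide = build_toy_ontology(closure_relations={"is_a", "part_of"})
    for t in narrow.terms:
        assert narrow.ancestors(t) <= wide.ancestors(t)
    for seed in range(3):
        spec = FixtureSpec(seed=seed, n_terms=30)
        o_wide, _, _ = make_fixture(spec)
        o_narrow = Ontology(o_wide.terms, closure_relations={"is_a"})
        for t in o_wide.terms:
            assert o_narrow.ancestors(t) <= o_wide.ancestors(t)
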