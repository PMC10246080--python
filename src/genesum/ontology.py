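"""Ontology container with ancestor/descendant closure over a configurable relation set.

A Gene Ontology-style ontology is a DAG of terms connected by typed relations
(``is_a``, ``part_of``, ...). This module loads OBO 1.4 flat files (via obonet)
and OBO-Graph JSON, keeps obsolete terms addressable (they matter for grounding
free-text phrases), and computes transitive closures restricted to a chosen set
of relations. Identifiers are opaque strings compared exactly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, Mapping, Optional, Tuple

import networkx as nx
import obonet

from .errors import FormatError, OntologyValidationError, UnknownTermError

logger = logging.getLogger(__name__)

#: Relations traversed for closure unless the caller chooses otherwise.
DEFAULT_CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')
# OBO Foundry PURLs and common predicate spellings seen in OBO-Graph JSON.
_OBO_PURL_RE = re.compile(r"^https?://purl\.obolibrary\.org/obo/([A-Za-z0-9]+)_(\S+)$")
_PRED_ALIASES = {"BFO:0000050": "part_of", "part of": "part_of"}


def _compact(identifier: str) -> str:
    m = _OBO_PURL_RE.match(identifier)
    if m:
        return f"{m.group(1)}:{m.group(2)}"
    return identifier


def _compact_pred(pred: str) -> str:
    pred = _compact(pred)
    return _PRED_ALIASES.get(pred, pred)


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term.

    ``parents`` holds typed edges as ``(relation, parent_id)`` pairs. Obsolete
    terms keep whatever parent assertions the file carried, but those edges are
    never used for closure traversal.
    """

    id: str
    label: str = ""
    synonyms: FrozenSet[str] = frozenset()
    obsolete: bool = False
    replaced_by: Optional[str] = None
    parents: FrozenSet[Tuple[str, str]] = frozenset()


class Ontology:
    """Immutable term collection plus memoized closure queries."""

    def __init__(
        self,
        terms: Mapping[str, OntologyTerm],
        closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
    ):
        self.terms = dict(terms)
        self.closure_relations = frozenset(closure_relations)
        self._parent_index: dict[str, set[str]] = {}
        self._child_index: dict[str, set[str]] = {}
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}
        self._validate()

    # -- construction -----------------------------------------------------

    def _validate(self) -> None:
        for t in self.terms.values():
            if not t.id:
                raise OntologyValidationError("empty term identifier")
            for rel, parent in t.parents:
                if parent not in self.terms:
                    raise OntologyValidationError(
                        f"term {t.id}: parent {parent} ({rel}) not in ontology"
                    )
            if t.replaced_by is not None:
                target = self.terms.get(t.replaced_by)
                if target is None:
                    logger.warning(
                        "term %s: replaced_by %s not in ontology", t.id, t.replaced_by
                    )
                elif target.obsolete:
                    logger.warning(
                        "term %s: replaced_by %s is itself obsolete", t.id, t.replaced_by
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            if t.obsolete:  # obsolete terms contribute no closure edges
                continue
            for rel, parent in t.parents:
                if rel in self.closure_relations:
                    g.add_edge(t.id, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = [edge[0] for edge in nx.find_cycle(g)]
            raise OntologyValidationError(
                "closure graph contains a cycle: " + " -> ".join(cycle + [cycle[0]]),
                cycle=cycle,
            )
        for child, parent in g.edges():
            self._parent_index.setdefault(child, set()).add(parent)
            self._child_index.setdefault(parent, set()).add(child)

    # -- queries ----------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Ontology)
            and self.terms == other.terms
            and self.closure_relations == other.closure_relations
        )

    def _require(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term: {term_id}") from None

    def _closure(self, term_id: str, index, cache) -> frozenset[str]:
        if term_id in cache:
            return cache[term_id]
        out: set[str] = set()
        stack = list(index.get(term_id, ()))
        while stack:
            current = stack.pop()
            if current in out:
                continue
            out.add(current)
            if current in cache:
                out |= cache[current]
            else:
                stack.extend(index.get(current, ()))
        result = frozenset(out)
        cache[term_id] = result
        return result

    def ancestors(self, term_id: str, reflexive: bool = False) -> frozenset[str]:
        """Transitive parents of ``term_id`` over the closure relations."""
        self._require(term_id)
        anc = self._closure(term_id, self._parent_index, self._anc_cache)
        return anc | {term_id} if reflexive else anc

    def descendants(self, term_id: str, reflexive: bool = False) -> frozenset[str]:
        """Transitive children of ``term_id`` over the closure relations."""
        self._require(term_id)
        desc = self._closure(term_id, self._child_index, self._desc_cache)
        return desc | {term_id} if reflexive else desc

    def related_by_hierarchy(self, a: str, b: str) -> bool:
        """True iff ``a`` equals ``b`` or lies on ``b``'s ancestor/descendant line."""
        self._require(a)
        self._require(b)
        return a == b or a in self.ancestors(b) or a in self.descendants(b)

    def roots(self) -> frozenset[str]:
        return frozenset(
            t for t, term in self.terms.items()
            if not term.obsolete and not self._parent_index.get(t)
        )


# -- loading ---------------------------------------------------------------


def _terms_from_obo_graph(graph) -> dict[str, OntologyTerm]:
    terms: dict[str, OntologyTerm] = {}
    for node, data in graph.nodes(data=True):
        synonyms = set()
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            if m:
                synonyms.add(m.group(1))
        parents = set()
        for parent in data.get("is_a", []):
            parents.add(("is_a", parent))
        for rel_entry in data.get("relationship", []):
            parts = rel_entry.split()
            if len(parts) >= 2:
                parents.add((parts[0], parts[1]))
        replaced = data.get("replaced_by")
        terms[node] = OntologyTerm(
            id=node,
            label=data.get("name", ""),
            synonyms=frozenset(synonyms),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            replaced_by=replaced[0] if replaced else None,
            parents=frozenset(parents),
        )
    # obonet may leave dangling parent references out of the node set; add stubs
    for term in list(terms.values()):
        for _, parent in term.parents:
            if parent not in terms:
                terms[parent] = OntologyTerm(id=parent)
    return terms


def _terms_from_obographs(doc: dict) -> dict[str, OntologyTerm]:
    graphs = doc.get("graphs", [])
    if not graphs:
        return {}
    nodes = []
    edges = []
    for g in graphs:
        nodes.extend(g.get("nodes", []))
        edges.extend(g.get("edges", []))
    parents: dict[str, set[Tuple[str, str]]] = {}
    for e in edges:
        sub = _compact(e["sub"])
        obj = _compact(e["obj"])
        parents.setdefault(sub, set()).add((_compact_pred(e["pred"]), obj))
    terms: dict[str, OntologyTerm] = {}
    for node in nodes:
        if node.get("type") not in (None, "CLASS"):
            continue
        nid = _compact(node["id"])
        meta = node.get("meta") or {}
        synonyms = frozenset(
            s["val"] for s in meta.get("synonyms", []) if s.get("val")
        )
        replaced_by = None
        for bpv in meta.get("basicPropertyValues", []):
            if _compact(bpv.get("pred", "")).endswith("0100001"):  # IAO replaced_by
                replaced_by = _compact(bpv["val"])
        terms[nid] = OntologyTerm(
            id=nid,
            label=node.get("lbl", ""),
            synonyms=synonyms,
            obsolete=bool(meta.get("deprecated", False)),
            replaced_by=replaced_by,
            parents=frozenset(parents.get(nid, ())),
        )
    for term in list(terms.values()):
        for _, parent in term.parents:
            if parent not in terms:
                terms[parent] = OntologyTerm(id=parent)
    return terms


def load_ontology(
    path,
    format: Optional[str] = None,
    closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
) -> Ontology:
    """Load an ontology from an OBO 1.4 flat file or OBO-Graph JSON document.

    Parameters
    ----------
    path:
        Filesystem path. When ``format`` is None the suffix decides:
        ``.json`` means OBO-Graph JSON, anything else the OBO flat file.
    format:
        ``"obo"`` or ``"obographs-json"``.
    closure_relations:
        Relation names traversed by :meth:`Ontology.ancestors` /
        :meth:`Ontology.descendants`.
    """
    path = Path(path)
    if format is None:
        format = "obographs-json" if path.suffix.lower() == ".json" else "obo"
    if format == "obo":
        try:
            graph = obonet.read_obo(str(path), ignore_obsolete=False)
        except Exception as exc:  # obonet raises bare ValueError on bad stanzas
            raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
        terms = _terms_from_obo_graph(graph)
    elif format == "obographs-json":
        try:
            with open(path) as handle:
                doc = json.load(handle)
            terms = _terms_from_obographs(doc)
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"cannot parse OBO-Graph JSON {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown ontology format: {format!r}")
    return Ontology(terms, closure_relations=closure_relations)
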