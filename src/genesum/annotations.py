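"""Gene annotation store (GAF ingestion) and gene set IO.

Annotations follow the GO convention that annotating a gene to a term
implicitly annotates it to every ancestor of that term ("annotation closure").
The store keeps the direct gene→term map and builds the closure-expanded
term→gene index lazily, since toy fixtures are tiny but a real GO GAF is not.
Gene symbols are stored case-preserving and compared case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

import yaml
from Bio.UniProt import GOA

from .errors import EmptyInputError, FormatError, UnknownTermError
from .ontology import Ontology

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """An ordered, duplicate-free list of gene symbols with a name and taxon."""

    name: str
    taxon: str
    genes: List[str]

    def __post_init__(self):
        seen: Set[str] = set()
        deduped = []
        for g in self.genes:
            key = g.casefold()
            if key in seen:
                logger.warning("gene set %s: duplicate symbol %s collapsed", self.name, g)
                continue
            seen.add(key)
            deduped.append(g)
        self.genes = deduped
        if not self.genes:
            raise EmptyInputError(f"gene set {self.name!r} is empty")
        if len(self.genes) < 3:
            logger.warning(
                "gene set %s has only %d genes; sets of 3-200 are typical",
                self.name,
                len(self.genes),
            )


def load_gene_set(path, name: Optional[str] = None, taxon: str = "Homo sapiens") -> GeneSet:
    """Read a gene set from a newline-delimited symbol list or a YAML mapping.

    YAML files use keys ``name``, ``taxon`` and ``genes``. For plain lists the
    file stem becomes the name and ``taxon`` falls back to the argument.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "genes" not in doc:
            raise FormatError(f"{path}: YAML gene set needs a 'genes' key")
        return GeneSet(
            name=str(doc.get("name", path.stem)),
            taxon=str(doc.get("taxon", taxon)),
            genes=[str(g) for g in doc["genes"]],
        )
    genes = [line.strip() for line in text.splitlines()]
    genes = [g for g in genes if g and not g.startswith("#")]
    # allow space-separated symbols on a single line, as printed gene lists often are
    if len(genes) == 1 and " " in genes[0]:
        genes = genes[0].split()
    if not genes:
        raise EmptyInputError(f"{path}: no gene symbols found")
    return GeneSet(name=name or path.stem, taxon=taxon, genes=genes)


def write_gene_set(gs: GeneSet, path) -> None:
    """Write a gene set as a YAML mapping (round-trips with load_gene_set)."""
    doc = {"name": gs.name, "taxon": gs.taxon, "genes": list(gs.genes)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


class GeneAnnotationStore:
    """Direct gene→term annotations plus a closure-expanded term→gene index.

    ``background`` is the gene universe for enrichment: by default every
    distinct symbol seen in the annotation file, whether or not any of its
    rows survived filtering.
    """

    def __init__(
        self,
        direct: Dict[str, Set[str]],
        background: Iterable[str],
        ontology: Ontology,
        term_aspect: Optional[Dict[str, str]] = None,
    ):
        self.direct = {g: set(ts) for g, ts in direct.items()}
        self.background = set(background)
        self.ontology = ontology
        self.term_aspect = dict(term_aspect or {})
        if not self.background:
            raise EmptyInputError("background gene universe is empty")
        for gene, terms in self.direct.items():
            if gene not in self.background:
                raise ValueError(f"annotated gene {gene} missing from background")
            for t in terms:
                if t not in ontology:
                    raise UnknownTermError(f"annotated term {t} not in ontology")
        self._canonical = {g.casefold(): g for g in self.background}
        self._closure_index: Optional[Dict[str, Set[str]]] = None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneAnnotationStore)
            and self.direct == other.direct
            and self.background == other.background
            and self.ontology == other.ontology
        )

    def canonical_symbol(self, symbol: str) -> Optional[str]:
        """Background spelling of ``symbol`` under case-insensitive match."""
        return self._canonical.get(symbol.casefold())

    def direct_terms(self, symbol: str) -> Set[str]:
        canon = self.canonical_symbol(symbol)
        return set(self.direct.get(canon, ())) if canon else set()

    def _ensure_closure_index(self) -> Dict[str, Set[str]]:
        # memoized: gene-level ancestor expansion of every direct annotation
        if self._closure_index is None:
            index: Dict[str, Set[str]] = {}
            for gene, terms in self.direct.items():
                expanded: Set[str] = set()
                for t in terms:
                    expanded |= self.ontology.ancestors(t, reflexive=True)
                for t in expanded:
                    index.setdefault(t, set()).add(gene)
            self._closure_index = index
        return self._closure_index

    def genes_annotated_to(self, term: str, within: Iterable[str]) -> Set[str]:
        """Genes in ``within`` annotated (under closure) to ``term``.

        A gene counts if it is directly annotated to ``term`` or to any
        descendant of ``term``.
        """
        if term not in self.ontology:
            raise UnknownTermError(f"unknown term: {term}")
        annotated = self._ensure_closure_index().get(term, set())
        restricted = set()
        for g in within:
            canon = self.canonical_symbol(g)
            if canon and canon in annotated:
                restricted.add(canon)
        return restricted

    def annotated_terms(self) -> Set[str]:
        """Every term with at least one background gene under closure."""
        return set(self._ensure_closure_index())


def load_gaf(
    path,
    ontology: Ontology,
    qualifier_policy: str = "exclude_not",
    evidence_codes: Optional[Set[str]] = None,
) -> GeneAnnotationStore:
    """Build a :class:`GeneAnnotationStore` from a GAF 2.x file.

    Parameters
    ----------
    qualifier_policy:
        ``"exclude_not"`` drops NOT-qualified rows (the gene stays in the
        background); ``"keep_all"`` keeps every row.
    evidence_codes:
        When given, only rows with these evidence codes contribute
        annotations. No filter by default.
    """
    if qualifier_policy not in ("exclude_not", "keep_all"):
        raise ValueError(f"unknown qualifier_policy: {qualifier_policy!r}")
    direct: Dict[str, Set[str]] = {}
    background: Set[str] = set()
    term_aspect: Dict[str, str] = {}
    skipped_unknown_term = 0
    skipped_malformed = 0
    with open(path) as handle:
        try:
            for rec in GOA.gafiterator(handle):
                symbol = rec.get("DB_Object_Symbol", "").strip()
                term = rec.get("GO_ID", "").strip()
                if not symbol or not term:
                    skipped_malformed += 1
                    continue
                background.add(symbol)
                qualifiers = rec.get("Qualifier", [])
                if qualifier_policy == "exclude_not" and "NOT" in qualifiers:
                    continue
                if evidence_codes is not None and rec.get("Evidence") not in evidence_codes:
                    continue
                if term not in ontology:
                    skipped_unknown_term += 1
                    logger.warning("GAF row for %s: term %s not in ontology; skipped", symbol, term)
                    continue
                direct.setdefault(symbol, set()).add(term)
                aspect = rec.get("Aspect", "").strip()
                if aspect:
                    term_aspect.setdefault(term, aspect)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"cannot parse GAF file {path}: {exc}") from exc
    if not background:
        raise EmptyInputError(f"{path}: no annotation rows found")
    if skipped_unknown_term or skipped_malformed:
        logger.warning(
            "load_gaf(%s): skipped %d rows with unknown terms, %d malformed rows",
            path, skipped_unknown_term, skipped_malformed,
        )
    return GeneAnnotationStore(direct, background, ontology, term_aspect)
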