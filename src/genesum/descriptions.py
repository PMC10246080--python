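"""Per-gene description lines for prompt construction.

Three sources are supported, mirroring the three summarization modes:

* ``none`` — the bare gene symbol (the purely generative mode, which leaves
  the model to its latent knowledge);
* ``narrative`` — curated prose looked up in a symbol→text table (the offline
  analogue of RefSeq gene summaries);
* ``ontological`` — controlled natural language rendered deterministically
  from the gene's direct GO-style annotations (the offline analogue of
  Alliance-style automated descriptions).

A description line is ``"SYMBOL: text"``, or the bare symbol for ``none``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional

from .annotations import GeneAnnotationStore
from .errors import FormatError

logger = logging.getLogger(__name__)

SOURCES = ("none", "narrative", "ontological")

#: Aspect code → verb phrase used by the controlled-language renderer.
DEFAULT_ASPECT_LABELS = {
    "P": "involved in",
    "F": "enables",
    "C": "located in",
}
_ASPECT_ORDER = ("P", "F", "C")


@dataclass(frozen=True)
class GeneDescription:
    symbol: str
    source: str
    text: str = ""

    @property
    def line(self) -> str:
        return self.symbol if self.source == "none" or not self.text else f"{self.symbol}: {self.text}"


def _join_natural(items) -> str:
    items = list(items)
    if not items:
        return ""
    if len(items) == 1:
        return items[0]
    return ", ".join(items[:-1]) + " and " + items[-1]


def render_ontological_synopsis(
    symbol: str,
    store: GeneAnnotationStore,
    aspect_labels: Optional[Mapping[str, str]] = None,
) -> str:
    """Deterministic controlled-language sentence from direct annotations.

    Term labels are grouped by GAF aspect (process / function / component),
    alphabetically ordered within each group, e.g.
    ``"involved in myelination and axon ensheathment; enables ATP binding"``.
    Genes without annotations yield an empty string.
    """
    aspect_labels = dict(aspect_labels or DEFAULT_ASPECT_LABELS)
    terms = store.direct_terms(symbol)
    if not terms:
        logger.warning("gene %s has no annotations; empty ontological synopsis", symbol)
        return ""
    by_aspect: Dict[str, list] = {}
    for t in sorted(terms):
        label = store.ontology.terms[t].label or t
        aspect = store.term_aspect.get(t, "P")
        by_aspect.setdefault(aspect, []).append(label)
    phrases = []
    seen_order = [a for a in _ASPECT_ORDER if a in by_aspect] + sorted(
        a for a in by_aspect if a not in _ASPECT_ORDER
    )
    for aspect in seen_order:
        verb = aspect_labels.get(aspect, "involved in")
        phrases.append(f"{verb} {_join_natural(sorted(by_aspect[aspect]))}")
    return "; ".join(phrases)


def describe_gene(
    symbol: str,
    source: str,
    narrative_table: Optional[Mapping[str, str]] = None,
    store: Optional[GeneAnnotationStore] = None,
    aspect_labels: Optional[Mapping[str, str]] = None,
) -> GeneDescription:
    """Build the description line for one gene under the chosen source.

    A symbol missing from its required source yields an empty-text description
    (the gene stays in the prompt as a bare symbol) with a logged warning.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown description source: {source!r}")
    if source == "none":
        return GeneDescription(symbol=symbol, source=source, text="")
    if source == "narrative":
        if narrative_table is None:
            raise ValueError("narrative source requires a narrative_table")
        lookup = {k.casefold(): v for k, v in narrative_table.items()}
        text = lookup.get(symbol.casefold(), "")
        if not text:
            logger.warning("no narrative description for %s; bare symbol kept", symbol)
        return GeneDescription(symbol=symbol, source=source, text=text)
    if store is None:
        raise ValueError("ontological source requires an annotation store")
    text = ""
    if store.canonical_symbol(symbol) is not None:
        text = render_ontological_synopsis(symbol, store, aspect_labels)
    else:
        logger.warning("gene %s not in annotation store; bare symbol kept", symbol)
    return GeneDescription(symbol=symbol, source=source, text=text)


def load_narrative_table(path) -> Dict[str, str]:
    """Read a two-column (symbol, text) TSV of narrative gene descriptions."""
    table: Dict[str, str] = {}
    with open(path, newline="") as handle:
        for i, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#") and len(row) == 1):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{i}: expected two tab-separated columns")
            table[row[0].strip()] = row[1].strip()
    return table


def write_narrative_table(table: Mapping[str, str], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for symbol in sorted(table):
            writer.writerow([symbol, table[symbol]])
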