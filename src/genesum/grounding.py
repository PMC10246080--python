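"""Completion payload parsing and ontology grounding.

A completion payload carries three sections — Summary, Mechanism, Enriched
Terms — of which only the term list is machine-read; the narrative sections
are passed through untouched. Each raw term string is grounded to the
ontology by exact normalized matching against primary labels first, then
synonyms. Failure to ground is a legitimate outcome, not an error: the
ungrounded strings are exactly the interesting cases (obsolete vocabulary,
paraphrases, fabricated content).

Identifier-shaped strings (``GO:0008150``-like) are never grounded, because
generative models are known to fabricate plausible-looking numeric
identifiers; and p-value-like substrings in any section are flagged as
fabricated statistics, never parsed as statistics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import List, Optional

from .errors import PayloadParseError
from .ontology import Ontology

logger = logging.getLogger(__name__)

GROUNDED = "grounded"
GROUNDED_OBSOLETE = "grounded_obsolete"
UNGROUNDED = "ungrounded"

_SECTION_RE = re.compile(
    r"^\s*(summary|mechanism|enriched terms)\s*:\s*", re.IGNORECASE
)
_ENUMERATION_RE = re.compile(r"^\s*(?:\d+\s*[.):\-]|[-*•])\s*")
_IDENTIFIER_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*:\d+$")
_PVALUE_RE = re.compile(r"\bp\s*(?:-?\s*value)?\s*[=<≤]\s*\d", re.IGNORECASE)


@dataclass(frozen=True)
class GroundingOutcome:
    raw: str
    status: str
    term: Optional[str] = None
    matched_via: Optional[str] = None  # "label" | "synonym"


@dataclass
class SummaryPayload:
    summary: str
    mechanism: str
    raw_terms: List[str]
    groundings: List[GroundingOutcome] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def grounded_terms(self, include_obsolete: bool = True) -> List[str]:
        """Grounded identifiers in raw-term order, duplicates removed."""
        statuses = {GROUNDED, GROUNDED_OBSOLETE} if include_obsolete else {GROUNDED}
        out: List[str] = []
        for g in self.groundings:
            if g.status in statuses and g.term is not None and g.term not in out:
                out.append(g.term)
        return out

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "mechanism": self.mechanism,
            "terms": [
                {
                    "raw": g.raw,
                    "status": g.status,
                    "term_id": g.term,
                    "matched_via": g.matched_via,
                }
                for g in self.groundings
            ],
            "raw_terms": list(self.raw_terms),
            "warnings": list(self.warnings),
        }


def _clean_term(fragment: str) -> str:
    fragment = _ENUMERATION_RE.sub("", fragment.strip())
    return fragment.strip()


def parse_payload(text: str) -> SummaryPayload:
    """Split a completion into summary, mechanism, and raw term strings.

    Section headers are matched case-insensitively. The term string splits on
    semicolons, falling back to commas when no semicolon is present;
    enumeration prefixes are stripped and empty fragments dropped. A payload
    without any term section is a parse error.
    """
    sections = {"summary": [], "mechanism": [], "enriched terms": []}
    current: Optional[str] = None
    found_terms = False
    for line in text.splitlines():
        m = _SECTION_RE.match(line)
        if m:
            current = m.group(1).lower()
            if current == "enriched terms":
                found_terms = True
            sections[current].append(line[m.end():])
        elif current is not None:
            sections[current].append(line)
    if not found_terms:
        raise PayloadParseError("no 'Enriched Terms' section found", raw_text=text)
    warnings: List[str] = []
    summary = "\n".join(sections["summary"]).strip()
    mechanism = "\n".join(sections["mechanism"]).strip()
    if not summary:
        warnings.append("missing Summary section")
        logger.warning("payload has no Summary section")
    if not mechanism:
        warnings.append("missing Mechanism section")
        logger.warning("payload has no Mechanism section")
    term_blob = " ".join(sections["enriched terms"]).strip()
    splitter = ";" if ";" in term_blob else ","
    raw_terms = [_clean_term(frag) for frag in term_blob.split(splitter)]
    raw_terms = [t for t in raw_terms if t]
    if _PVALUE_RE.search(text):
        warnings.append("fabricated-statistic: payload contains p-value-like text")
        logger.warning("payload contains p-value-like text; treating as fabricated")
    return SummaryPayload(
        summary=summary, mechanism=mechanism, raw_terms=raw_terms, warnings=warnings
    )


def normalize(text: str) -> str:
    """Case-fold, collapse internal whitespace, strip surrounding punctuation."""
    text = re.sub(r"\s+", " ", text.strip())
    text = text.strip("\"'`.,;:!?()[]{}")
    return text.casefold().strip()


class TermMatcher:
    """Exact normalized label/synonym index over an ontology."""

    def __init__(self, ontology: Ontology, synonym_scopes_all: bool = True):
        self.ontology = ontology
        self._labels: dict[str, str] = {}
        self._synonyms: dict[str, str] = {}
        label_collisions: dict[str, list] = {}
        syn_collisions: dict[str, list] = {}
        for term_id in sorted(ontology.terms):
            term = ontology.terms[term_id]
            if term.label:
                label_collisions.setdefault(normalize(term.label), []).append(term_id)
            for syn in term.synonyms:
                syn_collisions.setdefault(normalize(syn), []).append(term_id)
        # ambiguity broken by lexicographically smallest id (sorted insert order)
        for key, ids in label_collisions.items():
            if len(ids) > 1:
                logger.warning("label %r maps to %d terms; keeping %s", key, len(ids), ids[0])
            self._labels[key] = ids[0]
        for key, ids in syn_collisions.items():
            if len(ids) > 1:
                logger.warning("synonym %r maps to %d terms; keeping %s", key, len(ids), ids[0])
            self._synonyms[key] = ids[0]

    def ground(self, raw: str) -> GroundingOutcome:
        if _IDENTIFIER_RE.match(raw.strip()):
            logger.warning(
                "raw term %r looks like a bare identifier; refusing to ground "
                "(models fabricate plausible identifiers)", raw,
            )
            return GroundingOutcome(raw=raw, status=UNGROUNDED)
        key = normalize(raw)
        if not key:
            return GroundingOutcome(raw=raw, status=UNGROUNDED)
        term_id = self._labels.get(key)
        via = "label"
        if term_id is None:
            term_id = self._synonyms.get(key)
            via = "synonym"
        if term_id is None:
            return GroundingOutcome(raw=raw, status=UNGROUNDED)
        obsolete = self.ontology.terms[term_id].obsolete
        return GroundingOutcome(
            raw=raw,
            status=GROUNDED_OBSOLETE if obsolete else GROUNDED,
            term=term_id,
            matched_via=via,
        )


def ground_term(raw: str, ontology: Ontology) -> GroundingOutcome:
    """Ground one raw string (builds a throwaway index; prefer TermMatcher)."""
    return TermMatcher(ontology).ground(raw)


def ground_payload(
    payload: SummaryPayload,
    ontology: Ontology,
    matcher: Optional[TermMatcher] = None,
) -> SummaryPayload:
    """Ground every raw term; duplicate grounded identifiers keep the first hit.

    Idempotent: grounding an already-grounded payload recomputes the same
    outcomes from the same raw terms.
    """
    matcher = matcher or TermMatcher(ontology)
    groundings: List[GroundingOutcome] = []
    seen: set[str] = set()
    warnings = [w for w in payload.warnings if not w.startswith("duplicate grounding")]
    for raw in payload.raw_terms:
        outcome = matcher.ground(raw)
        if outcome.term is not None:
            if outcome.term in seen:
                # collapsed downstream by grounded_terms(); outcome itself kept
                warnings.append(f"duplicate grounding {outcome.term} from {raw!r}")
                logger.warning("duplicate grounding %s from %r", outcome.term, raw)
            else:
                seen.add(outcome.term)
        groundings.append(outcome)
    return SummaryPayload(
        summary=payload.summary,
        mechanism=payload.mechanism,
        raw_terms=list(payload.raw_terms),
        groundings=groundings,
        warnings=warnings,
    )
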