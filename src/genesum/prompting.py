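"""Token-budgeted prompt construction.

The prompt is a fixed instruction template (shipped as a package resource)
filled with the taxon and one description line per gene, then closed with an
end marker. When the description lines would push the prompt past the model's
token budget, every description is truncated to the same fraction of its
tokens — the truncation factor (TF). TF = 1.0 means nothing was shortened; a
TF of 0.25 means only 25% of each description survived. Text is cut from the
end of each line on the assumption that the head is the informative part.

The default tokenizer is whitespace word splitting (a rough stand-in for a
model tokenizer); any callable ``str -> list[str]`` can replace it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, List, Sequence

import jinja2

from .descriptions import GeneDescription
from .errors import BudgetError

logger = logging.getLogger(__name__)

Tokenizer = Callable[[str], List[str]]

DEFAULT_END_MARKER = "###"
#: Fraction of the token budget reserved for the model's own output.
DEFAULT_OUTPUT_RESERVE = 0.25
#: Common model context sizes: 4096 (GPT-3.x class), 8192 / 32768 (GPT-4 class).
KNOWN_BUDGETS = (4096, 8192, 32768)


def whitespace_tokenizer(text: str) -> List[str]:
    return text.split()


def count_tokens(text: str, tokenizer: Tokenizer = whitespace_tokenizer) -> int:
    """Number of tokens under ``tokenizer`` (whitespace words by default)."""
    return len(tokenizer(text))


def default_template_text() -> str:
    """The packaged instruction template (double-brace placeholders)."""
    return (
        resources.files("genesum").joinpath("templates/summarize.txt").read_text()
    )


@dataclass
class PromptSpec:
    """Everything needed to build one prompt."""

    taxon: str
    descriptions: List[GeneDescription]
    token_budget: int = 4096
    end_marker: str = DEFAULT_END_MARKER
    template_text: str = field(default_factory=default_template_text)
    output_reserve: float = DEFAULT_OUTPUT_RESERVE

    def __post_init__(self):
        if self.token_budget <= 0:
            raise ValueError("token_budget must be positive")
        if not self.end_marker:
            raise ValueError("end_marker must be nonempty")
        if not 0 <= self.output_reserve < 1:
            raise ValueError("output_reserve must be in [0, 1)")


@dataclass(frozen=True)
class BuiltPrompt:
    text: str
    truncation_factor: float
    token_count: int


def compute_truncation_factor(
    description_tokens: Sequence[int], available_budget: int
) -> float:
    """Uniform retention fraction fitting all descriptions into the budget.

    ``TF = min(1, available_budget / total_tokens)``; each description then
    keeps its first ``floor(TF * tokens)`` tokens, which sums to at most the
    budget. An exhausted budget (template alone over the limit) is an error.
    """
    if available_budget <= 0:
        raise BudgetError(
            f"no token budget left for descriptions (available={available_budget})"
        )
    total = sum(description_tokens)
    if total <= 0:
        return 1.0
    return min(1.0, available_budget / total)


def _render(template_text: str, taxon: str, gene_descriptions: str) -> str:
    template = jinja2.Template(template_text, keep_trailing_newline=True)
    return template.render(taxon=taxon, gene_descriptions=gene_descriptions)


def build_prompt(spec: PromptSpec, tokenizer: Tokenizer = whitespace_tokenizer) -> BuiltPrompt:
    """Fill the template under the token budget and report the TF.

    The budget available to description text is the full budget minus the
    output reserve, the fixed template/marker tokens, and one token of
    per-line overhead for each ``SYMBOL:`` prefix.
    """
    reserve = math.floor(spec.token_budget * spec.output_reserve)
    skeleton = _render(spec.template_text, spec.taxon, "") + spec.end_marker
    fixed = count_tokens(skeleton, tokenizer)
    overhead = sum(
        count_tokens(d.line, tokenizer) - count_tokens(d.text, tokenizer)
        for d in spec.descriptions
    )
    available = spec.token_budget - reserve - fixed - overhead
    token_counts = [count_tokens(d.text, tokenizer) for d in spec.descriptions]
    tf = compute_truncation_factor(token_counts, available)
    if tf < 1.0:
        logger.warning(
            "prompt over budget: truncating descriptions to TF=%.3f", tf
        )
    lines = []
    for d, n_tokens in zip(spec.descriptions, token_counts):
        if tf < 1.0 and n_tokens > 0:
            keep = math.floor(tf * n_tokens)
            tokens = tokenizer(d.text)[:keep]
            truncated = GeneDescription(symbol=d.symbol, source=d.source, text=" ".join(tokens))
            lines.append(truncated.line)
        else:
            lines.append(d.line)
    body = _render(spec.template_text, spec.taxon, "\n".join(lines))
    if not body.endswith("\n"):
        body += "\n"
    text = body + spec.end_marker
    return BuiltPrompt(
        text=text,
        truncation_factor=tf,
        token_count=count_tokens(text, tokenizer),
    )
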