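"""End-to-end runs: descriptions → prompt → completion → parsing → grounding.

These functions are the library face of the command-line tool: each wires
the lower modules into one run, returns the domain objects, and produces a
``RunManifest`` capturing everything needed to re-execute the run. With the
mock or cached-only backends a rerun reproduces output files byte-for-byte,
which is why manifests for deterministic backends carry no wall-clock
timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotations import GeneAnnotationStore, GeneSet
from .benchmark import (
    EvalConfig,
    EvaluationReport,
    StabilityReport,
    confusion,
    filter_standard,
    jaccard_terms,
    perturb_gene_set,
)
from .descriptions import GeneDescription, describe_gene
from .enrichment import EnrichmentRow, enrich
from .grounding import SummaryPayload, TermMatcher, ground_payload, parse_payload
from .llm import Backend, CompletionCache, CompletionRequest, complete
from .prompting import (
    BuiltPrompt,
    DEFAULT_END_MARKER,
    PromptSpec,
    Tokenizer,
    build_prompt,
    whitespace_tokenizer,
)


@dataclass
class RunManifest:
    """Reproducibility envelope for one pipeline run."""

    command: str
    config: Dict
    seeds: Dict[str, int]
    backend_id: str
    cache_path: Optional[str]
    truncation_factor: Optional[float]
    input_hashes: Dict[str, str]
    outputs: List[str]
    warnings: List[str]
    timestamps: Optional[Dict[str, float]]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _hash_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _hash_inputs(paths: Dict[str, Optional[str]]) -> Dict[str, str]:
    out = {}
    for name, p in paths.items():
        if p is not None and Path(p).exists():
            out[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return out


def build_descriptions(
    gene_set: GeneSet,
    source: str,
    store: Optional[GeneAnnotationStore] = None,
    narrative_table: Optional[Dict[str, str]] = None,
) -> List[GeneDescription]:
    return [
        describe_gene(g, source, narrative_table=narrative_table, store=store)
        for g in gene_set.genes
    ]


def run_summarize(
    gene_set: GeneSet,
    source: str,
    backend: Backend,
    store: Optional[GeneAnnotationStore] = None,
    narrative_table: Optional[Dict[str, str]] = None,
    cache: Optional[CompletionCache] = None,
    token_budget: int = 4096,
    end_marker: str = DEFAULT_END_MARKER,
    model_name: str = "mock-small",
    tokenizer: Tokenizer = whitespace_tokenizer,
    matcher: Optional[TermMatcher] = None,
    descriptions: Optional[Sequence[GeneDescription]] = None,
    input_paths: Optional[Dict[str, str]] = None,
) -> Tuple[SummaryPayload, RunManifest, BuiltPrompt]:
    """Full summarization chain for one gene set.

    ``descriptions`` overrides the generated description lines (used by the
    description-swap control). Grounding requires ``store`` (for its
    ontology); with source="none" and no store the payload is returned with
    raw terms only.
    """
    if descriptions is None:
        descriptions = build_descriptions(gene_set, source, store, narrative_table)
    spec = PromptSpec(
        taxon=gene_set.taxon,
        descriptions=list(descriptions),
        token_budget=token_budget,
        end_marker=end_marker,
    )
    prompt = build_prompt(spec, tokenizer)
    record = complete(
        CompletionRequest(prompt=prompt.text, model_name=model_name),
        backend,
        cache,
    )
    payload = parse_payload(record.response_text)
    if store is not None:
        payload = ground_payload(payload, store.ontology, matcher)
    manifest = RunManifest(
        command="summarize",
        config={
            "source": source,
            "token_budget": token_budget,
            "end_marker": end_marker,
            "model_name": model_name,
            "gene_set": gene_set.name,
            "taxon": gene_set.taxon,
            "n_genes": len(gene_set.genes),
        },
        seeds={"backend": getattr(backend, "seed", 0)},
        backend_id=backend.backend_id,
        cache_path=getattr(cache, "path", None),
        truncation_factor=prompt.truncation_factor,
        input_hashes={
            "prompt": _hash_text(prompt.text),
            "response": _hash_text(record.response_text),
            **_hash_inputs(input_paths or {}),
        },
        outputs=[],
        warnings=list(payload.warnings),
        timestamps=None if backend.deterministic else {"completed": time.time()},
    )
    return payload, manifest, prompt


def run_enrich(
    gene_set: GeneSet,
    store: GeneAnnotationStore,
    min_annotated: int = 1,
) -> List[EnrichmentRow]:
    return enrich(gene_set, store, min_annotated=min_annotated)


def evaluate_run(
    gene_set: GeneSet,
    source: str,
    backend: Backend,
    store: GeneAnnotationStore,
    cfg: EvalConfig,
    narrative_table: Optional[Dict[str, str]] = None,
    results: Optional[List[EnrichmentRow]] = None,
    matcher: Optional[TermMatcher] = None,
    **summarize_kwargs,
) -> Tuple[EvaluationReport, SummaryPayload, List[str]]:
    """Summarize one gene set and score it against standard enrichment."""
    if results is None:
        results = enrich(gene_set, store)
    standard = filter_standard(results, cfg)
    payload, _, _ = run_summarize(
        gene_set, source, backend, store=store,
        narrative_table=narrative_table, matcher=matcher, **summarize_kwargs,
    )
    predicted = payload.grounded_terms()
    report = confusion(predicted, standard, store.ontology, cfg)
    return report, payload, standard


def evaluate_grid(
    gene_set: GeneSet,
    source: str,
    backend: Backend,
    store: GeneAnnotationStore,
    top_ns: Sequence[int] = (1, 10),
    p_cutoffs: Sequence[float] = (0.05,),
    closure_matching: bool = True,
    narrative_table: Optional[Dict[str, str]] = None,
    **summarize_kwargs,
) -> pd.DataFrame:
    """Long-format evaluation over an (n, p) grid for one gene set."""
    results = enrich(gene_set, store)
    matcher = TermMatcher(store.ontology)
    rows = []
    for top_n in top_ns:
        for p_cutoff in p_cutoffs:
            cfg = EvalConfig(
                top_n=top_n, p_cutoff=p_cutoff, closure_matching=closure_matching
            )
            report, payload, standard = evaluate_run(
                gene_set, source, backend, store, cfg,
                narrative_table=narrative_table, results=results,
                matcher=matcher, **summarize_kwargs,
            )
            rows.append(
                {
                    "gene_set": gene_set.name,
                    "source": source,
                    "backend": backend.backend_id,
                    "n": top_n,
                    "p_cutoff": p_cutoff,
                    "n_standard": len(standard),
                    "n_predicted": len(payload.grounded_terms()),
                    "tp": report.tp,
                    "fp": report.fp,
                    "fn": report.fn,
                    "precision": report.precision,
                    "recall": report.recall,
                    "f1": report.f1,
                    "has_hit": report.has_hit,
                    "has_top_hit": report.has_top_hit,
                }
            )
    return pd.DataFrame(rows)


def run_stability(
    gene_set: GeneSet,
    source: str,
    backend: Backend,
    store: GeneAnnotationStore,
    narrative_table: Optional[Dict[str, str]] = None,
    marker_a: str = "###",
    marker_b: str = "===",
    **summarize_kwargs,
) -> StabilityReport:
    """The run-to-run stability probe.

    Re-runs the identical configuration with only the prompt end marker
    changed (``###`` → ``===``) and reports the direct-identifier Jaccard
    similarity of the two grounded term sets.
    """
    payload_a, _, _ = run_summarize(
        gene_set, source, backend, store=store,
        narrative_table=narrative_table, end_marker=marker_a, **summarize_kwargs,
    )
    payload_b, _, _ = run_summarize(
        gene_set, source, backend, store=store,
        narrative_table=narrative_table, end_marker=marker_b, **summarize_kwargs,
    )
    a = frozenset(payload_a.grounded_terms())
    b = frozenset(payload_b.grounded_terms())
    return StabilityReport(jaccard=jaccard_terms(a, b), run_a_terms=a, run_b_terms=b)


def run_perturbed_comparison(
    gene_set: GeneSet,
    source: str,
    backend: Backend,
    store: GeneAnnotationStore,
    cfg: EvalConfig,
    fraction: float = 0.1,
    seed: int = 0,
    narrative_table: Optional[Dict[str, str]] = None,
    **summarize_kwargs,
) -> Tuple[EvaluationReport, EvaluationReport, GeneSet]:
    """Evaluate a gene set and its noise-perturbed copy under one config."""
    report_orig, _, _ = evaluate_run(
        gene_set, source, backend, store, cfg,
        narrative_table=narrative_table, **summarize_kwargs,
    )
    perturbed = perturb_gene_set(gene_set, store.background, fraction=fraction, seed=seed)
    report_pert, _, _ = evaluate_run(
        perturbed, source, backend, store, cfg,
        narrative_table=narrative_table, **summarize_kwargs,
    )
    return report_orig, report_pert, perturbed
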