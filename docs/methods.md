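# Methods

This note records the models, conventions, and design choices behind
`genesum`, in the order data flows through the package.

## Ontology model and closure

An ontology is a set of terms with labels, synonyms, obsolescence flags,
optional `replaced_by` pointers, and typed parent edges. Ancestor and
descendant queries traverse a configurable relation set, defaulting to
`{is_a, part_of}` — the two relations over which GO annotation propagation
is standardly sound. Narrowing to `{is_a}` is a constructor argument; by
construction, widening the relation set can only grow closures.

Obsolete terms are loaded and indexed (they matter for grounding: a model
may emit vocabulary that has since been obsoleted) but contribute no edges
to closure traversal. `replaced_by` pointing at a missing or obsolete
target is logged rather than rejected, because released ontologies contain
such chains; the package's own fixtures never produce them. Identifiers
are opaque strings compared exactly; the only normalization applied is
compaction of OBO-PURL URIs to CURIE form when reading OBO-Graph JSON, so
the two serializations of the same ontology load identically.

Closure queries are memoized per ontology. Cycle detection runs at
construction over the closure subgraph and reports one offending cycle.

## Annotations and the background universe

GAF 2.x rows are read with Biopython's GAF iterator. The direct map keys
gene symbols (case-preserving storage, case-insensitive lookup) to term
sets; rows with a NOT qualifier are dropped by default (the gene stays in
the background), and an optional evidence-code allowlist can filter rows.
Rows naming terms absent from the ontology are skipped with a warning
counter rather than failing the load.

The background universe defaults to every distinct symbol in the
annotation file. This is one of two defensible choices (the other being an
externally supplied universe such as all protein-coding genes of the
species); the package defaults to the annotated universe because it is
derivable from the input alone, and both the CLI and
`GeneAnnotationStore` accept an explicit background. The closure-expanded
term→gene index is built lazily on first query and memoized: fixture
ontologies are tiny but a real GO GAF is not, and most sessions query few
terms.

## Enrichment baseline

Each candidate term — any term with at least `min_annotated` (default 1)
sample genes under closure — is scored with the hypergeometric upper tail
`P(X ≥ k)` computed via scipy's log-space survival function. The
Bonferroni factor is the number of candidate terms actually tested, not
the ontology size; testing only candidates is the common ORA convention,
and the factor is visible in the output so users can audit it. Ranking
sorts by (adjusted p, raw p, term id), making row order fully
deterministic under ties. Root terms are tested like any other; upper-tail
(over-representation) only.

## Description sources

Three sources produce the per-gene line `SYMBOL: text` (bare symbol for
the "none" source): bare symbols, a narrative symbol→text table (TSV), and
a controlled-language rendering of the gene's direct annotations —
aspect-grouped, alphabetized, e.g. `involved in myelination and axon
ensheathment; enables ATP binding`. The rendering is deliberately minimal:
its downstream contract is only to be informative and deterministic, not
to reproduce any production description-generation grammar. A gene missing
from its source stays in the prompt as a bare symbol (dropping it would
silently change the set size); the gap is logged.

## Prompt construction and truncation

The instruction template ships as a package resource with `{{ taxon }}`
and `{{ gene_descriptions }}` placeholders, rendered with jinja2 and
closed with an end marker (default `###`). Token accounting defaults to
whitespace word counting — a deliberate, documented approximation; any
`str -> list[str]` callable can replace it for model-accurate counts.

An output reserve (default 25% of the budget, since context limits cover
both input and output) and the fixed template/marker tokens are subtracted
from the budget; each line's `SYMBOL:` prefix counts as overhead. The
remaining allowance is divided by the total description tokens to give a
single global truncation factor `TF = min(1, available / total)`; each
description keeps its first `floor(TF × tokens)` tokens (heads are assumed
more informative than tails), so the floor-sum never exceeds the
allowance and the built prompt never exceeds the budget. `TF = 1` exactly
when nothing was shortened. A budget too small for the template alone is a
hard error rather than an empty prompt.

## Completion backends and caching

Backends implement a one-method contract. The cache is a single sqlite3
file keyed by a SHA-256 of (backend id, model, temperature, prompt);
temperature defaults to 0 (maximal determinism). Because the key includes
the prompt verbatim, the stability probe's end-marker change is a cache
miss by construction.

The mock backend is a pure function of (prompt, behavior, seed) and reads
only the description lines inside the prompt, never the symbols — so the
description-swap control behaves as expected: summaries follow the texts.
Faithful behavior returns every ontology label appearing in at least two
description lines; noisy appends one label not shared across lines, chosen
by prompt hash; ungroundable paraphrases one term into a phrase verifiably
absent from labels and synonyms. Fixture labels are generated
substring-free so the mock's substring matching cannot alias two terms.
A cached-only backend turns cache misses into transport errors, supporting
replay of shipped completions; a minimal OpenAI-compatible adapter (stdlib
HTTP, endpoint and key from environment variables only) is included but
exercised by no test.

## Parsing and grounding

Payloads are split on case-insensitive `Summary:` / `Mechanism:` /
`Enriched Terms:` headers; the term string splits on semicolons (commas as
fallback), enumeration prefixes are stripped, empty fragments dropped.
A payload with no term section anywhere is a parse error carrying the raw
text; missing narrative sections are warnings.

Grounding is exact matching on normalized strings (casefold, whitespace
collapse, surrounding punctuation stripped) against labels first, then
synonyms of all scopes pooled; ambiguous hits resolve to the smallest term
id with a warning. There is deliberately no fuzzy matching: near-miss
phrases staying ungrounded is part of what the benchmark measures.
Obsolete-term matches are kept and flagged `grounded_obsolete` rather than
auto-replaced, so obsolete-vocabulary use remains observable.
Identifier-shaped strings (`PREFIX:digits`) are never grounded — models
fabricate plausible identifiers — and p-value-like substrings anywhere in
the payload raise a fabricated-statistic warning, never a parsed statistic.
Whole-string matching (not longest-substring annotation) is used; a
substring annotator would ground more but blur the ungrounded category.

## Benchmark semantics

Standard results are filtered to the top-n terms passing the cutoff
(adjusted p by default; raw p is a flag). Matching is hierarchy-aware
(equal, ancestor, or descendant) or strict equality. A standard term
matched by any predicted term is a true positive; unmatched standard terms
are false negatives; predicted terms matching nothing are false positives.
Precision's numerator counts *accounted predicted terms* rather than tp:
one predicted ancestor can account for several standard terms and it would
be wrong to credit it multiple times in a fraction over predictions. Both
counts are recoverable from the report (accounted = |predicted| − fp).
Only grounded predictions enter the confusion counts; ungrounded strings
are a separate observable. Perturbed gene sets are scored against standard
enrichment run on the same perturbed set (the alternative — original-set
enrichment as gold — is computable by passing `results=` explicitly).

Perturbation replaces `r = max(1, round(fraction × N))` genes (so a
3-gene set still changes at the nominal 10% rate) with distinct random
pool genes, at the same positions; `fraction=0` is an explicit no-op. The
replacement pool is an explicit parameter (tests use the annotated
background). The stability probe re-runs one configuration with the end
marker toggled `###`→`===` and reports direct-identifier Jaccard (defined
as 1 when both sets are empty).

The exact Mann–Whitney test enumerates the rank-sum statistic with midrank
tie handling over all distinguishable arrangements when `|x|+|y| ≤ 20`
(the default threshold keeps enumeration under ~200k arrangements); larger
samples use scipy's tie-corrected normal approximation and the result is
flagged non-exact. Extremity comparisons use a 1e-9 slack so midrank
floating-point noise cannot drop arrangements tied with the observed one.

## Synthetic fixtures

`FixtureSpec` defaults define the study conditions used throughout the
tests and the acceptance script: a 20-term layered DAG (depth 3, one
root, 1–2 parents per term, 80/20 is_a/part_of), 100 genes, a 20-gene
sample — within the 3–200 range typical of curated evaluation sets — and
one planted term annotating 80% of the sample vs 10% of the remaining
background, which the hypergeometric baseline should recover essentially
always. Each gene carries 1–3 additional random annotations so the
background is not sterile; every gene has at least one annotation so the
GAF round-trips the background exactly. One obsolete term carries a
"retired …" live synonym as the grounded-obsolete probe. Labels are
two-word adjective–noun phrases kept pairwise substring-free. Rates that
would round to zero planted genes are rejected as infeasible.

Narrative tables embed each gene's annotation labels in terse prose with
occasional distractor clauses, so the narrative source is exactly as
solvable by the mock as the ontological source.

What the fixtures do *not* emulate: real GO's scale and topology
(tens of thousands of terms, multiple namespaces), realistic annotation
sparsity and evidence-code mixtures, species symbol conventions, or any
actual language-model behavior. Green tests therefore certify the
machinery — counting, truncation, grounding, scoring, determinism — not
the scientific performance of any real model on real gene sets.

## Reproducibility conventions

All generators take explicit integer seeds; the mock backend is pure; the
acceptance script derives every sub-seed from `--seed` (mod 2³¹). Run
manifests capture config, seeds, backend id, input hashes, and the
truncation factor; for deterministic backends the timestamp field is None
so a re-run reproduces the manifest byte-for-byte. Problem sizes in the
acceptance script (100 recovery fixtures, 500 oracle draws, 50
perturbation seeds, 6-term exhaustive confusion enumeration) were chosen
as the smallest sizes at which the checked rates are stable across seeds.

## Known limitations

- The whitespace tokenizer under-counts relative to BPE tokenizers by
  roughly 1.3–1.5×; budgets calibrated for real models should either use a
  model tokenizer or a correspondingly smaller budget.
- Grounding is whole-string and exact; paraphrases ground only if present
  as synonyms.
- The live-endpoint adapter is untested against any provider and exists as
  a convenience seam; the supported backends are mock and cached-only.
- Bonferroni (not FDR) is the only correction, matching the baseline being
  emulated; ranked-list GSEA is out of scope (inputs are unordered sets).
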