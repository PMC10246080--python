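"""Robustness controls: end-marker stability probe and 10% gene dropout.

The stability probe re-runs an identical configuration with only the prompt
end marker changed (### -> ===) and reports the Jaccard similarity of the
two grounded term sets — a deterministic summarizer scores 1.0, the noisy
mock drifts. The perturbation control replaces 10% of the gene set with
random background genes and re-evaluates.
"""

from genesum import EvalConfig, FixtureSpec, MockBackend, make_fixture
from genesum.pipeline import run_perturbed_comparison, run_stability

ontology, store, gene_set = make_fixture(FixtureSpec(seed=7))

for behavior in ("faithful", "noisy"):
    backend = MockBackend(store=store, behavior=behavior)
    report = run_stability(gene_set, "ontological", backend, store)
    print(f"stability probe ({behavior} mock): Jaccard = {report.jaccard:.3f}")

backend = MockBackend(store=store, behavior="faithful")
orig, pert, perturbed = run_perturbed_comparison(
    gene_set, "ontological", backend, store, EvalConfig(), fraction=0.1, seed=7
)
changed = sum(1 for a, b in zip(gene_set.genes, perturbed.genes) if a != b)
print(f"\nperturbation: {changed}/{len(gene_set.genes)} genes replaced")
print(f"recall original={orig.recall:.3f}  perturbed={pert.recall:.3f}")
print(f"precision original={orig.precision:.3f}  perturbed={pert.precision:.3f}")
print(
    "\nJaccard below 1.0 under a cosmetically different prompt shows the"
    "\nstability machinery detecting run-to-run drift; the perturbed set"
    "\nkeeps the planted signal but dilutes the supporting descriptions."
)
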