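"""Over-representation baseline on a synthetic gene set with a planted term.

Builds a seeded fixture (20-term ontology, 100 annotated genes, 20-gene
sample in which one term annotates 80% of sample genes vs 10% of the rest)
and runs the hypergeometric test with Bonferroni correction.
"""

from genesum import FixtureSpec, enrich, enrichment_table, make_fixture

ontology, store, gene_set = make_fixture(FixtureSpec(seed=7))
rows = enrich(gene_set, store)

print(f"gene set: {gene_set.name} ({len(gene_set.genes)} genes)")
print(f"planted term: {store.planted_term} "
      f"({ontology.terms[store.planted_term].label!r})\n")
print(enrichment_table(rows, store).head(5).to_string(index=False))
print(
    "\nEach row tests one candidate term: k of n sample genes vs K of N"
    "\nbackground genes annotated under closure; p_adj is Bonferroni-corrected."
    "\nThe planted term should sit at rank 1 with p_adj far below 0.05."
)
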