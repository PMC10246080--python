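I will give you a list of {{ taxon }} genes together with descriptions of their functions.
Perform a term enrichment test on these genes.
i.e. tell me what the commonalities are in their function.
Make use of classification hierarchies when you do this.
Only report gene functions in common, not diseases.
e.g. if gene1 is involved in "toe bone growth" and gene2 is involved in "finger morphogenesis"
then the term "digit development" would be enriched as represented by gene1 and gene2.
Only include terms that are statistically over-represented.
Also include a hypothesis of the underlying biological mechanism or pathway.
Provide results in the format
Summary: <high level summary>
Mechanism: <mechanism>
Enriched Terms: <term1>; <term2>; <term3>
For the list of terms, be sure to use a semicolon separator, and do not number the list.
Always put the list of terms last, after mechanism, summary, or hypotheses.
Here are the gene summaries:
{{ gene_descriptions }}
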