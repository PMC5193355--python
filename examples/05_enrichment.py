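"""Gene-set over-representation with one-sided Fisher's exact tests.

Tests whether a gene list is enriched for members of each pathway relative
to a background universe; significance is uncorrected p < 0.05 (a
Benjamini-Hochberg column is shown for reference).
"""

from indelsift.evidence import PathwayGeneSets, enrichment_table, fisher_enrichment

background = [f"g{i:03d}" for i in range(200)]
pathways = PathwayGeneSets(sets={
    "mTOR signaling pathway": set(background[0:12]),
    "MAPK signaling pathway": set(background[40:60]),
    "Ribosome": set(background[100:130]),
})

# a gene list heavily overlapping the mTOR set
gene_list = background[0:9] + background[150:161]
results = fisher_enrichment(gene_list, background, pathways, alpha=0.05)
print(enrichment_table(results).to_string(index=False))
print("\nk of K pathway members appear in the n-gene list drawn from N "
      "background genes; p is the hypergeometric upper tail P(X >= k).")
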