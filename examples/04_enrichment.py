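"""Gene-set over-representation: hypergeometric tail + BH-FDR + gene ratio.

A term collection with one planted enriched term is tested against a query
drawn from that term; the planted term should rank first with a small FDR,
and the worked example (N=20, K=5, n=5, k=3) prints its exact tail
probability 1126/15504.
"""

from ucsig import enrich, hypergeom_tail
from ucsig.synth import synth_genesets

universe = [f"g{i:03d}" for i in range(500)]
query = universe[:25]
collection = synth_genesets(universe, enriched_genes=query[:20], n_terms=15, seed=3)

result = enrich(query, universe, collection)
top = result.table.head(3)[["term_id", "k", "K", "gene_ratio", "p_value", "fdr"]]
print(top.to_string(index=False))
print(f"\nworked example P(X >= 3 | N=20, K=5, n=5) = {hypergeom_tail(3, 20, 5, 5):.5f} "
      f"(= 1126/15504 = {1126 / 15504:.5f})")
print(
    "\ngene_ratio is hits over expressed genes in the term; fdr is the "
    "BH-adjusted p-value used to color enrichment dot plots."
)
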