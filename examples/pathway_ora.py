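"""Over-representation of a gene list in user-supplied pathway sets.

Builds a toy pathway collection over a 1000-gene universe, plants one
genuinely enriched pathway in the query, and runs the hypergeometric test
with Benjamini-Hochberg FDR.
"""

import numpy as np

import senskin as sk

rng = np.random.default_rng(0)
universe = [f"GENE{i:04d}" for i in range(1000)]

# query: 40 genes from an "inflammation" block + 20 random genes
inflammation = universe[:60]
query = inflammation[:40] + list(rng.choice(universe[100:], 20, replace=False))
pathways = {
    "inflammation": inflammation,
    "metabolism": universe[200:280],
    "adhesion": list(rng.choice(universe, 70, replace=False)),
}

results = sk.ora(query, pathways, universe, fdr_alpha=0.05)
print(f"{'pathway':<14}{'overlap':>8}{'size':>6}{'p':>12}{'FDR':>12}")
for r in results:
    print(f"{r.pathway:<14}{r.k_overlap:>8}{r.K_pathway:>6}"
          f"{r.p:>12.2e}{r.fdr:>12.2e}")
print("\nA small FDR means the query contains more pathway members than "
      "expected\nby chance for its size (hypergeometric upper tail).")
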