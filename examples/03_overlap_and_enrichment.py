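"""Hypergeometric overlap and annotation enrichment on toy gene sets.

The overlap test asks how surprising the intersection of two sets is
within a finite universe; enrichment repeats it per annotation term and
controls the FDR with Benjamini-Hochberg across terms.
"""

import numpy as np

import mirdysnet as md

universe = {f"g{i}" for i in range(20000)}
neighbors = {f"g{i}" for i in range(649)}          # one-step neighbor genes
differential = {f"g{i}" for i in range(160)} | {f"g{i}" for i in range(9000, 9600)}

res = md.overlap_test(neighbors, differential, universe)
print(f"overlap {res.overlap}/{res.set_size} "
      f"({res.overlap_percent:.2f}% of the investigated set)")
print(f"expected by chance {res.expected:.1f}; "
      f"fold enrichment {res.fold_enrichment:.1f}; upper-tail p {res.p_upper:.3g}")

rng = np.random.default_rng(3)
query = {f"g{i}" for i in range(80)}
annotation = {"planted_term": {f"g{i}" for i in range(40)} | set(rng.choice(20000, 30).astype(str)),
              **{f"random_term_{j}": {f"g{k}" for k in rng.integers(0, 20000, 60)}
                 for j in range(10)}}
table = md.enrich(query, annotation, universe, alpha=0.05)
top = table.iloc[0]
print(f"top enriched term: {top['term']} "
      f"(overlap {top['overlap']}/{top['set_size']}, q = {top['q']:.2g}); "
      f"{int(table['significant'].sum())} of {len(table)} terms significant")
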