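"""Motif enrichment and the edge-sharing permutation test.

Recomputes a published-style cluster-enrichment 2x2 test, then shows the
network-level statistic: genes joined by a conserved co-expression edge
share candidate motifs far more often than a permutation null allows.
"""

import pandas as pd

from crenet import (
    ContingencyTable,
    edge_sharing_permutation,
    fisher_enrichment,
)

# A cluster of 350 genes in a 5999-gene universe; 87 cluster members and
# 948 outside genes carry the motif.
table = ContingencyTable(a=87, b=948, c=263, d=4701)
p = fisher_enrichment(table, sided="greater")
print(f"one-sided Fisher p for 87/350 vs 948/5649 with the motif: {p:.3g}")
print("(small p: the motif is over-represented inside the cluster)")

# Edge sharing: three 10-gene communities, each with a private motif.
genes = [f"g{i:02d}" for i in range(30)]
presence = pd.DataFrame(0, index=genes, columns=["m1", "m2", "m3"])
edges = []
for c in range(3):
    block = genes[10 * c : 10 * (c + 1)]
    presence.loc[block, f"m{c + 1}"] = 1
    edges += [(a, b) for i, a in enumerate(block) for b in block[i + 1 :]]

res = edge_sharing_permutation(edges, presence, n_permutations=999, seed=0)
print(
    f"\nedge sharing: observed fraction {res.observed:.2f}, "
    f"null mean {res.null_mean:.2f}, p = {res.p:.3g} (B = {res.n_permutations})"
)
print("p = 1/1000 is the smallest value attainable at B = 999 permutations.")
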