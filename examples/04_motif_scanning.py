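"""Degenerate-pattern scanning of promoters.

Expands IUPAC patterns, scans a promoter set for every occurrence
(overlaps included), and reports gene-level presence — the
presence/absence calls that feed the enrichment statistics.
"""

from crenet import (
    SimConfig,
    degeneracy,
    generate_promoters,
    genes_with_motif,
    scan_promoters,
)

for pattern in ("CACGTGT", "AGCMGNC", "TCSTYGACG"):
    print(f"{pattern}: degeneracy {degeneracy(pattern)} (exact words it matches)")

cfg = SimConfig(n_genes=200, promoter_length=500, gc_content=0.36, motif_specs=(), seed=3)
promoters, _ = generate_promoters(cfg.gene_ids(), None, (), cfg)

pattern = "AGCMGNC"
occ = scan_promoters(promoters, pattern)
genes = genes_with_motif(promoters, pattern)
print(
    f"\n{pattern}: {len(occ)} occurrences in {len(genes)} of {len(promoters)} "
    "background promoters (chance matches only — nothing was planted)"
)
first = occ[0]
print(f"example occurrence: gene {first.gene}, offset {first.offset}, word {first.word}")

both = scan_promoters(promoters, "TTGACY", strands="both")
minus = sum(o.strand == "-" for o in both)
print(f"\nTTGACY on both strands: {len(both)} occurrences ({minus} on the reverse strand)")
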