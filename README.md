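# crenet

**Cis-regulatory element (CRE) discovery from intersected co-expression
networks.**

`crenet` is a tested, reusable Python implementation of a promoter-motif
analysis pipeline for multi-condition transcriptome studies — the kind of
analysis used to find regulatory elements shared by developmental leaf
senescence, salt-stress-induced senescence, and the hydrogen-peroxide
response in *Arabidopsis*. It is aimed at regulatory genomicists who have
normalized expression matrices, per-condition time series, and promoter
sequences, and who want to go from "which genes respond in every
condition?" to "which promoter elements plausibly drive that shared
response?" with explicit, testable statistics at every step.

## What it computes

1. **Ternary response classification.** Per condition, a gene is called
   up (+1), down (−1) or unresponsive (0) using an inclusive 2-fold rule
   on the log2 scale (optionally gated by a paired-t-test BH-FDR filter).
   Two peroxide sampling times combine by an and/or rule. The
   (developmental, salt, H₂O₂) triple indexes one of the **26 non-null
   response clusters** (base-3 with the all-zero pattern removed):
   cluster 1 = down in all three conditions, cluster 26 = up in all three.
2. **Conserved co-expression networks.** Each time-series matrix is
   Z-transformed per gene; an edge joins genes *i, j* when Pearson
   *r(i,j) > τ* (default τ = 0.6). The per-condition networks are
   intersected — an edge survives only if present in **every**
   condition — and a threshold scan reports the τ interval over which
   the community structure is stable (adjusted Rand index between
   adjacent thresholds).
3. **Regulatory modules.** Communities of the intersection network by
   agglomerative greedy modularity maximization,
   *Q* = Σ_c (e_c − a_c²), with exact-integer merge gains and
   deterministic tie-breaking; modules are communities with more than
   five genes.
4. **ZOOPS motif discovery.** Expectation-maximization under the
   zero-or-one-occurrence-per-sequence site model: per sequence, a
   posterior over {no site, site at each offset} given a 4×w position
   probability matrix θ, site prior λ (capped so the expected site count
   ≤ `max_sites`, default 10) and a 0-order background; widths 6–12;
   discovered models are reported as minimal IUPAC consensus patterns
   and compared to a catalogue of known CREs by ungapped column
   alignment (mean per-column Pearson correlation, both orientations).
5. **Degenerate scanning.** PatMatch-style exact matching of IUPAC
   patterns at every offset (overlaps reported, sequence `N` never
   matches), with gene-level presence/absence for enrichment.
6. **Enrichment and permutation statistics.** One-sided Fisher exact
   (hypergeometric upper tail) 2×2 enrichment of motifs in clusters and
   communities; flat-map singular enrichment analysis (SEA) with
   Benjamini–Hochberg FDR; and a permutation test for whether genes
   joined by a conserved edge share candidate CREs (presence vectors
   permuted over nodes, add-one p-value).

A first-class synthetic-data module generates seeded studies with known
ground truth — planted response codes, planted co-expressed communities
driven by orthogonal smooth latent curves, and promoters with implanted
degenerate motifs — so every stage is validated by recovery of what was
planted.

## Worked example

`examples/05_enrichment_permutation.py` recomputes a published-style
cluster-enrichment test and the network edge-sharing statistic:

```text
one-sided Fisher p for 87/350 vs 948/5649 with the motif: 0.000131
(small p: the motif is over-represented inside the cluster)

edge sharing: observed fraction 1.00, null mean 0.31, p = 0.001 (B = 999)
p = 1/1000 is the smallest value attainable at B = 999 permutations.
```

The first number is the hypergeometric upper-tail probability that 87 of
350 cluster genes carry a motif found in 1035 of 5999 genes overall —
strong over-representation. The second block shows that when each planted
community carries a private motif, every conserved edge joins genes
sharing a CRE, while permuted assignments almost never do.

The other examples cover each capability end to end (classification,
networks and modules, ZOOPS discovery, scanning, and the full pipeline);
each prints what it computes and what the numbers mean. The `crenet`
command exposes the same stages as subcommands (`simulate`, `classify`,
`network`, `communities`, `discover`, `scan`, `enrich`, `permute`,
`run-all`):

```bash
crenet run-all --seed 42 --outdir demo_out
```

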