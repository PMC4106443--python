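# Methods

This note records the models, conventions, and numerical choices behind
`crenet`, and what the synthetic-data validation does and does not show.

## Response classification

Per condition, the signed log2 fold change of a gene is
`log2FC = mean(treated) − mean(control)` over replicates, and the call is

```
code = sign(log2FC)   if |log2FC| >= fc_threshold  (and q <= alpha, if gated)
     = 0              otherwise
```

with `fc_threshold = 1.0` (an inclusive 2-fold cut-off: the boundary
counts as responsive). The optional significance gate uses a paired
t-test when both arms carry matching replicate labels (the replicated
hydroponic design), a two-sample t-test otherwise, with
Benjamini–Hochberg FDR across genes. **The gate is off by default in the
pipeline**: with three replicates the paired t statistic has two degrees
of freedom, and gating at FDR 0.05 costs roughly a third of true
responders on realistic noise — moderated-variance methods exist to fix
exactly this, but classification here follows the plain fold-change rule
and exposes the gate for stricter analyses. Degenerate zero-variance
genes get p = 0 for a non-zero difference and p = 1 otherwise.

The two peroxide sampling times (1 h, 5 h) combine by an and/or rule:
non-zero if either is non-zero; a sign conflict resolves to the timepoint
with the larger |log2FC| and is flagged as discordant.

**Cluster numbering.** The (dev, salt, h2o2) ternary triple is read as a
base-3 number with H₂O₂ most significant and digits −1→0, 0→1, +1→2,
giving raw indices 1..27; the all-zero pattern (raw 14) is removed and
higher indices shift down. This is the unique labelling consistent with
all three anchor patterns: (−,−,−)→1, dev-only-up→14, (+,+,+)→26.

## Synthetic response data

Gaussian noise is additive on the log2 scale (microarray convention) with
SD `noise_sd` (default 0.25) per replicate measurement; baselines are
N(8, 1). A configurable fraction of genes (default 8% all-up, 4%
all-down) responds concordantly in every condition — the planted
cross-talk signal — and the rest respond independently per condition
(default 30% responders, symmetric up/down). Planted responders shift the
treated mean by ±`effect_log2fc`, default **2.0**: the decision threshold
is 2-fold, and planted effects sit well above it so that recovery
statistics measure the classifier rather than coin-flips at the decision
boundary (a responder planted exactly at the threshold would be called
correctly only half the time by symmetry, for any classifier). Each
peroxide timepoint expresses the gene's combined H₂O₂ code with
probability 0.75, at least one always expressing it, so the and/or rule
reconstructs the planted code exactly.

## Time series and networks

Each condition's latent community curves are random low-frequency
sinusoid mixtures, centred and Gram–Schmidt-orthogonalized, then scaled
to unit SD: within-community Pearson correlation is exactly 1 and
between-community correlation exactly 0 in the noiseless limit, so the
planted partition is identifiable by construction. Gene profiles are
`loading · f_c(t) + noise` with positive loadings uniform in
[0.75, 1.25] × `factor_amplitude`; the defaults
(`factor_amplitude = 1.0`, `noise_sd = 0.25`) give a signal-to-noise
ratio of 4. The same partition drives all three conditions, so planted
communities survive network intersection; genes outside every community
follow private random curves. Six timepoints per series mirror a 24-h
stress course sampled at 0.5–24 h; orthogonalization requires
`n_communities <= n_timepoints − 1`.

Networks: rows are Z-transformed (constant rows become all-zero with a
warning and never gain edges); an edge requires *r > τ* **strictly**, on
the signed correlation by default (positive co-expression is the regulon
assumption; an |r| mode and Spearman are available). τ defaults to 0.6 as
a compromise between correlation strength and community size; the
threshold scan quantifies robustness to this choice. Intersection drops
genes absent from any input and ANDs adjacency elementwise.

## Greedy modularity

Modularity is Q = Σ_c (e_c − a_c²). The agglomerative search starts from
singletons and merges the connected community pair with the largest
ΔQ = e_uv − 2 a_u a_v while ΔQ > 0. Merge gains are compared as the
integer 2mΔQ·m = 2m·E_uv − deg_u·deg_v (m = edge count), so ties are
exact; the tie-break picks the lexicographically smallest pair of
community ids, a community being identified by its smallest member gene
id. This makes the result independent of node input order. Isolated
nodes stay singletons and fall below the module size filter
(default: modules have ≥ 6 genes, i.e. "more than five"). Modularity on
an edgeless network is undefined and raises; the greedy search instead
returns all-singletons with a warning.

## ZOOPS EM

Under ZOOPS a sequence of length L carries one motif instance with
probability λ (uniform over the m = L − w + 1 offsets) or none. With
position probability matrix θ (4×w) and 0-order background b estimated
from the input set, the E-step computes the per-sequence posterior over
{no site, site at j} in log space; the M-step re-estimates θ from
posterior-weighted counts (plus a small Dirichlet pseudocount of 1e-3·b,
kept tiny so the data log likelihood is non-decreasing to numerical
precision) and sets λ to the mean posterior site probability, **capped at
`max_sites`/n** so the expected number of sequences carrying a site never
exceeds `max_sites` (default 10; ZOOPS already caps sites at one per
sequence, so the only coherent total-site cap is on λ·n). Convergence:
relative log-likelihood change < 1e-6 or 200 iterations. Hard site calls
require posterior > 0.5. Scores are the per-column log-likelihood ratio
(LL − LL_background)/w, comparable across widths.

Discovery enumerates seed w-mers present in ≥ 2 sequences, ranked by the
number of sequences containing them, takes the top `n_starts` (default
30, deterministic), screens each with a short EM (30 iterations), and
refines the best to convergence; called sites are masked with N before
the next motif is sought, so reported motifs never overlap. Discovery
scans the given strand only: promoters are directional (a both-strands
scanner flag exists in the pattern scanner). Model selection across
widths uses the per-column score. The formal E-value machinery of the
original motif-discovery tools is out of scope; an empirical
column-shuffle null serves for the catalogue comparison instead.

IUPAC consensus: per column, the minimal degenerate symbol covering all
bases with frequency ≥ 0.25 (a uniform column is N). Catalogue
comparison: ungapped sliding alignment (minimum overlap 4 columns, both
orientations), per-offset score = mean per-column Pearson correlation of
the probability 4-vectors; constant columns score 1 when equal, else 0.

## Scanning and statistics

The scanner compiles an IUPAC pattern into per-position character
classes inside a regex lookahead: every offset is tested, overlapping
matches are all reported, and `N` in a sequence matches nothing.
Coordinates are 0-based on the forward promoter string. Gene-level
statistics use presence/absence.

Enrichment uses the one-sided hypergeometric upper tail
(over-representation), which reproduces published cluster-enrichment
tables to printed precision; BH-FDR across motifs or terms. The cluster
universe is the set of promoters supplied (configurable); SEA takes flat
term→gene maps as given (no ontology propagation) and reports terms at
FDR ≤ 0.05 by default.

The edge-sharing statistic is the fraction of network edges whose
endpoints share ≥ 1 candidate motif. The null permutes the assignment of
presence vectors to nodes — preserving both the topology and the
motif-frequency spectrum (degree-preserving rewiring would change
neither marginal and is unnecessary here) — with
p = (1 + #{null ≥ observed})/(1 + B), B = 999 by default, so p is never
zero and is super-uniform under the null.

## Implanted promoters

Backgrounds are i.i.d. bases at the configured GC content (default 0.36,
plant-like). Implants overwrite the background at a uniform offset
(promoter length stays exactly 500 bp), sampling a uniform expansion of
the degenerate pattern, forward strand only; every implant event is
recorded. A later implant can overwrite an earlier overlapping one — at
the default rates this is vanishingly rare and planted-truth tests use
disjoint target sets.

## Validation scale and what it shows

Test and acceptance runs use deliberately desk-sized problems: 60–1000
genes, 6 timepoints, 100 × 500-bp promoter sets, 20 discovery seeds, 200
calibration repeats at B = 999 permutations. At these sizes the suite
shows that each algorithm recovers exactly what the generator planted
and that the statistics are calibrated under their nulls. It does not
show robustness to what the generator omits: probe-level artefacts,
correlated (batch) noise, non-Gaussian tails, chromatin context,
sequence evolution, or motif positional bias. Data-dependent quantities
of any particular real study (cluster occupancies, module counts,
genome-wide motif gene counts) depend on those real-data features and on
genome annotation versions, and are not reproduction targets; the
structural anchors (cluster numbering, 2×2 tables, threshold
conventions) are.
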