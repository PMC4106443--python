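"""Enrichment and permutation statistics downstream of motif scanning.

Fisher-exact over-representation of motifs in response clusters and
network communities, flat-map singular enrichment analysis (SEA) with
BH-FDR, and the permutation test for motif sharing along co-expression
network edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "bh_fdr",
    "fisher_enrichment",
    "cluster_motif_enrichment",
    "community_motif_enrichment",
    "term_enrichment_sea",
    "edge_sharing_permutation",
    "PermutationResult",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (in-set, out-of-set) x (with feature, without feature)."""

    a: int  # in-set with feature
    b: int  # out-of-set with feature
    c: int  # in-set without feature
    d: int  # out-of-set without feature

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def set_size(self) -> int:
        return self.a + self.c

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    table: ContingencyTable
    p: float
    q: float


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(table: ContingencyTable, sided: str = "greater") -> float:
    """Exact hypergeometric test on a 2x2 table.

    Default ``"greater"`` is one-sided over-representation, P[X >= a]
    under fixed margins — the convention that reproduces published
    cluster-enrichment tables; ``"two-sided"`` is available.
    """
    if sided not in ("greater", "two-sided"):
        raise ValueError("sided must be 'greater' or 'two-sided'")
    arr = [[table.a, table.b], [table.c, table.d]]
    return float(stats.fisher_exact(arr, alternative=sided)[1])


def _presence_frame(motif_presence: Mapping[str, Mapping[str, int]] | pd.DataFrame) -> pd.DataFrame:
    """Normalize gene -> motif -> {0,1} input into a genes x motifs DataFrame."""
    df = pd.DataFrame(motif_presence) if not isinstance(motif_presence, pd.DataFrame) else motif_presence
    return df.astype(bool)


def cluster_motif_enrichment(
    cluster_genes: set[str],
    universe_genes: set[str],
    motif_presence: pd.DataFrame,
    sided: str = "greater",
) -> list[EnrichmentResult]:
    """Per-motif 2x2 enrichment of a response cluster against a universe.

    ``motif_presence`` is a genes x motifs 0/1 DataFrame covering the
    universe. Returns one result per motif with BH-FDR across motifs,
    sorted by p.
    """
    if not cluster_genes <= universe_genes:
        raise ValueError("cluster genes must be a subset of the universe")
    pres = _presence_frame(motif_presence)
    missing = universe_genes - set(pres.index)
    if missing:
        raise ValueError(f"presence matrix misses {len(missing)} universe genes")
    pres = pres.loc[sorted(universe_genes)]
    in_cluster = pres.index.isin(cluster_genes)
    results = []
    for motif in pres.columns:
        with_motif = pres[motif].to_numpy()
        a = int((with_motif & in_cluster).sum())
        b = int((with_motif & ~in_cluster).sum())
        c = int((~with_motif & in_cluster).sum())
        d = int((~with_motif & ~in_cluster).sum())
        table = ContingencyTable(a, b, c, d)
        results.append((motif, table, fisher_enrichment(table, sided)))
    qvals = bh_fdr([r[2] for r in results])
    out = [
        EnrichmentResult(m, t, p, float(q)) for (m, t, p), q in zip(results, qvals)
    ]
    return sorted(out, key=lambda r: (r.p, r.feature))


def community_motif_enrichment(
    communities: Mapping[int, set[str]],
    universe_genes: set[str],
    motif_presence: pd.DataFrame,
) -> pd.DataFrame:
    """Per (community, motif) member counts and one-sided Fisher p-values.

    Communities must be pairwise disjoint subsets of the universe. Returns
    a tidy DataFrame with columns community, motif, n_with_motif, size, p.
    """
    ids = sorted(communities)
    all_members: set[str] = set()
    for cid in ids:
        members = communities[cid]
        if members & all_members:
            raise ValueError("communities overlap")
        all_members |= members
    if not all_members <= universe_genes:
        raise ValueError("community members must lie in the universe")
    pres = _presence_frame(motif_presence).loc[sorted(universe_genes)]
    rows = []
    for cid in ids:
        members = communities[cid]
        in_comm = pres.index.isin(members)
        for motif in pres.columns:
            with_motif = pres[motif].to_numpy()
            table = ContingencyTable(
                int((with_motif & in_comm).sum()),
                int((with_motif & ~in_comm).sum()),
                int((~with_motif & in_comm).sum()),
                int((~with_motif & ~in_comm).sum()),
            )
            rows.append(
                {
                    "community": cid,
                    "motif": motif,
                    "n_with_motif": table.a,
                    "size": len(members),
                    "p": fisher_enrichment(table, "greater"),
                }
            )
    return pd.DataFrame(rows)


def term_enrichment_sea(
    query_genes: set[str],
    background_genes: set[str],
    annotation: Mapping[str, set[str]],
    fdr: float | None = 0.05,
) -> list[EnrichmentResult]:
    """Singular enrichment analysis over a flat term -> gene map.

    Hypergeometric upper-tail p per term against the background, BH-FDR
    across terms; by default only terms with q <= ``fdr`` are returned
    (pass ``fdr=None`` for the full list). Terms with no background genes
    are skipped.
    """
    if not query_genes:
        raise ValueError("empty query gene set")
    if not query_genes <= background_genes:
        raise ValueError("query must be a subset of the background")
    n_bg, n_query = len(background_genes), len(query_genes)
    results = []
    for term in sorted(annotation):
        term_bg = annotation[term] & background_genes
        if not term_bg:
            continue
        a = len(annotation[term] & query_genes)
        table = ContingencyTable(a, len(term_bg) - a, n_query - a, n_bg - len(term_bg) - (n_query - a))
        p = float(stats.hypergeom.sf(a - 1, n_bg, len(term_bg), n_query))
        results.append((term, table, p))
    if not results:
        return []
    qvals = bh_fdr([r[2] for r in results])
    out = [EnrichmentResult(t, tb, p, float(q)) for (t, tb, p), q in zip(results, qvals)]
    out.sort(key=lambda r: (r.p, r.feature))
    if fdr is not None:
        out = [r for r in out if r.q <= fdr]
    return out


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p: float
    n_permutations: int
    null_mean: float


def edge_sharing_permutation(
    edges: Sequence[tuple[str, str]],
    motif_presence: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Permutation test: do connected genes share candidate motifs?

    Statistic: fraction of edges whose endpoints share >= 1 motif. Null:
    the assignment of presence vectors to nodes is permuted (network
    fixed, motif-frequency spectrum preserved), ``n_permutations`` times;
    p uses the add-one rule (1 + #{null >= observed}) / (1 + B), so it is
    never reported as zero.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if not edges:
        raise ValueError("edge-sharing statistic undefined on an edgeless network")
    pres = _presence_frame(motif_presence)
    nodes = list(pres.index)
    idx = {g: i for i, g in enumerate(nodes)}
    try:
        u = np.array([idx[a] for a, b in edges])
        v = np.array([idx[b] for a, b in edges])
    except KeyError as err:
        raise ValueError(f"presence matrix misses node {err.args[0]!r}") from None
    P = pres.to_numpy(dtype=bool)
    observed = float(np.any(P[u] & P[v], axis=1).mean())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = n_permutations
    perms = np.stack([rng.permutation(len(nodes)) for _ in range(B)])
    shared = np.any(P[perms[:, u]] & P[perms[:, v]], axis=2)  # (B, E)
    null = shared.mean(axis=1)
    p = (1.0 + int((null >= observed - 1e-12).sum())) / (1.0 + B)
    return PermutationResult(observed, float(p), B, float(null.mean()))
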