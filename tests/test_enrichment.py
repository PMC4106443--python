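"""Fisher enrichment, SEA, BH-FDR and the edge-sharing permutation test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from crenet.enrichment import (
    ContingencyTable,
    bh_fdr,
    cluster_motif_enrichment,
    community_motif_enrichment,
    edge_sharing_permutation,
    fisher_enrichment,
    term_enrichment_sea,
)


def exhaustive_fisher_greater(a, b, c, d):
    """Oracle: enumerate all tables with the same margins, sum P[X >= a]."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if x >= a:
            p += (
                math.comb(col1, x)
                * math.comb(n - col1, row1 - x)
                / math.comb(n, row1)
            )
    return p


class TestFisher:
    def test_known_cluster_enrichment_row(self):
        # 87 of 350 cluster genes vs 948 of 5649 others carry the motif
        table = ContingencyTable(87, 948, 263, 4701)
        assert fisher_enrichment(table) == pytest.approx(1.31e-4, rel=5e-3)

    def test_empty_feature_is_uninformative(self):
        assert fisher_enrichment(ContingencyTable(0, 0, 10, 20)) == 1.0

    def test_small_table_matches_enumeration(self):
        assert fisher_enrichment(ContingencyTable(2, 1, 1, 2)) == pytest.approx(
            exhaustive_fisher_greater(2, 1, 1, 2)
        )

    def test_random_tables_match_exhaustive_oracle(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            table = ContingencyTable(a, b, c, d)
            assert fisher_enrichment(table) == pytest.approx(
                exhaustive_fisher_greater(a, b, c, d), rel=1e-9
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_case(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_over_ranked_p(self, rng):
        p = np.sort(rng.random(30))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12) and np.all(q >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
def test_bh_is_monotone_capped_and_dominates_p(pvals):
    q = bh_fdr(pvals)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q <= 1.0) and np.all(q >= np.asarray(pvals) - 1e-12)


def presence_frame(universe, hits, motif="M"):
    return pd.DataFrame({motif: [g in hits for g in universe]}, index=list(universe))


class TestClusterEnrichment:
    def test_reconstructs_published_style_table(self):
        universe = [f"g{i}" for i in range(5999)]
        cluster = set(universe[:350])
        hits = set(universe[:87]) | set(universe[350 : 350 + 948])
        res = cluster_motif_enrichment(cluster, set(universe), presence_frame(universe, hits))
        (r,) = res
        t = r.table
        assert (t.a, t.b, t.c, t.d) == (87, 948, 263, 4701)
        assert r.p == pytest.approx(1.31e-4, rel=5e-3)

    def test_ubiquitous_motif_not_enriched(self):
        universe = [f"g{i}" for i in range(100)]
        res = cluster_motif_enrichment(
            set(universe[:20]), set(universe), presence_frame(universe, set(universe))
        )
        assert res[0].p == 1.0

    def test_planted_motif_ranks_first(self, rng):
        universe = [f"g{i}" for i in range(400)]
        cluster = set(universe[:60])
        planted = {g for g in universe if (g in cluster and rng.random() < 0.7) or rng.random() < 0.05}
        decoy = {g for g in universe if rng.random() < 0.2}
        pres = pd.DataFrame(
            {"planted": [g in planted for g in universe], "decoy": [g in decoy for g in universe]},
            index=universe,
        )
        res = cluster_motif_enrichment(cluster, set(universe), pres)
        assert res[0].feature == "planted"

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            cluster_motif_enrichment({"x"}, {"a"}, presence_frame(["a"], set()))


class TestCommunityEnrichment:
    def test_community_equal_to_universe_is_unenriched(self):
        universe = [f"g{i}" for i in range(30)]
        pres = presence_frame(universe, set(universe[:10]))
        df = community_motif_enrichment({0: set(universe)}, set(universe), pres)
        assert (df["p"] == 1.0).all()

    def test_private_motif_minimizes_p_in_its_community(self, rng):
        universe = [f"g{i}" for i in range(200)]
        comms = {c: set(universe[40 * c : 40 * (c + 1)]) for c in range(5)}
        pres = presence_frame(universe, comms[3])  # motif exactly in community 3
        df = community_motif_enrichment(comms, set(universe), pres)
        best = df.loc[df["p"].idxmin()]
        assert best["community"] == 3

    def test_counts_conserved(self, rng):
        universe = [f"g{i}" for i in range(100)]
        hits = {g for g in universe if rng.random() < 0.3}
        comms = {0: set(universe[:30]), 1: set(universe[30:60])}
        df = community_motif_enrichment(comms, set(universe), presence_frame(universe, hits))
        assert df["n_with_motif"].sum() <= len(hits)

    def test_overlapping_communities_rejected(self):
        with pytest.raises(ValueError):
            community_motif_enrichment(
                {0: {"a"}, 1: {"a"}}, {"a", "b"}, presence_frame(["a", "b"], set())
            )


class TestSEA:
    def test_full_term_query_matches_closed_form(self):
        background = {f"g{i}" for i in range(1000)}
        term_genes = set(sorted(background)[:20])
        annotation = {"T": term_genes}
        (res,) = term_enrichment_sea(term_genes, background, annotation, fdr=None)
        expected = float(hypergeom.sf(19, 1000, 20, 20))
        assert res.p == pytest.approx(expected)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment_sea(set(), {"a"}, {"T": {"a"}})

    def test_unannotated_term_skipped(self):
        res = term_enrichment_sea({"a"}, {"a", "b"}, {"T": {"zzz"}}, fdr=None)
        assert res == []


class TestEdgeSharing:
    def test_universal_presence_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        pres = pd.DataFrame({"m": [1] * 10}, index=genes)
        edges = [(genes[i], genes[i + 1]) for i in range(9)]
        res = edge_sharing_permutation(edges, pres, n_permutations=99, seed=0)
        assert res.observed == 1.0 and res.p == 1.0

    def test_private_community_motifs_reach_minimum_p(self):
        # three communities, each sharing a private motif: every edge shares,
        # permutations essentially never do as well
        genes = [f"g{i:02d}" for i in range(30)]
        pres = pd.DataFrame(0, index=genes, columns=["m1", "m2", "m3"])
        edges = []
        for c in range(3):
            block = genes[10 * c : 10 * (c + 1)]
            pres.loc[block, f"m{c + 1}"] = 1
            edges += [(a, b) for i, a in enumerate(block) for b in block[i + 1 :]]
        res = edge_sharing_permutation(edges, pres, n_permutations=999, seed=1)
        assert res.observed == 1.0
        assert res.p == pytest.approx(1 / 1000)

    def test_edgeless_network_rejected(self):
        pres = pd.DataFrame({"m": [1, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            edge_sharing_permutation([], pres)
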