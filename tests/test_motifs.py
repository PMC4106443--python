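"""ZOOPS EM: recovery of planted sites, EM guarantees, consensus, comparison."""

import numpy as np
import pytest

from crenet.motifs import (
    MotifModel,
    consensus_iupac,
    discover_motifs,
    match_known,
    zoops_em,
)
from crenet.scan import reverse_complement

from conftest import random_promoters


def implant(rng, seqs, word, genes, record=None):
    out = dict(seqs)
    for g in genes:
        s = out[g]
        off = int(rng.integers(0, len(s) - len(word) + 1))
        out[g] = s[:off] + word + s[off + len(word) :]
        if record is not None:
            record[g] = off
    return out


class TestZoopsEM:
    def test_recovers_planted_word_in_every_sequence(self, rng):
        word = "GATCCGTA"
        offsets = {}
        seqs = random_promoters(rng, n=25, length=80)
        # reject background collisions so every planted offset is unambiguous
        seqs = {g: s for g, s in seqs.items() if word not in s}
        seqs = implant(rng, seqs, word, list(seqs), record=offsets)
        model = zoops_em(seqs, 8, word, max_sites=len(seqs))
        planted_rows = [
            "ACGT".index(b) for b in word
        ]
        for k, row in enumerate(planted_rows):
            assert model.theta[row, k] > 0.95
        called = {g: off for g, off, _ in model.sites}
        assert called == offsets

    def test_log_likelihood_monotone_non_decreasing(self, rng):
        seqs = random_promoters(rng, n=20, length=120)
        seqs = implant(rng, seqs, "CCGGTTAA", list(seqs)[:10])
        model = zoops_em(seqs, 8, "CCGGTTAA", max_sites=20)
        trace = model.ll_trace
        for a, b in zip(trace, trace[1:]):
            assert b >= a - 1e-6 * abs(a)

    def test_no_motif_shrinks_lambda_or_matches_shuffled_null(self, rng):
        seqs = random_promoters(rng, n=30, length=150)
        seed_word = "ACGTACGT"
        model = zoops_em(seqs, 8, seed_word, max_sites=30)
        lam0 = min(0.5, 30 / 30)
        null_scores = []
        for b in range(20):
            shuffled = {
                g: "".join(rng.permutation(list(s))) for g, s in seqs.items()
            }
            null_scores.append(zoops_em(shuffled, 8, seed_word, max_sites=30).score)
        assert model.lam < 0.2 * lam0 or model.score <= max(null_scores) + 0.5

    def test_lambda_respects_max_sites_cap(self, rng):
        seqs = random_promoters(rng, n=40, length=100)
        seqs = implant(rng, seqs, "TTAACCGG", list(seqs))
        model = zoops_em(seqs, 8, "TTAACCGG", max_sites=10)
        assert model.lam <= 10 / 40 + 1e-12
        assert np.allclose(model.theta.sum(axis=0), 1.0)

    def test_width_longer_than_sequences_rejected(self):
        with pytest.raises(ValueError):
            zoops_em({"a": "ACGT"}, 8, "ACGTACGT")


class TestDiscoverMotifs:
    def test_two_planted_motifs_both_recovered(self, rng):
        seqs = random_promoters(rng, n=40, length=200)
        genes = list(seqs)
        w1, w2 = "TAGGCCAT", "CCGTTACG"
        seqs = implant(rng, seqs, w1, genes[:20])
        seqs = implant(rng, seqs, w2, genes[20:])
        models = discover_motifs(seqs, widths=[8], n_motifs=2, max_sites=40)
        consensi = [m.consensus for m in models[:2]]
        for word in (w1, w2):
            assert any(
                sum(a != b for a, b in zip(c, word)) <= 1 for c in consensi
            ), f"{word} not among {consensi}"

    def test_masking_prevents_overlapping_site_reports(self, rng):
        seqs = random_promoters(rng, n=30, length=150)
        seqs = implant(rng, seqs, "GGATCCGT", list(seqs))
        models = discover_motifs(seqs, widths=[8], n_motifs=2, max_sites=30)
        if len(models) == 2:
            sites1 = {(g, o) for g, o, _ in models[0].sites}
            for g, o, _ in models[1].sites:
                for g1, o1 in sites1:
                    if g == g1:
                        assert o + models[1].width <= o1 or o1 + models[0].width <= o

    def test_single_motif_equals_best_single_run(self, rng):
        seqs = random_promoters(rng, n=20, length=100)
        seqs = implant(rng, seqs, "ACCGGTTA", list(seqs))
        (model,) = discover_motifs(seqs, widths=[8], n_motifs=1, max_sites=20)
        assert model.consensus == "ACCGGTTA"

    def test_width_selection_brackets_planted_width(self, rng):
        word = "TTGACCA"  # planted 7-mer
        seqs = random_promoters(rng, n=40, length=150)
        seqs = implant(rng, seqs, word, list(seqs)[:30])
        (model,) = discover_motifs(seqs, widths=range(6, 13), n_motifs=1, max_sites=40)
        assert model.width in (6, 7, 8)
        assert word in model.consensus or model.consensus in word or (
            sum(a != b for a, b in zip(model.consensus, word)) <= 1
        )


class TestConsensus:
    def make_model(self, theta):
        theta = np.asarray(theta, float)
        return MotifModel(theta.shape[1], theta, 0.5, np.full(4, 0.25), [], 0.0, 0.0)

    def test_column_rules(self):
        theta = np.array(
            [
                [1.0, 0.5, 0.25],
                [0.0, 0.5, 0.25],
                [0.0, 0.0, 0.25],
                [0.0, 0.0, 0.25],
            ]
        )
        assert consensus_iupac(self.make_model(theta)) == "AMN"


class TestMatchKnown:
    def ppm_from_word(self, word):
        theta = np.full((4, len(word)), 0.0)
        for k, b in enumerate(word):
            theta["ACGT".index(b), k] = 1.0
        return theta

    def test_self_match_scores_one(self):
        ppm = self.ppm_from_word("CACGTG")
        match = match_known(ppm, [("self", ppm.copy())], n_shuffles=50)
        assert match.name == "self" and match.score == pytest.approx(1.0)
        assert match.offset == 0 and match.orientation == "+"

    def test_elongated_gbox_matches_gbox_core(self):
        cand = self.ppm_from_word("CACGTGT")
        match = match_known(cand, [("G-box", "CACGTG")], min_overlap=4, n_shuffles=50)
        assert match.name == "G-box" and match.score == pytest.approx(1.0)
        assert match.offset == 0  # the 6 shared columns align head-to-head

    def test_reverse_complement_scores_symmetrically(self):
        cand = self.ppm_from_word("TTGACC")
        rc = self.ppm_from_word(reverse_complement("TTGACC"))
        m_fwd = match_known(cand, [("W-box", "TTGACC")], n_shuffles=50)
        m_rc = match_known(rc, [("W-box", "TTGACC")], n_shuffles=50)
        assert m_fwd.score == pytest.approx(m_rc.score)
        assert {m_fwd.orientation, m_rc.orientation} == {"+", "-"}

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ValueError):
            match_known(self.ppm_from_word("ACGT"), [])
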