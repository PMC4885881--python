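"""PWM construction, exact p-values, scanning, ZOOPS EM, and enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bipscan.annotation import PromoterSequence, reverse_complement
from bipscan.motifs import (
    _ZoopsEM,
    _seq_arrays,
    _background_freqs,
    discover_motifs,
    enrichment_test,
    motif_distance,
    pwm_from_counts,
    scan_sequences,
    score_pvalue_table,
)
from bipscan.simulate import plant_motif, random_promoters

from conftest import consensus_pwm


def promoter(seq, seq_id="s0"):
    return PromoterSequence(
        seq_id=seq_id, sequence=seq, origin="intergenic", chrom="c", start=0, end=len(seq)
    )


class TestPwmFromCounts:
    def test_zero_counts_uniform(self):
        pwm = pwm_from_counts(np.zeros((3, 4)))
        assert np.allclose(pwm.probs, 0.25)

    def test_small_pseudocount_approaches_indicator(self):
        counts = np.eye(4)  # one "ACGT" site
        pwm = pwm_from_counts(counts, pseudocount=1e-9)
        assert np.allclose(np.diag(pwm.probs), 1.0, atol=1e-8)

    def test_rows_normalized(self, rng):
        pwm = pwm_from_counts(rng.uniform(0, 50, (10, 4)))
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.array([[-1.0, 0, 0, 0]]))


class TestScorePvalueTable:
    def test_single_letter_mass(self):
        eps = 1e-4
        probs = np.array([[1 - 3 * eps, eps, eps, eps]])
        pwm = pwm_from_counts(probs * 1e6, pseudocount=1e-9)
        dist = score_pvalue_table(pwm)
        a_score = pwm.log_odds[0, 0]
        assert dist.pvalue(a_score - 1e-6) == pytest.approx(0.25)

    def test_below_minimum_is_one(self, rng):
        pwm = pwm_from_counts(rng.uniform(0, 20, (5, 4)))
        dist = score_pvalue_table(pwm)
        assert dist.pvalue(pwm.log_odds.min(axis=1).sum() - 1.0) == 1.0

    @pytest.mark.parametrize("width", [2, 3, 4])
    def test_matches_exhaustive_enumeration(self, width, rng):
        """Tail probabilities from the convolution equal direct enumeration
        of all 4^w background words at 50 random thresholds."""
        pwm = pwm_from_counts(
            rng.uniform(0, 20, (width, 4)), background=np.array([0.3, 0.2, 0.2, 0.3])
        )
        dist = score_pvalue_table(pwm)
        words = np.array(list(itertools.product(range(4), repeat=width)))
        word_scores = dist.int_scores[np.arange(width)[None, :], words].sum(axis=1)
        word_probs = pwm.background[words].prod(axis=1)
        lo = word_scores.min() * dist.granularity
        hi = word_scores.max() * dist.granularity
        for t in rng.uniform(lo, hi, 50):
            t_int = int(np.ceil(t / dist.granularity - 1e-9))
            expected = word_probs[word_scores >= t_int].sum()
            assert dist.pvalue(t) == pytest.approx(expected, abs=1e-12)

    def test_pmf_sums_to_one_and_sf_monotone(self, rng):
        pwm = pwm_from_counts(rng.uniform(0, 30, (8, 4)))
        dist = score_pvalue_table(pwm)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(dist.sf) <= 1e-15).all()

    def test_granularity_refinement_stable(self, rng):
        """Refining the grid changes queried p-values by < 1e-3 relative."""
        pwm = pwm_from_counts(rng.uniform(0, 30, (8, 4)))
        coarse = score_pvalue_table(pwm, granularity=1e-3)
        fine = score_pvalue_table(pwm, granularity=1e-4)
        lo = coarse.offset * coarse.granularity
        span = len(coarse.pmf) * coarse.granularity
        for frac in (0.2, 0.4, 0.6, 0.8):
            t = lo + frac * span
            pc, pf = coarse.pvalue(t), fine.pvalue(t)
            assert pf > 0
            assert abs(pc - pf) / pf < 1e-3


class TestScan:
    def test_consensus_hit(self):
        pwm = consensus_pwm("ACGTAC")
        hits = scan_sequences(pwm, [promoter("ACGTAC")], p_threshold=1.0)
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].offset == 0
        assert max(hits, key=lambda h: h.score).strand == "+"

    def test_palindromic_pwm_strand_pairs(self):
        pwm = consensus_pwm("GAATTC")  # EcoRI site, reverse-complement palindrome
        seq = promoter("TTGAATTCAA")
        hits = scan_sequences(pwm, [seq], p_threshold=1.0)
        plus = {(h.offset, round(h.score, 6)) for h in hits if h.strand == "+"}
        minus = {(h.offset, round(h.score, 6)) for h in hits if h.strand == "-"}
        assert plus == minus

    def test_matches_sliding_window_oracle(self, rng):
        """Hit set equals brute-force scoring of every window on both strands
        with enumeration-based p-values."""
        pwm = pwm_from_counts(rng.uniform(0, 15, (5, 4)), motif_id="m")
        dist = score_pvalue_table(pwm)
        words = np.array(list(itertools.product(range(4), repeat=5)))
        word_scores = dist.int_scores[np.arange(5)[None, :], words].sum(axis=1)
        word_probs = pwm.background[words].prod(axis=1)
        seqs = random_promoters(20, 200, seed=11)
        threshold = 0.05
        hits = scan_sequences(pwm, seqs, p_threshold=threshold)
        got = {(h.seq_id, h.offset, h.strand) for h in hits}
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = set()
        for s in seqs:
            for strand in "+-":
                text = s.sequence if strand == "+" else reverse_complement(s.sequence)
                for off in range(len(text) - 4):
                    word = [idx[c] for c in text[off : off + 5]]
                    sc = int(dist.int_scores[np.arange(5), word].sum())
                    p = word_probs[word_scores >= sc].sum()
                    if p < threshold:
                        fwd = off if strand == "+" else len(text) - 5 - off
                        expected.add((s.seq_id, fwd, strand))
        assert got == expected

    def test_short_sequence_no_hits(self):
        pwm = consensus_pwm("ACGTACGT")
        assert scan_sequences(pwm, [promoter("ACG")], p_threshold=1.0) == []

    def test_n_windows_skipped(self):
        pwm = consensus_pwm("ACGT")
        hits = scan_sequences(pwm, [promoter("ACNTACGT")], p_threshold=1.0)
        assert all(h.offset >= 3 for h in hits if h.strand == "+")

    def test_strand_symmetry_under_reverse_complement(self, rng):
        pwm = pwm_from_counts(rng.uniform(0, 10, (6, 4)))
        seqs = random_promoters(10, 150, seed=5)
        rc = [promoter(reverse_complement(s.sequence), s.seq_id) for s in seqs]
        h1 = scan_sequences(pwm, seqs, p_threshold=0.05)
        h2 = scan_sequences(pwm, rc, p_threshold=0.05)
        assert len(h1) == len(h2)
        flip = {"+": "-", "-": "+"}
        assert {(h.seq_id, h.strand) for h in h1} == {
            (h.seq_id, flip[h.strand]) for h in h2
        }


class TestDiscovery:
    def test_noiseless_planting_recovers_consensus(self, rng):
        word = "GATTACAG"
        flanks = random_promoters(20, 60, seed=3)
        seqs = []
        for i, f in enumerate(flanks):
            off = int(rng.integers(0, 52))
            seqs.append(promoter(f.sequence[:off] + word + f.sequence[off + 8 :], f"s{i}"))
        (motif,) = discover_motifs(seqs, width=8, n_motifs=1, seed=1)
        assert motif_distance(motif, consensus_pwm(word)) < 0.1

    def test_two_planted_motifs_both_recovered(self):
        w1, w2 = "AGGATCCT", "TTCGAAGC"
        seqs = random_promoters(40, 300, seed=1)
        seqs, _ = plant_motif(seqs, consensus_pwm(w1), site_prob=0.9, seed=2)
        seqs, _ = plant_motif(seqs, consensus_pwm(w2), site_prob=0.9, seed=3)
        found = discover_motifs(seqs, width=8, n_motifs=2, seed=4)
        assert len(found) == 2
        d = [
            min(motif_distance(f, consensus_pwm(w)) for f in found) for w in (w1, w2)
        ]
        assert max(d) < 0.25

    def test_seed_determinism(self):
        seqs = random_promoters(15, 150, seed=9)
        a = discover_motifs(seqs, width=6, n_motifs=1, seed=5)
        b = discover_motifs(seqs, width=6, n_motifs=1, seed=5)
        assert (a[0].probs == b[0].probs).all()

    def test_width_exceeding_shortest_sequence_errors(self):
        with pytest.raises(ValueError, match="width"):
            discover_motifs([promoter("ACGT")], width=8)

    def test_em_log_likelihood_monotone(self):
        seqs = random_promoters(20, 200, seed=2)
        seqs, _ = plant_motif(seqs, consensus_pwm("ACGTACGT"), site_prob=0.8, seed=3)
        arrs = _seq_arrays(seqs)
        bg = _background_freqs(arrs)
        em = _ZoopsEM(arrs, 8, bg, [np.ones(len(a)) for a in arrs])
        probs0 = np.full((8, 4), 0.25)
        probs0[:, 0] = 0.4
        probs0 /= probs0.sum(axis=1, keepdims=True)
        trace = em.fit(probs0)["ll_trace"]
        assert all(b - a > -1e-7 for a, b in zip(trace, trace[1:]))


class TestEnrichment:
    @staticmethod
    def _fake(n, with_hit, prefix):
        from bipscan.motifs import MotifHit

        seqs = random_promoters(n, 100, seed=1, origin=prefix)
        hits = [
            MotifHit(seq_id=s.seq_id, motif_id="m", offset=0, strand="+", score=5.0,
                     p_value=1e-4)
            for s in seqs[:with_hit]
        ]
        return hits, seqs

    def test_no_enrichment(self):
        hits_fg, fg = self._fake(10, 8, "fg")
        hits_bg, bg = self._fake(10, 8, "bg")
        res = enrichment_test(hits_fg, fg, hits_bg, bg)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value >= 0.5

    def test_hypergeometric_closed_form(self):
        """10/10 foreground vs 0/10 background: p = 1/C(20,10) = 1/184756."""
        hits_fg, fg = self._fake(10, 10, "fg")
        hits_bg, bg = self._fake(10, 0, "bg")
        res = enrichment_test(hits_fg, fg, hits_bg, bg)
        assert res.p_value == pytest.approx(1 / 184756, rel=1e-9)

    def test_matches_independent_exact_test(self, rng):
        for _ in range(20):
            n_fg, n_bg = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            k_fg, k_bg = int(rng.integers(0, n_fg + 1)), int(rng.integers(0, n_bg + 1))
            hits_fg, fg = self._fake(n_fg, k_fg, "fg")
            hits_bg, bg = self._fake(n_bg, k_bg, "bg")
            res = enrichment_test(hits_fg, fg, hits_bg, bg)
            expected = stats.hypergeom.sf(k_fg - 1, n_fg + n_bg, k_fg + k_bg, n_fg)
            assert res.p_value == pytest.approx(expected, abs=1e-10)

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            enrichment_test([], [], [], [])
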