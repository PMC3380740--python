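import math
from itertools import product

import numpy as np
import pytest

from hotspot_transreg.motif_scan import (
    MotifError,
    MotifHit,
    MotifMatrix,
    attach_qvalues,
    count_region_hits,
    encode,
    hit_region_ids,
    make_scoring_matrix,
    n_scanned_positions,
    scan_regions,
    score_pvalue_function,
)
from hotspot_transreg.regions import GenomicInterval, RegionSet


def _enumerate_scores(llr: np.ndarray) -> np.ndarray:
    """All 4^w word scores — the brute-force oracle for the p-value DP."""
    w = llr.shape[0]
    words = np.array(list(product(range(4), repeat=w)))
    return llr[np.arange(w), words].sum(axis=1)


class TestScoringMatrix:
    def test_single_strict_column_scores_two_bits(self):
        m = MotifMatrix("m", [[1, 0, 0, 0]])
        sm = make_scoring_matrix(m, pseudocount=0.0)
        assert sm.llr[0, 0] == pytest.approx(2.0)  # log2(1 / 0.25)
        assert (sm.llr[0, 1:] < 0).all() and np.isfinite(sm.llr).all()

    def test_uniform_column_scores_zero(self):
        sm = make_scoring_matrix(MotifMatrix("m", [[0.25] * 4]), pseudocount=0.0)
        assert sm.llr == pytest.approx(np.zeros((1, 4)))

    def test_smoothed_counts_match_hand_arithmetic(self):
        # counts (8,2,0,0), pseudocount 0.1, uniform background
        sm = make_scoring_matrix(MotifMatrix("m", [[8, 2, 0, 0]]), pseudocount=0.1)
        expect = [math.log2(((c + 0.1 * 0.25) / 10.1) / 0.25) for c in (8, 2, 0, 0)]
        assert sm.llr[0] == pytest.approx(expect)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(MotifError):
            MotifMatrix("m", np.empty((0, 4)))
        with pytest.raises(MotifError):
            MotifMatrix("m", [[1, -1, 0, 0]])
        with pytest.raises(MotifError):
            make_scoring_matrix(MotifMatrix("m", [[1, 0, 0, 0]]), background=[0.5, 0.5, 0, 0])


class TestPValueFunction:
    def test_unique_best_word_has_p_one_over_4w(self):
        m = MotifMatrix.from_consensus("m", "ACGT", strength=1000)
        pv = score_pvalue_function(make_scoring_matrix(m))
        assert pv.pvalue(make_scoring_matrix(m).max_score) == pytest.approx(1 / 256)

    def test_below_minimum_score_p_is_one(self):
        sm = make_scoring_matrix(MotifMatrix("m", [[5, 1, 1, 1], [1, 5, 1, 1]]))
        pv = score_pvalue_function(sm)
        assert pv.pvalue(sm.min_score - 10) == 1.0

    def test_monotone_non_increasing(self):
        sm = make_scoring_matrix(MotifMatrix("m", np.random.default_rng(1).random((6, 4)) + 0.01))
        pv = score_pvalue_function(sm)
        grid = np.linspace(sm.min_score - 1, sm.max_score + 1, 200)
        ps = pv.pvalue(grid)
        assert (np.diff(ps) <= 1e-15).all()

    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_dp_matches_exhaustive_enumeration(self, width, rng):
        """DP tail probabilities equal brute-force word enumeration within
        discretization error of the score grid."""
        for _ in range(4):
            sm = make_scoring_matrix(MotifMatrix("m", rng.random((width, 4)) + 0.01))
            pv = score_pvalue_function(sm)
            scores = _enumerate_scores(sm.llr)
            slack = (width / 2 + 1) * pv.bin_width
            for thr in rng.choice(scores, size=20):
                p_dp = pv.pvalue(thr)
                assert (scores >= thr + slack).mean() <= p_dp <= (scores >= thr - slack).mean()


class TestScan:
    def test_palindrome_hits_both_strands_at_same_window(self):
        # ACGT is its own reverse complement: the offset-0 window matches twice
        sm = make_scoring_matrix(MotifMatrix.from_consensus("m", "ACGT", strength=1000))
        hits = scan_regions(sm, {"r": "ACGTA"}, 1 / 256 + 1e-12)
        assert {(h.offset, h.strand) for h in hits} == {(0, "+"), (0, "-")}
        assert all(h.p_value == pytest.approx(1 / 256) for h in hits)

    def test_non_palindromic_reverse_strand_hit(self):
        sm = make_scoring_matrix(MotifMatrix.from_consensus("m", "AAAC", strength=1000))
        hits = scan_regions(sm, {"r": "GTTT"}, 1 / 256 + 1e-12)  # revcomp(GTTT) = AAAC
        assert [(h.offset, h.strand) for h in hits] == [(0, "-")]

    def test_all_n_sequence_yields_no_hits(self):
        sm = make_scoring_matrix(MotifMatrix.from_consensus("m", "ACGT"))
        assert scan_regions(sm, {"r": "N" * 50}, 1.0) == []

    def test_strand_symmetry_property(self, rng):
        """Scanning a sequence with M equals scanning its reverse complement
        with M's reverse-complement matrix, coordinates reflected."""
        seq = "".join(rng.choice(list("ACGT"), size=200))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        m = MotifMatrix("m", rng.random((5, 4)) + 0.01)
        fwd = scan_regions(make_scoring_matrix(m), {"r": seq}, 0.01)
        rev = scan_regions(make_scoring_matrix(m.reverse_complement()), {"r": rc}, 0.01)
        # a + window of seq seen through (rc, M_rc) is still a + score at the
        # reflected coordinate: strands map to themselves, offsets reflect
        reflected = {(len(seq) - 5 - h.offset, h.strand, round(h.p_value, 12)) for h in rev}
        assert {(h.offset, h.strand, round(h.p_value, 12)) for h in fwd} == reflected

    def test_hit_count_monotone_in_threshold(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        sm = make_scoring_matrix(MotifMatrix("m", rng.random((6, 4)) + 0.01))
        counts = [
            len(scan_regions(sm, {"r": seq}, t)) for t in (3e-7, 3.73e-6, 1e-4, 1e-2, 1.0)
        ]
        assert counts == sorted(counts)
        assert counts[-1] == 2 * (2000 - 6 + 1)  # threshold 1: every window, both strands

    def test_threshold_validation(self):
        sm = make_scoring_matrix(MotifMatrix.from_consensus("m", "ACGT"))
        with pytest.raises(MotifError):
            scan_regions(sm, {"r": "ACGT"}, 0.0)


class TestQValues:
    def test_single_hit(self):
        hits = [MotifHit("m", "r", 0, "+", 1.0, 0.01)]
        attach_qvalues(hits, 1)
        assert hits[0].q_value == pytest.approx(0.01)

    def test_hand_computed_bh(self):
        hits = [
            MotifHit("m", "r", 0, "+", 1.0, 0.001),
            MotifHit("m", "r", 5, "+", 1.0, 0.002),
        ]
        attach_qvalues(hits, 2)
        assert [h.q_value for h in hits] == pytest.approx([0.002, 0.002])

    def test_q_capped_at_one_and_n_tests_checked(self):
        hits = [MotifHit("m", "r", 0, "+", 1.0, 0.9)]
        attach_qvalues(hits, 1000)
        assert hits[0].q_value == 1.0
        with pytest.raises(MotifError):
            attach_qvalues([MotifHit("m", "r", 0, "+", 1.0, 0.5)] * 3, 2)

    def test_n_scanned_positions(self):
        assert n_scanned_positions({"a": "ACGTACGT", "b": "ACG"}, 4) == 2 * (5 + 0)


class TestRegionHitCounts:
    REGIONS = RegionSet(
        role="hotspot",
        intervals=[GenomicInterval("chr1", i * 100, i * 100 + 50, f"r{i}") for i in range(10)],
    )

    def test_three_hits_one_region(self):
        hits = [MotifHit("m", "r0", o, "+", 1.0, 0.01) for o in (0, 5, 9)]
        assert count_region_hits(hits, self.REGIONS) == (3, 1)

    def test_no_hits(self):
        assert count_region_hits([], self.REGIONS) == (0, 0)

    def test_unknown_region_rejected(self):
        with pytest.raises(MotifError, match="rX"):
            count_region_hits([MotifHit("m", "rX", 0, "+", 1.0, 0.01)], self.REGIONS)

    def test_regions_with_hit_bounded(self, rng):
        hits = [
            MotifHit("m", f"r{rng.integers(10)}", int(o), "+", 1.0, 0.01) for o in range(25)
        ]
        total, with_hit = count_region_hits(hits, self.REGIONS)
        assert with_hit <= min(total, len(self.REGIONS))
        assert with_hit == len(hit_region_ids(hits))


def test_encode_maps_bases_and_n():
    assert encode("ACGTnX").tolist() == [0, 1, 2, 3, 4, 4]
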