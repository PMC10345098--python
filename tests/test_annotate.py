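import numpy as np
import pytest

import minseqfind as mf
from minseqfind.annotate import mode_precision_matrix, s_scores, snp_eta
from minseqfind.seqio import GenomicInterval, SnpRecord

from conftest import make_scoring_model


class TestScoreSequence:
    def test_direct_containment(self):
        model = make_scoring_model([("AACG", 5.0)])
        assert mf.score_sequence(model, "TTAACGTT") == 5.0

    def test_strand_policy(self):
        model_both = make_scoring_model([("AACG", 5.0)], strand_policy="both")
        model_given = make_scoring_model([("AACG", 5.0)], strand_policy="given")
        seq = "TTCGTTTT"  # contains CGTT = revcomp(AACG)
        assert mf.score_sequence(model_both, seq) == 5.0
        assert mf.score_sequence(model_given, seq) == 0.0

    def test_gapped_pattern_matches_across_spacer(self):
        model = make_scoring_model([("AAC-2-GGT", 7.0)])
        assert mf.score_sequence(model, "TTAACTTGGTCC") == 7.0
        assert mf.score_sequence(model, "TTAACTTTGGT") == 0.0  # wrong spacing

    def test_no_match_score(self):
        model = make_scoring_model([("AACG", 5.0)], no_match_score=0.0)
        assert mf.score_sequence(model, "TTTTTTTT") == 0.0

    def test_adding_records_monotone_under_max(self, rng):
        base = [("AACG", 5.0), ("GGTA", 3.0)]
        model = make_scoring_model(base)
        bigger = make_scoring_model(base + [("TTAA", 9.0)])
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), 30))
            assert mf.score_sequence(bigger, seq) >= mf.score_sequence(model, seq)

    def test_ambiguous_bases_do_not_match_specified_positions(self):
        model = make_scoring_model([("AACG", 5.0)])
        assert mf.score_sequence(model, "TTAANGTT") == 0.0
        # but a pattern gap happily spans an N
        gapped = make_scoring_model([("AA-1-CG", 4.0)])
        assert mf.score_sequence(gapped, "TTAANCGT") == 4.0

    def test_sum_aggregation_within_window(self):
        model = make_scoring_model([("AACG", 5.0), ("CGTT", 3.0)],
                                   window_agg="sum")
        # both fit in one 4..8-nt window region: AACGTT contains both
        assert mf.score_sequence(model, "AACGTT") == 8.0


class TestNegatives:
    def test_multiset_preserved(self, rng):
        seq = "ACGTACGTTTGGCCAA"
        for neg in mf.make_negatives(seq, 5, rng):
            assert sorted(neg) == sorted(seq)

    def test_count_and_determinism(self):
        negs1 = mf.make_negatives("ACGTACGT", 2, np.random.default_rng(9))
        negs2 = mf.make_negatives("ACGTACGT", 2, np.random.default_rng(9))
        assert len(negs1) == 2
        assert negs1 == negs2


class TestRoc:
    def test_complete_separation_gives_auroc_1(self):
        curve = mf.roc([2.0] * 10, [1.0] * 20)
        assert curve.auroc == 1.0

    def test_identical_distributions_near_half(self, rng):
        aurocs = [mf.roc(rng.random(500), rng.random(1000)).auroc
                  for _ in range(20)]
        assert abs(np.mean(aurocs) - 0.5) < 0.02

    def test_symmetry(self, rng):
        a, b = rng.random(50), rng.random(80)
        assert mf.roc(a, b).auroc + mf.roc(b, a).auroc == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self, rng):
        a, b = rng.random(60), rng.random(60)
        direct = mf.roc(a, b).auroc
        warped = mf.roc(np.exp(3 * a), np.exp(3 * b)).auroc
        assert direct == pytest.approx(warped, abs=1e-12)


class TestSScores:
    def test_top_peak_above_all_negatives_scores_1(self):
        pos = np.array([5.0, 0.4, 0.3])
        neg = np.array([1.0, 0.9, 0.2, 0.1])
        s = s_scores(pos, neg)
        assert s[0] == 1.0

    def test_peak_below_every_negative_scores_half(self):
        pos = np.array([0.1, 5.0])
        neg = np.array([1.0, 2.0, 3.0])
        s = s_scores(pos, neg)
        assert s[0] == 0.5

    def test_bounds_hold_for_random_scores(self, rng):
        s = s_scores(rng.random(40), rng.random(80))
        assert (s >= 0.5).all() and (s <= 1.0).all()

    def test_perfect_separation_all_ones_and_auroc_1(self, rng):
        pos = 1.0 + rng.random(30)
        neg = rng.random(60)
        assert mf.roc(pos, neg).auroc == 1.0
        assert (s_scores(pos, neg) == 1.0).all()


class TestPeakAssignEndToEnd:
    def test_planted_peaks_separate_from_permuted(self, rng):
        """Peaks carrying a planted site vs their own base permutations."""
        model = make_scoring_model([("AGGTCA-1-AGGTCA", 40.0)])
        peaks = []
        for i in range(60):
            s = "".join(rng.choice(list("ACGT"), 60))
            site = "AGGTCAT" + "AGGTCA"
            s = s[:20] + site + s[33:]
            peaks.append(GenomicInterval("chr1", i * 100, i * 100 + 60,
                                         name=f"pk{i}", sequence=s))
        scored, curve = mf.peak_s_scores(model, peaks, n_perm=2, rng=rng)
        assert curve.auroc >= 0.9
        assert all(0.5 <= p.s_score <= 1.0 for p in scored)


class TestModes:
    def test_28_categories(self):
        cats = mf.mode_categories("RGGTCR")
        assert len(cats) == 28
        labels = [c.label for c in cats]
        assert labels[0] == "monomer"
        assert "DR1" in labels and "IR8" in labels and "ER0" in labels

    @pytest.mark.parametrize("pattern,expected", [
        ("AGGTCA-1-AGGTCA", "DR1"),
        ("AGGTCA-3-TGACCT", "IR3"),     # right half = revcomp of left
        ("TGACCT-2-AGGTCA", "ER2"),
        ("AGGTCA", "monomer"),
        ("TGACCT-4-TGACCT", "DR4"),     # minus-strand direct repeat
        ("ACGTACGT", "other"),
        ("AGGTCA-1-AGGTCC", "other"),   # second half violates RGGTCR
    ])
    def test_classification(self, pattern, expected):
        model = make_scoring_model([(pattern, 2.0)])
        subs, totals = mf.classify_modes(model, "RGGTCR")
        hits = [label for label, sub in subs.items() if sub is not None]
        assert hits == [expected]
        assert totals[expected] == 2.0

    def test_partition_exactly_one_category_per_record(self):
        pats = [("AGGTCA-1-AGGTCA", 2.0), ("AGGTCA", 1.0), ("TTTTTTTT", 1.0),
                ("GGGTCG-0-CGACCC", 3.0)]
        model = make_scoring_model(pats)
        subs, totals = mf.classify_modes(model, "RGGTCR")
        placed = sum(len(sub.patterns) for sub in subs.values() if sub is not None)
        assert placed == len(pats)

    def test_palindromic_halfsite_precedence_is_deterministic(self):
        # with a palindromic half-site, DR/IR/ER all match; DR (first) wins
        model = make_scoring_model([("ACGCGT-0-ACGCGT", 2.0)])
        subs, _ = mf.classify_modes(model, "ACGCGT")
        assert subs["DR0"] is not None

    def test_mode_precision_matrix_shape(self, rng):
        model = make_scoring_model([("AGGTCA-1-AGGTCA", 20.0), ("AGGTCA", 5.0)])
        peaks = []
        for i in range(10):
            s = "".join(rng.choice(list("ACGT"), 50))
            peaks.append(GenomicInterval("chr1", i, i + 50, name=f"p{i}",
                                         sequence=s[:10] + "AGGTCACAGGTCA" + s[23:]))
        mat = mode_precision_matrix(model, peaks, "RGGTCR", rng=rng)
        assert mat.shape == (10, 28)
        assert mat["DR1"].between(0.5, 1.0).all()


def _snp(ref_flank, alt_flank):
    return SnpRecord("rs1", "chr1", 21, ref_flank[20], alt_flank[20],
                     ref_flank=ref_flank, alt_flank=alt_flank)


class TestSnpAlign:
    def test_worked_eta_example(self):
        """e_ref=0, e_alt=30, max enrichment 100 -> eta=10, log2fc=2, gain."""
        model = make_scoring_model([("AGGTCAAAGGTCA", 30.0), ("TTTTTTTTTTTTT", 100.0)])
        assert snp_eta(model) == 10.0
        flank = "GCGCGCGCGCGCGCGCGCGC"
        ref = flank + "C" + "GGTCAAAGGTCAGCGCGCGC"   # no site
        alt = flank + "A" + "GGTCAAAGGTCAGCGCGCGC"   # creates AGGTCAAAGGTCA
        score = mf.snp_logfc(model, _snp(ref, alt))
        assert score.e_ref == 0.0 and score.e_alt == 30.0
        assert score.log2fc == pytest.approx(2.0)
        assert score.call == "gain"

    def test_identical_flanks_neutral(self):
        model = make_scoring_model([("AACG", 5.0)])
        seq = "A" * 20 + "C" + "A" * 20
        alt = "A" * 20 + "G" + "A" * 20
        s = mf.snp_logfc(model, SnpRecord("r", "c", 21, "C", "G",
                                          ref_flank=seq, alt_flank=alt))
        assert s.log2fc == 0.0 and s.call == "neutral"

    def test_allele_swap_antisymmetry(self):
        model = make_scoring_model([("AGGTCAAAGGTCA", 30.0), ("TTTTTTTTTTTTT", 100.0)])
        flank = "GCGCGCGCGCGCGCGCGCGC"
        ref = flank + "C" + "GGTCAAAGGTCAGCGCGCGC"
        alt = flank + "A" + "GGTCAAAGGTCAGCGCGCGC"
        fwd = mf.snp_logfc(model, _snp(ref, alt))
        rev = mf.snp_logfc(model, _snp(alt, ref))
        assert fwd.log2fc == pytest.approx(-rev.log2fc)

    def test_two_fold_call_threshold(self):
        model = make_scoring_model([("AGGTCAAAGGTCA", 10.0), ("TTTTTTTTTTTTT", 100.0)])
        flank = "GCGCGCGCGCGCGCGCGCGC"
        ref = flank + "C" + "GGTCAAAGGTCAGCGCGCGC"
        alt = flank + "A" + "GGTCAAAGGTCAGCGCGCGC"
        s = mf.snp_logfc(model, _snp(ref, alt))
        # log2((10+10)/10) = 1.0 exactly: at the 2-fold boundary -> gain
        assert s.log2fc == pytest.approx(1.0)
        assert s.call == "gain"
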