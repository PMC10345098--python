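import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import minseqfind as mf
from minseqfind.minseq import atom_probe_matrix, poisson_threshold
from minseqfind.patterns import MinSeqPattern


def naive_count(reads, shape):
    """Brute-force wildcard substring counting, independent of the fast path."""
    k, g, l = shape
    span = k + g + l
    out = {}
    for read in reads:
        for off in range(len(read) - span + 1):
            w = read[off:off + span]
            text = w[:k] if l == 0 else f"{w[:k]}-{g}-{w[k + g:]}"
            out[text] = out.get(text, 0) + 1
    return out


class TestCounting:
    def test_two_windows_of_a_hexamer(self):
        counts = mf.enumerate_and_count(mf.ReadSet(["AACGTT"]), [(2, 1, 2)])
        assert counts.get(MinSeqPattern.from_text("AA-1-GT")) == 1
        assert counts.get(MinSeqPattern.from_text("AC-1-TT")) == 1
        assert counts.shape_total((2, 1, 2)) == 2

    @pytest.mark.parametrize("shape", [(3, 0, 0), (3, 2, 3), (4, 0, 4), (2, 5, 3)])
    def test_window_count_identity(self, rng, shape):
        reads = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(300)]
        counts = mf.enumerate_and_count(mf.ReadSet(reads), [shape])
        span = sum(shape)
        assert counts.shape_total(shape) == 300 * (20 - span + 1)

    def test_matches_naive_oracle_all_small_shapes(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(100)]
        shapes = [s for s in mf.ShapeConfig().shapes(20) if sum(s) <= 10]
        counts = mf.enumerate_and_count(mf.ReadSet(reads), shapes)
        assert shapes, "no shapes with span <= 10"
        for shape in shapes:
            expect = naive_count(reads, shape)
            codes, n = counts.counts[shape]
            got = {mf.minseq._codes_to_text(codes, shape)[i]: int(n[i])
                   for i in range(len(codes))}
            assert got == expect

    def test_ambiguous_reads_flagged_not_counted(self):
        counts = mf.enumerate_and_count(mf.ReadSet(["AACGTT", "AANGTT"]), [(3, 0, 0)])
        assert counts.total_reads == 2
        assert counts.n_reads_counted == 1
        assert counts.shape_total((3, 0, 0)) == 4

    def test_oversized_shape_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="span exceeds"):
            counts = mf.enumerate_and_count(mf.ReadSet(["ACGTAC"]), [(3, 0, 0), (8, 8, 8)])
        assert (8, 8, 8) not in counts.counts


class TestThreshold:
    def test_absolute_boundary_keeps_at_CT(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(400)]
        raw = mf.enumerate_and_count(mf.ReadSet(reads), [(3, 0, 0)])
        filt = mf.apply_threshold(raw, mf.ThresholdPolicy("absolute", C_T=5))
        codes, n = filt.counts[(3, 0, 0)]
        assert (n >= 5).all()
        raw_codes, raw_n = raw.counts[(3, 0, 0)]
        assert set(codes) == set(raw_codes[raw_n >= 5])

    def test_poisson_threshold_matches_tail_summation(self):
        """lambda=1, M=1e6, alpha=0.01: smallest c with P(X>=c) <= alpha/M."""
        lam, M, alpha = 1.0, 10 ** 6, 0.01
        # independent oracle: accumulate the tail by direct summation
        target = alpha / M
        c = 0
        while True:
            from math import exp, factorial
            tail = 1.0 - sum(exp(-lam) * lam ** j / factorial(j)
                             for j in range(c))
            if tail <= target:
                break
            c += 1
        assert poisson_threshold(lam, M, alpha) == c
        assert poisson.sf(c - 1, lam) <= target < poisson.sf(c - 2, lam)

    def test_empty_counts_pass_through(self):
        raw = mf.PatternCounts({(3, 0, 0): (np.array([], dtype=np.int64),
                                            np.array([], dtype=np.int64))},
                               read_length=20, n_reads_counted=0, total_reads=0)
        filt = mf.apply_threshold(raw, mf.ThresholdPolicy())
        assert len(filt.counts[(3, 0, 0)][0]) == 0


class TestEnrichment:
    def test_direct_substitution_into_formula(self):
        """C_b=50, T_b=1000, C*=10, T=2000 -> E* = 10."""
        tables = [np.full((4 ** min(i, 1), 4), 0.25) for i in range(6)]
        model = mf.PagloModel(order=1, read_length=6, tables=tables, T=2000)
        pat = MinSeqPattern.from_text("ACG")
        # uniform model: C* = 2000 * 4 offsets * (1/4)^3 = 125; rescale T_b to hit 10
        cstar = model.expected_count(pat)[0]
        counts = mf.PatternCounts({(3, 0, 0): (np.array([pat.code]), np.array([50]))},
                                  read_length=6, n_reads_counted=1000, total_reads=1000)
        table = mf.compute_enrichment(counts, model)
        row = table.df.iloc[0]
        assert row.enrichment == pytest.approx((50 / 1000) / (cstar / 2000))

    def test_low_expected_flagged_out_of_ranking(self):
        tables = [np.full((4 ** min(i, 1), 4), 0.25) for i in range(6)]
        model = mf.PagloModel(order=1, read_length=6, tables=tables, T=10)
        pat = MinSeqPattern.from_text("ACGTA")   # C* = 10*2*(1/4)^5 ~ 0.02
        counts = mf.PatternCounts({(5, 0, 0): (np.array([pat.code]), np.array([3]))},
                                  read_length=6, n_reads_counted=10, total_reads=10)
        table = mf.compute_enrichment(counts, model, expected_floor=0.5)
        assert table.df.iloc[0].low_expected
        assert len(table.ranked()) == 0

    def test_null_library_calibration(self):
        """Bound reads drawn from the library distribution: mean E* ~ 1.

        Restricted to shape classes whose null mean count is far above the
        count threshold, where retention does not truncate the null.
        """
        libA = mf.simulate_library(mf.SimConfig(library_size=50_000, planted=[], seed=1))
        libB = mf.simulate_library(mf.SimConfig(library_size=50_000, planted=[], seed=2))
        model = mf.fit_paglo(libA, order=1)
        shapes = mf.ShapeConfig(k_min=3, k_max=4, l_min=3, l_max=3)
        table = mf.find_minseqs(libB, model, shapes=shapes)
        r = table.ranked()
        assert len(r) > 10_000
        assert 0.9 < r.enrichment.mean() < 1.1

    def test_zero_T_model_rejected(self):
        tables = [np.full((4 ** min(i, 1), 4), 0.25) for i in range(6)]
        model = mf.PagloModel(order=1, read_length=6, tables=tables, T=0)
        counts = mf.PatternCounts({}, read_length=6, n_reads_counted=1, total_reads=1)
        with pytest.raises(ValueError):
            mf.compute_enrichment(counts, model)


class TestWeighting:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["pattern", "k", "g", "l", "C_b",
                                         "C_expected", "enrichment"])
        df["weighted"] = np.nan
        df["omp_weight"] = np.nan
        df["low_expected"] = False
        return mf.MinSeqTable(df, T_b=100, T=100)

    def test_log2_per_specified_base(self):
        t = self._table([("ACGT-0-ACGT", 4, 0, 4, 10, 1.0, 16.0)])
        out = mf.weight_enrichment(t)
        assert out.df.iloc[0].weighted == pytest.approx(np.log2(16) / 8)  # 0.5

    def test_shorter_pattern_ranks_higher_at_equal_enrichment(self):
        t = self._table([("ACGTACGT", 8, 0, 0, 10, 1.0, 16.0),
                         ("ACGTAC", 6, 0, 0, 10, 1.0, 16.0)])
        out = mf.weight_enrichment(t)
        assert out.df.iloc[0].pattern == "ACGTAC"

    def test_rank_invariant_under_input_permutation(self, rng):
        rows = [(f"{'ACGT'[i % 4] * 4}-1-CGT", 4, 1, 3, 10 + i, 1.0, 2.0 + (i % 3))
                for i in range(8)]
        a = mf.weight_enrichment(self._table(rows))
        b = mf.weight_enrichment(self._table([rows[i] for i in rng.permutation(8)]))
        assert list(a.df.pattern) == list(b.df.pattern)

    def test_tsv_round_trip(self, tmp_path):
        t = mf.weight_enrichment(self._table([("ACG-2-TTA", 3, 2, 3, 9, 1.5, 6.0)]))
        t.policy = "absolute:10"
        path = tmp_path / "t.tsv"
        t.to_tsv(path)
        back = mf.MinSeqTable.from_tsv(path)
        assert back.T_b == 100 and back.policy == "absolute:10"
        assert back.df.iloc[0].pattern == "ACG-2-TTA"
        assert back.df.iloc[0].weighted == pytest.approx(t.df.iloc[0].weighted)


def _toy_table(patterns, weights):
    df = pd.DataFrame({
        "pattern": patterns,
        "k": [MinSeqPattern.from_text(p).k for p in patterns],
        "g": [MinSeqPattern.from_text(p).g for p in patterns],
        "l": [MinSeqPattern.from_text(p).l for p in patterns],
        "C_b": 10, "C_expected": 1.0,
        "enrichment": [2.0 ** (w * 4) for w in weights],
        "weighted": weights, "omp_weight": np.nan, "low_expected": False,
    })
    return mf.MinSeqTable(df, T_b=100, T=100)


class TestOmp:
    def _disjoint_setup(self, rng):
        probes = []
        for i in range(60):
            s = "".join(rng.choice(list("ACGT"), 20))
            s = s.replace("AAGGTCA", "AAGGTCC").replace("TGACCTT", "TGACCAT")
            if i < 20:
                s = s[:3] + "AAGGTCA" + s[10:]
            elif i < 40:
                s = s[:5] + "CCGTGGTTAG" + s[15:]
            probes.append(s)
        table = _toy_table(["AAGGTCA", "CCGT-2-TTAG"], [0.5, 0.25])
        A = atom_probe_matrix(table.patterns(), probes)
        return probes, table, A

    def test_two_disjoint_atoms_recovered_exactly(self, rng):
        probes, table, A = self._disjoint_setup(rng)
        assert not (A[0] * A[1]).any(), "atoms must hit disjoint probes"
        target = 3.0 * A[0] + 1.0 * A[1]
        res = mf.omp_reduce(table, probes=probes, target=target, max_atoms=10)
        got = dict(zip(res.selected.pattern, res.selected.omp_weight))
        assert got["AAGGTCA"] == pytest.approx(3.0, abs=1e-9)
        assert got["CCGT-2-TTAG"] == pytest.approx(1.0, abs=1e-9)
        assert res.residual_trace[-1] < 1e-9

    def test_single_step_is_argmax_correlation(self, rng):
        probes, table, A = self._disjoint_setup(rng)
        target = 3.0 * A[0] + 1.0 * A[1]
        res = mf.omp_reduce(table, probes=probes, target=target, max_atoms=1)
        assert list(res.selected.pattern) == ["AAGGTCA"]

    def test_residual_trace_non_increasing(self, rng):
        probes = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(80)]
        pats = ["ACG", "CGT", "GTA", "TAC", "AC-1-GT", "TTT"]
        table = _toy_table(pats, [0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        target = rng.random(80)
        res = mf.omp_reduce(table, probes=probes, target=target, max_atoms=6)
        trace = np.array(res.residual_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_zero_target_selects_nothing(self, rng):
        probes, table, _ = self._disjoint_setup(rng)
        res = mf.omp_reduce(table, probes=probes, target=np.zeros(60))
        assert len(res.selected) == 0

    def test_matches_best_subset_search(self, rng):
        """Greedy OMP equals exhaustive best subsets on a well-separated toy."""
        from itertools import combinations
        probes, table, A = self._disjoint_setup(rng)
        target = 3.0 * A[0] + 1.0 * A[1]
        # exhaustive size-2 nonnegative LS over the two available atoms
        from scipy.optimize import nnls
        best = None
        for size in (1, 2):
            for combo in combinations(range(A.shape[0]), size):
                w, res_norm = nnls(A[list(combo)].T, target)
                if best is None or res_norm < best[0]:
                    best = (res_norm, combo)
        res = mf.omp_reduce(table, probes=probes, target=target, max_atoms=2)
        assert tuple(sorted(res.selected_indices)) == tuple(sorted(best[1]))
        assert res.residual_trace[-1] == pytest.approx(best[0], abs=1e-9)

    def test_strand_aware_containment(self):
        probes = ["TTTTCGTTTT"]  # contains revcomp of AACG
        A = atom_probe_matrix([MinSeqPattern.from_text("AACG")], probes)
        assert A[0, 0] == 1.0
        A1 = atom_probe_matrix([MinSeqPattern.from_text("AACG")], probes,
                               both_strands=False)
        assert A1[0, 0] == 0.0
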