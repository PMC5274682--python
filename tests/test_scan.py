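"""Scanning protocol arithmetic: windows, merging, frequency matrices, overlap."""

import numpy as np
import pytest

from latentscan.align import EMPTY_ALIGNMENT, GapParams, PeriodicAlignment, local_align_periodic
from latentscan.matrices import FrequencyMatrix, WeightMatrix
from latentscan.scan import (
    ComparisonCounts,
    PeriodicRegion,
    ScanConfig,
    frequency_matrix_from_alignment,
    iter_windows,
    merge_overlapping,
    overlap_compare,
    scan,
)
from latentscan.sequence import NucleotideSequence, random_sequence


def region(start, end, fmax, seq_id="chr1", n=10, z=None):
    return PeriodicRegion(
        seq_id=seq_id, start=start, end=end, n=n, mF_max=fmax, triplet_Z=0.0,
        matrix=WeightMatrix(np.zeros((4, n))), freq=FrequencyMatrix(np.zeros((4, n))),
        consensus="", alignment=EMPTY_ALIGNMENT, z=z,
    )


class TestWindows:
    def test_exact_window_length(self):
        S = random_sequence(600, np.random.default_rng(0))
        assert iter_windows(S, ScanConfig()) == [(1, 600)]

    def test_short_sequence_no_windows(self):
        S = random_sequence(599, np.random.default_rng(0))
        assert iter_windows(S, ScanConfig()) == []

    def test_1400_gives_five_windows(self):
        S = random_sequence(1400, np.random.default_rng(0))
        wins = iter_windows(S, ScanConfig())
        assert [w[0] for w in wins] == [1, 201, 401, 601, 801]
        assert all(e - s + 1 == 600 for s, e in wins)

    def test_count_matches_closed_form(self):
        cfg = ScanConfig()
        rng = np.random.default_rng(1)
        for N in list(range(0, 30)) + [599, 600, 601, 799, 800, 801, 2000, 4999, 5000]:
            S = random_sequence(N, rng)
            expected = 0 if N < 600 else (N - 600) // 200 + 1
            assert len(iter_windows(S, cfg)) == expected, N

    def test_step_cannot_exceed_window(self):
        with pytest.raises(ValueError):
            ScanConfig(window=200, step=300)


class TestMerge:
    def test_disjoint_unchanged(self):
        rs = [region(1, 100, 400), region(200, 300, 350)]
        assert merge_overlapping(rs) == sorted(rs, key=lambda r: r.start)

    def test_higher_score_wins(self):
        a = region(1, 700, 400)
        b = region(300, 900, 500)
        kept = merge_overlapping([a, b])
        assert kept == [b]

    def test_chain_keeps_maximal_only(self):
        # A-B overlap, B-C overlap, A-C disjoint; F(B) maximal -> only B kept
        a = region(1, 400, 400)
        b = region(300, 700, 600)
        c = region(650, 900, 450)
        assert merge_overlapping([a, b, c]) == [b]

    def test_greedy_matches_exhaustive_on_small_instances(self, rng):
        """Greedy-by-score equals brute force under the keep-best-first rule."""
        for _ in range(50):
            regs = [
                region(int(s), int(s + rng.integers(50, 400)), float(rng.uniform(100, 900)))
                for s in rng.integers(1, 2000, size=5)
            ]
            kept = merge_overlapping(regs)
            # independently: iteratively pick global max, discard intersectors
            remaining = sorted(regs, key=lambda r: (-r.mF_max, r.start, r.n))
            expect = []
            while remaining:
                best = remaining.pop(0)
                expect.append(best)
                remaining = [
                    r for r in remaining
                    if r.end < best.start or r.start > best.end
                ]
            assert sorted(kept, key=lambda r: r.start) == sorted(expect, key=lambda r: r.start)

    def test_different_seq_ids_never_compete(self):
        a = region(1, 500, 300, seq_id="chr1")
        b = region(1, 500, 900, seq_id="chr2")
        assert len(merge_overlapping([a, b])) == 2


class TestFrequencyMatrix:
    def test_perfect_tandem_counts(self):
        S = NucleotideSequence("s", "ACGT" * 10)
        w = -np.ones((4, 4))
        for j in range(4):
            w[j, j] = 1.0
        aln = local_align_periodic(S, WeightMatrix(w), GapParams())
        F = frequency_matrix_from_alignment(aln, 4)
        assert F.total == 40
        for j in range(4):
            assert F.counts[j, j] == 10

    def test_total_equals_match_steps_only(self, rng):
        """Indel steps contribute nothing to the counts."""
        for _ in range(20):
            S = random_sequence(80, rng)
            M = WeightMatrix(rng.standard_normal((4, 5)))
            aln = local_align_periodic(S, M, GapParams(1.0, 0.25))
            F = frequency_matrix_from_alignment(aln, 5)
            n_match = sum(1 for s in aln.path if s[0] == "M" and s[3] < 4)
            assert F.total == n_match
            # aligned length minus inserted bases == match steps
            n_ins = sum(1 for s in aln.path if s[0] == "I")
            assert aln.length - n_ins == sum(1 for s in aln.path if s[0] == "M")


class TestOverlapCompare:
    def test_identical_sets_fully_matched(self):
        rs = [region(1, 600, 400), region(1000, 1500, 500)]
        c = overlap_compare(rs, list(rs))
        assert c.matched_A == c.total_A == 2
        assert c.matched_B == c.total_B == 2

    def test_below_fraction_unmatched(self):
        a = [region(1, 600, 400)]
        b = [region(551, 1150, 400)]  # 50/600 ~ 8.3%
        c = overlap_compare(a, b)
        assert c.matched_A == 0

    def test_boundary_fraction_inclusive(self):
        a = [region(1, 600, 400)]
        b = [region(421, 1020, 400)]  # 180/600 = 30% exactly
        c = overlap_compare(a, b)
        assert c.matched_A == 1

    def test_fraction_relative_to_query_length(self):
        short = [region(100, 199, 300)]  # 100 nt
        long_ = [region(150, 1150, 300)]  # overlap 50 = 50% of short, 5% of long
        c = overlap_compare(short, long_)
        assert c.matched_A == 1
        assert c.matched_B == 0

    def test_disjoint_seq_ids_zero_matches(self):
        c = overlap_compare([region(1, 100, 10, seq_id="x")],
                            [region(1, 100, 10, seq_id="y")])
        assert c.matched_A == 0 and c.matched_B == 0


class TestScanSmoke:
    def test_input_shorter_than_window_empty(self):
        S = random_sequence(300, np.random.default_rng(3))
        assert scan([S], ScanConfig()) == []

    def test_perfect_repeat_detected_raw_mode(self):
        """A clean tandem array in background is found with the raw threshold."""
        rng = np.random.default_rng(11)
        unit = "ACGTTGACGG"  # period 10
        background = random_sequence(200, rng).residues
        S = NucleotideSequence("toy", background + unit * 60 + background)
        from latentscan.ga import GAConfig

        cfg = ScanConfig(
            periods=(5, 10, 15), F0=300.0, step=200, window=600,
            ga=GAConfig(population_size=16, max_generations=50,
                        plateau_generations=8),
        )
        regions = scan([S], cfg)
        assert len(regions) >= 1
        r = max(regions, key=lambda r: r.mF_max)
        assert r.n == 10
        assert r.mF_max > 300
        # region overlaps the implant [201, 800]
        assert min(r.end, 800) - max(r.start, 201) > 0.5 * (800 - 201)
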