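"""Information distance between frequency matrices and uniqueness protocol."""

import numpy as np
import pytest
from scipy.special import xlogy

from latentscan.compare import (
    distance_to_normal,
    matrix_distance,
    matrix_distance_normal,
    permutation_null_matrix,
    unique_repeat_count,
)
from latentscan.matrices import FrequencyMatrix


def hand_distance(fk, fl):
    """Term-by-term evaluation of the distance formula, written separately."""
    fk, fl = np.asarray(fk, float), np.asarray(fl, float)
    sk, sl = fk.sum(axis=0), fl.sum(axis=0)
    t = 0.0
    for i in range(4):
        for j in range(fk.shape[1]):
            t += xlogy(fk[i, j], fk[i, j]) + xlogy(fl[i, j], fl[i, j])
            t -= xlogy(fk[i, j] + fl[i, j], fk[i, j] + fl[i, j])
    for j in range(fk.shape[1]):
        t += xlogy(sk[j] + sl[j], sk[j] + sl[j]) - xlogy(sk[j], sk[j]) - xlogy(sl[j], sl[j])
    return t


class TestDistance:
    def test_identity_is_zero(self, rng):
        F = FrequencyMatrix(rng.integers(0, 50, size=(4, 6)).astype(float))
        assert matrix_distance(F, F) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        A = FrequencyMatrix(rng.integers(0, 50, size=(4, 5)).astype(float))
        B = FrequencyMatrix(rng.integers(0, 50, size=(4, 5)).astype(float))
        assert matrix_distance(A, B) == pytest.approx(matrix_distance(B, A), abs=1e-12)

    def test_matches_hand_arithmetic(self):
        k = np.array([[10.0, 0], [0, 10], [0, 0], [0, 0]])
        l = np.array([[5.0, 0], [5, 5], [0, 5], [0, 0]])
        I = matrix_distance(FrequencyMatrix(k), FrequencyMatrix(l))
        assert I == pytest.approx(hand_distance(k, l), abs=1e-12)
        assert I > 0

    def test_non_negative_on_random_pairs(self, rng):
        for _ in range(2000):
            n = int(rng.integers(2, 8))
            A = FrequencyMatrix(rng.integers(0, 30, size=(4, n)).astype(float))
            B = FrequencyMatrix(rng.integers(0, 30, size=(4, n)).astype(float))
            assert matrix_distance(A, B) >= 0.0

    def test_period_mismatch_rejected(self, rng):
        A = FrequencyMatrix(np.ones((4, 3)))
        B = FrequencyMatrix(np.ones((4, 4)))
        with pytest.raises(ValueError):
            matrix_distance(A, B)

    def test_chi_square_null_mean(self):
        """Under the shuffled-sequence null, E[2I] ~ df = 3(n-1)."""
        rng = np.random.default_rng(99)
        for n in [3, 5, 11]:
            s = 40
            base = FrequencyMatrix(
                np.array([np.bincount(rng.choice(4, s), minlength=4) for _ in range(n)]).T.astype(float)
            )
            vals = []
            for _ in range(1000):
                a = permutation_null_matrix(base, rng)
                b = permutation_null_matrix(base, rng)
                vals.append(2 * matrix_distance(a, b))
            df = 3 * (n - 1)
            assert np.mean(vals) == pytest.approx(df, rel=0.10)


class TestNormalTransform:
    def test_zero_point(self):
        # 4I = 2 df - 1  ->  X = 0
        n = 5
        df = 3 * (n - 1)
        I = (2 * df - 1) / 4.0
        assert distance_to_normal(I, n).X == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_I(self):
        xs = [distance_to_normal(I, 4).X for I in [0.5, 1.0, 2.0, 5.0]]
        assert xs == sorted(xs)

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            distance_to_normal(1.0, 1)

    def test_null_calibration_standard_normal(self):
        """X on shuffled-composition matrix pairs is ~ N(0,1)."""
        rng = np.random.default_rng(4242)
        n, s = 5, 50
        base = FrequencyMatrix(
            np.array([np.bincount(rng.choice(4, s), minlength=4) for _ in range(n)]).T.astype(float)
        )
        xs = []
        for _ in range(2000):
            a = permutation_null_matrix(base, rng)
            b = permutation_null_matrix(base, rng)
            xs.append(distance_to_normal(matrix_distance(a, b), n).X)
        assert -0.2 < np.mean(xs) < 0.2
        assert 0.8 < np.std(xs) < 1.2

    def test_cyclic_shift_minimization(self, rng):
        A = FrequencyMatrix(rng.integers(0, 40, size=(4, 6)).astype(float))
        shifted = FrequencyMatrix(np.roll(A.counts, 2, axis=1))
        assert matrix_distance_normal(A, shifted, cyclic=True).I == pytest.approx(0.0, abs=1e-9)
        assert matrix_distance_normal(A, shifted, cyclic=False).I > 0


def family_matrix(consensus_col, n, s, rng, noise=0.15):
    """Counts concentrated on a family-specific base pattern."""
    counts = np.zeros((4, n))
    for j in range(n):
        draws = rng.choice(4, size=s, p=_family_p(consensus_col, j, noise))
        counts[:, j] = np.bincount(draws, minlength=4)
    return FrequencyMatrix(counts)


def _family_p(cons, j, noise):
    p = np.full(4, noise / 3)
    p[cons[j]] = 1 - noise
    return p


class TestUniqueness:
    def test_self_comparison_zero_unique(self, rng):
        mats = [
            FrequencyMatrix(rng.integers(5, 40, size=(4, 4)).astype(float))
            for _ in range(6)
        ]
        rep = unique_repeat_count(mats, list(mats), seed=1)
        assert np.all(rep.x_min < 0.5)
        assert rep.unique_count == 0 or rep.x0 is None or rep.x0 > max(rep.x_min)

    def test_planted_unique_family_detected(self):
        rng = np.random.default_rng(31)
        n, s = 6, 60
        fam_shared = rng.integers(0, 4, n)
        fam_unique = (fam_shared + 2) % 4  # disjoint consensus
        A = [family_matrix(fam_shared, n, s, rng) for _ in range(10)]
        A += [family_matrix(fam_unique, n, s, rng) for _ in range(10)]
        B = [family_matrix(fam_shared, n, s, rng) for _ in range(10)]
        rep = unique_repeat_count(A, B, seed=7)
        assert rep.threshold_found
        assert 8 <= rep.unique_count <= 12

    def test_increasing_ratio_never_increases_count(self):
        rng = np.random.default_rng(32)
        n, s = 5, 50
        fam = rng.integers(0, 4, n)
        other = (fam + 1) % 4
        A = [family_matrix(fam, n, s, rng) for _ in range(8)]
        A += [family_matrix(other, n, s, rng) for _ in range(8)]
        B = [family_matrix(fam, n, s, rng) for _ in range(8)]
        counts = [
            unique_repeat_count(A, B, ratio=r, seed=3).unique_count
            for r in [5.0, 20.0, 100.0]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            unique_repeat_count([], [FrequencyMatrix(np.ones((4, 3)))])

    def test_no_same_period_partner_skipped(self, rng):
        A = [FrequencyMatrix(rng.integers(1, 20, size=(4, 3)).astype(float)),
             FrequencyMatrix(rng.integers(1, 20, size=(4, 7)).astype(float))]
        B = [FrequencyMatrix(rng.integers(1, 20, size=(4, 3)).astype(float))]
        rep = unique_repeat_count(A, B, seed=2)
        assert rep.skipped == 1
        assert len(rep.x_min) == 1
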