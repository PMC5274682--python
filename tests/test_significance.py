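"""Shuffle nulls, p-values and threshold calibration (cheap contracts)."""

import numpy as np
import pytest

from latentscan.ga import GAConfig
from latentscan.sequence import NucleotideSequence, random_sequence
from latentscan.significance import (
    ShuffleStats,
    _upper_quantile,
    calibrate_threshold,
    dinucleotide_shuffle,
    log10_p_value,
    null_stats,
    p_value,
    shuffle_sequence,
)


def stats(mean, sigma, n=10):
    return ShuffleStats(
        n=n, n_shuffles=100, mean_Fr=mean, sigma_Fr=sigma,
        samples=(), source_length=600,
    )


class TestShuffle:
    def test_composition_and_length_preserved(self, rng):
        S = random_sequence(300, rng, composition=[0.4, 0.3, 0.2, 0.1])
        out = shuffle_sequence(S, seed=7)
        assert len(out) == 300
        assert sorted(out.residues) == sorted(S.residues)
        assert out.residues != S.residues  # astronomically unlikely otherwise

    def test_seed_determinism(self, rng):
        S = random_sequence(100, rng)
        assert shuffle_sequence(S, 1).residues == shuffle_sequence(S, 1).residues
        assert shuffle_sequence(S, 1).residues != shuffle_sequence(S, 2).residues

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shuffle_sequence(NucleotideSequence("e", ""), 0)

    def test_dinucleotide_shuffle_preserves_dinucleotides(self, rng):
        S = random_sequence(200, rng)
        out = dinucleotide_shuffle(S, seed=3)
        assert sorted(out.residues) == sorted(S.residues)

        def dinucs(s):
            from collections import Counter
            return Counter(zip(s[:-1], s[1:]))

        # walk may drop a short tail in rare degenerate cases; usually exact
        a, b = dinucs(S.residues), dinucs(out.residues)
        diff = sum((a - b).values()) + sum((b - a).values())
        assert diff <= 4


class TestPValue:
    def test_mean_gives_half(self):
        assert p_value(142.6, stats(142.6, 52.3)) == pytest.approx(0.5)

    def test_strictly_decreasing(self):
        s = stats(142.6, 52.3)
        ps = [p_value(f, s) for f in [100, 200, 300, 400]]
        assert ps == sorted(ps, reverse=True)

    def test_extreme_tail_on_log_scale(self):
        """A score ~11 sigma above the null: normal tail below 1e-28."""
        s = stats(142.6, 52.3)
        lp = log10_p_value(726.31, s)
        assert lp < -28
        assert lp > -32  # the normal model cannot produce e.g. 1e-50 here

    def test_degenerate_sigma(self):
        s = stats(100.0, 0.0)
        assert p_value(99.0, s) == 1.0
        assert p_value(101.0, s) == 0.0


class TestNullStats:
    def test_small_null_run_moments(self):
        """Mean/sigma recomputable from samples; sigma positive on real data."""
        S = random_sequence(80, np.random.default_rng(5))
        cfg = GAConfig(
            population_size=10, max_generations=20, plateau_generations=5, seed=3
        )
        st = null_stats(S, 5, n_shuffles=4, ga_cfg=cfg)
        arr = np.array(st.samples)
        assert st.mean_Fr == pytest.approx(arr.mean())
        assert st.sigma_Fr == pytest.approx(arr.std(ddof=1))
        assert st.sigma_Fr >= 0
        assert st.source_length == 80

    def test_too_few_shuffles_rejected(self):
        S = random_sequence(50, np.random.default_rng(0))
        with pytest.raises(ValueError):
            null_stats(S, 3, n_shuffles=1)


class TestCalibration:
    def test_upper_quantile_guarantee(self, rng):
        for _ in range(20):
            vals = rng.normal(size=60)
            q = _upper_quantile(vals, 0.05)
            assert np.mean(vals >= q) <= 0.05

    def test_threshold_monotone_in_fpr(self, rng):
        vals = rng.normal(size=200)
        qs = [_upper_quantile(vals, a) for a in [0.01, 0.05, 0.2]]
        assert qs == sorted(qs, reverse=True)

    def test_invalid_fpr_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(target_fpr=1.5, n_windows=20)

    def test_small_calibration_end_to_end(self):
        """Tiny design: returned F0 satisfies the quantile contract exactly."""
        cfg = GAConfig(
            population_size=8, max_generations=15, plateau_generations=4, seed=1
        )
        cal = calibrate_threshold(
            window_length=60, n_windows=20, n_values=(3, 5),
            target_fpr=0.10, ga_cfg=cfg, curve_reps=3, seed=9,
        )
        assert cal.exceedance(cal.F0) <= 0.10
        assert cal.exceedance(cal.Z0, standardized=True) <= 0.10
        assert len(cal.null_scores) == 20
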