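"""Shuffle nulls, p-values and detection-threshold calibration.

The null model for a periodicity score is the same optimization run on
randomly mixed (permuted) sequence: composition is preserved, order is
destroyed.  Because the genetic algorithm partially overfits whatever
sequence it is given, the null mean of mF_max grows with the period length
(a 4 x n matrix has 4n adjustable weights), so scores at different periods
are only comparable after standardization against a per-period null curve.
The scanner therefore carries a :class:`NullSpectrumCurve` — the null mean
and pooled standard deviation of mF_max per period for windows of a fixed
length — and works with the standardized spectrum

    z(n) = (mF_max(n) - mu_null(n)) / sigma_null,

mirroring the selection of the detected period by highest statistical
significance rather than by raw score.  Thresholds for a target
false-positive ratio are calibrated empirically on simulated null windows,
family-wise over the tested periods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .align import GapParams
from .ga import GAConfig, ga_optimize
from .sequence import NucleotideSequence, from_codes, random_sequence


@dataclass(frozen=True)
class ShuffleStats:
    """Null mean/sigma of mF_max over shuffled copies of one sequence."""

    n: int
    n_shuffles: int
    mean_Fr: float
    sigma_Fr: float
    samples: tuple[float, ...]
    source_length: int


@dataclass(frozen=True)
class SignificanceConfig:
    n_shuffles: int = 100
    threshold_P0: float = 0.05
    F0: float = 390.0
    target_fpr: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_P0 < 1.0:
            raise ValueError("threshold_P0 must be in (0, 1)")
        if self.F0 < 0:
            raise ValueError("F0 must be non-negative")


def shuffle_sequence(S: NucleotideSequence, seed: int) -> NucleotideSequence:
    """Uniform random permutation of the residues (composition preserved)."""
    if len(S) < 1:
        raise ValueError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    return from_codes(rng.permutation(S.codes), id=f"{S.id}|shuffled")


def dinucleotide_shuffle(S: NucleotideSequence, seed: int) -> NucleotideSequence:
    """Shuffle preserving dinucleotide composition (Altschul-Erickson style
    random Eulerian walk on the dinucleotide graph); optional stricter null."""
    rng = np.random.default_rng(seed)
    codes = S.codes
    if len(codes) < 3:
        return S
    # successor lists per symbol
    succ: dict[int, list[int]] = {}
    for a, b in zip(codes[:-1], codes[1:]):
        succ.setdefault(int(a), []).append(int(b))
    for k in succ:
        rng.shuffle(succ[k])
    out = [int(codes[0])]
    idx = {k: 0 for k in succ}
    for _ in range(len(codes) - 1):
        k = out[-1]
        lst = succ.get(k, [])
        if idx.get(k, 0) >= len(lst):
            break  # walk stuck; extremely rare, tail dropped
        out.append(lst[idx[k]])
        idx[k] += 1
    if len(out) < len(codes):  # pad by mononucleotide shuffle of the remainder
        rest = list(codes)
        for v in out:
            rest.remove(v)
        rng.shuffle(rest)
        out.extend(int(v) for v in rest)
    return from_codes(np.array(out, dtype=np.int8), id=f"{S.id}|dishuffled")


def null_stats(
    S: NucleotideSequence,
    n: int,
    n_shuffles: int = 100,
    ga_cfg: GAConfig | None = None,
    gaps: GapParams | None = None,
) -> ShuffleStats:
    """Mean and sample sigma of mF_max over seeded shuffles of ``S`` at period n."""
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2 (sigma undefined otherwise)")
    ga_cfg = ga_cfg or GAConfig()
    base = np.random.SeedSequence([int(ga_cfg.seed) % (2**31), 777, n])
    samples = []
    for child in base.spawn(n_shuffles):
        s = int(child.generate_state(1)[0] % (2**31))
        shuffled = shuffle_sequence(S, seed=s)
        res = ga_optimize(shuffled, n, replace(ga_cfg, seed=s), gaps)
        samples.append(res.mF_max)
    arr = np.array(samples)
    return ShuffleStats(
        n=n,
        n_shuffles=n_shuffles,
        mean_Fr=float(arr.mean()),
        sigma_Fr=float(arr.std(ddof=1)),
        samples=tuple(float(x) for x in arr),
        source_length=len(S),
    )


def p_value(F: float, stats: ShuffleStats) -> float:
    """Upper-tail P(F_r > F) under the normal null model.

    Underflows to 0.0 for extreme scores; use :func:`log10_p_value` there.
    """
    if stats.sigma_Fr == 0:
        return 1.0 if F <= stats.mean_Fr else 0.0
    return float(norm.sf(F, loc=stats.mean_Fr, scale=stats.sigma_Fr))


def log10_p_value(F: float, stats: ShuffleStats) -> float:
    """log10 of the upper-tail probability; safe for extreme tails."""
    if stats.sigma_Fr == 0:
        return 0.0 if F <= stats.mean_Fr else -np.inf
    return float(norm.logsf(F, loc=stats.mean_Fr, scale=stats.sigma_Fr) / np.log(10.0))


@dataclass(frozen=True)
class NullSpectrumCurve:
    """Per-period null mean of mF_max, with a pooled sigma, at fixed length."""

    length: int
    periods: tuple[int, ...]
    means: tuple[float, ...]
    sigma: float
    reps: int

    def mean(self, n: int, length: int | None = None) -> float:
        """Null mean at period n; linearly rescaled for a nearby length.

        Null mF_max is close to proportional to sequence length at fixed
        period, so small length deviations (indel jitter around a design
        length) are handled by scaling the mean rather than re-estimating
        the curve.
        """
        m = self.means[self.periods.index(n)]
        if length is not None and length != self.length:
            m *= length / self.length
        return m

    def z(self, n: int, score: float, length: int | None = None) -> float:
        return (score - self.mean(n, length)) / self.sigma


def null_spectrum_curve(
    length: int,
    periods,
    ga_cfg: GAConfig | None = None,
    gaps: GapParams | None = None,
    reps: int = 8,
    composition=None,
    seed: int = 0,
) -> NullSpectrumCurve:
    """Estimate the null curve from ``reps`` random windows of ``length``."""
    if reps < 2:
        raise ValueError("need at least 2 replicate windows")
    ga_cfg = ga_cfg or GAConfig()
    periods = tuple(int(n) for n in periods)
    vals = np.zeros((reps, len(periods)))
    ss = np.random.SeedSequence([int(seed) % (2**31), 31337, length])
    for r, child in enumerate(ss.spawn(reps)):
        s = int(child.generate_state(1)[0] % (2**31))
        S = random_sequence(length, np.random.default_rng(s), composition)
        for j, n in enumerate(periods):
            vals[r, j] = ga_optimize(S, n, replace(ga_cfg, seed=s), gaps).mF_max
    sigma = float(np.mean(vals.std(axis=0, ddof=1)))
    return NullSpectrumCurve(
        length=length,
        periods=periods,
        means=tuple(float(m) for m in vals.mean(axis=0)),
        sigma=max(sigma, 1e-9),
        reps=reps,
    )


@dataclass(frozen=True)
class ThresholdCalibration:
    """Empirical family-wise null calibration for a window/period design."""

    F0: float  # raw-score threshold (max over periods)
    Z0: float  # standardized threshold (max over periods of z)
    target_fpr: float
    window_length: int
    periods: tuple[int, ...]
    null_scores: tuple[float, ...]  # per-window max mF_max
    null_zmax: tuple[float, ...]  # per-window max z
    curve: NullSpectrumCurve

    def exceedance(self, x: float, standardized: bool = False) -> float:
        vals = self.null_zmax if standardized else self.null_scores
        return float(np.mean([v >= x for v in vals]))


def _upper_quantile(values: np.ndarray, target_fpr: float) -> float:
    """Smallest observed value whose >=-exceedance on the sample is <= target."""
    vals = np.sort(values)[::-1]
    m = len(vals)
    k = int(np.floor(target_fpr * m))  # allowed exceedances
    for i in range(min(k, m - 1), -1, -1):
        cand = vals[i]
        if np.sum(values >= cand) <= target_fpr * m:
            return float(cand)
    return float(vals[0] + 1e-9)


def calibrate_threshold(
    window_length: int = 600,
    n_windows: int = 100,
    n_values=range(2, 51),
    target_fpr: float = 0.05,
    ga_cfg: GAConfig | None = None,
    gaps: GapParams | None = None,
    composition=None,
    curve: NullSpectrumCurve | None = None,
    curve_reps: int = 8,
    seed: int = 0,
) -> ThresholdCalibration:
    """Calibrate family-wise detection thresholds on simulated null windows.

    A null window counts as a false positive if its maximum over all tested
    periods exceeds the threshold — matching how real windows are scored.
    Returns both the raw-score threshold F0 and the standardized-threshold
    Z0, each the empirical (1 - target_fpr) quantile of the calibration
    batch.
    """
    if not 0.0 < target_fpr < 1.0:
        raise ValueError("target_fpr must be in (0, 1)")
    if n_windows < 20:
        raise ValueError("need at least 20 calibration windows")
    ga_cfg = ga_cfg or GAConfig()
    periods = tuple(int(n) for n in n_values)
    if curve is None:
        curve = null_spectrum_curve(
            window_length, periods, ga_cfg, gaps, reps=curve_reps,
            composition=composition, seed=seed + 1,
        )
    maxima = np.zeros(n_windows)
    zmaxima = np.zeros(n_windows)
    ss = np.random.SeedSequence([int(seed) % (2**31), 424242])
    for w, child in enumerate(ss.spawn(n_windows)):
        s = int(child.generate_state(1)[0] % (2**31))
        S = random_sequence(window_length, np.random.default_rng(s), composition)
        scores = {
            n: ga_optimize(S, n, replace(ga_cfg, seed=s), gaps).mF_max for n in periods
        }
        maxima[w] = max(scores.values())
        zmaxima[w] = max(curve.z(n, f) for n, f in scores.items())
    return ThresholdCalibration(
        F0=_upper_quantile(maxima, target_fpr),
        Z0=_upper_quantile(zmaxima, target_fpr),
        target_fpr=target_fpr,
        window_length=window_length,
        periods=periods,
        null_scores=tuple(float(x) for x in maxima),
        null_zmax=tuple(float(x) for x in zmaxima),
        curve=curve,
    )
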