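"""Information distance between frequency matrices and cross-set uniqueness.

Two detected periodicities are compared through their 4 x n frequency
matrices with an information-theoretic distance: per period position the
G-statistic of the 2 x 4 (matrix x base) contingency table, summed over
positions,

    I(F_k, F_l) = sum_ij f_k ln f_k + sum_ij f_l ln f_l
                - sum_ij (f_k + f_l) ln(f_k + f_l)
                + sum_j [(s_k(j)+s_l(j)) ln(s_k(j)+s_l(j))
                         - s_k(j) ln s_k(j) - s_l(j) ln s_l(j)]

with 0 ln 0 = 0 and s(j) the column sums.  For matrices built by
distributing a fixed base composition over columns (which is what shuffling
the underlying sequence does), 2I is asymptotically chi-square with
df = 3(n-1), and the root transform

    X = sqrt(4 I) - sqrt(2 df - 1)

is approximately N(0, 1) — the classic sqrt(2 chi2) normal approximation.

Uniqueness protocol: for every matrix k of set A take the minimum X over
all same-period matrices of set B (phase-free: minimized over cyclic column
shifts).  The survival curve F_k(x) of these minima is compared with the
curve Fr_k(x) from shuffled-matrix nulls; the smallest x where
F_k/Fr_k exceeds a ratio (default 20, i.e. < 5% false positives) defines
the count of repeats unique to A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .matrices import FrequencyMatrix


@dataclass(frozen=True)
class DistanceResult:
    I: float  # nats
    df: int
    X: float


@dataclass(frozen=True)
class UniquenessReport:
    x_min: np.ndarray  # per-A-matrix minimum X
    null_x_min: np.ndarray
    grid: np.ndarray
    survival: np.ndarray  # F_k on grid
    null_survival: np.ndarray  # Fr_k on grid
    x0: float | None
    unique_count: int
    ratio: float
    threshold_found: bool
    skipped: int = 0  # A-matrices with no same-period partner in B


def _info(fk: np.ndarray, fl: np.ndarray) -> float:
    sk = fk.sum(axis=0)
    sl = fl.sum(axis=0)
    both = fk + fl
    val = (
        np.sum(xlogy(fk, fk))
        + np.sum(xlogy(fl, fl))
        - np.sum(xlogy(both, both))
        + np.sum(xlogy(sk + sl, sk + sl) - xlogy(sk, sk) - xlogy(sl, sl))
    )
    return float(max(val, 0.0))


def matrix_distance(F_k: FrequencyMatrix, F_l: FrequencyMatrix) -> float:
    """Information distance I between two equal-period frequency matrices."""
    if F_k.n != F_l.n:
        raise ValueError(f"period mismatch: {F_k.n} vs {F_l.n}")
    return _info(F_k.counts, F_l.counts)


def distance_to_normal(I: float, n: int) -> DistanceResult:
    """Normal-scale transform of the distance at period n (df = 3(n-1))."""
    if n < 2:
        raise ValueError("period must be >= 2")
    if I < 0:
        raise ValueError("I must be non-negative")
    df = 3 * (n - 1)
    X = float(np.sqrt(4.0 * I) - np.sqrt(2.0 * df - 1.0))
    return DistanceResult(I=I, df=df, X=X)


def matrix_distance_normal(
    F_k: FrequencyMatrix, F_l: FrequencyMatrix, cyclic: bool = True
) -> DistanceResult:
    """X between two matrices; if ``cyclic``, minimized over column shifts.

    Periods have arbitrary phase, so the distance between two detections of
    the same repeat family is taken at the best cyclic alignment of their
    columns.
    """
    if F_k.n != F_l.n:
        raise ValueError(f"period mismatch: {F_k.n} vs {F_l.n}")
    shifts = range(F_k.n) if cyclic else (0,)
    best = min(_info(F_k.counts, np.roll(F_l.counts, s, axis=1)) for s in shifts)
    return distance_to_normal(best, F_k.n)


def permutation_null_matrix(F: FrequencyMatrix, rng: np.random.Generator) -> FrequencyMatrix:
    """A shuffled-sequence analogue of ``F``.

    The matrix's residues (its total base composition) are randomly
    redistributed over its period positions, preserving the column sums —
    exactly the matrix a randomly mixed source sequence would give.
    """
    comp = np.rint(F.counts.sum(axis=1)).astype(int)
    cols = np.rint(F.column_sums).astype(int)
    residues = np.repeat(np.arange(4), comp)
    rng.shuffle(residues)
    out = np.zeros((4, F.n))
    start = 0
    for j, c in enumerate(cols):
        chunk = residues[start : start + c]
        out[:, j] = np.bincount(chunk, minlength=4)
        start += c
    return FrequencyMatrix(out)


def _min_x(
    A: list[FrequencyMatrix], B: list[FrequencyMatrix], cyclic: bool
) -> tuple[np.ndarray, int]:
    by_n: dict[int, list[FrequencyMatrix]] = {}
    for f in B:
        by_n.setdefault(f.n, []).append(f)
    mins: list[float] = []
    skipped = 0
    for fk in A:
        partners = by_n.get(fk.n)
        if not partners:
            skipped += 1
            continue
        mins.append(
            min(matrix_distance_normal(fk, fl, cyclic=cyclic).X for fl in partners)
        )
    return np.array(mins), skipped


def unique_repeat_count(
    matrices_A: list[FrequencyMatrix],
    matrices_B: list[FrequencyMatrix],
    null_A: list[FrequencyMatrix] | None = None,
    null_B: list[FrequencyMatrix] | None = None,
    ratio: float = 20.0,
    cyclic: bool = True,
    bin_width: float = 0.05,
    seed: int = 0,
) -> UniquenessReport:
    """Count repeats of set A absent from set B.

    ``null_A``/``null_B`` default to permutation nulls of the real matrices
    (one shuffled matrix per real matrix, seeded).
    """
    if not matrices_A or not matrices_B:
        raise ValueError("both matrix sets must be non-empty")
    rng = np.random.default_rng(seed)
    if null_A is None:
        null_A = [permutation_null_matrix(f, rng) for f in matrices_A]
    if null_B is None:
        null_B = [permutation_null_matrix(f, rng) for f in matrices_B]
    x_min, skipped = _min_x(matrices_A, matrices_B, cyclic)
    null_x_min, _ = _min_x(null_A, null_B, cyclic)
    if x_min.size == 0:
        raise ValueError("no comparable (same-period) matrix pairs")
    lo = min(x_min.min(), null_x_min.min())
    hi = max(x_min.max(), null_x_min.max())
    grid = np.arange(np.floor(lo / bin_width) * bin_width, hi + bin_width, bin_width)
    surv = np.array([(x_min > x).sum() for x in grid], dtype=float)
    null_surv = np.array([(null_x_min > x).sum() for x in grid], dtype=float)
    x0 = None
    unique = 0
    found = False
    for x, f, fr in zip(grid, surv, null_surv):
        ok = (fr == 0 and f > 0) or (fr > 0 and f / fr > ratio)
        if ok:
            x0 = float(x)
            unique = int(f)
            found = True
            break
    return UniquenessReport(
        x_min=x_min,
        null_x_min=null_x_min,
        grid=grid,
        survival=surv,
        null_survival=null_surv,
        x0=x0,
        unique_count=unique,
        ratio=ratio,
        threshold_found=found,
        skipped=skipped,
    )
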