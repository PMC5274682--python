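"""Position weight matrices and frequency matrices.

A :class:`WeightMatrix` is the scoring profile of a candidate periodicity:
4 rows (bases A, C, G, T) by ``n`` columns (period positions).  Weight
matrices are kept on a fixed scale — every column has mean 0 and population
variance 1 across the four base weights — so that alignment scores of
different matrices, periods and sequences are directly comparable and the
expected per-base score on a uniform random sequence is 0.

A :class:`FrequencyMatrix` holds the base counts per period position
tallied from a detected region's alignment; it is the input both to the
consensus caller and to the between-matrix information distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class WeightMatrix:
    """4 x n real scoring matrix; the genetic algorithm's "organism"."""

    weights: np.ndarray  # shape (4, n)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4 or w.shape[1] < 2:
            raise ValueError(f"weight matrix must be 4 x n with n >= 2, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weight matrix contains non-finite entries")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[1]

    def is_normalized(self, tol: float = 1e-9) -> bool:
        w = self.weights
        mean = w.mean(axis=0)
        var = w.var(axis=0)
        ok = (np.abs(mean) <= tol) & (np.abs(var - 1.0) <= tol)
        zero = np.all(np.abs(w) <= tol, axis=0)
        return bool(np.all(ok | zero))


@dataclass(frozen=True)
class FrequencyMatrix:
    """4 x n non-negative base counts per period position."""

    counts: np.ndarray  # shape (4, n)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError(f"frequency matrix must be 4 x n, got {c.shape}")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("frequency matrix counts must be finite and non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    @property
    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def normalize_weight_matrix(M: WeightMatrix) -> WeightMatrix:
    """Rescale each column to mean 0 / population variance 1.

    Columns whose four weights are all equal carry no preference and are
    mapped to all-zero columns.  Idempotent.
    """
    w = np.asarray(M.weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weight matrix contains non-finite entries")
    mean = w.mean(axis=0)
    std = w.std(axis=0)  # population (ddof=0)
    out = np.zeros_like(w)
    live = std > _NORM_TOL
    out[:, live] = (w[:, live] - mean[live]) / std[live]
    return WeightMatrix(out)


def random_weight_matrix(n: int, rng: np.random.Generator) -> WeightMatrix:
    """A random normalized 4 x n matrix (standard-normal entries, normalized)."""
    return normalize_weight_matrix(WeightMatrix(rng.standard_normal((4, n))))


def weight_matrix_from_frequency(F: FrequencyMatrix, pseudocount: float = 0.5) -> WeightMatrix:
    """Log-odds-style weights from counts, then column-normalized."""
    c = F.counts + pseudocount
    return normalize_weight_matrix(WeightMatrix(np.log(c / c.sum(axis=0))))


def consensus_from_matrix(F: FrequencyMatrix, two_base_fraction: float = 1.0 / 3.0) -> str:
    """Call the period consensus from a frequency matrix.

    Per column the majority base is emitted; when the runner-up base exceeds
    ``two_base_fraction`` of the column total the two-base ambiguity form
    ``(X/Y)`` is emitted, majority base first.  Zero-count columns yield "N".
    """
    parts: list[str] = []
    for j in range(F.n):
        col = F.counts[:, j]
        s = col.sum()
        if s <= 0:
            parts.append("N")
            continue
        order = np.argsort(-col, kind="stable")
        top, second = order[0], order[1]
        if col[second] > two_base_fraction * s:
            parts.append(f"({BASES[top]}/{BASES[second]})")
        else:
            parts.append(BASES[top])
    return "".join(parts)
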