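"""Triplet-periodicity filter.

Protein-coding DNA carries strong period-3 structure (codon bias), which a
tandem-repeat scanner must not mistake for a repeat.  The filter measures
the mutual information I (in nats) between base identity and position
modulo 3 in a window.  Under the no-triplet-structure null, 2NI is
asymptotically chi-square with df = (4-1)(3-1) = 6, so

    Z = (2NI - 6) / sqrt(12)

is on a standard-normal-like scale; windows with Z above a threshold
(default 3.0) are skipped by the genome scanner as likely coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .sequence import NucleotideSequence

DF = 6


@dataclass(frozen=True)
class TripletStats:
    counts: np.ndarray  # 4 bases x 3 frame positions
    information: float  # nats
    z: float

    @property
    def n_counted(self) -> int:
        return int(self.counts.sum())


def triplet_z(S: NucleotideSequence, min_length: int = 30) -> TripletStats:
    """Triplet-periodicity statistics of a window.

    Frames are counted from the window's first base; ``N`` bases are
    excluded from the table.  Mutual information is frame-shift invariant,
    so no reading-frame search is needed.
    """
    if len(S) < min_length:
        raise ValueError(f"window of {len(S)} nt is shorter than {min_length}")
    codes = S.codes
    counts = np.zeros((4, 3))
    for frame in range(3):
        sub = codes[frame::3]
        sub = sub[sub < 4]
        counts[:, frame] = np.bincount(sub, minlength=4)
    N = counts.sum()
    if N == 0:
        raise ValueError("window contains no A/C/G/T bases")
    p = counts / N
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    info = float(np.sum(xlogy(p, p)) - np.sum(xlogy(pi, pi)) - np.sum(xlogy(pj, pj)))
    info = max(info, 0.0)
    z = (2.0 * N * info - DF) / np.sqrt(2.0 * DF)
    return TripletStats(counts=counts, information=info, z=float(z))
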