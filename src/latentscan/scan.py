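"""Genome scanning protocol.

Sliding 600-nt windows stepped by 200 bp are screened for periodicity:
windows with significant triplet periodicity (likely protein-coding) are
skipped; in every other window the GA optimizes a weight matrix for each
tested period length, giving the spectrum mF_max(n).  The detected period
of a window is the most significant one — argmax of the standardized
spectrum when a null curve is available, raw argmax otherwise.  Windows
passing the detection threshold become candidate regions (the alignment
span, not the whole window); intersecting candidates are resolved by
keeping the higher-scoring one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from .align import GapParams, PeriodicAlignment
from .ga import GAConfig, PeriodicitySpectrum
from .matrices import FrequencyMatrix, WeightMatrix, consensus_from_matrix
from .sequence import NucleotideSequence
from .significance import NullSpectrumCurve, null_spectrum_curve
from .triplet import triplet_z

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    window: int = 600
    step: int = 200
    n_min: int = 2
    n_max: int = 50
    periods: tuple[int, ...] | None = None  # explicit period grid; overrides n_min..n_max
    F0: float = 390.0  # raw-score threshold
    Z0: float | None = None  # standardized threshold; enables z-mode when set
    z_skip: float = 3.0  # triplet-periodicity skip level
    ga: GAConfig = field(default_factory=GAConfig)
    gaps: GapParams = field(default_factory=GapParams)
    curve_reps: int = 8
    refine_period: bool = True  # two-stage period call for emitted windows (z-mode)

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if not 2 <= self.n_min <= self.n_max:
            raise ValueError("need 2 <= n_min <= n_max")

    @property
    def period_grid(self) -> tuple[int, ...]:
        if self.periods is not None:
            return tuple(int(n) for n in self.periods)
        return tuple(range(self.n_min, self.n_max + 1))


@dataclass(frozen=True)
class PeriodicRegion:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    n: int
    mF_max: float
    triplet_Z: float
    matrix: WeightMatrix
    freq: FrequencyMatrix
    consensus: str
    alignment: PeriodicAlignment
    z: float | None = None  # standardized score, when a null curve was used

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ComparisonCounts:
    matched_A: int
    total_A: int
    matched_B: int
    total_B: int
    min_overlap_fraction: float


def iter_windows(S: NucleotideSequence, cfg: ScanConfig) -> list[tuple[int, int]]:
    """Full-length 1-based inclusive windows: starts 1, 1+step, ..."""
    N = len(S)
    if N < cfg.window:
        return []
    count = (N - cfg.window) // cfg.step + 1
    return [(1 + k * cfg.step, cfg.window + k * cfg.step) for k in range(count)]


def frequency_matrix_from_alignment(alignment: PeriodicAlignment, n: int) -> FrequencyMatrix:
    """Tally matched bases per period column; indel steps contribute nothing."""
    counts = np.zeros((4, n))
    for step in alignment.path:
        if step[0] == "M" and step[3] < 4:
            counts[step[3], step[2] - 1] += 1
    return FrequencyMatrix(counts)


def frequency_matrix_from_region(region: PeriodicRegion) -> FrequencyMatrix:
    return frequency_matrix_from_alignment(region.alignment, region.n)


def _window_region(
    seq_id: str,
    win_start: int,
    spectrum: PeriodicitySpectrum,
    best_n: int,
    z: float | None,
    trip_z: float,
) -> PeriodicRegion:
    res = spectrum.entries[best_n]
    aln = res.alignment
    freq = frequency_matrix_from_alignment(aln, best_n)
    return PeriodicRegion(
        seq_id=seq_id,
        start=win_start + aln.seq_start - 1,
        end=win_start + aln.seq_end - 1,
        n=best_n,
        mF_max=res.mF_max,
        triplet_Z=trip_z,
        matrix=res.best_matrix,
        freq=freq,
        consensus=consensus_from_matrix(freq),
        alignment=aln,
        z=z,
    )


def scan(
    sequences: list[NucleotideSequence],
    cfg: ScanConfig | None = None,
    curve: NullSpectrumCurve | None = None,
) -> list[PeriodicRegion]:
    """Run the scanning protocol over a set of sequences.

    In z-mode (``cfg.Z0`` set) the detected period is the argmax of the
    standardized spectrum and the threshold applies to that z value; the
    null curve is estimated from ``cfg.curve_reps`` random windows if not
    supplied.  Otherwise the raw spectrum argmax is thresholded at
    ``cfg.F0``.
    """
    cfg = cfg or ScanConfig()
    periods = cfg.period_grid
    use_z = cfg.Z0 is not None
    if use_z and curve is None:
        curve = null_spectrum_curve(
            cfg.window, periods, cfg.ga, cfg.gaps,
            reps=cfg.curve_reps, seed=cfg.ga.seed + 99,
        )
    candidates: list[PeriodicRegion] = []
    for ri, S in enumerate(sequences):
        if len(S) == 0:
            logger.warning("skipping zero-length record %s", S.id)
            continue
        for wi, (ws, we) in enumerate(iter_windows(S, cfg)):
            window = S.subsequence(ws, we)
            try:
                trip = triplet_z(window)
            except ValueError:
                continue  # all-N window
            if trip.z > cfg.z_skip:
                continue
            wseed = int(
                np.random.SeedSequence(
                    [int(cfg.ga.seed) % (2**31), ri, wi]
                ).generate_state(1)[0]
                % (2**31)
            )
            spectrum = periodicity_spectrum_grid(
                window, periods, replace(cfg.ga, seed=wseed), cfg.gaps
            )
            if not spectrum.entries:
                continue
            if use_z:
                zs = {n: curve.z(n, spectrum.mF_max(n)) for n in spectrum.periods}
                best_n = max(zs, key=lambda n: (zs[n], -n))
                if zs[best_n] < cfg.Z0:
                    continue
                if cfg.refine_period:
                    best_n, zs = refine_period_call(
                        window, spectrum, curve,
                        replace(cfg.ga, seed=wseed), cfg.gaps,
                    )
                z = zs[best_n]
            else:
                best_n = spectrum.argmax
                if spectrum.mF_max(best_n) < cfg.F0:
                    continue
                z = None
            if spectrum.entries[best_n].alignment.span == 0:
                continue
            candidates.append(
                _window_region(S.id, ws, spectrum, best_n, z, trip.z)
            )
    return merge_overlapping(candidates)


def periodicity_spectrum_grid(
    S: NucleotideSequence,
    periods,
    ga_cfg: GAConfig,
    gaps: GapParams,
) -> PeriodicitySpectrum:
    """Spectrum over an explicit period grid (not necessarily contiguous)."""
    from .ga import ga_optimize

    entries = {}
    failures = {}
    for n in periods:
        try:
            entries[n] = ga_optimize(S, n, ga_cfg, gaps)
        except ValueError as exc:
            failures[n] = str(exc)
    return PeriodicitySpectrum(entries=entries, failures=failures)


def refine_period_call(
    S: NucleotideSequence,
    spectrum: PeriodicitySpectrum,
    curve,
    ga_cfg: GAConfig,
    gaps: GapParams,
    refine_top: int = 4,
    refine_shuffles: int = 8,
    decisive_margin: float = 3.0,
) -> tuple[int, dict[int, float]]:
    """Two-stage period call for a sequence with a computed spectrum.

    Stage 1 standardizes against the uniform-composition null curve.  A
    compositionally skewed sequence beats that curve at *every* period,
    which can spuriously favour small periods; so unless the stage-1 leader
    is decisive (margin over the runner-up >= ``decisive_margin``), the
    leading candidates are re-standardized against the composition-
    preserving null — the mean mF_max of seeded shuffles of S itself at
    each candidate period, keeping the pooled curve sigma.  Returns the
    called period and the z map (stage-2 values where refined).
    """
    from .significance import shuffle_sequence

    zs = {n: curve.z(n, spectrum.mF_max(n), len(S)) for n in spectrum.periods}
    ranked = sorted(zs, key=lambda n: (-zs[n], n))
    leader = ranked[0]
    # harmonics of the leader are the same periodicity, not competitors
    rivals = [n for n in ranked[1:] if leader % n != 0 and n % leader != 0]
    if (
        not refine_top
        or not refine_shuffles
        or not rivals
        or zs[leader] - zs[rivals[0]] >= decisive_margin
    ):
        return leader, zs
    top = ranked[:refine_top]
    ss = np.random.SeedSequence([int(ga_cfg.seed) % (2**31), 555])
    shuffle_seeds = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(refine_shuffles)
    ]
    from .ga import ga_optimize

    for n in top:
        null_scores = [
            ga_optimize(shuffle_sequence(S, seed=s), n, replace(ga_cfg, seed=s), gaps).mF_max
            for s in shuffle_seeds
        ]
        zs[n] = (spectrum.mF_max(n) - float(np.mean(null_scores))) / curve.sigma
    best = max(top, key=lambda n: (zs[n], -n))
    return best, zs


def _sort_key(r: PeriodicRegion):
    rank = r.z if r.z is not None else r.mF_max
    return (-rank, r.start, r.n)


def merge_overlapping(candidates: list[PeriodicRegion]) -> list[PeriodicRegion]:
    """Resolve intersecting candidates greedily by descending score.

    Any coordinate intersection (>= 1 shared base, same seq_id) triggers
    competition; ties break by smaller start, then smaller period.
    """
    kept: list[PeriodicRegion] = []
    trees: dict[str, IntervalTree] = {}
    for r in sorted(candidates, key=_sort_key):
        tree = trees.setdefault(r.seq_id, IntervalTree())
        if not tree.overlap(r.start, r.end + 1):  # half-open query
            tree.addi(r.start, r.end + 1)
            kept.append(r)
    kept.sort(key=lambda r: (r.seq_id, r.start))
    return kept


def overlap_compare(
    set_A: list[PeriodicRegion],
    set_B: list[PeriodicRegion],
    min_fraction: float = 0.3,
) -> ComparisonCounts:
    """Fractional-overlap matching of two region sets, both directions.

    A region is matched if a single region of the other set on the same
    seq_id overlaps it by at least ``min_fraction`` of its own length
    (inclusive); period lengths are ignored.
    """
    ids_a = {r.seq_id for r in set_A}
    ids_b = {r.seq_id for r in set_B}
    if set_A and set_B and not (ids_a & ids_b):
        logger.warning("region sets share no seq_ids; zero matches")

    def count(query, target) -> int:
        trees: dict[str, IntervalTree] = {}
        for r in target:
            trees.setdefault(r.seq_id, IntervalTree()).addi(r.start, r.end + 1)
        matched = 0
        for r in query:
            tree = trees.get(r.seq_id)
            if tree is None:
                continue
            need = min_fraction * r.length
            for iv in tree.overlap(r.start, r.end + 1):
                ov = min(r.end, iv.end - 1) - max(r.start, iv.begin) + 1
                if ov >= need - 1e-9:
                    matched += 1
                    break
        return matched

    return ComparisonCounts(
        matched_A=count(set_A, set_B),
        total_A=len(set_A),
        matched_B=count(set_B, set_A),
        total_B=len(set_B),
        min_overlap_fraction=min_fraction,
    )
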