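"""Period-recovery benchmark on synthetic latent tandem arrays.

The study conditions: tandem arrays degraded by 1.0 substitution events per
nucleotide (Jukes-Cantor rounds, ~55% divergence from consensus) plus 5%
indel events per base, with at least 40 copies of the unit — the latent
regime in which period similarity is pairwise invisible.  Copy numbers are
chosen to give roughly 1.2 kb arrays (more copies for short units), the
scale at which the per-base signal of the consensus exceeds the per-base
noise-fitting capacity of the weight matrix.

A run is counted as a success when the period called from the standardized
spectrum (argmax of z against the null curve) is the true period or an
integer multiple or divisor of it — harmonics of a tandem structure are
genuine periodicities of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .align import GapParams
from .ga import GAConfig
from .scan import periodicity_spectrum_grid
from .sequence import NucleotideSequence
from .significance import NullSpectrumCurve, null_spectrum_curve
from .simulate import ImplantSpec, random_consensus, tandem_array

#: Period grid used for benchmark spectra: dense over the short periods
#: where confusable neighbours live, sparser over long ones.
BENCHMARK_GRID: tuple[int, ...] = tuple(range(2, 14)) + (16, 21, 28, 35, 42, 50)

#: GA budget for benchmark runs: discovery is carried by the EM-polished
#: initialization, so a lean generation budget suffices.
BENCHMARK_GA = GAConfig(
    population_size=24, max_generations=120, plateau_generations=15,
    em_init_starts=12,
)

#: Arrays are sized so the per-base consensus signal (~0.46 score/base at
#: 1.0 substitutions/nt) clears the per-base noise-fitting capacity of the
#: matrix with a workable z margin; the margin grows linearly with array
#: length while the null sd stays flat.
TARGET_ARRAY_LENGTH = 1800  # nt; copies = max(40, round(length / period))


def benchmark_copies(period: int, min_copies: int = 40, target_length: int = TARGET_ARRAY_LENGTH) -> int:
    return max(min_copies, int(round(target_length / period)))


@dataclass(frozen=True)
class RecoveryRun:
    period: int
    seed: int
    called_period: int
    z_called: float
    z_true: float
    success: bool
    array_length: int


@dataclass(frozen=True)
class RecoveryResult:
    runs: tuple[RecoveryRun, ...]

    @property
    def rate(self) -> float:
        return float(np.mean([r.success for r in self.runs]))

    def rate_for(self, period: int) -> float:
        rs = [r.success for r in self.runs if r.period == period]
        return float(np.mean(rs)) if rs else float("nan")


def is_harmonic(called: int, true: int) -> bool:
    return called % true == 0 or true % called == 0


def call_period(
    S: NucleotideSequence,
    curve: NullSpectrumCurve,
    grid=BENCHMARK_GRID,
    ga_cfg: GAConfig = BENCHMARK_GA,
    gaps: GapParams | None = None,
    refine_top: int = 0,
    refine_shuffles: int = 0,
    decisive_margin: float = 3.0,
) -> tuple[int, dict[int, float]]:
    """Most significant period of S: argmax of the standardized spectrum.

    By default this is the plain stage-1 call (z against the null curve);
    passing ``refine_top``/``refine_shuffles`` enables the two-stage
    shuffle-refined call of :func:`latentscan.scan.refine_period_call`.
    """
    from .scan import refine_period_call

    gaps = gaps or GapParams()
    spectrum = periodicity_spectrum_grid(S, grid, ga_cfg, gaps)
    return refine_period_call(
        S, spectrum, curve, ga_cfg, gaps,
        refine_top=refine_top,
        refine_shuffles=refine_shuffles,
        decisive_margin=decisive_margin,
    )


def recovery_benchmark(
    periods_with_reps: list[tuple[int, int]],
    seed: int = 0,
    grid=BENCHMARK_GRID,
    ga_cfg: GAConfig = BENCHMARK_GA,
    substitution_rate: float = 1.0,
    indel_rate: float = 0.05,
    curve_reps: int = 8,
) -> RecoveryResult:
    """Run the recovery benchmark.

    ``periods_with_reps``: list of (true period, number of seeded runs).
    Null curves are estimated per distinct array length with the same GA
    protocol as the signal runs.
    """
    gaps = GapParams()
    rng = np.random.default_rng(seed)
    curves: dict[int, NullSpectrumCurve] = {}

    def curve_for(length: int) -> NullSpectrumCurve:
        # bucket lengths to the nearest 200 nt; the curve's length scaling
        # absorbs the residual mismatch
        key = int(round(length / 200.0) * 200)
        if key not in curves:
            curves[key] = null_spectrum_curve(
                key, grid, ga_cfg, gaps, reps=curve_reps, seed=seed + key,
            )
        return curves[key]

    runs: list[RecoveryRun] = []
    for period, reps in periods_with_reps:
        copies = benchmark_copies(period)
        for k in range(reps):
            run_seed = int(rng.integers(0, 2**31))
            spec = ImplantSpec(
                consensus=random_consensus(period, np.random.default_rng(run_seed)),
                copies=copies,
                substitution_rate=substitution_rate,
                indel_rate=indel_rate,
                background_length=period * copies + 10,
                seed=run_seed,
            )
            S = tandem_array(spec)
            curve = curve_for(len(S))
            called, zs = call_period(
                S, curve, grid, replace(ga_cfg, seed=run_seed), gaps,
                refine_top=4, refine_shuffles=8,
            )
            runs.append(
                RecoveryRun(
                    period=period,
                    seed=run_seed,
                    called_period=called,
                    z_called=zs[called],
                    z_true=zs[period],
                    success=is_harmonic(called, period),
                    array_length=len(S),
                )
            )
    return RecoveryResult(runs=tuple(runs))
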