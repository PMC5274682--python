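"""Genetic-algorithm optimization of the period weight matrix.

For a fixed period length ``n`` the GA searches the space of normalized
4 x n weight matrices for the one whose cyclic-profile local alignment
against the sequence scores highest (mF_max).  Organisms are matrices;
fitness is the alignment score; selection is elitist; crossover exchanges a
column block between two parents; mutation perturbs cells with Gaussian
noise, after which children are re-normalized so all fitness values stay on
one scale.  The run stops when the best fitness has not improved for a
plateau of generations, or at the generation cap.

Repeating the optimization for every period length in a range yields the
periodicity spectrum mF_max(n), whose argmax is the detected period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import EMPTY_ALIGNMENT, GapParams, PeriodicAlignment, local_align_periodic
from .matrices import WeightMatrix, normalize_weight_matrix, random_weight_matrix
from .sequence import NucleotideSequence


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    elite_fraction: float = 0.1
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05  # per matrix cell
    mutation_sigma: float = 0.5
    plateau_generations: int = 30
    max_generations: int = 500
    refine_every: int = 10  # generations between alignment-refinement injections; 0 disables
    em_init_starts: int = 8  # initial organisms polished by alternating refinement; 0 disables
    em_init_iters: int = 12  # refinement iterations per polished start
    restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must be in (0, 1)")
        if self.plateau_generations < 1:
            raise ValueError("plateau_generations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass(frozen=True)
class OptimizationResult:
    n: int
    best_matrix: WeightMatrix
    mF_max: float
    alignment: PeriodicAlignment
    fitness_trace: tuple[float, ...]
    generations_run: int


@dataclass(frozen=True)
class PeriodicitySpectrum:
    """mF_max(n) over a range of period lengths."""

    entries: dict[int, OptimizationResult]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def periods(self) -> list[int]:
        return sorted(self.entries)

    def mF_max(self, n: int) -> float:
        return self.entries[n].mF_max

    @property
    def argmax(self) -> int:
        """Period with the largest mF_max (smallest period on exact ties)."""
        return max(self.periods, key=lambda n: (self.entries[n].mF_max, -n))

    @property
    def max(self) -> float:
        return self.entries[self.argmax].mF_max

    @property
    def best(self) -> OptimizationResult:
        return self.entries[self.argmax]


def _refined(S: NucleotideSequence, matrix: np.ndarray, gaps: GapParams) -> np.ndarray | None:
    """Log-odds matrix from the frequency counts of the best-matrix alignment.

    Alternating matrix -> alignment -> matrix refinement: given an alignment,
    the per-column base frequencies point at the locally optimal profile.
    """
    from .matrices import weight_matrix_from_frequency
    from .scan import frequency_matrix_from_alignment

    aln = local_align_periodic(S, WeightMatrix(matrix), gaps)
    if not aln.path:
        return None
    freq = frequency_matrix_from_alignment(aln, matrix.shape[1])
    if freq.total == 0:
        return None
    return weight_matrix_from_frequency(freq).weights


def _evolve(
    S: NucleotideSequence,
    n: int,
    cfg: GAConfig,
    gaps: GapParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[float], int]:
    codes = S.codes
    go, ge = float(gaps.gap_open), float(gaps.gap_extend)

    from .align import _score_kernel

    def fitness(w: np.ndarray) -> float:
        return float(_score_kernel(codes, w, go, ge))

    def polish(w: np.ndarray) -> np.ndarray:
        """Alternating matrix/alignment refinement until the score plateaus."""
        sc = fitness(w)
        for _ in range(cfg.em_init_iters):
            w2 = _refined(S, w, gaps)
            if w2 is None:
                break
            sc2 = fitness(w2)
            if sc2 <= sc + 1e-6:
                break
            w, sc = w2, sc2
        return w

    n_polished = min(cfg.em_init_starts, cfg.population_size)
    pop = [polish(random_weight_matrix(n, rng).weights) for _ in range(n_polished)]
    pop += [
        random_weight_matrix(n, rng).weights
        for _ in range(cfg.population_size - n_polished)
    ]
    fits = np.array([fitness(w) for w in pop])
    n_elite = max(1, int(round(cfg.elite_fraction * cfg.population_size)))
    best_w = pop[int(np.argmax(fits))].copy()
    best_f = float(fits.max())
    trace = [best_f]
    stale = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        order = np.argsort(-fits, kind="stable")
        elites = [pop[i] for i in order[:n_elite]]
        children: list[np.ndarray] = []
        # parents drawn from the better half
        half = max(2, cfg.population_size // 2)
        pool = [pop[i] for i in order[:half]]
        while len(children) < cfg.population_size - n_elite:
            pa, pb = rng.integers(0, len(pool), size=2)
            a = pool[pa].copy()
            if rng.random() < cfg.crossover_rate and n >= 2:
                cut = int(rng.integers(1, n))
                child = np.concatenate([a[:, :cut], pool[pb][:, cut:]], axis=1)
            else:
                child = a
            mask = rng.random(child.shape) < cfg.mutation_rate
            if mask.any():
                child = child + mask * rng.normal(0.0, cfg.mutation_sigma, size=child.shape)
            child = normalize_weight_matrix(WeightMatrix(child)).weights
            children.append(child)
        if cfg.refine_every and gen % cfg.refine_every == 0:
            ref = _refined(S, best_w, gaps)
            if ref is not None:
                children[-1] = ref
        pop = elites + children
        fits = np.array(
            [fits[order[i]] for i in range(n_elite)] + [fitness(w) for w in children]
        )
        gen_best = float(fits.max())
        if gen_best > best_f + 1e-9:
            best_f = gen_best
            best_w = pop[int(np.argmax(fits))].copy()
            stale = 0
        else:
            stale += 1
        trace.append(best_f)
        if stale >= cfg.plateau_generations:
            break
    return best_w, best_f, trace, gen


def ga_optimize(
    S: NucleotideSequence,
    n: int,
    cfg: GAConfig | None = None,
    gaps: GapParams | None = None,
) -> OptimizationResult:
    """Optimize the weight matrix for period ``n`` on sequence ``S``."""
    cfg = cfg or GAConfig()
    gaps = gaps or GapParams()
    if not 2 <= n <= min(100, len(S)):
        raise ValueError(f"period {n} outside [2, min(100, |S|={len(S)})]")
    if set(S.residues) <= {"N"}:
        return OptimizationResult(
            n, random_weight_matrix(n, np.random.default_rng(cfg.seed)), 0.0,
            EMPTY_ALIGNMENT, (0.0,), 0,
        )
    ss = np.random.SeedSequence([int(cfg.seed) % (2**31), n])
    best: tuple[np.ndarray, float, list[float], int] | None = None
    for child in ss.spawn(cfg.restarts):
        cand = _evolve(S, n, cfg, gaps, np.random.default_rng(child))
        if best is None or cand[1] > best[1]:
            best = cand
    best_w, best_f, trace, gens = best
    matrix = WeightMatrix(best_w)
    alignment = local_align_periodic(S, matrix, gaps) if best_f > 0 else EMPTY_ALIGNMENT
    return OptimizationResult(
        n=n,
        best_matrix=matrix,
        mF_max=float(best_f),
        alignment=alignment,
        fitness_trace=tuple(trace),
        generations_run=gens,
    )


def periodicity_spectrum(
    S: NucleotideSequence,
    n_min: int = 2,
    n_max: int = 50,
    cfg: GAConfig | None = None,
    gaps: GapParams | None = None,
) -> PeriodicitySpectrum:
    """Independent, seeded GA run per period length in [n_min, n_max]."""
    cfg = cfg or GAConfig()
    if not 2 <= n_min <= n_max:
        raise ValueError("need 2 <= n_min <= n_max")
    entries: dict[int, OptimizationResult] = {}
    failures: dict[int, str] = {}
    for n in range(n_min, n_max + 1):
        try:
            entries[n] = ga_optimize(S, n, cfg, gaps)
        except ValueError as exc:
            failures[n] = str(exc)
    return PeriodicitySpectrum(entries=entries, failures=failures)
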