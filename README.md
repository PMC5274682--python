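# latentscan

Detection of **latent periodicity** in DNA: tandem repeats that have
accumulated more than ~1 substitution per nucleotide *plus* insertions and
deletions, so that no two periods show statistically significant pairwise
similarity.  Seed-based repeat finders (TRF-style) and spectral methods
(Fourier, wavelets) both fail in this regime — the former for lack of
conserved seeds, the latter because indels destroy phase.  latentscan is for
genome analysts who want to find and compare such diverged tandem arrays.

## Method

A candidate periodicity of length *n* is a position weight matrix
*M* ∈ ℝ^{4×n} with column-standardized weights *m(i, j)* (mean 0, variance 1
per column).  A sequence *S* is scored by the maximum-weight **local
alignment of *S* against the cyclic profile** of *M* — equivalently against
the artificial periodic index sequence 1, 2, …, *n*, 1, 2, … — via a
Smith–Waterman-style dynamic program with affine gaps (open 4.0, extend
1.0), so indels inside the repeat are first-class alignment steps.

For each period *n* a **genetic algorithm** (organisms = matrices, fitness =
alignment score, elitist selection, column-block crossover, Gaussian
mutation, alternating alignment↔matrix refinement) finds the optimal matrix
and its score **mF_max(n)**; the function mF_max(n) over *n* = 2…50 is the
periodicity spectrum.  Because a 4×*n* matrix partially overfits any
sequence, null scores grow with *n*; significance is therefore judged
against shuffle/random-sequence nulls: *z(n)* = (mF_max(n) − μ_null(n)) / σ,
with p-values from the normal model P(F_r > F_max).  The genome scanner
slides 600-nt windows by 200 bp, skips windows with triplet periodicity
Z > 3 (likely protein-coding), thresholds at an empirically calibrated
false-positive level, and resolves intersecting windows by score.

Detected regions are compared across genomes by an information distance
between their 4×*n* frequency matrices (per-column G statistic; 2*I* ~
χ²_{3(n−1)} under the shuffle null; X = √(4I) − √(2·df − 1) ≈ N(0,1)), and
summarized along chromosomes by ΣF_max per 100-kb bin.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Implant a diverged period-10 array (0.8 substitution events/nt — about half
the bases differ from the consensus — plus 5% indels, 120 copies) into
random background and find it again:

```python
import numpy as np
from dataclasses import replace
from latentscan import ImplantSpec, ScanConfig, scan, simulate_latent_periodic
from latentscan.benchmark import BENCHMARK_GA
from latentscan.simulate import random_consensus

spec = ImplantSpec(
    consensus=random_consensus(10, np.random.default_rng(7)),  # TGGTGTTAAC
    copies=120, substitution_rate=0.8, indel_rate=0.05,
    background_length=3600, seed=7,
)
seq, truth = simulate_latent_periodic(spec)
print("implant:", truth.implant_start, truth.implant_end, "period", truth.true_period)

cfg = ScanConfig(periods=(5, 10, 11, 24), Z0=3.0,
                 ga=replace(BENCHMARK_GA, seed=1))
for r in scan([seq], cfg):
    print(f"{r.seq_id}:{r.start}-{r.end} period={r.n} "
          f"mF_max={r.mF_max:.1f} z={r.z:.1f} consensus={r.consensus}")
```

Output:

```
implant: 1135 2333 period 10
synthetic_p10_s7:1001-1600 period=10 mF_max=295.2 z=4.0 consensus=G(T/G)TAACTGGT
synthetic_p10_s7:1601-2200 period=10 mF_max=308.4 z=5.0 consensus=GTTGA(A/C)TG(G/C)T
```

Two non-intersecting regions cover the implant, both call the true period,
and each scores 4-5 null standard deviations above random sequence; the
recovered consensus `GTTAACTGGT` is a cyclic rotation of the implanted unit
`TGGTGTTAAC` (period phase is arbitrary), with `(X/Y)` marking positions
where divergence leaves two strong bases.  The same pipeline is available
from the shell: `latentscan simulate`, `latentscan scan`,
`latentscan spectrum`, `latentscan calibrate`, `latentscan compare-matrices`,
`latentscan compare-regions`, `latentscan profile`, `latentscan triplet`.

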