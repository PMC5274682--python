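# Methods

## Problem and model

A DNA tandem repeat with period `n` that has accumulated more than ~1
substitution per nucleotide plus insertions and deletions ("latent
periodicity") shows no statistically significant similarity between any two
of its periods, so seed- and pairwise-alignment-based repeat finders cannot
see it.  What survives is the *profile* structure: the base composition of
each period position.  latentscan models a candidate periodicity as a 4 x n
position weight matrix `M` with entries m(i, j) (base i, period position j)
and scores a sequence `S` by the maximum-weight local alignment between `S`
and the cyclic period profile — conceptually an alignment against the
artificial index sequence 1, 2, ..., n, 1, 2, ..., with matrix columns as
the "symbols" of the index.  Insertions and deletions are explicit
alignment steps, which is what distinguishes this detector from spectral
(Fourier/wavelet/information-decomposition) methods.

The optimal matrix for a given sequence and period is found by a genetic
algorithm whose organisms are weight matrices and whose fitness is the
alignment score; the optimum is called mF_max(n), and the function
mF_max(n) over a period range is the periodicity spectrum.

## Alignment scoring

The dynamic program is Smith-Waterman-style over the cyclic profile with
affine gaps and a floor at zero:

    M[i,c] = m(S_i, c) + max(0, M[i-1,c-1], I[i-1,c-1], D[i-1,c-1])
    I[i,c] = max(M[i-1,c] - g_open, I[i-1,c] - g_ext)     # base of S inserted
    D[i,c] = max(M[i,c-1] - g_open, D[i,c-1] - g_ext)     # period column skipped

with all column indices modulo n.  Alignments start and end with a match;
insertion and deletion runs are never adjacent.  The within-row cyclic
dependence of D is resolved by two relaxation passes around the circle:
deletion runs of at least n columns (a full cycle at pure cost) can never
improve a maximum, so two passes reach the fixed point.  The traceback
prefers match > deletion > insertion on ties, and the smallest sequence end
position (then smallest column) among equal-scoring end cells, making
results deterministic.

Numerical choices: scores are float64; the local floor uses an exact 0;
path/score consistency is enforced to 1e-6 in tests.  `N` bases score 0
against every column, never start or end an alignment (boundary N matches
are trimmed), and are excluded from frequency-matrix counts.

**Score scale.**  Weight matrices are normalized so every column has mean 0
and population variance 1 over the four base weights (all-equal columns
become all-zero).  On this scale a fixed matrix has expectation 0 per
matched base on random sequence, one-hot columns score sqrt(3) for the
consensus base, and scores of different periods, windows and genomes are
directly comparable.  Gap penalties default to open 4.0 / extend 1.0 (on
the normalized scale).  Published scores of the original method (e.g. a
detection threshold of 390.0, null means of ~142.6) live on that
implementation's own scale and do not transfer to this one; all thresholds
here are calibrated empirically (below).

## Why scores are standardized per period

The GA partially overfits whatever it is given: with 4n free weights the
null (shuffled-sequence) mean of mF_max grows with n — measured on 600-nt
uniform windows it rises from ~140 at n = 2 to ~340 at n = 50, roughly
proportional to sequence length at fixed n.  Raw mF_max is therefore not
comparable across periods, and a family-wise argmax over raw scores would
always favour the largest period.  The detected period of a window is
instead the argmax of the standardized spectrum

    z(n) = (mF_max(n) - mu_null(n)) / sigma_null,

i.e. the *most significant* period, with mu_null(n) and the pooled
sigma_null estimated once per window-length/GA design from seeded random
windows (`NullSpectrumCurve`).  For sequences whose length deviates
slightly from the curve's design length (indel jitter), the null mean is
rescaled linearly with length.  This mirrors selecting the period of
"highest statistical significance" rather than highest raw score.

An important measured consequence: the per-base noise-fitting capacity of a
4 x n matrix is roughly constant in sequence length (~0.40-0.45 score/base
at n = 10-50), while the per-base signal of a true consensus at 1.0
substitutions/nt is ~0.46.  The absolute signal-over-null margin therefore
grows linearly with array length while the null sd stays nearly flat, so
separation improves with length; very long periods (n ~ 35+) with few
copies sit at the information limit of this score: a GA seeded with the
*true* consensus matrix scores no higher than the shuffle null there.  The
recovery benchmark documents this honestly rather than hiding it.

A second measured subtlety: the null curve is estimated on
uniform-composition windows, but a repeat array inherits the (skewed) base
composition of its consensus, which lifts its score at *every* period.
Re-standardizing against shuffles of the query itself (the composition-
preserving null) removes that lift but also absorbs a substantial part of
the true-period signal — for short periods the composition *is* much of the
signal (an extreme case: a period-2 array's structure is largely its
alternating composition) — and costs several GA runs per candidate period,
whose sampling noise can flip close calls.  The two-stage call
(`refine_period_call`) therefore only refines when it can matter: the
stage-1 leader is kept outright when every close runner-up is harmonically
related to it (a multiple or divisor is the same periodicity) or when its
margin over the best non-harmonic rival is decisive (3 pooled sigma);
otherwise the few leading candidates are re-standardized against shuffles
of the query and the best refined candidate wins.  The scanner applies
this to windows that already passed the detection threshold; the recovery
benchmark applies it to every array.

## Genetic algorithm

Organisms: normalized 4 x n matrices.  Defaults: population 40, elite
fraction 0.1, single-cut column-block crossover with probability 0.8,
per-cell Gaussian mutation (rate 0.05, sigma 0.5), children re-normalized
so fitness stays on one scale, plateau stop after 30 unimproved
generations, cap 500 generations, one restart.  Every 10 generations the
current best matrix is refined by one alternating step — align, tally the
frequency matrix from the alignment, convert to a normalized log-odds
matrix (pseudocount 0.5) — and the result is injected into the population;
this is the classic profile/alignment self-consistency iteration and
accelerates convergence at no measurable cost to the null.  Per-period runs
are seeded as SeedSequence([seed, n]), so spectra are reproducible and
parallelizable.  The spectrum range defaults to 2-50 (the scanning
protocol's range; 2-100 is configurable).

## Significance machinery

* `shuffle_sequence`: uniform residue permutation (composition preserved);
  a dinucleotide-preserving shuffle is available but not the default.
* `null_stats`: mean and sample sigma (ddof = 1) of mF_max over seeded
  shuffles of a sequence at one period (default 100 shuffles).
* `p_value`: upper tail of N(mean_Fr, sigma_Fr^2); `log10_p_value` avoids
  underflow for extreme scores (a score ~11 sigma above the null gives
  log10 p ~ -28.5; a normal tail cannot produce bounds like 1e-50).
* `calibrate_threshold`: draws seeded random windows of the scan's window
  length and composition, computes each window's spectrum over the tested
  periods, and returns both the raw family-wise threshold F0 and the
  standardized threshold Z0 as the empirical (1 - alpha) upper quantiles
  (the returned value's exceedance on the calibration set is <= alpha by
  construction).  A null window counts as a false positive if its maximum
  over all tested periods exceeds the threshold — the family-wise
  accounting that matches how real windows are scored.

## Scanning protocol

600-nt windows stepped by 200 bp (full windows only; a sequence shorter
than one window yields nothing).  Windows with triplet-periodicity Z > 3.0
are skipped as likely protein-coding: the filter is the mutual information
I between base identity and position mod 3; 2NI is asymptotically
chi-square(df = 6) under no triplet structure and Z = (2NI - 6)/sqrt(12).
Frames are counted from the window start — I is frame-shift invariant — and
no reverse-strand search is needed for a flag statistic.

Each surviving window gets a spectrum; the detected period is the
standardized argmax (z-mode, when a threshold Z0/null curve is supplied) or
the raw argmax (F0-mode, default threshold 390.0 kept for continuity with
the published protocol constants; meaningful only after calibration on
this score scale).  The emitted region is the span of the optimal local
alignment inside the window (regions are typically shorter than the
window), carrying period, mF_max, z, triplet Z, weight matrix, frequency
matrix (tallied from the alignment path; indel steps contribute nothing, so
the matrix total equals the aligned length minus inserted bases), and the
consensus string (majority base per column; "(X/Y)" when the runner-up
exceeds 1/3 of the column sum; "N" for empty columns).

Intersecting candidates (any shared base, same sequence) are resolved
greedily by descending score — z in z-mode, otherwise mF_max — with ties by
smaller start then smaller period; the kept set is pairwise disjoint.  The
30%-overlap rule is *not* used for merging; it belongs to region-set
comparison (`overlap_compare`), where a region is matched if a single
region of the other set overlaps at least 30% (inclusive) of its own
length, periods ignored, both directions reported.  Scanning is forward-
strand only.

## Matrix comparison and uniqueness

The distance between two equal-period frequency matrices is the summed
per-column G-statistic (see `compare` module docstring for the explicit
formula); 0·ln 0 = 0.  Matrices built by distributing a fixed residue
multiset over columns — which is exactly what shuffling the underlying
sequence does — give 2I asymptotically chi-square with df = 3(n - 1)
(verified by Monte-Carlo: mean 2I within ~5% of 3(n-1) for n in {3,5,11}).
A per-column multinomial null would instead give E[2I] = 3n; the shuffle
(fixed-composition) null is the one used throughout, including for the
generated null matrices (`permutation_null_matrix`).  The normal transform
is X = sqrt(4I) - sqrt(2 df - 1), the classic sqrt(2 chi2) approximation,
giving X ~ N(0,1) under the null (Monte-Carlo: mean within ±0.2, sd within
0.8-1.2).

Uniqueness protocol: only equal-period matrices are compared; each pair
distance is minimized over the n cyclic column shifts of one matrix
(periods have arbitrary phase; reverse-complement matching is off by
default).  For each matrix k of genome A, X_k^min is the minimum X over
genome B; survival curves F_k(x) (real) and Fr_k(x) (shuffled nulls, one
per real matrix) are tabulated on a 0.05-wide grid; x0 is the smallest grid
value where F_k/Fr_k exceeds the ratio (default 20.0, i.e. <5% false
positives; Fr = 0 with F > 0 counts as exceeding); the unique-repeat count
is F_k(x0), zero with a flag when the ratio is never exceeded.

## Density profile

Sum of mF_max per fixed-size bin (default 1e5 bases) along a chromosome;
each region contributes its whole score to the bin containing its start
(length-weighted splitting available).  Total score is conserved; profile
length is ceil(seq_length / bin_size).

## Synthetic data

`simulate_latent_periodic` builds consensus x copies; applies Poisson(rate)
substitution events per base, each to a uniformly chosen different base
(Jukes-Cantor rounds: the probability a base ends up differing is
3/4 (1 - exp(-4r/3)), ~55% at r = 1.0, saturating at 75%); then applies
indel events per base at the indel rate (insert or delete 1..3 bases,
equiprobable, lengths uniform); and embeds the result at a seeded random
offset inside i.i.d. background of given composition (the emitted sequence
has the requested background length; a stretch of it is replaced by the
array).  Truth records implant coordinates, period and realized event
counts.  What the generator does *not* emulate: composition heterogeneity
and repeat nesting of real genomes, microsatellite slippage dynamics, and
phylogenetic structure among copies — so passing benchmarks demonstrate
detector behaviour under the stated degradation model, not performance on
any particular genome.

## Recovery benchmark (study conditions)

Arrays at 1.0 substitution events/nt and 5% indel events/nt, copy number
max(40, round(1800/period)) — i.e. ~1.8 kb arrays, more copies for shorter
units, sized by the power consideration above — over true periods
{2, 5, 10, 11, 12, 35}, 20 seeded runs, success when the called period
(standardized-spectrum argmax over an 18-value period grid, dense at 2-13
and sparser above) is the true period or an integer multiple/divisor of
it.  Null curves use the same GA protocol as the signal runs.  Period 35
sits nearest the information limit described above and is expected to be
the weakest cell; the per-period breakdown is reported.

## Problem sizes used in tests and the acceptance script

The suite and `scripts/acceptance.py` run desk-scale versions of every
protocol: oracle cross-checks at |S| <= 10, calibration with dozens of
600-nt windows over a reduced period set, recovery with 20 runs, and
uniqueness with planted matrix families — sizes chosen so the whole suite
completes in tens of minutes on one CPU while every statistic retains
enough replicates to be meaningful.  Genome-scale quantities from the
original study (tens of thousands of regions, full chromosomes) are out of
desk scope by design.

## Known limitations

* Micro/minisatellites much shorter than ~200 aligned bases score below
  any family-wise threshold calibrated at 600-nt windows; this detector
  targets long diverged arrays, complementing exact-repeat finders.
* The raw-score threshold F0 = 390.0 carried from the published protocol is
  meaningless on this score scale without recalibration; use
  `calibrate_threshold` (the calibrated raw threshold at 5% FPR on 600-nt
  uniform windows is reported by the acceptance script).
* Null-curve estimation is Monte-Carlo; with few replicates its noise
  propagates into z and can flip near-tied period calls (n vs n±1).
* Long periods with few copies are information-limited (see above).
* Forward strand only by default; no repeat-family taxonomy.
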