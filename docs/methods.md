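# Methods

This note documents the statistical model behind `cnarray`, the
calibration of its synthetic-data generator, the numerical choices made
where the design was genuinely open, and the limitations a user should
know before trusting output on real arrays.

## 1. Signal model and calibration

All analysis operates on a per-locus signal `S_i` normalized so that a
diploid locus in an uncontaminated, overall-diploid sample has
expectation 2.0.  The array response to copy number is calibrated, not
assumed linear: the response table

| c | 0 | 1 | 2 | 3 | 4 | 5 |
|---|---|---|---|---|---|---|
| S0(c) | 0.36 | 1.14 | 2.0 | 2.72 | 3.41 | 4.1 |

is anchored by samples of known karyotype (a homozygous deletion still
yields residual signal 0.36 from cross-hybridization; one copy yields
1.14, not 1.0), and for c ≥ 8 the response is linear,
`S0(c) = 0.314·c + 3.41`, as calibrated against qPCR copy-number
estimates (`qpcr_copy_number` implements the ΔΔCt formula
`CN = 2^(1 − CTgc + CTrc + CTgr − CTrr)`).  The table does not cover
c = 6, 7; we interpolate linearly between S0(5) and the line's value at
c = 8 (knots 4.707, 5.315), which preserves strict monotonicity and
keeps the table→line junction continuous to within 0.61 signal units.
The calibration is a plain config object (JSON-serializable) so a
re-calibrated curve can be swapped in per platform.

A sample is described by three parameters: contamination **α** ∈ [0, 1)
(fraction of benign diploid DNA), genome-size factor **β** ∈ [0.5, 2]
(arrays measure per-unit-DNA concentrations, so a genome whose average
copy number is not 2 rescales every signal), and residual log-signal
variance **σ²**.  The expected signal is `S(c) = β(2α + (1−α)S0(c))`.
Modes: `normal` fixes α=0, β=1; `cell_line` fixes α=0; `tumor` frees
both; `agilent` behaves like `tumor` but disables genotype-based peak
anchoring (oligo-CGH probes carry no genotypes).

## 2. Probe combination (SNP arrays)

Quartet-level background-corrected intensities ΔI = PM − MM are divided
by the mean ΔI of all probes on PCR amplicons of the same size within a
subarray (amplicon size is the dominant sample-specific intensity
covariate; GC content is deliberately not modeled).  Sizes with fewer
than 20 quartet observations are pooled with the nearest well-populated
size — a choice the data do not dictate; exact-size grouping is the
default otherwise.  Negative ΔI propagates through normalization and is
only clamped (floor 0.01) immediately before logarithms.

Per SNP, allele gains (k_A, k_B) minimize
`Σ_gt N_gt (k_A x_gt + k_B y_gt − 2)²` over the genotype classes of a
diploid reference panel, where x/y are panel medians of the normalized
A/B intensities (lower-median convention for even counts, for
determinism).  The minimizer is closed-form (2×2 normal equations); SNPs
monomorphic in the panel or with a degenerate design are excluded.  For
X-chromosome SNPs outside the pseudoautosomal regions only female panel
samples enter the fit.  Quartets are combined with inverse-variance
weights `w_q ∝ 1/σ_q²` (σ_q² estimated across panel samples; zero
variances floored at 1e-6), giving combined variance
`σ_i² = 1/Σ(1/σ_q²)`; the equal-weight benchmark `s_i² = mean(σ_q²)` is
reported alongside.  SNPs whose panel variance `mean((S_i − 2)²)`
exceeds 0.25 are dropped.  SNPs sharing one PCR amplicon cannot carry
independent CN information; their signals are averaged onto the
lowest-position member and the rest dropped.

## 3. Contamination and ploidy estimation

`log S_i` is smoothed with a centered 101-probe mean per chromosome
(windows truncated at ends, never spanning chromosomes), and the
smoothed track is histogrammed with bin 0.1.  Each copy-number level
present in the genome produces a mode.  A mode is a bin strictly higher
than both neighbors after merging equal-height plateaus; its position is
the mass centroid of the values in its bins ±1 (a bin-center convention
quantizes positions by up to 0.05, which is enough to blur the low-CN
curvature the fit depends on — see §5).  Modes below 0.02% of probes
are flagged but retained.

Genotype annotations (per-probe calls AA/AB/BB/NC) yield a call rate
and heterozygosity per mode (over probes in the mode's bins ±1), and the
anchoring rules run in order: a single mode is CN=2; a first mode with
call rate < 60% is CN=0; heterozygosity < 3% marks CN=1 (also for the
second mode when the first is CN=0); a mode at least twice as high as
the runner-up is CN=2.  Conflicts keep the earlier rule's anchor.
Anchoring is idempotent; in `agilent` mode only the single-mode and
dominance rules apply.

(α, β) are then fitted by direct enumeration on a grid (α step 0.01 on
[0, 0.99], β step 0.005 on [0.5, 2]) minimizing

```
E1(α, β) = Σ_k H(T_k) · (log T_k − log S(c_k))²
```

with anchored modes keeping their c_k and free modes taking the nearest
level at each grid point.  Natural logarithms are used throughout (the
choice of base only rescales E1).  Grid steps resolve α to ±0.01 and β
to ±0.0025, matching the few-percent accuracy the histogram supports.

### Non-identifiability and its resolution

The integer ladder admits a family of near-exact aliases: the map
c = 1,2,3,4 → 0,2,4,6 together with α′ = (1+α)/2 and a slightly
adjusted β reproduces every mode position to within histogram noise,
because both parameterizations have two free constants and the only
curvature constraint (the break between S0(0) and the rest of the
table) can be absorbed.  The genotype rules disambiguate at low
contamination, but above roughly 25% contamination they genuinely fail:
a hemizygous locus with admixed normal DNA really does show both
alleles, and a homozygously deleted locus genotypes like the normal DNA
that remains there.  Every alias sits at *higher* α than the solution
it shadows (a lower-α alias would need half-integer states), so
`fit_alpha_beta` resolves near-ties toward parsimony: grid points within
an absolute E1 slack of 0.05 (height-%·log² units — above the ≤0.02
noise that smoothing-transition artifacts contribute, far below the
≥0.1 misfit of a genuinely wrong solution) are clustered into connected
basins; the basin whose optimum has the smallest α wins; and within that
basin the smallest α tying the optimum (slack 0.002) is returned, since
at strong contamination the compressed ladder merges truth and alias
into one flat valley.  With the near-tie margin set to 0 the function
reduces to the plain grid argmin with smaller-α/smaller-β tie-breaking.

On mixtures of an aneuploid genome (size factor β_c) with diploid DNA at
mass fraction α, the model's identifiable parameters are
β = α + (1−α)β_c and α′ = α/β; the estimator recovers α′, which differs
from the mass fraction by up to α(1−α)|β_c−1|/β — a physical coupling,
not an estimation error, and small (<0.05) for β_c within ±20% of 1.

## 4. Segmentation and refinement

The likelihood of a CN path multiplies per-probe Gaussian emissions of
`log S_i` about `log S(c_i)` (common variance σ²) with a factor γ for
every adjacent pair that changes state.  With states 0..70 and a flat
change penalty λ = −ln γ = 54, the maximum-likelihood path per
chromosome is found by an O(n·states) dynamic program: the best
predecessor of any state is either the same state or the globally
cheapest state plus λ.  Ties resolve to the smaller CN, making decoding
fully deterministic.  An exhaustive-enumeration oracle over all state
sequences verifies the decoder on small instances in the test suite.

σ² is initialized from the residuals of signals about the CN levels
nearest the smoothed track (floor 1e-4).  After decoding, (α, β) are
re-estimated by grid-minimizing the mean squared log-residual E2 with
the path held fixed (vectorized via per-state sufficient statistics),
σ² is set to the attained E2, and the loop repeats until |Δα| < 0.03
and |Δβ|/β < 0.001 (at most 20 iterations; revisiting a parameter state
returns the best-E2 iterate flagged unconverged).  `normal` mode decodes
once with α=0, β=1.  E2 with its paired path is non-increasing across
iterations; convergence typically takes 1–2 rounds.  Peak anchoring is
not re-run inside the loop.

Because the decoded path depends on σ²·λ, the penalty and the noise
scale jointly set a detectability threshold: an interior event of k
probes with level shift Δ = log S(c_true) − log S(2) is decoded only if
`k·Δ²/(2σ²) > 2λ`.  At the calibrated noise (σ² ≈ 0.0094, §6) this
gives **~6.4 probes for a heterozygous deletion** — alterations of ≥7
probes are reliably called, shorter ones absorbed — but **~21 probes for
a single-copy gain** (CN=3), whose log-shift is 1.8× smaller.  Short
amplifications are therefore systematically missed at the default
penalty; this is a property of the model at its published operating
point, reported honestly by the false-call benchmark (§7), not tuned
away.

## 5. Output conventions

Per-probe tables keep 1-based input positions; segment tables are
BED-like 0-based half-open (`start` = first probe's position − 1,
`end` = last probe's position).  Segments partition each chromosome's
probes and adjacent segments always differ in CN.  Model reports (α, β,
σ², iterations, convergence, peaks) are JSON.

## 6. The synthetic-data generator

The generator is calibrated to the noise statistics a well-behaved
500K-style experiment shows, and those choices are fixed:

- **Per-probe log-signal sd 0.097.**  The per-SNP panel variance
  `mean((S_i − 2)²)` of a typical retained SNP is ≈ 0.0376 on the raw
  signal scale; at S ≈ 2 this corresponds to a log-scale sd of
  √0.0376/2 ≈ 0.097 (log-variance ≈ 0.0094).  This scale is
  corroborated independently by the break penalty: with λ = 54 it puts
  the deletion-detectability threshold at ~6.4 probes, exactly where
  the ≥7-probe reliability of germline deletion calls lands.
- **Allelic bias sd 0.353 per allele** (lognormal gains), making the
  median of max(k_A/k_B, k_B/k_A) ≈ 1.40 — one allele of a typical SNP
  amplifies ~40% stronger than the other.
- **Quartet variances ~ U(0.08, 0.5)** on the S_q scale; with six
  quartets the inverse-variance combination lands the median σ_i² near
  0.038.
- **Amplicon structure**: a dozen discrete sizes spanning 100–1143 bp,
  one multiplicative effect per (sample, size), at least ~50 SNPs per
  size group so the group means the normalization divides by are stable
  (real arrays have ~10⁴ probes per size; with only a handful, each
  sample's group mean depends on its own genotype draws and adds a
  percent-scale artifact the tests account for).
- **Genomes**: segment-tiled chromosomes with the diploid state
  dominant (~55% of segments), non-diploid levels weighted toward
  single-copy changes (CN 0/1/3/4/5/6 at 0.04/0.30/0.30/0.20/0.10/0.06),
  homozygous deletions focal (30–120 probes; large zero-copy spans are
  not viable), other segments 800–2500 probes so that, as on real
  arrays, only a few percent of probes sit in smoothing-transition
  zones — short-segment genomes seed spurious histogram modes that feed
  the alias of §3.  Genome-size factors draw from [0.9, 1.2].
- **Genotype annotations** follow the CN of the region: call
  probability 0.35 at CN=0, ~0.9–0.93 elsewhere; heterozygote fraction
  among called 1% at CN=1, ~20–25% at CN≥2.  Mixture annotations are
  derived from allele dosage: each source contributes copies in
  proportion to its DNA fraction, a heterozygote is reported only when
  the minor allele reaches 25% of the locus's copies, and the call rate
  follows the total copy dose.
- Mixing of samples is linear in signal space (DNA quantity is
  additive), emulating mass-mixing of extracted DNA before
  hybridization.

What the generator does **not** emulate: probe-level noise
autocorrelation along the genome (negligible on these platforms, strong
on dense custom arrays), intra-tumor heterogeneity (all cancer cells
share one CN profile), GC effects, and raw genotype-calling physics
(annotations are drawn from the CN-conditional rates above, not called
from intensities).  Passing tests therefore demonstrate correctness of
the algorithms under the stated noise model, not robustness to
platform pathologies outside it.

## 7. Benchmarks and problem sizes

Two seeded benchmarks drive the acceptance script and the heavier
tests; their sizes were chosen to finish in seconds on one CPU while
keeping every rate estimate based on ~200 events or ~20,000 probes:

- **Germline false-call rate**: 20 normal genomes (4 chromosomes ×
  5,000 probes) each with 10 implanted CNVs of 7–50 probes, CN drawn
  from {1, 3}; the full pipeline runs in normal mode and the combined
  rate of spurious plus missed alterations of ≥7 probes is reported.
  Deletions are essentially always recovered (the ≥7-probe threshold of
  §4); gains shorter than ~20–25 probes are not, so the combined rate
  is dominated by missed short CN=3 events (~17–33% depending on seed,
  with zero spurious calls).  A deletions-only version of the same
  design stays below 5%.
- **Contamination series**: one aneuploid genome (segments spanning
  CN 0–6, size factor in [0.9, 1.2]) called pure (cell-line mode) and
  in diploid mixtures at α = 0.1..0.7 (tumor mode); reported are the
  minimum probe-level concordance of mixture calls against the pure
  calls (≥99.7% across validation seeds) and the mean |α̂ − α| (~0.01,
  bounded by the genome-size coupling of §3).

## 8. Known limitations

- Copy-neutral loss of heterozygosity, translocations, and subclonal
  (non-integer) states are out of scope.
- The purity/ploidy alias is resolved by parsimony (§3); a genome whose
  histogram truly contains only evenly-spaced modes with no sub-diploid
  peak remains unidentifiable, and the estimator will prefer the
  least-contaminated consistent explanation.
- Short amplifications below the detectability threshold of §4 are
  absorbed into their background segment at the default penalty.
- Genotype anchoring assumes annotations of the sample being called;
  platforms without genotypes fall back to dominance anchoring only.
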