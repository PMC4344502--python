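# Methods

## Model and rationale

After transcription shutoff, a mature miRNA species whose molecules all
share one fate decays as a single exponential, R(t) = 2^(−t/h). Many
fast-turnover species — predominantly star strands — instead behave as a
mixture of two pools with very different fates: an AGO-associated but
not fully loaded pool that is degraded quickly, and a fully loaded pool
that is protected. `mirturn` models this as

    R(t) = F_fast · 2^(−t/h_fast) + F_slow · 2^(−t/h_slow)

with F_fast + F_slow = 1 and h_fast ≤ h_slow; h_slow = ∞ is an exact
plateau. R(t) is the replicate-mean normalized frequency at time t
divided by the 0-h mean, so R(0) = 1 by construction.

Normalization assumes total mature-miRNA content is approximately
constant over the time course (justified independently via spike-in
normalized profiling totals): every read count is divided by its
sample's total mature-mapped read count. Loop-region and unassigned
reads are excluded from that denominator.

## Quantification

Reads ≥ 15 nt are assigned by exact substring matching against the
hairpin reference (a 15-mer seed index with full verification; an
exhaustive position-scan oracle backs this in the tests). A read's
footprint is attributed to a mature arm when ≥ 75% of its bases fall
inside the annotated mature interval extended by 2 nt on each side
(ties toward 5p); to the loop when fully contained between the arms;
otherwise to "other". An optional second pass rescues reads whose only
mismatches are ≤ 2 non-templated bases at the 3′ end (NTA); it is off
by default because NTA isoforms are typically too few to support
statistics. Mature arms with identical sequence across hairpins form a
cross-reference group counted once; reads matching several groups are
flagged multimapped and counted once in per-sample totals.

Detection ("reliably quantifiable") requires mean 0-h frequency
≥ 5×10⁻⁶. Star/non-star roles are assigned per hairpin from mean 0-h
frequency (more abundant arm = non-star; single-arm hairpins =
non-star; exact ties go to 5p and are flagged ambiguous).

## Turnover classes and tests

Per entity, two-sided equal-variance Student's t-tests compare 0-h
replicate frequencies with the 4-h group, the 12-h group, and the
pooled 4+12-h group (pooling replicates, recorded in the output attrs).
Raw frequencies are tested, not log-frequencies. fast_lt50 requires
R(12) < 0.50 plus any nominal p < 0.05; fast_lt25 additionally
R(12) < 0.25; slow requires R(12) ≥ 0.75 and no significant comparison;
otherwise intermediate. No multiple-testing correction is applied to
the calls (the class definitions use nominal p-values); a
Benjamini–Hochberg column over each entity's minimal p is emitted for
information only. Groups with fewer than two replicates make the tests
undefined and the entity unclassified. Both a fitted half-life and the
endpoint-ratio half-life −12/log2 R(12) are reported, since either
convention appears in practice. The endpoint (12 h) and mid (4 h)
comparison times are configurable so other inhibitor time grids work
unchanged.

When both groups of a comparison have (numerically) zero variance the
t-test is degenerate; p is set to 1 when the means agree and 0
otherwise. Variance is compared against a relative tolerance because
identical floating-point replicates can produce O(1e-34) variances by
cancellation, which would otherwise yield arbitrary p-values.

## Decay fitting

Single exponential: least-squares slope of log2 R̄(t) against t through
the origin, excluding non-positive R̄; a non-negative slope reports
h = ∞.

Two-phase: weighted SSE on the linear scale (weights = replicate counts
per timepoint), parameterized as (F_fast, h_fast, r = h_fast/h_slow)
with F_fast ∈ [0,1], h_fast ∈ [0.05, 50] h, r ∈ [0,1] (r = 0 encodes
h_slow = ∞). A coarse grid (21 × 30 × 13) seeds a bounded
trust-region least-squares refinement; the single-exponential solution
mapped into this family and the flat curve are always evaluated as
candidates, so the two-phase SSE never exceeds the nested
single-exponential SSE. Model comparison uses
AIC = n·ln(SSE/n) + 2k (k = 1 vs 3).

Kinetic shapes, applied in order: **ultrafast** if R(1 h) ≤ 0.10 (the
loop-read regime; requires a 1-h timepoint); **stable** if the turnover
class is slow; **two_step** if the two-phase fit beats the single
exponential by an AIC margin ≥ 2 with h_fast ≤ 2 h and F_slow ≥ 0.10;
**continuous** for remaining fast-class entities; else unclassified.
Checking stable before the two-step gate is deliberate: with only four
timepoints the three-parameter fit can chase replicate noise on an
essentially flat curve and clear the AIC margin, and a two-step label
is only meaningful when the decline itself is established. The
continuous class is likewise not gated on h ≥ 4 h: a fast decayer that
fails the ultrafast and two-step gates has no other honest label.

## Sequence features

Fast vs slow isoform sets (disjoint; intermediate/unclassified
excluded) are compared per position (1-based from the 5′ end, plus the
final base) with Fisher's exact test on the 2×2
(nucleotide yes/no) × (fast/slow) table — two-sided by summing
hypergeometric probabilities ≤ the observed table's — and a permutation
null: draw |fast| isoforms from the pooled sets without replacement,
M = 10 000 times, and count draws with a frequency at least as extreme
as observed, one-sided in the observed direction, no pseudocount (a
zero count reports p = 0 with the 1/M resolution noted in the output).
Because the permutation statistic depends only on how many marked
isoforms land in the drawn set, the draws are sampled directly from the
hypergeometric distribution, which is distributionally identical to
permuting labels and much faster. The A-rich motif indicator is
≥ 3 A's at positions 13–16 (sequences < 16 nt are excluded and
tallied); per-position A statistics are emitted alongside, since
"A-rich" has no canonical numeric definition.

## Profiling normalization

Spike-in: each sample is scaled by (reference ÷ geometric mean of its
spike-in intensities), the reference being the across-sample geometric
mean. The geometric mean over the three spike-in probes is robust to a
single outlier probe on the multiplicative scale. Total-constant: each
sample is scaled so its mature-probe sum equals the across-sample mean.
Both are pure per-sample rescalings — within-sample probe ratios are
preserved exactly — and both are equivariant to rescaling a sample up
to the global target constant (any positive target is equivalent up to
a global factor). Total miRNA abundance is the mature-probe sum per
spike-in-normalized sample, reported with per-timepoint means and the
slope of the totals-vs-time regression with a 95% CI.

## Synthetic data generator

The generator emulates the assumed study design so that planted truth
is recoverable by the pipeline:

* **Design**: 0/1/4/12 h with biological triplicate; depth 2×10⁶
  expected mature-mapped reads per sample (defaults; both
  configurable). A profiling companion uses 0/2/4/6/12/24 h duplicates.
* **Reference**: each hairpin is flank (4–8 nt) + 22-nt 5p arm +
  loop (15–18 nt) + 22-nt 3p arm + flank, i.e. 64–78 nt total; mature
  sequences are unique and three 22-nt spike-ins occur in no hairpin.
* **Kinetics**: 8% of species are fast, 80% of those star strands;
  fast species decay as the two-pool law with h_fast = 1 h and a
  stable fraction uniform in [0.05, 0.4] (h_slow = ∞ by default, i.e.
  a pure plateau; finite values supported); slow species have h = ∞;
  loop reads decay with a 0.3 h half-life, emulating unprotected Dicer
  byproducts.
* **Abundance**: log-normal (σ = 1) across species — the abundance law
  is not pinned down by available data, so a heavy-tailed default was
  chosen once; the non-star:star ratio is skewed ≥ 4:1
  (4·e^|N(0,0.5)|).
* **Isoforms**: one dominant isoform (90%) plus six 5′/3′
  trim/extension variants with geometrically decaying weights (factor
  0.5 per offset base); all map exactly to the hairpin.
* **Composition biases**: fast species draw their first base with
  elevated G/C and depleted U, their last base with elevated C and
  depleted G, and positions 13–16 with a lower per-position A
  probability (0.12 vs 0.35) than slow species.
* **Noise**: counts are negative-binomial around the expectations with
  dispersion 0.05, which places replicate CVs in the ≲ 0.4 regime of
  good biological triplicates (dispersion 0 gives Poisson). Expected
  totals equal the depth at 0 h and shrink with the total surviving
  miRNA content at later times (< ~2% at defaults), mirroring the
  near-constancy of total miRNA that justifies the normalization.
  Spike-in reads are constant in expectation (0.5% of depth each).

What the generator does **not** emulate: sequencing errors, adapters,
quality scores, genomic multimapping outside the supplied hairpins,
cross-hairpin duplicate matures, residual transcription under
inhibition, and cell-division dilution. Passing tests therefore show
that the statistical machinery recovers truth under the assumed model,
not that the model captures every property of real libraries.

## Problem sizes used in tests and benchmarks

The recovery benchmark simulates 1250 hairpins (2500 species, 200
planted two-step species) at full default depth and fits each detected
fast species; classifier fidelity uses the 300-hairpin default. Unit
tests use 10–60 hairpins at 10⁵–10⁶ reads. These sizes were chosen so
the whole suite runs in a few minutes on one CPU while keeping ≥ 200
species in the headline median.

## Known limitations

* The remaining-fraction estimator is a ratio of means; with the
  total-mapped-count normalization it carries a small (≈ 1–2% at
  default conditions) upward drift because fast species shrink the
  denominator over time — negligible against the class boundaries but
  visible in high-precision comparisons.
* The two-phase fit is only weakly identified when the curve has fewer
  than four informative timepoints or the plateau is below ~5%;
  bounds and the AIC gate keep such fits from being over-interpreted.
* Star annotation is purely empirical (0-h abundance); hairpins whose
  strand bias flips between conditions will be annotated by the
  supplied data, not by any database convention.
* Permutation p-values have 1/M resolution and no pseudocount; treat
  p = 0 as p < 1/M.
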