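# mirturn

Genome-wide **miRNA turnover analysis** from transcription-shutoff
small-RNA time courses.

When transcription is frozen with actinomycin D (or DRB), the abundance
trajectory of every mature miRNA and every sequence isoform (isomiR)
reveals its decay kinetics. `mirturn` turns time-course small-RNA reads
(or a pre-collapsed sequence-level count table) plus a hairpin reference
into:

* per-miRNA and per-isoform **remaining fractions** R(t) — mean
  normalized frequency at time *t* over the 0-h mean, with frequencies
  normalized to total mature-mapped reads per sample;
* **turnover classes** — fast (<50% or <25% remaining at the endpoint
  with a nominal Student's t-test p < 0.05 in any of 0-vs-4 h,
  0-vs-12 h, 0-vs-(4+12) h), slow (≥75% remaining, no significant
  change), or intermediate; detection requires a mean 0-h frequency
  ≥ 5×10⁻⁶ ("reliably quantifiable");
* **decay-model fits** — a single exponential R(t) = 2^(−t/h), and a
  constrained two-pool mixture

      R(t) = F_fast · 2^(−t/h_fast) + F_slow · 2^(−t/h_slow),
      F_fast + F_slow = 1,  h_fast ≤ h_slow (h_slow may be ∞),

  which captures the two-step kinetics of many fast-turnover star
  strands: a ~1 h fast phase (the AGO-associated but not fully loaded
  pool) decaying onto a stable plateau (the loaded pool);
* **kinetic shapes** — ultrafast (loop-like collapse within 1 h),
  two-step, continuous, stable;
* empirical **star/non-star strand roles** from 0-h abundance per
  hairpin arm;
* **positional sequence-feature statistics** comparing fast vs slow
  isoform sets: first-base and last-base composition, total composition,
  the A-rich positions-13–16 motif, and length distributions, each with
  a two-sided Fisher exact p and a 10 000-iteration permutation p
  (drawing the fast-set size from the pooled isoforms, one-sided in the
  observed direction);
* **bead-array profiling support** — spike-in normalization (abundance
  per total RNA), total-constant normalization, and total-miRNA
  abundance trends.

A first-class synthetic-data module generates hairpin references,
truth-labelled kinetics and replicate count tables with the statistical
structure the analysis assumes (two-pool decay, ultrafast loop reads,
~90% dominant isoforms, star-biased fast species, planted composition
biases, negative-binomial noise, constant spike-ins), so the whole
pipeline is testable end to end without any downloads.

## Worked example

Simulate a small study (60 hairpins → 120 mature species, 500 k reads
per sample, 0/1/4/12 h × 3 replicates) and run every stage:

```python
from mirturn import SimConfig
from mirturn.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_run", seed=7,
                     sim=SimConfig(n_hairpins=60, depth=5e5, seed=7))
run_pipeline(cfg)
```

or equivalently from the shell:

```bash
mirturn run --config demo.yaml        # out_dir/seed/sim in the YAML
mirturn report --run-dir demo_run
```

`demo_run/summary.json` then contains (output of the run above):

```json
{
 "detectable_mirnas": 120,
 "detectable_isoforms": 884,
 "fast_lt50_total": 10,
 "fast_lt50_star": 7,
 "fast_lt25_total": 6,
 "turnover_classes": {
  "fast_lt25": {"total": 6, "star": 3, "non_star": 3},
  "fast_lt50": {"total": 4, "star": 4, "non_star": 0},
  "slow":      {"total": 94, "star": 45, "non_star": 49},
  "intermediate": {"total": 16, "star": 8, "non_star": 8}
 },
 "shape_classes": {"stable": 94, "ultrafast": 36, "continuous": 23,
                   "two_step": 13, "unclassified": 14},
 "confusion_fast_lt50": {"tp": 10, "fp": 0, "fn": 0, "tn": 110},
 "sensitivity_fast_lt50": 1.0,
 "specificity_fast_lt50": 1.0
}
```

Reading: of 120 detectable miRNAs, 10 are fast-turnover (<50% left
after 12 h; 6 of them below 25%), mostly star strands; 94 are stable.
The 36 "ultrafast" entities are dominated by hairpin-loop byproducts,
which collapse with sub-hour half-lives. The confusion matrix compares
the calls against the generator's planted truth — here the classifier
recovers every planted fast species with no false positives. The
feature tables in the same directory report, e.g., that the A-rich
13–16 motif is depleted in the fast set (in this run: frequency 0.00 vs
0.097, Fisher p = 0.004, permutation p = 0.002).

Each stage is also exposed directly (`mirturn simulate / quantify /
profiling / kinetics / features`) and as plain library functions
(`quantify_reads`, `compute_frequencies`, `annotate_star`,
`turnover_calls`, `fit_two_phase`, `position_enrichment_tests`, ...).

## Data formats

Hairpins as FASTA with a tab-separated mature annotation
(`hairpin_id, mature_id, arm, start, end`; 0-based half-open
coordinates); reads as adapter-free FASTA/FASTQ per sample or one
sequence × sample count TSV; a sample sheet
(`sample_id, time_h, replicate`); profiling matrices as probe × sample
TSV plus a probe-class TSV. All outputs are TSVs with header rows plus
a JSON summary. See `docs/methods.md` for the model, parameter and
design details.
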