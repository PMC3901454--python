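# Methods

`mirachip` implements the analysis chain used for MIRA-chip (methylated-CpG
island recovery assay hybridized to CpG-island/promoter tiling arrays)
differential DNA-methylation studies, together with the bisulfite-based
verification assays (COBRA and clone sequencing) used to check candidate
loci, and a synthetic-data generator that provides ground truth for every
stage.

## The array model

Each array tiles regions — CpG islands and RefSeq promoter windows
(−2.4 kb to +0.6 kb around the TSS) — with short probes. Every
hybridization yields two channels per probe: the MIRA-enriched fraction and
input DNA. Methylation appears as elevated log2(MIRA/input) over runs of
consecutive probes. All coordinates are 0-based half-open internally; BED
is written without shifts.

## Normalization

1. **Loess, per array.** M = log2(mira/input) and A = (log2 mira +
   log2 input)/2; a robust locally weighted regression of M on A
   (statsmodels `lowess`) is subtracted from M. Defaults: span 0.3,
   3 robustifying iterations, degree-1 local fit — common two-color-array
   practice; both are exposed in the configuration. A `delta`
   speed-up of 1% of the A range is used above 200 probes (numerically
   negligible at these noise levels). Degenerate input with zero A range
   falls back to subtracting the mean of M.
2. **Quantile, across all arrays of the experiment** (treated and control
   pooled). Every sample's sorted log2-ratio vector is replaced by the
   across-sample mean of order statistics; ranks are preserved and tied
   values receive the mean of their tied reference quantiles. The
   operation is idempotent to floating-point precision.

Thresholding happens only after both steps: positivity is defined on
normalized ratios.

## Peak calling

A probe is **positive** when its normalized log2 ratio is strictly above
1.0 (ratio above 2-fold). A **peak** is a run of probes within one tiled
region containing at least 4 positive probes, tolerating at most one
single-probe gap strictly in the run's interior. Decisions the rule's
prose leaves open, fixed here and configurable:

- a "gap" is exactly one negative probe; two consecutive negatives always
  end a run, whatever the gap budget;
- gap probes do not count toward the 4 positives but do enter the peak's
  mean log2 ratio (the peak's reported signal averages every member probe);
- peaks never start or end on a gap probe;
- consecutive probes more than 500 bp apart (`max_spacing`) never share a
  run, so a peak cannot silently bridge unrelated tilings;
- peaks never cross region boundaries.

When overlapping windows both satisfy the predicate (possible when a gap
can be spent in two ways), the scan keeps the leftmost-starting, longest
window and continues after it. This makes the output deterministic,
maximal and non-overlapping; the test suite checks exact agreement with a
brute-force enumeration of all valid intervals under the same tie-break.

## Differential methylation

For a treated/control pair, the candidate set is the union of both
samples' peaks (scoring only treated peaks could never detect the loss of
a control-only peak); candidates whose probe footprints overlap are merged
on the footprint union. For each candidate the mean normalized log2 ratio
over its footprint is computed in both samples; the call is
**hypermethylated** when (treated − control) strictly exceeds log2(3) ≈
1.585 and **hypomethylated** when it is strictly below −log2(3). This is a
fixed effect-size rule: no variance model, no p-values, no multiple-testing
correction, and it is antisymmetric under swapping the two samples.
Comparisons are declared explicitly as (treated_id, control_id) pairs;
summaries report hyper/hypo counts per comparison.

## Annotation

Peaks and differential calls are annotated by ≥1 bp half-open overlap
against strand-aware promoter windows (TSS − 2400 bp to TSS + 600 bp,
clipped at the chromosome start) and CpG islands, with categories
promoter / cpg_island / both / intergenic. A peak overlapping several
promoters reports all gene names, alphabetically. Transcript tables are
read as BED6 or UCSC refFlat (both 0-based half-open); records without a
usable strand are skipped with a warning.

## Bisulfite verification arm

- **Conversion** turns every unmethylated C into T with probability equal
  to the conversion rate (deterministic at 1.0); methylated CpG Cs resist.
  Failures can strike unmethylated CpG Cs too — this is how incomplete
  conversion produces spurious methylation calls in real data.
- **COBRA** with TaqαI (T^CGA): a site stays cleavable after conversion
  and PCR only if its CpG is methylated (TCGA → TTGA otherwise). The
  report lists per-site retention and expected fragment sizes for the
  fully methylated digest, the fully unmethylated (uncut) case, and any
  explicit methylation state; fragment lengths always sum to the amplicon
  length.
- **Clone calling** aligns each read gaplessly to the converted reference
  frame of its amplicon, trying both orientations and (for shorter reads)
  every offset; C at a CpG position reads methylated, T unmethylated,
  anything else missing. Only the top strand is modeled — clones are PCR
  products of a fixed amplicon, so indel-containing reads fail QC rather
  than being realigned. Mismatches not explainable by C/T chemistry above
  10% of the read flag the clone `pass_qc=False`; above 30% the read is
  rejected as unalignable.
- **QC and percentages.** Conversion efficiency is the converted fraction
  of covered non-CpG cytosines; an optional filter (default threshold
  0.95) excludes poorly converted clones, but it is off by default in the
  pipeline because the assays this mirrors applied no such filter.
  Percent methylation is 100·methylated/(methylated+unmethylated) over
  included clones, missing calls excluded; it is invariant to clone order
  and duplication. Lollipop diagrams render one row per clone (● methylated,
  ○ unmethylated, · missing).

## The synthetic-data generator

Per probe, on the log2 scale: input = baseline + N(0, baseline_sd);
MIRA = input + effect + dye_bias(A) + N(0, noise_sd), where effect is the
elevation of any truth peak covering the probe in the sample's group and
dye_bias is a polynomial in the pre-bias mean intensity A. Raw channels
are 2^(log2 value), hence strictly positive. With zero noise and zero
bias, the raw log2 ratio equals the injected effect exactly.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `probes_per_region` | 8–15 | typical island/promoter tilings at 100 bp start-to-start spacing |
| `peak_density` | 0.2 | a minority of CpG islands is methylated in normal cells |
| `effect_mean` / `min_effect` | 2.0 / 1.2 log2 | enrichment well above the 1.0 positivity threshold so truth peaks are callable |
| `min_peak_span` | 6 probes | every truth peak satisfies the 4-positive rule with margin |
| `noise_sd` | 0.3 log2 | per-probe replicate noise |
| `baseline_log2` / `baseline_sd` | 10 / 2.0 | a wide intensity range, as on real tiling arrays |
| `dye_bias` | (0, 0.1, 0.03) in (A−10) | a gentle MA "banana" within ~1 log2 unit across the range |
| `conversion_rate` | 0.99 | realistic near-complete bisulfite conversion |

Truth peaks are drawn per region (Bernoulli `peak_density`); differential
peaks are injected into peak-free regions, split evenly between hyper
(present only in the treated group) and hypo (present only in the
control group). One global seed drives named substreams per stage
(design, truth, each sample, each clone set), so every stage is
independently reproducible and identical config+seed gives byte-identical
pipeline outputs.

What the generator does **not** emulate: scanner saturation, spatial
artifacts, probe cross-hybridization, sequence-dependent pulldown
efficiency, or the empirical intensity distribution of any particular
scanner — the lognormal baseline is a stand-in, not a claim about real
NimbleGen data. Passing recovery tests therefore demonstrates the
pipeline's correctness under its own assumptions, not performance on any
specific archived dataset.

## Numerical choices and degenerate inputs

- Positivity, differential and QC thresholds are all strict inequalities;
  a delta of exactly log2(3) is not a call.
- Loess refuses runs with fewer than max(8, ⌈4/span⌉) probes, naming the
  minimum; raw intensities must be strictly positive.
- Quantile normalization of a single sample is the identity (and marks
  the sample normalized).
- Empty flag vectors, empty clone lists and zero-CpG amplicons yield
  empty results or informative errors rather than silent zeros.

## Known limitations

- Very small arrays (below roughly 1500 probes at the default
  configuration) can place enriched probes in the majority within the
  extreme intensity stratum; robust loess then tracks the enrichment and
  subtracts real signal. This is a property of MA-loess on any enriched
  sample, not of this implementation; simulations here use ≥150 regions
  (~1700 probes) where the effect vanishes.
- The differential rule is deterministic and replicate-blind by design;
  sporadic single-comparison calls are expected at realistic noise (the
  null simulations show a median of zero calls between replicates, not a
  guarantee of zero).
- Gapless clone alignment means indel-containing clones are discarded,
  slightly biasing clone counts in data with real indels.
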