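# Methods

## Scope and data model

The package analyses two-condition (wild-type vs mutant) ChIP tiling-array
experiments for a centromeric histone variant, plus locus-level ChIP-qPCR.
All genomic coordinates are 0-based half-open internally (BED convention);
GFF3 converts to 1-based closed at the file boundary. Signal lives in a
`ProbeTrack`: ordered probes with strictly increasing positions per
chromosome, a uniform nominal spacing, and a declared scale — `linear`
(values > 0) or `log2` (unbounded). Scale conversions are exact inverses.

## Synthetic genome and arrays

No public accessions exist for the original arrays, so all inputs come from
a generator whose defaults are the study conditions.

**Genome.** Three chromosomes of 5.58, 4.54 and 2.45 Mb (12.57 Mb total)
with centromeres of 40, 65 and 110 kb at the chromosome midpoints and 50-kb
subtelomeres. With a 100-kb proximity window this makes the
centromere-proximal fraction of the genome 600 kb / 12.57 Mb = 4.8%, the
figure the proximity statistics are calibrated against. 5073 genes are
tiled without overlap on the chromosome arms, apportioned to arms by
length; gene length is drawn within each slot (seeded), strands are random.
Expression values (5–15 a.u.) are assigned by exact largest-remainder
quotas over the five classes in the proportions 815 : 1904 : 1726 : 591 :
37 (very_low … very_high), then drawn uniformly within each class band. A
multinomial draw would miss the smallest class (n = 37) by more than 10%
too often to serve as a stable fixture; the quota scheme reproduces the
class sizes exactly while leaving per-gene values random.

**Arrays.** Wild-type chromosomal baseline is 1.0 (linear). The mutant is
baseline × global fold multiplier × planted-domain fold inside domains ×
`2^(slope × expression)` over gene bodies (strand-aware TSS→TES span;
negative slope depletes transcribed genes). Noise is Gaussian on the log2
scale (sd 0.25 by default, a fixture choice — the source data's probe-level
noise is not quantified), i.e. multiplicative on linear signal, keeping it
positive — the standard tiling-array error model. Probes tile every 20 bp
(also a fixture choice). Spike-in controls sit on a separate virtual contig
(`spikein`): four abundance levels (0.5, 1, 2, 4) across 400 probes,
identical references in both conditions. Per-array efficiency factors
multiply everything including spikes; that is precisely what spike
normalization removes. The generator does not model probe GC bias,
cross-hybridization, saturation, or replicate arrays — passing tests show
the estimators are correct under the declared noise model, not that they
are robust to array artefacts absent from it.

**Planted domains.** `plant_domains` places 96 domains with midpoints
inside the six 100-kb centromere flanks (apportioned by flank length,
evenly spaced with ±100 bp seeded jitter, center-to-center ≥ 6 kb, never
overlapping a centromere body) and 72 domains on the distal arms at least
105 kb from any centromere edge and 10 kb from chromosome ends. Width 2 kb
and fold 6 by default. The margins make the proximal/distal labels
unambiguous under the midpoint rule even after calling jitters region
edges by a probe.

**qPCR.** Replicates are the true %IP times a unit-mean lognormal factor
with coefficient of variation `cv` (default 5%, three replicates).

## Normalization and the global fold change

`scale_by_spike_ins` multiplies an array by the single scalar that makes
its spike-probe mean equal the reference mean — idempotent and
rank-preserving. The global chromosomal fold change is
`2^(mean log2(mut/wt))` over non-spike probes after both arrays are
spike-scaled: a geometric mean, unbiased under symmetric log-scale noise
and invariant to pre-multiplying either array by any positive constant.
(An arithmetic mean of linear ratios would be biased upward by
`exp((σ ln 2)²)`-type terms under the multiplicative noise model; whether
the published figure was arithmetic or geometric, and smoothed or raw, is
not stated, so the unbiased estimator was chosen.) With 400 spike probes
and log2 noise sd 0.2, the estimator's standard error is ≈ 1%, dominated by
the spike-mean noise rather than the ~630k chromosomal probes.

`running_average` is a centered moving mean per chromosome; even window
sizes are widened to the next odd integer so the window is symmetric, and
windows truncate (shrink) at chromosome ends rather than padding with
invented data. The 100-probe default matches the display convention of the
source figures.

## Enriched-domain calling

On a linear-scale ratio track, probes strictly above
`fold_threshold × genome-wide average` (arithmetic mean over chromosomal
probes) are marked; maximal marked runs — optionally bridging up to
`max_gap` consecutive sub-threshold probes, default 0 as the most
conservative reading — become regions spanning
`[first probe, last probe + spacing)`, so an n-probe run at spacing s has
length n·s and a 50-probe run at 20 bp reaches the 1-kb minimum. Runs
shorter than `min_length` are discarded. Calling operates on the raw
(unsmoothed) ratio by default; smoothing first is exposed as an option
since the published search's input signal is unstated. The reading
"value > 2 × mean" was adopted over "(value − mean) > 2 × mean"; with the
default 6-fold plants either reading recovers all domains, but the
convention is stated because it changes marginal calls on real data. The
caller is verified against a brute-force interval-enumeration oracle on
random tracks.

## Proximity statistics

A region is proximal when its midpoint lies within `window` (default
100 kb) of the nearest centromere edge, boundary inclusive — a single-point
rule chosen for unambiguity. Distances are edge-based, not
midpoint-based: "within 100 kb of centromeres" then corresponds to the
4.8% genome fraction above. The null population is the set of 1-kb bins
tiling the non-centromeric genome (N ≈ 12 354 bins, K ≈ 600 proximal on the
default fixture), making the hypergeometric parameterization explicit and
reportable; 1 kb matches the minimum region length. The upper tail
P(X ≥ k) is summed in log space from `scipy`'s log-pmf, and results carry
log10 p alongside p, since values near 10⁻⁸⁰ are meaningless to compare on
a linear scale. For the headline configuration (k = 96 of n = 168 with
4.8% of bins proximal) this parameterization gives log10 p ≈ −82; because
the population behind the originally printed exponent is unknown, the
package treats that figure as a qualitative bound (tests assert
log10 p < −50) rather than a number to match. Under a
randomized-placement null the p-values are verified super-uniform at the
5% and 1% levels over 2000 replicates.

## Expression stratification and metagene profiles

Class boundaries are 8, 10, 12, 14 a.u.: very_low < 8; 8 ≤ low < 10;
10 ≤ medium < 12; 12 ≤ high ≤ 14; very_high > 14. The top and bottom
conventions follow the printed "(>14)"/"(<8)" endpoints; interior
boundaries are lower-inclusive, an arbitrary but documented choice. The
source legend's mention of "four groups" conflicts with its own explicit
five-category list; the five categories are used.

`tss_aligned_matrix` gives one strand-oriented vector per gene (− strand
relative coordinate is `tss − position`, so downstream always means the
direction of transcription); bins average their member probes and empty
bins are missing values; genes whose window leaves the probed extent of
their chromosome are skipped with a logged warning. Class profiles report
the per-position mean and a two-sided Student-t interval at `ci_level`
(default 99%) with per-position n (missing values excluded); t is the
appropriate small-n choice given a 37-gene smallest class. Coverage is
verified ≥ 97% over 5000 simulated cells. Moving-average curves sort genes
by expression and slide a 100-gene window with step 1 over (expression,
occupancy) means.

## qPCR quantification

`%IP = 100 × IP / (input × dilution factor)`, with the dilution factor a
per-experiment config field defaulting to 1 (the correction factors used in
the source experiments are unstated). A result above 100% is reported as an
error: it indicates inconsistent quantities, and %IP is bounded by
definition. Replicate summaries are the arithmetic mean and the n−1
standard deviation (undefined, flagged, for a single replicate); relative
enrichment between loci is the ratio of means, matching how bar-plot ratios
are formed from plotted means (not a mean of per-replicate ratios).

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; the pipeline derives all
stage seeds from the single config seed, and a fixed seed reproduces the
results directory byte for byte. The shipped verification runs use the
full-scale fixture (≈ 628 500 chromosomal probes at 20-bp spacing) for the
planted-domain and global-fold recoveries, and a 1-Mb two-chromosome,
300-gene genome with balanced expression classes for unit-level
simulations — chosen so the whole suite exercises full-scale recovery once
while keeping routine checks light.

## Known limitations

- The generator's noise is i.i.d. per probe; real tiling arrays show
  spatially correlated noise, probe-sequence effects and dye bias, none of
  which are modeled. Parameter-recovery results should be read as
  correctness checks, not performance claims on real arrays.
- The domain caller is a plain threshold rule by design (matching the
  analysis it reimplements); it has no change-point model, no FDR control,
  and its calls near the threshold are sensitive to the genome-wide-average
  estimate.
- The hypergeometric population is a modeling choice (1-kb bins outside
  centromere bodies); other parameterizations shift the exponent of
  extremely small p-values, which is why log10 p is reported and only
  order-of-magnitude claims are made.
- Expression values are fixture annotations standing in for
  transcriptomics-derived estimates; the package does not estimate
  expression from RNA data.
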