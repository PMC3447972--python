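# cenmisloc

Quantitative ChIP-chip analysis of centromeric-histone (CENP-A/Cnp1)
mislocalization in fission yeast, built for the situation where histone
chaperone or deacetylase mutants let the centromeric H3 variant leak into
chromosome arms. The package answers three questions a chromatin biologist
asks of such tiling-array data:

1. **How much more CENP-A is on chromatin overall?** Exogenous spike-in
   control probes of known, condition-invariant abundance put both arrays on
   an absolute scale, so a genuine global gain is measured instead of being
   normalized away. The estimate is the geometric mean of per-probe ratios,
   `2^(mean log2(mut/wt))`, after each array is multiplied by the scalar
   matching its spike-probe mean to the reference mean.
2. **Where does it accumulate?** Enriched domains are maximal probe runs of
   at least 1 kb whose linear mut/wt ratio strictly exceeds 2× the
   genome-wide average. Their spatial association with centromeres is
   tested with a hypergeometric upper tail: for *k* of *n* regions whose
   midpoints fall within 100 kb of a centromere edge, with *K* of *N* 1-kb
   genomic bins proximal, `p = P(X ≥ k), X ~ Hypergeom(N, K, n)`, evaluated
   in log space.
3. **How does transcription shape it?** Genes are stratified into five
   expression classes (boundaries 8/10/12/14 on a 5–15 a.u. scale),
   profiled TSS-aligned with per-position 99% Student-t confidence
   intervals, and summarized as moving-average occupancy-vs-expression
   curves (window 100 genes, step 1). Percent-input ChIP-qPCR utilities
   (`%IP = 100 × IP / input`, replicate mean ± SD, ratio-of-means relative
   enrichment) cover locus-level validation.

Because the original arrays are not publicly deposited, the package ships a
first-class synthetic-data generator: a 12.57-Mb three-chromosome genome
with centromeres, subtelomeres and 5073 expression-annotated genes, probe
tracks at 20-bp spacing with multiplicative (log2-Gaussian) noise, planted
enrichment domains, a global fold multiplier, transcription-proportional
gene-body depletion, and spike-in probes on a virtual contig. Every
analysis is validated by recovering what was planted.

## Worked example

```python
import cenmisloc as cm

genome = cm.build_genome_model(seed=1)
domains = cm.plant_domains(genome, seed=1)          # 96 proximal + 72 distal 2-kb domains
params = cm.SimulationParams(seed=1, domains=domains)
wt, mut, spikes = cm.simulate_probe_tracks(genome, params)

ratio = cm.ratio_track(cm.scale_by_spike_ins(mut, spikes),
                       cm.scale_by_spike_ins(wt, spikes), "linear")
regions = cm.call_enriched_regions(ratio, min_length=1000, fold_threshold=2.0)
result = cm.test_proximity_enrichment(regions, genome, window=100_000)

print(f"regions called: {len(regions)}")
print(f"proximal (<=100 kb of a centromere): {result.k_proximal} "
      f"({100 * result.proportion:.0f}% of regions in "
      f"{100 * result.genome_fraction:.1f}% of the genome)")
print(f"hypergeometric log10 p = {result.log10_p:.1f}")
```

prints

```
regions called: 168
proximal (<=100 kb of a centromere): 96 (57% of regions in 4.8% of the genome)
hypergeometric log10 p = -82.1
```

All 168 planted domains are recovered, the 96 centromere-proximal ones are
classified correctly by the midpoint rule (57% of regions in 4.8% of the
genome), and the clustering is astronomically unlikely under random
placement.

The same pipeline is scriptable from the shell:

```
cenmisloc simulate --seed 1 --outdir sim/
cenmisloc call-regions --mut sim/mut.bedgraph --wt sim/wt.bedgraph \
    --spikes sim/spikes.tsv --out regions.bed
cenmisloc proximity-test --regions regions.bed \
    --centromeres sim/centromeres.bed --chrom-sizes sim/chrom.sizes
cenmisloc run-all --seed 1 --outdir results/
```

with `normalize`, `global-fold`, `metagene`, `ma-curve` and
`qpcr summarize|ratio` covering the remaining stages. Tracks travel as
bedGraph (with a JSON sidecar recording scale and spacing), regions as
BED5, genes as GFF3 with `expression` attributes, qPCR tables as TSV.

## Layout

- `cenmisloc.genome` — synthetic genome model and centromere-distance gene subsets
- `cenmisloc.simulate` — probe-track, spike-in and qPCR simulators
- `cenmisloc.normalize` — spike-in scaling, ratio tracks, running averages, global fold change
- `cenmisloc.domains` — enriched-region calling
- `cenmisloc.proximity` — proximal genome fraction and hypergeometric testing
- `cenmisloc.metagene` — expression classes, TSS-aligned profiles, moving-average curves
- `cenmisloc.qpcr` — percent-input quantification and replicate summaries
- `cenmisloc.io`, `cenmisloc.config`, `cenmisloc.pipeline`, `cenmisloc.cli` — formats, configuration, the end-to-end pipeline and its CLI

See `docs/methods.md` for the statistical model, parameter choices and
known limitations.
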