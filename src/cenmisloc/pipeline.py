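"""End-to-end pipeline: simulate → spike-normalize → ratio → (smooth) →
call regions → proximity test → metagene + moving-average curve.

Every stage draws its randomness from the single config seed; a fixed seed
reproduces the results directory byte for byte. Outputs are standard
plain-text formats plus a machine-readable manifest of inputs, parameters
and stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, write_config
from .domains import EnrichedRegion, call_enriched_regions, genome_wide_average
from .genome import GenomeConfig, GenomeModel, build_genome_model
from .io import (
    write_chrom_sizes,
    write_genes,
    write_intervals_bed,
    write_regions,
    write_track,
)
from .metagene import (
    MetageneProfile,
    gene_body_mean_signal,
    metagene_profile,
    occupancy_vs_expression,
    tss_aligned_matrix,
)
from .normalize import (
    estimate_global_fold_change,
    ratio_track,
    running_average,
    scale_by_spike_ins,
)
from .proximity import ProximityEnrichmentResult, test_proximity_enrichment
from .simulate import (
    ProbeTrack,
    SimulationParams,
    SpikeInSet,
    plant_domains,
    simulate_probe_tracks,
)

logger = logging.getLogger("cenmisloc")

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class PipelineResult:
    genome: GenomeModel
    wt: ProbeTrack
    mut: ProbeTrack
    spikes: SpikeInSet
    ratio: ProbeTrack
    regions: list[EnrichedRegion]
    proximity: ProximityEnrichmentResult
    profile: MetageneProfile
    ma_curve: pd.DataFrame
    global_fold_estimate: float
    outdir: Path | None


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapper

    return decorate


def run_pipeline(config: AnalysisConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the whole analysis on a simulated dataset under ``config``.

    When ``outdir`` is given, writes the genome annotation, called regions,
    proximity statistics, metagene profile, moving-average curve, the exact
    config used and a manifest with stage counts (and the raw tracks when
    ``config.write_tracks``).
    """
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, 3)

    genome = _stage("genome")(build_genome_model)(
        GenomeConfig(n_genes=config.n_genes), seed=int(seeds[0])
    )
    logger.info("genome: %d chromosomes, %d genes", len(genome.chromosomes), len(genome.genes))

    domains = _stage("plant-domains")(plant_domains)(
        genome,
        n_proximal=config.n_proximal_domains,
        n_distal=config.n_distal_domains,
        width=config.domain_width,
        fold=config.domain_fold,
        window=config.proximity_window,
        seed=int(seeds[1]),
    )
    params = SimulationParams(
        seed=int(seeds[2]),
        probe_spacing=config.probe_spacing,
        noise_sd=config.noise_sd,
        domains=domains,
        global_fold=config.global_fold,
        depletion_slope=config.depletion_slope,
    )
    wt, mut, spikes = _stage("simulate")(simulate_probe_tracks)(genome, params)
    logger.info("simulate: %d probes (%d spike-in), %d planted domains",
                wt.n_probes, len(spikes.indices), len(domains))

    wt_n = _stage("normalize")(scale_by_spike_ins)(wt, spikes)
    mut_n = _stage("normalize")(scale_by_spike_ins)(mut, spikes)
    global_fold_est = _stage("normalize")(estimate_global_fold_change)(mut, wt, spikes)
    logger.info("normalize: global fold-change estimate %.3f", global_fold_est)

    ratio = _stage("ratio")(ratio_track)(mut_n, wt_n, "linear")
    call_input = ratio
    if config.smooth:
        call_input = _stage("smooth")(running_average)(ratio, config.smoothing_window)

    regions = _stage("call-regions")(call_enriched_regions)(
        call_input,
        min_length=config.min_region_length,
        fold_threshold=config.fold_threshold,
        max_gap=config.max_gap,
    )
    logger.info("call-regions: %d regions above %.2f x genome-wide average (%.4f)",
                len(regions), config.fold_threshold, genome_wide_average(call_input))

    if not regions:
        raise PipelineError(
            "stage 'proximity-test': no enriched regions were called "
            f"(fold_threshold={config.fold_threshold}); nothing to test"
        )
    proximity = _stage("proximity-test")(test_proximity_enrichment)(
        regions, genome, window=config.proximity_window, bin_size=config.proximity_bin
    )
    logger.info("proximity-test: %d/%d proximal, log10 p = %.1f",
                proximity.k_proximal, proximity.n_regions, proximity.log10_p)

    log_ratio = ratio.to_log2()
    matrix = _stage("metagene")(tss_aligned_matrix)(
        log_ratio,
        genome.genes,
        upstream=config.metagene_upstream,
        downstream=config.metagene_downstream,
        bin_size=config.metagene_bin,
    )
    classes = {g.id: g.expression_class for g in genome.genes}
    profile = _stage("metagene")(metagene_profile)(matrix, classes, config.ci_level)

    occupancy = _stage("ma-curve")(gene_body_mean_signal)(log_ratio, genome.genes)
    expression = pd.Series({g.id: g.expression_value for g in genome.genes})
    keep = occupancy.notna()
    ma_curve = _stage("ma-curve")(occupancy_vs_expression)(
        occupancy[keep].to_numpy(),
        expression[keep].to_numpy(),
        window=config.ma_window,
        step=config.ma_step,
    )
    logger.info("metagene: %d genes profiled; ma-curve: %d points",
                matrix.shape[0], len(ma_curve))

    out_path: Path | None = None
    if outdir is not None:
        out_path = Path(outdir)
        _write_results(out_path, config, genome, wt, mut, ratio, regions,
                       proximity, profile, ma_curve, global_fold_est)

    return PipelineResult(
        genome=genome,
        wt=wt,
        mut=mut,
        spikes=spikes,
        ratio=ratio,
        regions=regions,
        proximity=proximity,
        profile=profile,
        ma_curve=ma_curve,
        global_fold_estimate=global_fold_est,
        outdir=out_path,
    )


def _write_results(outdir, config, genome, wt, mut, ratio, regions,
                   proximity, profile, ma_curve, global_fold_est) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_config(config, outdir / "config.txt")
    write_genes(genome.genes, outdir / "genes.gff3")
    write_intervals_bed(genome.centromeres, outdir / "centromeres.bed", "cen")
    write_intervals_bed(genome.subtelomeres, outdir / "subtelomeres.bed", "subtel")
    write_chrom_sizes(genome, outdir / "chrom.sizes")
    write_regions(regions, outdir / "regions.bed")
    (outdir / "proximity.json").write_text(
        json.dumps(dataclasses.asdict(proximity), indent=2) + "\n"
    )
    profile.data.to_csv(outdir / "metagene.tsv", sep="\t", index=False)
    ma_curve.to_csv(outdir / "ma_curve.tsv", sep="\t", index=False)
    if config.write_tracks:
        write_track(wt, outdir / "wt.bedgraph")
        write_track(mut, outdir / "mut.bedgraph")
        write_track(ratio, outdir / "ratio.bedgraph")
    manifest = {
        "package": "cenmisloc",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "counts": {
            "n_probes": int(wt.n_probes),
            "n_genes": len(genome.genes),
            "n_regions": len(regions),
            "k_proximal": proximity.k_proximal,
        },
        "global_fold_estimate": global_fold_est,
        "proximity_log10_p": proximity.log10_p,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
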