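import numpy as np
import pytest

from cenmisloc import (
    AnalysisConfig,
    GenomeConfig,
    ProbeTrack,
    SimulationParams,
    build_genome_model,
    call_enriched_regions,
    plant_domains,
    ratio_track,
    scale_by_spike_ins,
    simulate_probe_tracks,
    test_proximity_enrichment,
)


def _make_track(values, spacing=100, chrom="I", scale="linear"):
    values = np.asarray(values, dtype=float)
    positions = np.arange(values.size) * spacing
    return ProbeTrack(
        np.full(values.size, chrom, dtype=object), positions, values, scale, spacing
    )


@pytest.fixture
def make_track():
    """Factory for single-chromosome tracks on a regular grid."""
    return _make_track


@pytest.fixture(scope="session")
def small_genome_config():
    """A 1-Mb two-chromosome genome with balanced expression classes."""
    return GenomeConfig(
        chromosome_lengths=(("A", 600_000), ("B", 400_000)),
        centromere_spans=(20_000, 20_000),
        subtelomere_length=10_000,
        n_genes=300,
        class_weights=(1, 1, 1, 1, 1),
    )


@pytest.fixture(scope="session")
def small_genome(small_genome_config):
    return build_genome_model(small_genome_config, seed=11)


@pytest.fixture(scope="session")
def default_genome():
    """The full-scale default fixture genome (12.57 Mb, 5073 genes)."""
    return build_genome_model(seed=1)


@pytest.fixture(scope="session")
def planted_experiment(default_genome):
    """Full-scale planted-domain experiment: 168 two-kb 6-fold domains
    (96 centromere-proximal), 20-bp probes, log2 noise sd 0.25, seed 1."""
    genome = default_genome
    domains = plant_domains(
        genome, n_proximal=96, n_distal=72, width=2000, fold=6.0,
        window=100_000, seed=1,
    )
    params = SimulationParams(seed=1, probe_spacing=20, noise_sd=0.25, domains=domains)
    wt, mut, spikes = simulate_probe_tracks(genome, params)
    ratio = ratio_track(
        scale_by_spike_ins(mut, spikes), scale_by_spike_ins(wt, spikes), "linear"
    )
    regions = call_enriched_regions(ratio, min_length=1000, fold_threshold=2.0, max_gap=0)
    proximity = test_proximity_enrichment(regions, genome, window=100_000, bin_size=1000)
    return {
        "genome": genome,
        "domains": domains,
        "wt": wt,
        "mut": mut,
        "spikes": spikes,
        "ratio": ratio,
        "regions": regions,
        "proximity": proximity,
    }


@pytest.fixture
def small_config():
    """Pipeline config scaled to the small genome for fast end-to-end runs."""
    return AnalysisConfig(
        seed=5,
        n_genes=300,
        probe_spacing=50,
        n_proximal_domains=10,
        n_distal_domains=8,
        ma_window=50,
    )
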