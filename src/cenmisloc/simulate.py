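"""Tiling-array and ChIP-qPCR simulator.

Emulates two-condition (wild-type vs mutant) ChIP-chip experiments on the
synthetic genome: regularly spaced probes carrying linear-scale occupancy
signal with multiplicative (log2-additive Gaussian) noise, exogenous
spike-in control probes of known condition-invariant abundance on a
separate virtual contig, planted enrichment domains, a global chromosomal
fold multiplier, and expression-proportional signal depletion over gene
bodies. Also simulates replicate percent-input qPCR measurements with
lognormal multiplicative noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .genome import GenomeModel, largest_remainder
from .qpcr import QPCRSample

__all__ = [
    "SPIKE_CONTIG",
    "ProbeTrack",
    "SpikeInSet",
    "PlantedDomain",
    "SimulationParams",
    "plant_domains",
    "simulate_probe_tracks",
    "simulate_qpcr",
]

#: name of the virtual contig holding spike-in control probes
SPIKE_CONTIG = "spikein"


@dataclass
class ProbeTrack:
    """Ordered probe-level signal with a declared scale.

    Probes are stored contiguously per chromosome with strictly increasing
    positions; ``scale`` is ``"linear"`` (values > 0) or ``"log2"``
    (unbounded). ``spacing`` is the nominal distance between adjacent
    probes within a chromosome.
    """

    chroms: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    scale: str
    spacing: int

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.chroms) == len(self.positions) == len(self.values)):
            raise ValueError("chroms, positions, values must be equal length")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        for _, sl in self.chrom_blocks():
            if np.any(np.diff(self.positions[sl]) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        if self.scale == "linear" and self.n_probes and np.any(self.values <= 0):
            raise ValueError("linear-scale values must be > 0")

    @property
    def n_probes(self) -> int:
        return len(self.values)

    def chrom_blocks(self) -> Iterator[tuple[str, slice]]:
        """Yield (chromosome, slice) for each contiguous chromosome block."""
        n = len(self.chroms)
        start = 0
        while start < n:
            name = self.chroms[start]
            end = start + 1
            while end < n and self.chroms[end] == name:
                end += 1
            yield str(name), slice(start, end)
            start = end

    def chromosomal_mask(self) -> np.ndarray:
        """True for genomic probes, False for spike-in control probes."""
        return self.chroms != SPIKE_CONTIG

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ProbeTrack":
        return ProbeTrack(
            self.chroms, self.positions, values, scale or self.scale, self.spacing
        )

    def to_linear(self) -> "ProbeTrack":
        if self.scale == "linear":
            return self
        return self.with_values(np.exp2(self.values), "linear")

    def to_log2(self) -> "ProbeTrack":
        if self.scale == "log2":
            return self
        return self.with_values(np.log2(self.values), "log2")

    def same_grid(self, other: "ProbeTrack") -> bool:
        return (
            self.spacing == other.spacing
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.chroms, other.chroms)
        )


@dataclass
class SpikeInSet:
    """Spike-in control probes: indices into a ProbeTrack plus their known,
    condition-invariant reference abundances (linear scale)."""

    indices: np.ndarray
    reference_values: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        if len(self.indices) != len(self.reference_values):
            raise ValueError("indices and reference_values must be equal length")
        if len(self.indices) and np.any(self.reference_values <= 0):
            raise ValueError("spike-in reference values must be > 0")


@dataclass(frozen=True)
class PlantedDomain:
    """A planted enrichment domain: ``[start, end)`` at a uniform linear fold."""

    chrom: str
    start: int
    end: int
    fold: float
    proximal: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("domain end must exceed start")
        if self.fold <= 0:
            raise ValueError("domain fold must be > 0")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class SimulationParams:
    """Parameters of the two-condition array simulation.

    ``noise_sd`` is the per-probe Gaussian sd on the log2 scale (the noise
    is multiplicative on linear signal, keeping it positive).
    ``global_fold`` multiplies all mutant chromosomal (not spike-in) signal.
    ``depletion_slope`` is the log2 change of mutant gene-body signal per
    expression a.u. (negative values deplete transcribed genes).
    ``wt_scale``/``mut_scale`` are per-array efficiency factors applied to
    everything including spikes — what spike-in normalization removes.
    """

    seed: int
    probe_spacing: int = 20
    noise_sd: float = 0.25
    domains: tuple[PlantedDomain, ...] = ()
    global_fold: float = 1.0
    depletion_slope: float = 0.0
    n_spike_probes: int = 400
    spike_levels: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    wt_scale: float = 1.0
    mut_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.global_fold <= 0 or self.wt_scale <= 0 or self.mut_scale <= 0:
            raise ValueError("folds and array scales must be > 0")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        if any(level <= 0 for level in self.spike_levels):
            raise ValueError("spike levels must be > 0")
        self.domains = tuple(
            sorted(self.domains, key=lambda d: (d.chrom, d.start))
        )
        by_chrom: dict[str, list[PlantedDomain]] = {}
        for d in self.domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        for ds in by_chrom.values():
            for a, b in zip(ds, ds[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping planted domains on {a.chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )


def _even_centers(
    lo: float, hi: float, q: int, min_spacing: int, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """q jittered centers evenly spread over [lo, hi] with pairwise spacing
    >= min_spacing."""
    if q == 1:
        return np.array([(lo + hi) / 2 + rng.uniform(-jitter, jitter)])
    pitch = (hi - lo) / (q - 1)
    if pitch - 2 * jitter < min_spacing:
        raise ValueError(
            f"cannot place {q} domains with spacing >= {min_spacing} bp "
            f"in a {hi - lo:.0f} bp span"
        )
    return lo + pitch * np.arange(q) + rng.uniform(-jitter, jitter, q)


def plant_domains(
    genome: GenomeModel,
    n_proximal: int = 96,
    n_distal: int = 72,
    width: int = 2000,
    fold: float = 6.0,
    window: int = 100_000,
    min_center_spacing: int = 6000,
    seed: int | None = None,
) -> tuple[PlantedDomain, ...]:
    """Place non-overlapping enrichment domains on the genome.

    ``n_proximal`` domains have midpoints within ``window`` bp of a
    centromere edge (spread over the 2×3 flanks, apportioned by flank
    length); ``n_distal`` domains sit on the distal arms, at least
    ``window`` + 5 kb away from any centromere edge and 10 kb from
    chromosome ends. Center-to-center spacing is kept >= ``min_center_spacing``.
    Deterministic per seed (small jitter around even placement).
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    margin = 5000
    half = width / 2
    jitter = 100.0

    flanks: list[tuple[str, int, int]] = []
    for chrom, cs, ce in genome.centromeres:
        length = genome.chrom_length(chrom)
        left = (chrom, max(0, cs - window), cs)
        right = (chrom, ce, min(length, ce + window))
        flanks.extend([left, right])
    distal: list[tuple[str, int, int]] = []
    for chrom, length in genome.chromosomes:
        cursor = 10_000
        for cs, ce in sorted(genome.centromeres_of(chrom)):
            stop = cs - window - margin
            if stop > cursor:
                distal.append((chrom, cursor, stop))
            cursor = max(cursor, ce + window + margin)
        if length - 10_000 > cursor:
            distal.append((chrom, cursor, length - 10_000))

    domains: list[PlantedDomain] = []
    for intervals, total, proximal in ((flanks, n_proximal, True), (distal, n_distal, False)):
        if total == 0:
            continue
        lengths = [e - s for _, s, e in intervals]
        per = largest_remainder(total, lengths)
        for (chrom, s, e), q in zip(intervals, per):
            if q == 0:
                continue
            centers = _even_centers(
                s + half + jitter, e - half - jitter, q, min_center_spacing, jitter, rng
            )
            for c in centers:
                start = int(round(c - half))
                domains.append(
                    PlantedDomain(chrom, start, start + width, fold, proximal)
                )
    return tuple(sorted(domains, key=lambda d: (d.chrom, d.start)))


def _chromosome_positions(genome: GenomeModel, spacing: int) -> list[tuple[str, np.ndarray]]:
    out = []
    for chrom, length in genome.chromosomes:
        if length % spacing:
            raise ValueError(
                f"probe spacing {spacing} does not tile chromosome {chrom} "
                f"(length {length}) evenly"
            )
        out.append((chrom, np.arange(0, length, spacing, dtype=np.int64)))
    return out


def simulate_probe_tracks(
    genome: GenomeModel, params: SimulationParams
) -> tuple[ProbeTrack, ProbeTrack, SpikeInSet]:
    """Simulate wild-type and mutant linear-scale probe tracks plus spikes.

    Wild-type chromosomal baseline is 1.0; the mutant is baseline ×
    ``global_fold`` × planted-domain fold × ``2^(depletion_slope × expression)``
    over gene bodies. Per-probe Gaussian noise of sd ``noise_sd`` is added
    on the log2 scale, independently per condition. Spike-in probes share
    the reference abundances between conditions (identical in expectation
    when the array scales are equal) and are appended on the virtual
    ``spikein`` contig.
    """
    rng = np.random.default_rng(params.seed)
    lengths = dict(genome.chromosomes)
    for d in params.domains:
        if d.chrom not in lengths or not (0 <= d.start < d.end <= lengths[d.chrom]):
            raise ValueError(f"planted domain outside the genome: {d}")

    blocks = _chromosome_positions(genome, params.probe_spacing)
    chrom_arrays, pos_arrays, mut_mult_arrays = [], [], []
    for chrom, pos in blocks:
        mult = np.full(pos.size, params.global_fold)
        for d in params.domains:
            if d.chrom == chrom:
                i0, i1 = np.searchsorted(pos, (d.start, d.end))
                mult[i0:i1] *= d.fold
        if params.depletion_slope != 0.0:
            for gene in genome.genes:
                if gene.chrom != chrom:
                    continue
                i0, i1 = np.searchsorted(pos, (gene.start, gene.end))
                mult[i0:i1] *= 2.0 ** (params.depletion_slope * gene.expression_value)
        chrom_arrays.append(np.full(pos.size, chrom, dtype=object))
        pos_arrays.append(pos)
        mut_mult_arrays.append(mult)

    n_chromosomal = sum(p.size for p in pos_arrays)
    wt_base = np.ones(n_chromosomal)
    mut_base = np.concatenate(mut_mult_arrays) if mut_mult_arrays else np.empty(0)

    n_spikes = params.n_spike_probes
    reps = largest_remainder(n_spikes, np.ones(len(params.spike_levels)))
    spike_refs = np.repeat(np.asarray(params.spike_levels, dtype=float), reps)

    def noisy(base: np.ndarray, scale: float) -> np.ndarray:
        noise = rng.normal(0.0, params.noise_sd, base.size) if params.noise_sd else 0.0
        return base * scale * np.exp2(noise)

    wt_chrom = noisy(wt_base, params.wt_scale)
    mut_chrom = noisy(mut_base, params.mut_scale)
    wt_spike = noisy(spike_refs, params.wt_scale)
    mut_spike = noisy(spike_refs, params.mut_scale)

    chroms = np.concatenate(
        chrom_arrays + [np.full(n_spikes, SPIKE_CONTIG, dtype=object)]
    )
    positions = np.concatenate(
        pos_arrays
        + [np.arange(0, n_spikes * params.probe_spacing, params.probe_spacing)]
    )
    wt = ProbeTrack(
        chroms, positions, np.concatenate([wt_chrom, wt_spike]), "linear",
        params.probe_spacing,
    )
    mut = wt.with_values(np.concatenate([mut_chrom, mut_spike]))
    spikes = SpikeInSet(
        np.arange(n_chromosomal, n_chromosomal + n_spikes), spike_refs
    )
    return wt, mut, spikes


def simulate_qpcr(
    true_percent_ip: float,
    n_replicates: int = 3,
    cv: float = 0.05,
    seed: int | None = None,
    locus: str = "locus",
    antibody: str = "antibody",
) -> QPCRSample:
    """Replicate %IP measurements under multiplicative lognormal noise.

    Each replicate is the true value times a unit-mean lognormal factor with
    coefficient of variation ``cv``; deterministic per seed.
    """
    if not 0 < true_percent_ip <= 100:
        raise ValueError("true_percent_ip must be in (0, 100]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    if cv == 0:
        values = np.full(n_replicates, true_percent_ip)
    else:
        sigma = math.sqrt(math.log1p(cv**2))
        values = true_percent_ip * rng.lognormal(-sigma**2 / 2, sigma, n_replicates)
    return QPCRSample(locus=locus, antibody=antibody, replicates=values)
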