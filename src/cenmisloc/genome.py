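"""Synthetic genome model: chromosomes, centromeres, subtelomeres and
expression-annotated genes.

The model is a stand-in for the fission-yeast genome at its familiar scale
(three chromosomes totalling 12.57 Mb, one regional centromere per
chromosome). It is the coordinate frame for every downstream analysis:
probe tracks, enriched-region calls, proximity statistics and metagene
profiles all refer to its intervals. All coordinates are 0-based half-open
(BED convention); writers convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .metagene import classify_expression, EXPRESSION_CLASSES

__all__ = [
    "GeneAnnotation",
    "GenomeModel",
    "GenomeConfig",
    "build_genome_model",
    "proximal_gene_subset",
    "interval_gap",
    "non_centromeric_intervals",
]

#: default class weights ordered very_low .. very_high (observed group sizes
#: on the 5–15 a.u. expression scale: 815, 1904, 1726, 591, 37 of 5073 genes)
DEFAULT_CLASS_WEIGHTS = (815, 1904, 1726, 591, 37)

# sampling bands per class on the expression scale; high is closed at 14,
# very_high strictly above 14, very_low strictly below 8
_CLASS_BANDS = {
    "very_low": (5.0, 8.0),
    "low": (8.0, 10.0),
    "medium": (10.0, 12.0),
    "high": (12.0, 14.0),
    "very_high": (math.nextafter(14.0, 15.0), 15.0),
}


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with strand-aware TSS/TES and an expression annotation.

    ``tss``/``tes`` are 0-based; on the + strand ``tss < tes`` and the gene
    occupies ``[tss, tes)``; on the − strand ``tss > tes`` and the gene
    occupies ``[tes, tss)``.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    expression_value: float
    expression_class: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.id}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"+ strand gene {self.id} must have tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"- strand gene {self.id} must have tss > tes")
        if not (5.0 <= self.expression_value <= 15.0):
            raise ValueError(
                f"expression value {self.expression_value} of gene {self.id} "
                "outside the 5–15 a.u. scale"
            )
        expected = classify_expression(self.expression_value)
        if expected != self.expression_class:
            raise ValueError(
                f"gene {self.id}: class {self.expression_class!r} inconsistent "
                f"with value {self.expression_value} (expected {expected!r})"
            )

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


@dataclass
class GenomeModel:
    """Chromosomes, centromeres, subtelomeres and genes."""

    chromosomes: list[tuple[str, int]]
    centromeres: list[tuple[str, int, int]]
    subtelomeres: list[tuple[str, int, int]]
    genes: list[GeneAnnotation]

    def __post_init__(self) -> None:
        self.validate()

    def chrom_length(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def centromeres_of(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.centromeres if c == chrom]

    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, start, end in self.centromeres + self.subtelomeres:
            if name not in lengths:
                raise ValueError(f"interval on unknown chromosome {name!r}")
            if not (0 <= start < end <= lengths[name]):
                raise ValueError(
                    f"interval {name}:{start}-{end} outside chromosome bounds"
                )
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for name, start, end in self.centromeres:
            per_chrom.setdefault(name, []).append((start, end))
        for name, ivals in per_chrom.items():
            if len(ivals) > 1:
                raise ValueError(f"more than one centromere on {name}")
        for gene in self.genes:
            if gene.chrom not in lengths:
                raise ValueError(f"gene {gene.id} on unknown chromosome")
            if not (0 <= gene.start < gene.end <= lengths[gene.chrom]):
                raise ValueError(f"gene {gene.id} outside chromosome bounds")
            for cs, ce in self.centromeres_of(gene.chrom):
                if gene.start < ce and cs < gene.end:
                    raise ValueError(f"gene {gene.id} overlaps a centromere")


@dataclass(frozen=True)
class GenomeConfig:
    """Fixture parameters for :func:`build_genome_model`.

    Defaults: 3 chromosomes of 5.58 / 4.54 / 2.45 Mb (12.57 Mb total) with
    centromeres of 40 / 65 / 110 kb at the chromosome midpoints and 50-kb
    subtelomeres, carrying 5073 genes whose expression classes follow the
    observed 815:1904:1726:591:37 split (very_low .. very_high).
    """

    chromosome_lengths: tuple[tuple[str, int], ...] = (
        ("I", 5_580_000),
        ("II", 4_540_000),
        ("III", 2_450_000),
    )
    centromere_spans: tuple[int, ...] = (40_000, 65_000, 110_000)
    subtelomere_length: int = 50_000
    n_genes: int = 5073
    class_weights: tuple[float, ...] = DEFAULT_CLASS_WEIGHTS

    def __post_init__(self) -> None:
        if len(self.centromere_spans) != len(self.chromosome_lengths):
            raise ValueError("one centromere span per chromosome required")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if len(self.class_weights) != len(EXPRESSION_CLASSES):
            raise ValueError("one weight per expression class required")


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they touch/overlap."""
    return max(0, b_start - a_end, a_start - b_end)


def non_centromeric_intervals(genome: GenomeModel) -> list[tuple[str, int, int]]:
    """Maximal per-chromosome intervals outside centromere bodies ("arms")."""
    out: list[tuple[str, int, int]] = []
    for name, length in genome.chromosomes:
        cursor = 0
        for cs, ce in sorted(genome.centromeres_of(name)):
            if cs > cursor:
                out.append((name, cursor, cs))
            cursor = max(cursor, ce)
        if cursor < length:
            out.append((name, cursor, length))
    return out


def largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``total`` items across bins proportionally to ``weights``.

    Exact (sums to ``total``) and deterministic: ties on the fractional part
    are broken toward earlier bins.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    if remainder:
        order = np.lexsort((np.arange(len(weights)), -(quota - counts)))
        counts[order[:remainder]] += 1
    return counts.tolist()


def _sample_expression(
    n_genes: int, class_weights: Sequence[float], rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    quotas = largest_remainder(n_genes, class_weights)
    labels = np.repeat(np.array(EXPRESSION_CLASSES, dtype=object), quotas)
    rng.shuffle(labels)
    values = np.empty(n_genes)
    for cls in EXPRESSION_CLASSES:
        lo, hi = _CLASS_BANDS[cls]
        mask = labels == cls
        values[mask] = rng.uniform(lo, hi, mask.sum())
    return values, labels.tolist()


def build_genome_model(
    config: GenomeConfig | None = None, seed: int | None = None
) -> GenomeModel:
    """Build the synthetic genome deterministically from ``seed``.

    Genes are tiled without overlap on the chromosome arms (never across a
    centromere), apportioned to arms by length; expression classes receive
    exact largest-remainder quotas so the default model reproduces the
    815:1904:1726:591:37 split, and per-gene values are drawn uniformly
    within each class band.
    """
    if config is None:
        config = GenomeConfig()
    if seed is None:
        raise ValueError("a seed is required (the model is a random fixture)")
    rng = np.random.default_rng(seed)

    chromosomes = list(config.chromosome_lengths)
    centromeres = []
    for (name, length), span in zip(chromosomes, config.centromere_spans):
        start = (length - span) // 2
        centromeres.append((name, start, start + span))
    subtelomeres = []
    for name, length in chromosomes:
        st = min(config.subtelomere_length, length // 2)
        subtelomeres.append((name, 0, st))
        subtelomeres.append((name, length - st, length))

    genome = GenomeModel(chromosomes, centromeres, subtelomeres, genes=[])
    if config.n_genes == 0:
        return genome

    arms = non_centromeric_intervals(genome)
    arm_lengths = [end - start for _, start, end in arms]
    per_arm = largest_remainder(config.n_genes, arm_lengths)

    values, labels = _sample_expression(config.n_genes, config.class_weights, rng)
    genes: list[GeneAnnotation] = []
    idx = 0
    min_pitch = 300  # smallest slot that still fits a gene plus margin
    for (chrom, astart, aend), n_arm in zip(arms, per_arm):
        if n_arm == 0:
            continue
        pitch = (aend - astart) // n_arm
        if pitch < min_pitch:
            raise ValueError(
                f"infeasible packing: {n_arm} genes in a {aend - astart} bp arm "
                f"of {chrom} leaves {pitch} bp per gene (need >= {min_pitch})"
            )
        for i in range(n_arm):
            slot_start = astart + i * pitch
            glen = int(pitch * rng.uniform(0.4, 0.7))
            glen = max(200, min(glen, pitch - 50))
            offset = int(rng.integers(0, pitch - glen + 1))
            gstart = slot_start + offset
            gend = gstart + glen
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (gstart, gend) if strand == "+" else (gend, gstart)
            genes.append(
                GeneAnnotation(
                    id=f"gene{idx + 1:05d}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    expression_value=float(values[idx]),
                    expression_class=labels[idx],
                )
            )
            idx += 1
    return GenomeModel(chromosomes, centromeres, subtelomeres, genes)


def gene_centromere_distance(genome: GenomeModel, gene: GeneAnnotation) -> float:
    """bp gap between a gene's span and the nearest same-chromosome centromere."""
    cens = genome.centromeres_of(gene.chrom)
    if not cens:
        return math.inf
    return min(interval_gap(gene.start, gene.end, cs, ce) for cs, ce in cens)


def proximal_gene_subset(
    genome: GenomeModel, distance: int = 100_000
) -> list[GeneAnnotation]:
    """Genes whose span lies within ``distance`` bp of a centromere edge.

    Distance is measured from the gene's closest coordinate to the nearest
    centromere edge; the boundary is inclusive, and overlapping/abutting
    genes have distance 0.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return [
        g for g in genome.genes if gene_centromere_distance(genome, g) <= distance
    ]
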