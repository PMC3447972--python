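"""Spatial association of called regions with centromeres.

Regions are classified proximal when their midpoint lies within a window of
the nearest centromere edge; significance of the proximal fraction is
assessed with a hypergeometric upper tail over a population of fixed-size
genomic bins tiling the non-centromeric genome, evaluated in log space so
p-values far below the linear-underflow regime stay exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .domains import EnrichedRegion
from .genome import GenomeModel, non_centromeric_intervals

__all__ = [
    "ProximityEnrichmentResult",
    "point_centromere_distance",
    "proximal_genome_fraction",
    "hypergeometric_tail",
    "log10_hypergeometric_tail",
    "test_proximity_enrichment",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ProximityEnrichmentResult:
    """Counts, genome fraction, and hypergeometric tail of region proximity."""

    n_regions: int
    k_proximal: int
    proportion: float
    genome_fraction: float
    p_value: float
    log10_p: float
    population_size: int
    proximal_population: int
    window: int
    bin_size: int


def point_centromere_distance(genome: GenomeModel, chrom: str, point: float) -> float:
    """Distance in bp from a point to the nearest centromere edge on its
    chromosome (0 inside a centromere; inf if the chromosome has none)."""
    cens = genome.centromeres_of(chrom)
    if not cens:
        return math.inf
    return min(max(0.0, cs - point, point - ce) for cs, ce in cens)


def proximal_genome_fraction(genome: GenomeModel, window: int = 100_000) -> float:
    """Fraction of the genome within ``window`` bp of a centromere edge.

    Counts the flanking intervals extending outward from each centromere
    edge, clipped to chromosome bounds and excluding centromere bodies.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if window == 0:
        return 0.0
    total = 0
    for chrom, length in genome.chromosomes:
        cens = sorted(genome.centromeres_of(chrom))
        flanks: list[tuple[int, int]] = []
        for cs, ce in cens:
            flanks.append((max(0, cs - window), cs))
            flanks.append((ce, min(length, ce + window)))
        # merge overlaps, then subtract centromere bodies
        flanks = [(s, e) for s, e in sorted(flanks) if e > s]
        merged: list[list[int]] = []
        for s, e in flanks:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            span = e - s
            for cs, ce in cens:
                span -= max(0, min(e, ce) - max(s, cs))
            total += span
    return total / genome.total_length


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``n`` draws from a population of ``N`` with ``K`` successes. The sum is
    accumulated in log space (exact down to the smallest positive float).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    if k > min(n, K):
        return 0.0
    return float(math.exp(_log_tail(k, n, K, N)))


def log10_hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """log10 of the hypergeometric upper tail (−inf when the tail is empty)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 0.0
    if k > min(n, K):
        return -math.inf
    return _log_tail(k, n, K, N) / _LN10


def _log_tail(k: int, n: int, K: int, N: int) -> float:
    xs = np.arange(k, min(n, K) + 1)
    return float(logsumexp(stats.hypergeom.logpmf(xs, N, K, n)))


def region_is_proximal(
    region: EnrichedRegion, genome: GenomeModel, window: int = 100_000
) -> bool:
    """True when the region midpoint lies within ``window`` bp of a
    centromere edge (boundary inclusive)."""
    return point_centromere_distance(genome, region.chrom, region.midpoint) <= window


def test_proximity_enrichment(
    regions: Sequence[EnrichedRegion],
    genome: GenomeModel,
    window: int = 100_000,
    bin_size: int = 1000,
) -> ProximityEnrichmentResult:
    """Test whether called regions concentrate near centromeres.

    ``k`` regions of ``n`` are proximal by the midpoint rule. The
    population is the set of ``bin_size`` bins tiling the non-centromeric
    genome (N bins, of which K have proximal midpoints); the p-value is the
    hypergeometric upper tail P(X >= k) of drawing that many proximal bins
    in n draws.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions to test: the region list is empty")
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    n = len(regions)
    k = sum(region_is_proximal(r, genome, window) for r in regions)

    N = 0
    K = 0
    for chrom, start, end in non_centromeric_intervals(genome):
        nb = (end - start) // bin_size
        if nb == 0:
            continue
        mids = start + (np.arange(nb) + 0.5) * bin_size
        cens = genome.centromeres_of(chrom)
        N += nb
        if cens:
            dist = np.full(nb, np.inf)
            for cs, ce in cens:
                d = np.maximum(0.0, np.maximum(cs - mids, mids - ce))
                dist = np.minimum(dist, d)
            K += int(np.count_nonzero(dist <= window))
    if N == 0:
        raise ValueError("genome has no non-centromeric bins")
    n_eff = min(n, N)
    k_eff = min(k, n_eff)
    p = hypergeometric_tail(k_eff, n_eff, K, N)
    log10_p = log10_hypergeometric_tail(k_eff, n_eff, K, N)
    return ProximityEnrichmentResult(
        n_regions=n,
        k_proximal=k,
        proportion=k / n,
        genome_fraction=proximal_genome_fraction(genome, window),
        p_value=p,
        log10_p=log10_p,
        population_size=N,
        proximal_population=K,
        window=window,
        bin_size=bin_size,
    )


# a library function, not a pytest test, despite the name
test_proximity_enrichment.__test__ = False
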