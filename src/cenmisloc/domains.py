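"""Enriched-domain calling on a linear-scale ratio track.

A probe is marked when its value strictly exceeds ``fold_threshold`` times
the genome-wide average; maximal runs of marked probes (optionally allowing
short internal gaps) whose span reaches the minimum length are reported as
enriched regions. The span convention includes one trailing probe spacing,
so an n-probe run at spacing s has length n × s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ProbeTrack

__all__ = ["EnrichedRegion", "genome_wide_average", "call_enriched_regions"]


@dataclass(frozen=True)
class EnrichedRegion:
    """A called enrichment domain, 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_probes: int | None
    mean_fold: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if self.n_probes is not None and self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def length(self) -> int:
        return self.end - self.start


def genome_wide_average(track: ProbeTrack) -> float:
    """Arithmetic mean over all chromosomal probes (spike probes excluded)."""
    if track.scale != "linear":
        raise ValueError("genome-wide average is defined on the linear scale")
    mask = track.chromosomal_mask()
    if not mask.any():
        raise ValueError("track has no chromosomal probes")
    return float(track.values[mask].mean())


def call_enriched_regions(
    track: ProbeTrack,
    min_length: int = 1000,
    fold_threshold: float = 2.0,
    max_gap: int = 0,
) -> list[EnrichedRegion]:
    """Call regions of at least ``min_length`` bp whose probes exceed
    ``fold_threshold`` × the genome-wide average.

    ``max_gap`` permits that many consecutive sub-threshold probes inside a
    run without splitting it (gap probes still count as region members).
    Regions are returned sorted by coordinate. The probe spacing must be
    uniform within each chromosome.
    """
    if min_length <= 0:
        raise ValueError("min_length must be > 0")
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    cutoff = fold_threshold * genome_wide_average(track)
    spacing = track.spacing
    regions: list[EnrichedRegion] = []
    for name, sl in track.chrom_blocks():
        if name == "spikein":
            continue
        pos = track.positions[sl]
        val = track.values[sl]
        diffs = np.diff(pos)
        if diffs.size and np.any(diffs != spacing):
            raise ValueError(f"mixed probe spacing within chromosome {name}")
        marked = np.flatnonzero(val > cutoff)
        if marked.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(marked) > max_gap + 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [marked.size - 1]))
        for a, b in zip(run_starts, run_ends):
            first, last = marked[a], marked[b]
            start = int(pos[first])
            end = int(pos[last]) + spacing
            if end - start < min_length:
                continue
            member = val[first : last + 1]
            regions.append(
                EnrichedRegion(
                    chrom=name,
                    start=start,
                    end=end,
                    n_probes=int(last - first + 1),
                    mean_fold=float(member.mean()),
                )
            )
    return regions
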