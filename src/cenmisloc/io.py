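"""Readers and writers for the standard plain-text dialects.

Tracks travel as 4-column bedGraph with a JSON sidecar recording scale and
spacing; regions as BED5 (score = mean fold × 100, rounded); centromeres
and subtelomeres as BED6; genes as GFF3 with ``expression`` /
``expression_class`` attributes. Internally everything is 0-based
half-open; GFF3 converts to 1-based closed on write and back on read.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .domains import EnrichedRegion
from .genome import GeneAnnotation, GenomeModel
from .qpcr import QPCRSample
from .simulate import ProbeTrack, SpikeInSet

__all__ = [
    "read_track",
    "write_track",
    "read_regions",
    "write_regions",
    "read_genes",
    "write_genes",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_spikes",
    "write_spikes",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_qpcr_table",
    "write_qpcr_summary",
]

_GFF_SOURCE = "cenmisloc"


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_track(track: ProbeTrack, path: str | Path) -> None:
    """Write a ProbeTrack as bedGraph plus a sidecar with scale/spacing."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "chrom": track.chroms,
            "start": track.positions,
            "end": track.positions + track.spacing,
            "value": track.values,
        }
    )
    # %.17g guarantees an exact binary round trip for doubles
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")
    _sidecar(path).write_text(
        json.dumps({"scale": track.scale, "spacing": track.spacing}) + "\n"
    )


def read_track(path: str | Path, declared_scale: str | None = None) -> ProbeTrack:
    """Read a bedGraph track; scale comes from the sidecar unless declared.

    Raises with the offending 1-based line number on malformed, unsorted or
    overlapping records; an empty file is an error, not an empty track.
    """
    path = Path(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    scale = declared_scale or meta.get("scale")
    if scale is None:
        raise ValueError(f"{path}: no sidecar metadata; pass declared_scale")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            comment="#",
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty bedGraph file") from None
    except (ValueError, pd.errors.ParserError):
        _locate_bad_line(path, n_fields=4)
        raise
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph file")
    for col in ("start", "end", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(
                f"{path}: malformed {col} field at line {int(bad.idxmax()) + 1}"
            )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["end"] <= df["start"]
    if bad.any():
        raise ValueError(f"{path}: end <= start at line {int(bad.idxmax()) + 1}")
    spacing = meta.get("spacing")
    if spacing is None:
        spacing = int((df["end"] - df["start"]).iloc[0])
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            i = int(np.flatnonzero(np.diff(starts) <= 0)[0])
            line = int(sub.index[i + 1]) + 1
            raise ValueError(f"{path}: unsorted interval on {chrom} at line {line}")
        if np.any(starts[1:] < ends[:-1]):
            i = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
            line = int(sub.index[i + 1]) + 1
            raise ValueError(f"{path}: overlapping interval on {chrom} at line {line}")
    return ProbeTrack(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(),
        df["value"].to_numpy(dtype=float),
        scale,
        int(spacing),
    )


def _locate_bad_line(path: Path, n_fields: int) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != n_fields:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected {n_fields} "
                    f"tab-separated fields"
                )


def write_regions(regions: Sequence[EnrichedRegion], path: str | Path) -> None:
    """Write enriched regions as BED5 (name = index, score = mean_fold × 100)."""
    rows = [
        (r.chrom, r.start, r.end, f"region_{i + 1}", int(round(r.mean_fold * 100)))
        for i, r in enumerate(regions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_regions(path: str | Path) -> list[EnrichedRegion]:
    """Read BED5 regions (mean_fold recovered from score/100; n_probes unknown)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score"],
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return []
    bad = df["end"] <= df["start"]
    if bad.any():
        raise ValueError(f"{path}: end <= start at line {int(bad.idxmax()) + 1}")
    return [
        EnrichedRegion(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            n_probes=None,
            mean_fold=float(row.score) / 100.0,
        )
        for row in df.itertuples()
    ]


def write_intervals_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | Path, prefix: str = "ival"
) -> None:
    """Write (chrom, start, end) intervals as BED6."""
    rows = [
        (chrom, start, end, f"{prefix}_{i + 1}", 0, ".")
        for i, (chrom, start, end) in enumerate(intervals)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int]]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    bad = df[2] <= df[1]
    if bad.any():
        raise ValueError(f"{path}: end <= start at line {int(bad.idxmax()) + 1}")
    return [(str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)]


def write_genes(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write genes as GFF3 (1-based closed) with expression attributes."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = (
            f"ID={g.id};expression={g.expression_value!r};"
            f"expression_class={g.expression_class}"
        )
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    _GFF_SOURCE,
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read GFF3 gene records back into annotations (exact coordinate
    round trip: GFF start − 1 → internal start)."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            start = int(start1) - 1
            end = int(end1)
            if end <= start:
                raise ValueError(f"{path}: non-positive span at line {lineno}")
            kv = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(
                GeneAnnotation(
                    id=kv.get("ID", f"gene_line{lineno}"),
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    expression_value=float(kv["expression"]),
                    expression_class=kv["expression_class"],
                )
            )
    return genes


def write_spikes(spikes: SpikeInSet, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_index": spikes.indices, "reference_value": spikes.reference_values}
    ).to_csv(path, sep="\t", index=False)


def read_spikes(path: str | Path) -> SpikeInSet:
    df = pd.read_csv(path, sep="\t")
    return SpikeInSet(
        df["probe_index"].to_numpy(), df["reference_value"].to_numpy()
    )


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    pd.DataFrame(genome.chromosomes).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    return [(str(r[0]), int(r[1])) for r in df.itertuples(index=False)]


def read_qpcr_table(path: str | Path) -> list[QPCRSample]:
    """Read a qPCR TSV: locus, antibody, then one column per replicate %IP."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "antibody"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: qPCR table needs columns {sorted(required)}")
    rep_cols = [c for c in df.columns if c not in required]
    samples = []
    for row in df.itertuples(index=False):
        values = [getattr(row, c) for c in rep_cols]
        values = [v for v in values if pd.notna(v)]
        samples.append(
            QPCRSample(locus=row.locus, antibody=row.antibody, replicates=values)
        )
    return samples


def write_qpcr_summary(samples: Sequence[QPCRSample], path: str | Path) -> None:
    rows = [
        {
            "locus": s.locus,
            "antibody": s.antibody,
            "n": s.n,
            "mean_percent_ip": s.mean,
            "sd_percent_ip": s.sd,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
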