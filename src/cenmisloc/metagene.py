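"""Expression classification, TSS-aligned metagene profiles and
occupancy-vs-expression moving-average curves.

Genes are binned into five expression classes on the 5–15 a.u. scale
(boundaries 8, 10, 12, 14). Metagene profiles align genes at the
transcription start site, strand-oriented so that positive relative
positions point in the direction of transcription, and report per-class
means with two-sided Student-t confidence intervals (99% by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .genome import GeneAnnotation
    from .simulate import ProbeTrack

logger = logging.getLogger("cenmisloc")

__all__ = [
    "EXPRESSION_CLASSES",
    "CLASS_BOUNDARIES",
    "classify_expression",
    "tss_aligned_matrix",
    "MetageneProfile",
    "metagene_profile",
    "occupancy_vs_expression",
    "gene_body_mean_signal",
]

#: class labels ordered from lowest to highest expression
EXPRESSION_CLASSES = ("very_low", "low", "medium", "high", "very_high")

#: class boundaries on the expression scale (a.u.)
CLASS_BOUNDARIES = (8.0, 10.0, 12.0, 14.0)


def classify_expression(
    value: float, boundaries: Sequence[float] = CLASS_BOUNDARIES
) -> str:
    """Assign an expression value (a.u.) to one of the five classes.

    very_low: value < 8; low: 8 <= value < 10; medium: 10 <= value < 12;
    high: 12 <= value <= 14; very_high: value > 14. Interior boundaries are
    lower-inclusive; the top boundary belongs to ``high`` so that only
    values strictly above it are ``very_high``.
    """
    if not math.isfinite(value):
        raise ValueError(f"expression value must be finite, got {value!r}")
    b1, b2, b3, b4 = boundaries
    if not (b1 < b2 < b3 < b4):
        raise ValueError("class boundaries must be strictly increasing")
    if value < b1:
        return "very_low"
    if value < b2:
        return "low"
    if value < b3:
        return "medium"
    if value <= b4:
        return "high"
    return "very_high"


def tss_aligned_matrix(
    track: "ProbeTrack",
    genes: Iterable["GeneAnnotation"],
    upstream: int = 500,
    downstream: int = 2000,
    bin_size: int = 20,
) -> pd.DataFrame:
    """Per-gene signal vectors aligned at the TSS.

    Returns a DataFrame (rows: gene ids, columns: relative bin start
    positions from ``-upstream`` to ``downstream - bin_size``). Vectors are
    strand-oriented: for − strand genes the relative coordinate is
    ``tss − position`` so downstream always means the direction of
    transcription. Bins average their member probes; bins with no probe are
    NaN. Genes whose window leaves the probed extent of their chromosome
    are skipped with a logged warning.
    """
    if upstream < 0 or downstream <= 0:
        raise ValueError("window extents must be positive")
    if bin_size <= 0 or (upstream + downstream) % bin_size:
        raise ValueError("bin size must divide the window length")
    n_bins = (upstream + downstream) // bin_size
    lo = -upstream
    positions = np.arange(n_bins) * bin_size + lo

    blocks = {
        name: (track.positions[sl], track.values[sl])
        for name, sl in track.chrom_blocks()
    }
    rows: dict[str, np.ndarray] = {}
    for gene in genes:
        if gene.chrom not in blocks:
            logger.warning("gene %s: no probes on chromosome %s", gene.id, gene.chrom)
            continue
        pos, val = blocks[gene.chrom]
        extent_lo, extent_hi = pos[0], pos[-1] + track.spacing
        if gene.strand == "+":
            need_lo, need_hi = gene.tss + lo, gene.tss + lo + n_bins * bin_size
        else:
            need_lo = gene.tss - (lo + n_bins * bin_size - 1)
            need_hi = gene.tss - lo + 1
        if need_lo < extent_lo or need_hi > extent_hi:
            logger.warning(
                "gene %s: window exceeds probed extent of %s; skipped",
                gene.id,
                gene.chrom,
            )
            continue
        i0, i1 = np.searchsorted(pos, (need_lo, need_hi))
        rel = pos[i0:i1] - gene.tss if gene.strand == "+" else gene.tss - pos[i0:i1]
        j = (rel - lo) // bin_size
        keep = (j >= 0) & (j < n_bins)
        sums = np.bincount(j[keep], weights=val[i0:i1][keep], minlength=n_bins)
        counts = np.bincount(j[keep], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            rows[gene.id] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame.from_dict(rows, orient="index", columns=positions)


@dataclass
class MetageneProfile:
    """Per-class TSS-aligned mean signal with CI half-widths.

    ``data`` is tidy: position, expression_class, n_genes, mean,
    ci_half_width — one row per (class, position).
    """

    ci_level: float
    data: pd.DataFrame

    @property
    def positions(self) -> np.ndarray:
        return np.unique(self.data["position"].to_numpy())

    def class_mean(self, label: str) -> pd.Series:
        sub = self.data[self.data["expression_class"] == label]
        return sub.set_index("position")["mean"]


def metagene_profile(
    matrix: pd.DataFrame,
    classes: Mapping[str, str],
    ci_level: float = 0.99,
) -> MetageneProfile:
    """Average the per-gene matrix within expression classes.

    Per class and relative position: mean over genes with data there, and a
    two-sided Student-t confidence half-width at ``ci_level`` (NaN where
    fewer than two genes contribute). Classes with no member gene in the
    matrix are excluded with a warning. Row order of ``matrix`` is
    irrelevant.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    records = []
    for label in EXPRESSION_CLASSES:
        members = [g for g in matrix.index if classes.get(g) == label]
        if not members:
            logger.warning("expression class %s: no genes; excluded", label)
            continue
        sub = matrix.loc[members].to_numpy(dtype=float)
        n_genes = len(members)
        m = np.sum(~np.isnan(sub), axis=0)
        mean = np.full(sub.shape[1], np.nan)
        sd = np.full(sub.shape[1], np.nan)
        has = m > 0
        if has.any():
            mean[has] = np.nanmean(sub[:, has], axis=0)
        ok = m >= 2
        if ok.any():
            sd[ok] = np.nanstd(sub[:, ok], axis=0, ddof=1)
        half = np.full(sub.shape[1], np.nan)
        if ok.any():
            tq = stats.t.ppf(1 - (1 - ci_level) / 2, m[ok] - 1)
            half[ok] = tq * sd[ok] / np.sqrt(m[ok])
        for pos, mu, hw in zip(matrix.columns, mean, half):
            records.append(
                {
                    "position": int(pos),
                    "expression_class": label,
                    "n_genes": n_genes,
                    "mean": mu,
                    "ci_half_width": hw,
                }
            )
    if not records:
        raise ValueError("no expression class has member genes in the matrix")
    return MetageneProfile(ci_level=ci_level, data=pd.DataFrame.from_records(records))


def occupancy_vs_expression(
    gene_values: Sequence[float],
    expression: Sequence[float],
    window: int = 100,
    step: int = 1,
) -> pd.DataFrame:
    """Moving-average occupancy as a function of expression rank.

    Genes are sorted by expression (ascending); point *i* is the pair of
    window means over genes ``[i, i+window)``. Returns a DataFrame with
    columns mean_expression, mean_occupancy of length
    ``(n - window) // step + 1``.
    """
    occ = np.asarray(gene_values, dtype=float)
    expr = np.asarray(expression, dtype=float)
    if occ.shape != expr.shape or occ.ndim != 1:
        raise ValueError("gene_values and expression must be 1-D and aligned")
    n = occ.size
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if n < window:
        raise ValueError(f"need at least window={window} genes, got {n}")
    order = np.argsort(expr, kind="stable")
    occ, expr = occ[order], expr[order]
    starts = np.arange(0, n - window + 1, step)
    csum_occ = np.concatenate(([0.0], np.cumsum(occ)))
    csum_exp = np.concatenate(([0.0], np.cumsum(expr)))
    mean_occ = (csum_occ[starts + window] - csum_occ[starts]) / window
    mean_exp = (csum_exp[starts + window] - csum_exp[starts]) / window
    return pd.DataFrame({"mean_expression": mean_exp, "mean_occupancy": mean_occ})


def gene_body_mean_signal(
    track: "ProbeTrack", genes: Iterable["GeneAnnotation"]
) -> pd.Series:
    """Mean probe signal over each gene body ``[start, end)`` (NaN if no probe)."""
    blocks = {
        name: (track.positions[sl], track.values[sl])
        for name, sl in track.chrom_blocks()
    }
    out: dict[str, float] = {}
    for gene in genes:
        if gene.chrom not in blocks:
            out[gene.id] = np.nan
            continue
        pos, val = blocks[gene.chrom]
        i0, i1 = np.searchsorted(pos, (gene.start, gene.end))
        out[gene.id] = float(val[i0:i1].mean()) if i1 > i0 else np.nan
    return pd.Series(out, name="occupancy")
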