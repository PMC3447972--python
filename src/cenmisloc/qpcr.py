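"""ChIP-qPCR quantification: percent-input enrichment, replicate summaries
and relative-enrichment ratios."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("cenmisloc")

__all__ = [
    "QPCRSample",
    "percent_ip",
    "summarize_replicates",
    "relative_enrichment",
]


@dataclass
class QPCRSample:
    """Replicate %IP measurements for one locus/antibody pair."""

    locus: str
    antibody: str
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.size == 0:
            raise ValueError("at least one replicate is required")
        if np.any(self.replicates < 0):
            raise ValueError("%IP values must be >= 0")
        if np.any(self.replicates > 100):
            logger.warning(
                "%s/%s: replicate %%IP above 100%% — check input quantities",
                self.locus,
                self.antibody,
            )

    @property
    def n(self) -> int:
        return self.replicates.size

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (n−1); NaN for a single replicate."""
        m, s = summarize_replicates(self.replicates)
        return s


def percent_ip(
    ip_quantity: float, input_quantity: float, input_dilution_factor: float = 1.0
) -> float:
    """Percent of input chromatin recovered in the immunoprecipitate.

    ``100 × ip / (input × dilution)`` where ``input_dilution_factor`` scales
    an input measured on a dilution back to the undiluted amount. A result
    above 100% means the quantities are inconsistent and is reported as an
    error.
    """
    if ip_quantity <= 0 or input_quantity <= 0:
        raise ValueError("quantities must be > 0")
    if input_dilution_factor < 1:
        raise ValueError("input_dilution_factor must be >= 1")
    pct = 100.0 * ip_quantity / (input_quantity * input_dilution_factor)
    if pct > 100.0:
        raise ValueError(
            f"computed %IP = {pct:.3g} exceeds 100%; IP quantity is larger "
            "than the dilution-corrected input"
        )
    return pct


def summarize_replicates(values) -> tuple[float, float]:
    """Mean and n−1 standard deviation of replicate measurements.

    With a single replicate the sd is undefined: NaN is returned and a
    warning logged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    if arr.size == 1:
        logger.warning("single replicate: standard deviation undefined")
        return float(arr[0]), math.nan
    return float(arr.mean()), float(arr.std(ddof=1))


def relative_enrichment(a: QPCRSample, b: QPCRSample) -> float:
    """Ratio of mean %IP of sample ``a`` over sample ``b``."""
    if b.mean <= 0:
        raise ValueError("denominator sample has non-positive mean")
    return a.mean / b.mean
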