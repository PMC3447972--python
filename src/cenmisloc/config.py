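"""Analysis configuration: every numeric parameter of the pipeline in one
place, with a flat key-value file format."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

__all__ = ["AnalysisConfig", "read_config", "write_config"]


@dataclass
class AnalysisConfig:
    """Defaults are the study conditions of the analysis.

    Region calling: >= 1 kb spans with > 2-fold signal above the
    genome-wide average; proximity window 100 kb around centromere edges on
    a 1-kb-bin population; smoothing over 100 probes; metagene CIs at 99%;
    expression class boundaries 8/10/12/14 a.u.; moving-average curves with
    window 100 genes, step 1. Simulation: 20 bp probe spacing, log2 noise
    sd 0.25, 96 centromere-proximal plus 72 distal planted 2-kb domains at
    6-fold, qPCR replicate CV 5%.
    """

    seed: int = 1
    # genome fixture
    n_genes: int = 5073
    # simulation
    probe_spacing: int = 20
    noise_sd: float = 0.25
    global_fold: float = 1.0
    depletion_slope: float = 0.0
    n_proximal_domains: int = 96
    n_distal_domains: int = 72
    domain_width: int = 2000
    domain_fold: float = 6.0
    qpcr_cv: float = 0.05
    # region calling
    min_region_length: int = 1000
    fold_threshold: float = 2.0
    max_gap: int = 0
    smooth: bool = False
    smoothing_window: int = 100
    # proximity statistics
    proximity_window: int = 100_000
    proximity_bin: int = 1000
    # metagene / expression
    metagene_upstream: int = 500
    metagene_downstream: int = 2000
    metagene_bin: int = 20
    ci_level: float = 0.99
    class_boundaries: tuple[float, ...] = (8.0, 10.0, 12.0, 14.0)
    ma_window: int = 100
    ma_step: int = 1
    # output
    write_tracks: bool = False

    def __post_init__(self) -> None:
        positive = (
            "probe_spacing",
            "min_region_length",
            "fold_threshold",
            "smoothing_window",
            "proximity_window",
            "proximity_bin",
            "metagene_downstream",
            "metagene_bin",
            "ma_window",
            "ma_step",
            "domain_width",
            "domain_fold",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        bounds = tuple(float(b) for b in self.class_boundaries)
        if any(a >= b for a, b in zip(bounds, bounds[1:])):
            raise ValueError("class_boundaries must be strictly increasing")
        self.class_boundaries = bounds
        if self.noise_sd < 0 or self.qpcr_cv < 0:
            raise ValueError("noise_sd and qpcr_cv must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _format_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (tuple, list)):
        return ",".join(str(v) for v in value)
    return str(value)


def _parse_value(raw: str, ftype: Any) -> Any:
    raw = raw.strip()
    text = str(ftype)
    if ftype is bool or text == "bool":
        if raw.lower() not in ("true", "false"):
            raise ValueError(f"expected true/false, got {raw!r}")
        return raw.lower() == "true"
    if ftype is int or text == "int":
        return int(raw)
    if ftype is float or text == "float":
        return float(raw)
    if "tuple" in text:
        return tuple(float(v) for v in raw.split(","))
    return raw


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    lines = [
        f"{f.name} = {_format_value(getattr(config, f.name))}"
        for f in fields(config)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> AnalysisConfig:
    """Read a flat ``key = value`` config; unknown keys are an error."""
    ftypes = {f.name: f.type for f in fields(AnalysisConfig)}
    kwargs: dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed config line {lineno}: {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in ftypes:
            raise ValueError(f"{path}: unknown config key {key!r} at line {lineno}")
        kwargs[key] = _parse_value(raw, ftypes[key])
    return AnalysisConfig(**kwargs)
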