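"""Spike-in normalization, condition ratio tracks, running-average
smoothing, and the global fold-change estimator.

Spike-in scaling puts two arrays on a common absolute scale: each array is
multiplied by the single scalar that makes the mean of its spike-in control
probes equal the known reference mean. Because the controls are exogenous
and condition-invariant, a genuine global gain of chromosomal signal
survives normalization instead of being divided away — which is what lets
the pipeline quantify an absolute genome-wide increase in occupancy.
"""

from __future__ import annotations

import numpy as np

from .simulate import ProbeTrack, SpikeInSet

__all__ = [
    "spike_scale_factor",
    "scale_by_spike_ins",
    "ratio_track",
    "running_average",
    "estimate_global_fold_change",
]


def spike_scale_factor(track: ProbeTrack, spikes: SpikeInSet) -> float:
    """Scalar that maps the track's spike-probe mean onto the reference mean."""
    if track.scale != "linear":
        raise ValueError("spike scaling operates on linear-scale tracks")
    if len(spikes.indices) == 0:
        raise ValueError("spike-in set is empty")
    observed = float(track.values[spikes.indices].mean())
    if not observed > 0:
        raise ValueError(f"spike-in probe mean must be > 0, got {observed}")
    return float(spikes.reference_values.mean()) / observed


def scale_by_spike_ins(track: ProbeTrack, spikes: SpikeInSet) -> ProbeTrack:
    """Multiply the whole track by its spike-in scale factor.

    Idempotent (a scaled track has factor 1) and rank-preserving.
    """
    return track.with_values(track.values * spike_scale_factor(track, spikes))


def ratio_track(mut: ProbeTrack, wt: ProbeTrack, scale: str = "linear") -> ProbeTrack:
    """Per-probe mut/wt ratio on the requested scale, preserving the grid."""
    if scale not in ("linear", "log2"):
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    if not mut.same_grid(wt):
        raise ValueError("mutant and wild-type tracks are on different probe grids")
    num = mut.to_linear().values
    den = wt.to_linear().values
    if np.any(den == 0):
        raise ValueError("division by zero: wild-type track has zero-valued probes")
    ratio = num / den
    if scale == "log2":
        ratio = np.log2(ratio)
    return mut.with_values(ratio, scale)


def running_average(track: ProbeTrack, window: int = 100) -> ProbeTrack:
    """Centered moving mean over probes, per chromosome.

    Even windows are widened to the next odd integer so the window is
    symmetric about each probe; at chromosome ends the window is truncated
    (shrinks) rather than padded. The probe grid is unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    out = np.empty_like(track.values)
    kernel = np.ones(window)
    for name, sl in track.chrom_blocks():
        v = track.values[sl]
        if window > v.size:
            raise ValueError(
                f"window {window} exceeds probe count {v.size} on {name}"
            )
        sums = np.convolve(v, kernel, mode="same")
        counts = np.convolve(np.ones(v.size), kernel, mode="same")
        out[sl] = sums / counts
    return track.with_values(out)


def estimate_global_fold_change(
    mut: ProbeTrack, wt: ProbeTrack, spikes: SpikeInSet
) -> float:
    """Global chromosomal fold change of mutant over wild type.

    Both arrays are spike-in normalized; the estimate is the geometric mean
    of per-probe linear ratios over chromosomal (non-spike) probes, i.e.
    ``2^(mean log2 ratio)`` — unbiased under symmetric log-scale noise and
    invariant to pre-multiplying either track by any positive constant.
    """
    mut_n = scale_by_spike_ins(mut.to_linear(), spikes)
    wt_n = scale_by_spike_ins(wt.to_linear(), spikes)
    log_ratio = ratio_track(mut_n, wt_n, scale="log2")
    mask = log_ratio.chromosomal_mask()
    if not mask.any():
        raise ValueError("tracks contain no chromosomal probes")
    return float(np.exp2(log_ratio.values[mask].mean()))
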