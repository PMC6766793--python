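"""Sampling-campaign bookkeeping.

Small helpers for translating a simulation campaign (replicates × segment
durations at a fixed coordinate-save interval) into frame counts and total
sampling time.
"""

from __future__ import annotations

from collections.abc import Iterable

__all__ = ["frames_in_sampling", "total_sampling_ns"]


def frames_in_sampling(total_ns: float, frame_interval_ps: float = 4.0) -> int:
    """Number of saved frames in ``total_ns`` of sampling at one frame per
    ``frame_interval_ps`` picoseconds."""
    if total_ns < 0 or frame_interval_ps <= 0:
        raise ValueError("need total_ns >= 0 and frame_interval_ps > 0")
    frames = total_ns * 1000.0 / frame_interval_ps
    if abs(frames - round(frames)) > 1e-9:
        raise ValueError(
            f"{total_ns} ns is not a whole number of {frame_interval_ps} ps frames"
        )
    return int(round(frames))


def total_sampling_ns(segments_ns: Iterable[float]) -> float:
    """Total sampling time of a campaign given its segment durations (ns)."""
    return float(sum(segments_ns))
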