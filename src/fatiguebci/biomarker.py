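"""Resting-state alpha-band power — the EEG fatigue biomarker.

The study's physiological outcome is the absolute power of the classic alpha
band (8-12 Hz) during 2-minute eyes-open resting-state periods before and
after each session task, computed as the integrated Welch power spectral
density (10 s windows, 5 s overlap, trapezoidal integration).

Quality control follows the study rules: channels with impedance above
5 MΩ are removed before analysis, and sessions whose aggregate alpha power
exceeds 99 are excluded.

A note on units: integrating a µV²/Hz density over a band yields µV², but
band-power values are conventionally *reported* with the µV²/Hz label of the
underlying density; this package computes the true integral and carries the
reporting label unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signals import (
    DegenerateInputError,
    EEGRecording,
    integrate_band,
    welch_psd,
)

__all__ = [
    "AlphaPowerResult",
    "qc_channels",
    "resting_alpha",
    "alpha_change",
    "IMPEDANCE_LIMIT_MOHM",
    "ALPHA_EXCLUSION_LIMIT",
    "POSTERIOR_CHANNELS",
]

IMPEDANCE_LIMIT_MOHM = 5.0
ALPHA_EXCLUSION_LIMIT = 99.0
ALPHA_BAND = (8.0, 12.0)

#: Posterior channel subset for the optional "posterior-subset" aggregation.
POSTERIOR_CHANNELS = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")


@dataclass
class AlphaPowerResult:
    """Alpha band power of one resting-state recording.

    ``aggregate`` is the mean band power over the aggregated channels (µV²,
    reported with the conventional µV²/Hz label); ``excluded`` flags the
    session-level exclusion rule (aggregate > 99) with its reason.
    """

    per_channel: dict[str, float]
    aggregate: float
    phase: str = "pre"
    excluded: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.excluded and not self.reason:
            raise ValueError("excluded results must carry a reason")
        if not self.excluded and self.aggregate < 0:
            raise ValueError("aggregate power cannot be negative")


def qc_channels(recording: EEGRecording, impedances: dict[str, float]) -> EEGRecording:
    """Flag channels with impedance strictly greater than 5 MΩ as bad.

    ``impedances`` maps every channel label to its impedance in MΩ; a value
    of exactly 5 MΩ is retained.  Raises if no channel survives.
    """
    missing = set(recording.channel_labels) - set(impedances)
    if missing:
        raise ValueError(f"impedance map missing channels: {sorted(missing)}")
    bad = {c for c in recording.channel_labels
           if impedances[c] > IMPEDANCE_LIMIT_MOHM}
    if len(bad) == len(recording.channel_labels):
        raise DegenerateInputError("all channels exceed the impedance limit")
    return recording.copy_with(bad_channels=set(recording.bad_channels) | bad)


def resting_alpha(
    recording: EEGRecording,
    phase: str = "pre",
    aggregation: str = "mean-all",
    min_duration_s: float = 120.0,
) -> AlphaPowerResult:
    """Alpha band power of a resting-state recording.

    Welch PSD (10 s / 5 s) on QC-retained channels, trapezoidal 8-12 Hz
    integral per channel; the aggregate is the mean over the aggregated
    channel set (``"mean-all"`` = all retained channels,
    ``"posterior-subset"`` = retained posterior channels only).  Aggregates
    above 99 mark the session excluded with reason ``"alpha>99"``.
    """
    if recording.duration < min_duration_s:
        raise ValueError(
            f"resting-state recording must be >= {min_duration_s:.0f}s, "
            f"got {recording.duration:.1f}s"
        )
    if aggregation not in ("mean-all", "posterior-subset"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    spectrum = welch_psd(recording, window_s=10.0, overlap_s=5.0)
    band = integrate_band(spectrum, *ALPHA_BAND)
    per_channel = dict(zip(spectrum.channel_labels, band.astype(float)))
    if aggregation == "posterior-subset":
        vals = [v for c, v in per_channel.items() if c in POSTERIOR_CHANNELS]
        if not vals:
            raise DegenerateInputError("no posterior channels survive QC")
    else:
        vals = list(per_channel.values())
    aggregate = float(np.mean(vals))
    excluded = aggregate > ALPHA_EXCLUSION_LIMIT
    return AlphaPowerResult(
        per_channel=per_channel,
        aggregate=aggregate,
        phase=phase,
        excluded=excluded,
        reason="alpha>99" if excluded else None,
    )


def alpha_change(pre: AlphaPowerResult, post: AlphaPowerResult) -> float:
    """Post-minus-pre aggregate alpha power.

    If either phase is excluded the change is *missing* (NaN) — exclusions
    propagate, they are never silently treated as zero.
    """
    if pre.excluded or post.excluded:
        return math.nan
    return post.aggregate - pre.aggregate
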