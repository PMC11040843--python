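"""Filtering, epoching, and spectral-estimation primitives.

These are the shared building blocks of the motor-imagery and P300 decoding
pipelines and of the resting-state alpha-power biomarker: causal Butterworth
band-pass filtering, event-locked epoch extraction, Welch power spectral
density estimation, and trapezoidal band integration.

All amplitudes are in microvolts (µV); power spectral densities are one-sided
densities in µV²/Hz, so integrating a density over a band yields band power
in µV².
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

#: The 19-channel DSI-24 dry-electrode montage (10-20 names), left-ear
#: reference. Order is frontal to occipital.
DSI24_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

MARKER_KINDS = ("mi_left", "mi_right", "flash", "rest_start")


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate to process (e.g. all channels bad)."""


@dataclass(frozen=True)
class EventMarker:
    """A single protocol event.

    Parameters
    ----------
    onset : float
        Seconds from recording start (>= 0).
    kind : str
        One of ``mi_left``, ``mi_right``, ``flash``, ``rest_start``.
    box : int or None
        Grid index 1-9; present iff ``kind == "flash"``.
    is_target : bool or None
        Whether the flashed box is the attended target; flash events only.
    """

    onset: float
    kind: str
    box: int | None = None
    is_target: bool | None = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.kind == "flash") != (self.box is not None):
            raise ValueError("box must be present iff kind == 'flash'")
        if self.kind == "flash" and not (1 <= int(self.box) <= 9):
            raise ValueError(f"flash box must be in 1..9, got {self.box}")


@dataclass
class EEGRecording:
    """A labeled multichannel EEG time series.

    ``samples`` is channels x time in µV; ``bad_channels`` flags channels
    excluded by quality control (they are retained in ``samples`` but dropped
    by epoching and spectral analysis).
    """

    channel_labels: list[str]
    fs: float
    samples: np.ndarray
    bad_channels: set[str] = field(default_factory=set)
    events: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        unknown_bad = set(self.bad_channels) - set(self.channel_labels)
        if unknown_bad:
            raise ValueError(f"bad_channels not in montage: {sorted(unknown_bad)}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.fs

    @property
    def good_channels(self) -> list[str]:
        return [c for c in self.channel_labels if c not in self.bad_channels]

    def good_data(self) -> np.ndarray:
        """Samples restricted to QC-retained channels (view order = montage order)."""
        idx = [i for i, c in enumerate(self.channel_labels) if c not in self.bad_channels]
        if not idx:
            raise DegenerateInputError("all channels are marked bad")
        return self.samples[idx]

    def copy_with(self, **changes) -> "EEGRecording":
        return dataclasses.replace(self, **changes)


@dataclass
class EpochSet:
    """Windowed trials: ``epochs`` is trials x channels x samples (µV)."""

    epochs: np.ndarray
    labels: np.ndarray
    channel_labels: list[str]
    fs: float
    window_s: float
    t0_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass
class PowerSpectrum:
    """One-sided power spectral density, channels x frequencies, in µV²/Hz."""

    freqs: np.ndarray
    psd: np.ndarray
    channel_labels: list[str]
    window_s: float
    overlap_s: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < -1e-12):
            raise ValueError("psd must be non-negative")

    @property
    def resolution(self) -> float:
        """Grid spacing of the frequency axis in Hz."""
        return float(np.median(np.diff(self.freqs)))


def bandpass(
    recording: EEGRecording,
    low_hz: float,
    high_hz: float,
    order: int = 5,
    zero_phase: bool = False,
) -> EEGRecording:
    """Butterworth band-pass filter a recording.

    The default is a causal (forward-only) filter so that offline results
    honestly reflect what an online decoder sees.  ``zero_phase=True``
    applies the filter forward and backward (offline spectra only).

    ``low_hz == 0`` degrades gracefully to a pure low-pass.
    """
    nyq = recording.fs / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"corner frequencies must satisfy 0 <= low < high < fs/2 "
            f"(got low={low_hz}, high={high_hz}, fs/2={nyq})"
        )
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    if low_hz == 0:
        sos = sps.butter(order, high_hz / nyq, btype="lowpass", output="sos")
    else:
        sos = sps.butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        filtered = sps.sosfilt(sos, recording.samples, axis=1)
    return recording.copy_with(samples=np.ascontiguousarray(filtered))


def extract_epochs(
    recording: EEGRecording,
    events: Sequence[EventMarker] | None = None,
    t0_offset_s: float = 0.0,
    window_s: float = 2.0,
    labels: Sequence | None = None,
) -> EpochSet:
    """Cut one fixed-length window per event from the recording.

    Windows start at ``event.onset + t0_offset_s`` and last ``window_s``
    seconds.  Overlapping windows are permitted (P300 flash windows overlap,
    since the 600 ms analysis window exceeds the 175 ms flash spacing).
    Channels flagged bad are dropped.

    Raises
    ------
    IndexError
        If any requested window falls outside the recording; the error names
        the offending event.
    """
    if events is None:
        events = recording.events
    if labels is None:
        labels = [e.kind for e in events]
    if len(labels) != len(events):
        raise ValueError("labels length must equal event count")
    n_win = int(round(window_s * recording.fs))
    if n_win < 1:
        raise ValueError("window_s too short for the sampling rate")
    data = recording.good_data()
    good = recording.good_channels
    out = np.empty((len(events), data.shape[0], n_win), dtype=float)
    for i, ev in enumerate(events):
        start = int(round((ev.onset + t0_offset_s) * recording.fs))
        stop = start + n_win
        if start < 0 or stop > recording.n_times:
            raise IndexError(
                f"epoch window [{start}, {stop}) for event #{i} "
                f"(kind={ev.kind}, onset={ev.onset:.3f}s) exceeds recording "
                f"bounds [0, {recording.n_times})"
            )
        out[i] = data[:, start:stop]
    return EpochSet(
        epochs=out,
        labels=np.asarray(labels),
        channel_labels=good,
        fs=recording.fs,
        window_s=window_s,
        t0_offsets=np.full(len(events), t0_offset_s),
    )


def sliding_windows(
    recording: EEGRecording, start_s: float, window_s: float, n_windows: int
) -> np.ndarray:
    """Consecutive non-overlapping windows from ``start_s``: n x channels x samples."""
    n_win = int(round(window_s * recording.fs))
    data = recording.good_data()
    start = int(round(start_s * recording.fs))
    stop = start + n_windows * n_win
    if start < 0 or stop > recording.n_times:
        raise IndexError("requested windows exceed recording bounds")
    block = data[:, start:stop]
    return np.stack(np.split(block, n_windows, axis=1), axis=0)


def welch_psd(
    recording: EEGRecording, window_s: float = 10.0, overlap_s: float = 5.0
) -> PowerSpectrum:
    """Welch power spectral density with Hann-tapered, mean-detrended segments.

    Defaults are 10 s segments with 5 s overlap. The one-sided density
    scaling makes the integral of the PSD over (0, fs/2) approximate the
    per-channel signal variance (Parseval).
    """
    if recording.duration < window_s:
        raise ValueError(
            f"recording of {recording.duration:.1f}s is shorter than one "
            f"{window_s:.1f}s Welch segment"
        )
    if not (0 <= overlap_s < window_s):
        raise ValueError("overlap must satisfy 0 <= overlap_s < window_s")
    nperseg = int(round(window_s * recording.fs))
    noverlap = int(round(overlap_s * recording.fs))
    freqs, psd = sps.welch(
        recording.good_data(),
        fs=recording.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=1,
    )
    return PowerSpectrum(
        freqs=freqs,
        psd=psd,
        channel_labels=recording.good_channels,
        window_s=window_s,
        overlap_s=overlap_s,
    )


def full_window_psd(recording: EEGRecording) -> PowerSpectrum:
    """Single-segment periodogram over the entire recording.

    The frequency grid spacing equals 1/duration, so a 120 s resting-state
    recording yields a grid finer than 0.01 Hz.  This estimator trades the
    variance reduction of Welch averaging for maximal spectral resolution;
    :func:`welch_psd` is the primary band-power estimator.
    """
    freqs, psd = sps.periodogram(
        recording.good_data(),
        fs=recording.fs,
        window="hann",
        detrend="constant",
        scaling="density",
        axis=1,
    )
    # periodogram returns the DC bin; keep the grid strictly increasing as-is
    return PowerSpectrum(
        freqs=freqs,
        psd=psd,
        channel_labels=recording.good_channels,
        window_s=recording.duration,
        overlap_s=0.0,
    )


def integrate_band(
    spectrum: PowerSpectrum, lo_hz: float = 8.0, hi_hz: float = 12.0
) -> np.ndarray:
    """Trapezoidal band integral of the PSD, per channel, in µV².

    Band edges that fall between grid points are handled by linear
    interpolation, which makes the integral exactly additive over adjacent
    sub-bands. ``lo_hz == hi_hz`` returns zeros.
    """
    if lo_hz > hi_hz:
        raise ValueError(f"band must satisfy lo <= hi (got {lo_hz} > {hi_hz})")
    f = spectrum.freqs
    if lo_hz < f[0] or hi_hz > f[-1]:
        raise ValueError(
            f"band [{lo_hz}, {hi_hz}] Hz outside spectrum range [{f[0]}, {f[-1]}] Hz"
        )
    if lo_hz == hi_hz:
        return np.zeros(spectrum.psd.shape[0])
    inner = (f > lo_hz) & (f < hi_hz)
    grid = np.concatenate(([lo_hz], f[inner], [hi_hz]))
    vals = np.empty((spectrum.psd.shape[0], grid.size))
    vals[:, 1:-1] = spectrum.psd[:, inner]
    for j, edge in ((0, lo_hz), (-1, hi_hz)):
        vals[:, j] = np.array(
            [np.interp(edge, f, spectrum.psd[c]) for c in range(spectrum.psd.shape[0])]
        )
    return np.trapezoid(vals, grid, axis=1)
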