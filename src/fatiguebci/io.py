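"""File formats and configuration: EDF recordings, JSON Lines event sidecars,
CSV tables, and the study configuration document.

Recordings travel as EDF (16-bit, per-channel physical scaling) with a JSON
Lines sidecar holding one event marker per line (onsets in seconds, so the
sidecar is independent of the sampling rate).  EDF is written by a compact
built-in writer and read back through MNE's EDF reader, so round-trips are
verified against an independent implementation.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signals import DSI24_CHANNELS, EEGRecording, EventMarker, PowerSpectrum
from .simulate import SimulationConfig

__all__ = [
    "write_edf",
    "read_edf",
    "write_events",
    "read_events",
    "write_session",
    "read_session",
    "spectrum_to_csv",
    "StudyConfig",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and offending record."""


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long for EDF header: {text!r} ({width} bytes)")
    return b.ljust(width)


def write_edf(recording: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF (one 1 s data record per second).

    The sampling rate must be a whole number of samples per second.  Each
    channel gets a symmetric physical range covering its extremes, so the
    quantization step is ~range/65535.  The final partial second, if any, is
    zero-padded.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1 s record
    ns = recording.n_channels
    n_records = int(np.ceil(recording.n_times / spr))
    data = np.zeros((ns, n_records * spr))
    data[:, : recording.n_times] = recording.samples

    # symmetric physical range per channel, rounded *up* so nothing clips,
    # and quantized against the limits exactly as written in the 8-char
    # header fields, so reader and writer agree on the scaling
    pmax_raw = np.maximum(np.abs(data).max(axis=1), 1.0)
    pmax_str = []
    for v in pmax_raw:
        s = f"{np.ceil(v * 1000) / 1000:.3f}" if v < 999 else f"{np.ceil(v):.0f}"
        pmax_str.append(s)
    pmax = np.array([float(s) for s in pmax_str])
    pmin = -pmax
    pmin_str = ["-" + s for s in pmax_str]
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = _io.BytesIO()
    header.write(_pad("0", 8))
    header.write(_pad("X X X X", 80))                   # patient id (anonymous)
    header.write(_pad("Startdate X X X X", 80))         # recording id
    header.write(_pad("01.01.00", 8))
    header.write(_pad("00.00.00", 8))
    header.write(_pad(str(256 * (ns + 1)), 8))
    header.write(_pad("", 44))
    header.write(_pad(str(n_records), 8))
    header.write(_pad("1", 8))                          # record duration, seconds
    header.write(_pad(str(ns), 4))
    for lab in recording.channel_labels:
        header.write(_pad(lab, 16))
    for _ in range(ns):
        header.write(_pad("EEG", 80))
    for _ in range(ns):
        header.write(_pad("uV", 8))
    for s in pmin_str:
        header.write(_pad(s, 8))
    for s in pmax_str:
        header.write(_pad(s, 8))
    for _ in range(ns):
        header.write(_pad(str(dmin), 8))
    for _ in range(ns):
        header.write(_pad(str(dmax), 8))
    for _ in range(ns):
        header.write(_pad("", 80))
    for _ in range(ns):
        header.write(_pad(str(spr), 8))
    for _ in range(ns):
        header.write(_pad("", 32))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF recording via MNE (samples returned in µV)."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as err:
        raise ParseError(f"malformed EDF file {path}: {err}") from err
    samples = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EEGRecording(
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# event sidecars (JSON Lines, one marker per line)


def write_events(events: list[EventMarker], path) -> None:
    with open(path, "w") as fh:
        for e in events:
            rec = {"onset": e.onset, "kind": e.kind}
            if e.kind == "flash":
                rec["box"] = e.box
                rec["is_target"] = e.is_target
            fh.write(json.dumps(rec) + "\n")


def read_events(path) -> list[EventMarker]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as err:
                raise ParseError(f"{path}:{lineno}: invalid JSON ({err})") from None
            try:
                events.append(
                    EventMarker(
                        onset=rec["onset"],
                        kind=rec["kind"],
                        box=rec.get("box"),
                        is_target=rec.get("is_target"),
                    )
                )
            except (KeyError, ValueError) as err:
                raise ParseError(f"{path}:{lineno}: bad event record {rec}: {err}") from None
    return events


def write_session(recording: EEGRecording, edf_path, events_path) -> None:
    """Write a recording as EDF plus its JSON Lines event sidecar."""
    write_edf(recording, edf_path)
    write_events(recording.events, events_path)


def read_session(edf_path, events_path) -> EEGRecording:
    """Load a session recording with its events.

    Channel labels are validated against the 19-name DSI-24 montage; unknown
    labels produce a warning, not an error.
    """
    rec = read_edf(edf_path)
    unknown = [c for c in rec.channel_labels if c not in DSI24_CHANNELS]
    if unknown:
        warnings.warn(f"channels not in the DSI-24 montage: {unknown}", stacklevel=2)
    rec.events = read_events(events_path)
    return rec


def spectrum_to_csv(spectrum: PowerSpectrum, path) -> None:
    """Export a PSD as long-format CSV: freq_hz, channel, psd_uv2_per_hz."""
    rows = []
    for c, label in enumerate(spectrum.channel_labels):
        for f, v in zip(spectrum.freqs, spectrum.psd[c]):
            rows.append({"freq_hz": f, "channel": label, "psd_uv2_per_hz": v})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study configuration


@dataclass
class StudyConfig:
    """All knobs of an end-to-end simulated study, serializable to YAML/JSON."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    k_folds: int = 5
    shrinkage: float | None = None      # None = analytic Ledoit-Wolf
    n_xdawn_filters: int = 4
    mi_timeout_windows: int = 60
    alpha_aggregation: str = "mean-all"  # or "posterior-subset"
    mdc_level: float = 0.95
    n_game_trials_mi: int = 10
    n_game_trials_p300: int = 6

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.shrinkage is not None and not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must be in [0, 1]")
        if self.alpha_aggregation not in ("mean-all", "posterior-subset"):
            raise ValueError(f"unknown alpha_aggregation {self.alpha_aggregation!r}")
        if not 0 < self.mdc_level < 1:
            raise ValueError("mdc_level must be in (0, 1)")
        # keep the simulation seed slaved to the study seed unless overridden
        if self.simulation.seed != self.seed and self.simulation.seed == 0:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix == ".json":
                d = json.load(fh)
            else:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)
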