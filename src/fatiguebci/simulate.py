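"""Synthetic EEG and cohort generators for the three-session fatigue protocol.

The generators emulate the statistical structure the downstream analysis
assumes, so every pipeline stage is testable without recorded data:

* eyes-open resting EEG — an occipital-dominant 8-12 Hz alpha rhythm of
  configurable amplitude over 1/f ("pink") background noise;
* motor-imagery calibration — 18 alternating left/right imagined-squeeze
  trials (12 s imagery, 6 s break) in which the mu rhythm on the central
  channel contralateral to the imagined hand is attenuated by a configurable
  event-related desynchronization depth;
* P300 calibration — 9 selections on a 3x3 flash grid (15 flashes per box
  per selection, 175 ms onset asynchrony) where target flashes carry a
  parietal positive deflection peaking near 300 ms;
* session tables — per-participant pre/post fatigue scores (0-10 visual
  analog scale) and alpha band power with participant random intercepts and
  a common within-subject pre-to-post shift, plus questionnaire composites
  in their legal ranges.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .signals import DSI24_CHANNELS, EEGRecording, EventMarker

__all__ = [
    "SimulationConfig",
    "gen_resting",
    "gen_mi_session",
    "gen_p300_session",
    "gen_mi_stream",
    "gen_p300_selection",
    "gen_cohort",
    "ALPHA_TOPOGRAPHY",
    "P300_TOPOGRAPHY",
]

# Relative source amplitudes per electrode. The alpha rhythm is strongest
# occipitally and decays frontally; the P300 deflection is parieto-central.
ALPHA_TOPOGRAPHY: dict[str, float] = {
    "O1": 1.0, "O2": 1.0,
    "Pz": 0.8, "P3": 0.8, "P4": 0.8,
    "T5": 0.6, "T6": 0.6,
    "Cz": 0.4, "C3": 0.4, "C4": 0.4,
    "T3": 0.3, "T4": 0.3,
    "Fz": 0.2, "F3": 0.2, "F4": 0.2, "F7": 0.2, "F8": 0.2,
    "Fp1": 0.1, "Fp2": 0.1,
}

P300_TOPOGRAPHY: dict[str, float] = {
    "Pz": 1.0, "P3": 0.8, "P4": 0.8,
    "Cz": 0.6, "T5": 0.4, "T6": 0.4,
    "O1": 0.4, "O2": 0.4,
    "Fz": 0.2, "C3": 0.3, "C4": 0.3,
}

# Protocol constants (flash grid timing and trial structure)
FLASH_ON_S = 0.100
FLASH_PAUSE_S = 0.075
SOA_S = FLASH_ON_S + FLASH_PAUSE_S          # 175 ms stimulus-onset asynchrony
FLASHES_PER_BOX = 15
N_BOXES = 9
P300_PAUSE_S = 2.0
MI_TRIAL_S = 12.0
MI_BREAK_S = 6.0
MI_SELECTIONS = 18
P300_SELECTIONS = 9
MI_WINDOW_S = 2.0


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    EEG effect parameters (``alpha_amp``, ``erd_depth``, ``p3_amp`` ...) are
    simulator-only; the montage (19 channels) and sampling rate (300 Hz)
    match the recording hardware the protocol assumes.
    """

    seed: int = 0
    n_channels: int = 19
    fs: float = 300.0
    alpha_amp: float = 14.0         # µV at the occipital maximum
    alpha_freq: float = 10.0        # Hz, within the 8-12 Hz alpha band
    noise_sd: float = 4.0           # µV, 1/f background per channel
    mu_amp: float = 6.0             # µV sensorimotor rhythm on C3/C4
    erd_depth: float = 0.5          # fractional contralateral mu attenuation
    p3_amp: float = 5.0             # µV evoked deflection at Pz
    p3_latency: float = 300.0       # ms post flash onset
    pre_post_shift: float = 1.2     # VASF points, common within-subject shift
    n_participants: int = 32
    # cohort-level distribution parameters
    vasf_pre_mean: float = 3.4
    vasf_between_sd: float = 1.5
    vasf_resid_sd: float = 0.8
    alpha_pre_mean: float = 29.4    # µV² band power
    alpha_shift: float = 2.8
    alpha_between_sd: float = 12.0
    alpha_resid_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if self.alpha_amp < 0:
            raise ValueError(f"alpha_amp must be >= 0, got {self.alpha_amp}")
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")
        if self.n_channels > len(DSI24_CHANNELS):
            raise ValueError(f"montage has only {len(DSI24_CHANNELS)} channels")
        if not 8.0 <= self.alpha_freq <= 12.0:
            raise ValueError("alpha_freq must lie in the 8-12 Hz band")

    @property
    def channels(self) -> list[str]:
        return list(DSI24_CHANNELS[: self.n_channels])

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent generator for a named sub-stream of the base seed."""
        return np.random.default_rng([self.seed, *stream])

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# signal building blocks


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, sd: float) -> np.ndarray:
    """1/f-shaped noise: white noise whose amplitude spectrum is scaled by
    f^{-1/2} (power slope -1), renormalized to standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n_channels, n))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** -0.5
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std * sd


def _topo_weights(channels: list[str], topo: dict[str, float]) -> np.ndarray:
    return np.array([topo.get(c, 0.1) for c in channels])


def _alpha_background(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Occipital-dominant alpha sinusoid with a random phase, channels x time."""
    if config.alpha_amp == 0:
        return np.zeros((config.n_channels, n))
    t = np.arange(n) / config.fs
    phase = rng.uniform(0, 2 * np.pi)
    w = _topo_weights(config.channels, ALPHA_TOPOGRAPHY)
    return w[:, None] * config.alpha_amp * np.sin(2 * np.pi * config.alpha_freq * t + phase)


# ---------------------------------------------------------------------------
# resting state


def gen_resting(
    config: SimulationConfig,
    duration_s: float = 120.0,
    alpha_scale: float = 1.0,
    stream: tuple[int, ...] = (1,),
) -> EEGRecording:
    """Eyes-open resting EEG: occipital alpha over 1/f noise.

    ``alpha_scale`` multiplies the alpha source amplitude (used to inject a
    post-task alpha-power increase into end-to-end study simulations).
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    rng = config.rng(*stream)
    n = int(round(duration_s * config.fs))
    data = _pink_noise(rng, config.n_channels, n, config.noise_sd)
    data += alpha_scale * _alpha_background(config, rng, n)
    return EEGRecording(
        channel_labels=config.channels,
        fs=config.fs,
        samples=data,
        events=[EventMarker(onset=0.0, kind="rest_start")],
    )


# ---------------------------------------------------------------------------
# motor imagery


def _mu_signal(
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
    env_c3: np.ndarray,
    env_c4: np.ndarray,
) -> np.ndarray:
    """Sensorimotor mu rhythm on C3/C4 with independent phases and the given
    amplitude envelopes (1 = baseline, 1 - erd_depth = suppressed)."""
    out = np.zeros((config.n_channels, n))
    channels = config.channels
    t = np.arange(n) / config.fs
    for label, env in (("C3", env_c3), ("C4", env_c4)):
        if label not in channels:
            continue
        i = channels.index(label)
        phase = rng.uniform(0, 2 * np.pi)
        out[i] = env * config.mu_amp * np.sin(2 * np.pi * config.alpha_freq * t + phase)
    return out


def gen_mi_session(
    config: SimulationConfig, stream: tuple[int, ...] = (2,)
) -> tuple[EEGRecording, list[EventMarker]]:
    """Motor-imagery calibration: 18 alternating left/right selections.

    Each selection is 12 s of imagery followed by a 6 s break; alternation
    starts with the left hand.  During imagery the mu rhythm on the central
    channel contralateral to the imagined hand (C4 for left-hand imagery,
    C3 for right) is attenuated by ``erd_depth``.
    """
    rng = config.rng(*stream)
    fs = config.fs
    lead_in = 2.0
    total_s = lead_in + MI_SELECTIONS * (MI_TRIAL_S + MI_BREAK_S)
    n = int(round(total_s * fs))
    env_c3 = np.ones(n)
    env_c4 = np.ones(n)
    events: list[EventMarker] = []
    for k in range(MI_SELECTIONS):
        side = "mi_left" if k % 2 == 0 else "mi_right"
        onset = lead_in + k * (MI_TRIAL_S + MI_BREAK_S)
        events.append(EventMarker(onset=onset, kind=side))
        i0 = int(round(onset * fs))
        i1 = int(round((onset + MI_TRIAL_S) * fs))
        # contralateral suppression: left hand -> right hemisphere (C4)
        if side == "mi_left":
            env_c4[i0:i1] = 1.0 - config.erd_depth
        else:
            env_c3[i0:i1] = 1.0 - config.erd_depth
    data = _pink_noise(rng, config.n_channels, n, config.noise_sd)
    data += _alpha_background(config, rng, n)
    data += _mu_signal(config, rng, n, env_c3, env_c4)
    rec = EEGRecording(
        channel_labels=config.channels, fs=fs, samples=data, events=events
    )
    return rec, events


def gen_mi_stream(
    config: SimulationConfig,
    side: str,
    n_windows: int = 60,
    stream: tuple[int, ...] = (20,),
) -> EEGRecording:
    """Continuous imagery stream for online game play.

    ``side`` is ``"left"`` or ``"right"``; the stream carries sustained
    imagery of that hand (contralateral mu suppression) for
    ``n_windows`` x 2 s.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    rng = config.rng(*stream)
    n = int(round(n_windows * MI_WINDOW_S * config.fs))
    env_c3 = np.ones(n)
    env_c4 = np.ones(n)
    if side == "left":
        env_c4[:] = 1.0 - config.erd_depth
    else:
        env_c3[:] = 1.0 - config.erd_depth
    data = _pink_noise(rng, config.n_channels, n, config.noise_sd)
    data += _alpha_background(config, rng, n)
    data += _mu_signal(config, rng, n, env_c3, env_c4)
    return EEGRecording(channel_labels=config.channels, fs=config.fs, samples=data)


# ---------------------------------------------------------------------------
# P300


def _p3_template(config: SimulationConfig) -> tuple[float, np.ndarray]:
    """Half-sine (one-cycle raised-cosine) deflection of 300 ms width whose
    peak sits at ``p3_latency`` ms post flash onset; sampled at fs."""
    width_s = 0.300
    onset_s = config.p3_latency / 1000.0 - width_s / 2
    n = int(round(width_s * config.fs))
    bump = np.sin(np.pi * np.arange(n) / n)
    return onset_s, bump


def _flash_schedule(rng: np.random.Generator) -> np.ndarray:
    """15 successive random permutations of the 9 boxes (one flash each)."""
    return np.concatenate(
        [rng.permutation(N_BOXES) + 1 for _ in range(FLASHES_PER_BOX)]
    )


def _render_p300_block(
    config: SimulationConfig,
    rng: np.random.Generator,
    target: int,
    start_s: float,
    data: np.ndarray,
    events: list[EventMarker],
) -> float:
    """Append one selection's flash sequence to ``data``/``events``.

    Returns the end time (after the 2 s pause)."""
    fs = config.fs
    onset_rel, bump = _p3_template(config)
    w = _topo_weights(config.channels, P300_TOPOGRAPHY) * config.p3_amp
    boxes = _flash_schedule(rng)
    for j, box in enumerate(boxes):
        onset = start_s + j * SOA_S
        is_target = bool(box == target)
        events.append(
            EventMarker(onset=onset, kind="flash", box=int(box), is_target=is_target)
        )
        if is_target and config.p3_amp > 0:
            i0 = int(round((onset + onset_rel) * fs))
            m = min(len(bump), data.shape[1] - i0)
            if m > 0:
                data[:, i0 : i0 + m] += w[:, None] * bump[None, :m]
    return start_s + len(boxes) * SOA_S + P300_PAUSE_S


def gen_p300_selection(
    config: SimulationConfig, target: int, stream: tuple[int, ...] = (30,)
) -> tuple[EEGRecording, list[EventMarker]]:
    """One game selection: a full 15-flashes-per-box sequence with the given
    target box (1-9), over background noise and alpha."""
    if not 1 <= target <= N_BOXES:
        raise ValueError(f"target box must be 1..9, got {target}")
    rng = config.rng(*stream)
    lead_in = 1.0
    total_s = lead_in + FLASHES_PER_BOX * N_BOXES * SOA_S + P300_PAUSE_S
    n = int(round(total_s * config.fs))
    data = _pink_noise(rng, config.n_channels, n, config.noise_sd)
    data += _alpha_background(config, rng, n)
    events: list[EventMarker] = []
    _render_p300_block(config, rng, target, lead_in, data, events)
    rec = EEGRecording(
        channel_labels=config.channels, fs=config.fs, samples=data, events=events
    )
    return rec, events


def gen_p300_session(
    config: SimulationConfig, stream: tuple[int, ...] = (3,)
) -> tuple[EEGRecording, list[EventMarker]]:
    """P300 calibration: 9 selections, each grid box once as the target.

    Per selection the 9 boxes flash in 15 random permutation rounds at
    175 ms onset asynchrony (100 ms on + 75 ms pause), followed by a 2 s
    pause.  Target flashes carry the parietal positive deflection."""
    rng = config.rng(*stream)
    lead_in = 1.0
    per_sel = FLASHES_PER_BOX * N_BOXES * SOA_S + P300_PAUSE_S
    total_s = lead_in + P300_SELECTIONS * per_sel
    n = int(round(total_s * config.fs))
    data = _pink_noise(rng, config.n_channels, n, config.noise_sd)
    data += _alpha_background(config, rng, n)
    events: list[EventMarker] = []
    t = lead_in
    for target in range(1, P300_SELECTIONS + 1):
        t = _render_p300_block(config, rng, target, t, data, events)
    rec = EEGRecording(
        channel_labels=config.channels, fs=config.fs, samples=data, events=events
    )
    return rec, events


# ---------------------------------------------------------------------------
# cohort tables


SESSIONS = ("MI", "P300", "video")

#: Latin-square session orders cycled over participants (balanced crossover).
_LATIN_SQUARE = (
    ("MI", "P300", "video"),
    ("P300", "video", "MI"),
    ("video", "MI", "P300"),
)

VASF_TIMELINE_MIN = (0, 5, 10, 15, 20, 25, 30)


def _truncate_round(x: np.ndarray, lo: float, hi: float, step: float = 0.1) -> np.ndarray:
    return np.round(np.clip(x, lo, hi) / step) * step


def gen_cohort(config: SimulationConfig, stream: tuple[int, ...] = (4,)) -> pd.DataFrame:
    """Simulate the three-session cohort table (one row per session).

    Pre/post fatigue scores are drawn around the configured marginal means
    with participant random intercepts plus residual noise, truncated to the
    0-10 visual-analog scale and rounded to 0.1; alpha band power gets an
    analogous structure with its own shift. Questionnaire composites are
    drawn uniformly within their legal ranges; age group is a median split
    by date of birth.
    """
    if config.n_participants < 2:
        raise ValueError("need at least 2 participants")
    rng = config.rng(*stream)
    n = config.n_participants
    b_vasf = rng.normal(0, config.vasf_between_sd, size=n)
    b_alpha = rng.normal(0, config.alpha_between_sd, size=n)
    ages = rng.uniform(6.0, 17.0, size=n)
    median_age = np.median(ages)
    sexes = rng.choice(["F", "M"], size=n, p=[0.6, 0.4])
    mfs = np.clip(rng.normal(72, 12, size=n), 0, 100)
    rows = []
    for p in range(n):
        order = _LATIN_SQUARE[p % 3]
        for o, session in enumerate(order, start=1):
            pre = config.vasf_pre_mean + b_vasf[p] + rng.normal(0, config.vasf_resid_sd)
            post = (
                config.vasf_pre_mean + config.pre_post_shift + b_vasf[p]
                + rng.normal(0, config.vasf_resid_sd)
            )
            pre, post = _truncate_round(np.array([pre, post]), 0, 10)
            a_pre = max(
                config.alpha_pre_mean + b_alpha[p] + rng.normal(0, config.alpha_resid_sd),
                0.5,
            )
            a_post = max(
                config.alpha_pre_mean + config.alpha_shift + b_alpha[p]
                + rng.normal(0, config.alpha_resid_sd),
                0.5,
            )
            timeline = np.linspace(pre, post, len(VASF_TIMELINE_MIN))
            timeline = _truncate_round(
                timeline + rng.normal(0, config.vasf_resid_sd / 2, len(timeline)), 0, 10
            )
            row = {
                "participant": f"P{p + 1:03d}",
                "session": session,
                "order": o,
                "vasf_pre": pre,
                "vasf_post": post,
                "alpha_pre": a_pre,
                "alpha_post": a_post,
                "motivation_total": float(np.round(rng.uniform(26, 45), 1)),
                "workload_total": float(np.round(rng.uniform(10, 75), 1)),
                "pain": int(rng.integers(0, 6)),
                "age": float(np.round(ages[p], 1)),
                "age_group": "younger" if ages[p] < median_age else "older",
                "sex": sexes[p],
                "mfs_total": float(np.round(mfs[p], 1)),
            }
            for m, v in zip(VASF_TIMELINE_MIN, timeline):
                row[f"vasf_min{m}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
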