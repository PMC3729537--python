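"""EMG and kinematics conditioning: filtering, onset detection, windowing.

The analysis window is the 200 ms of muscle activity straddling movement
onset ([-100, +100] ms), the interval in which surface EMG already encodes
the upcoming reach direction.  Onset is detected from the tangential hand
speed with a 5%-of-peak threshold.  All filters are applied forward-backward
(zero phase) so onset timing is not shifted.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ChannelMismatchError, ConfigError, NoMovementError, TrialTooShortError
from .synth import EMG_BAND_HZ, EmgTrial

__all__ = [
    "FilterConfig",
    "Window",
    "detect_onset",
    "drop_channels",
    "extract_window",
    "filter_emg",
    "tangential_speed",
    "window_session",
]


@dataclass(frozen=True)
class FilterConfig:
    """Filter chain configuration.

    EMG: optional 20-450 Hz band-pass (only when the source is marked
    unfiltered), 10 Hz Butterworth high-pass, and a 20 ms moving average of
    the rectified signal (the smoothed activity envelope).  Kinematics:
    15 Hz Butterworth low-pass.  All Butterworth filters are zero-phase.
    """

    emg_bandpass: tuple[float, float] = EMG_BAND_HZ
    emg_highpass_cutoff: float = 10.0
    emg_smooth_window_ms: float = 20.0
    pos_lowpass_cutoff: float = 15.0
    butterworth_order: int = 4

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        for cutoff in (*self.emg_bandpass, self.emg_highpass_cutoff, self.pos_lowpass_cutoff):
            if cutoff >= nyquist:
                raise ConfigError(f"cutoff {cutoff} Hz is not below Nyquist ({nyquist} Hz)")


@dataclass(frozen=True)
class Window:
    """The [-100, +100] ms analysis window of one trial.

    ``signals`` holds the signed (band/high-passed, unrectified) samples;
    ``envelope`` the rectified 20 ms moving-average version.  Half-open
    sample convention: exactly ``round(0.2 * sampling_rate)`` samples.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    direction_deg: float
    onset_sample: int
    envelope: np.ndarray | None = None
    trial_id: str = ""
    subject_id: str = ""
    duration_ms: float | None = None

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def filter_emg(trial: EmgTrial, cfg: FilterConfig | None = None) -> EmgTrial:
    """Condition a trial's EMG channels.

    Band-pass (20-450 Hz) is applied only when ``trial.bandpassed`` is
    False — data acquired through hardware band-pass must not be filtered
    twice.  The returned trial carries the signed high-passed signal in
    ``signals`` and the rectified, 20 ms moving-averaged envelope in
    ``envelope``; both are needed downstream (sign-sensitive features and
    the PCA covariance consume the signed data).
    """
    cfg = cfg or FilterConfig()
    cfg.validate(trial.sampling_rate)
    fs = trial.sampling_rate
    x = trial.signals
    if not trial.bandpassed:
        sos_bp = sps.butter(cfg.butterworth_order, cfg.emg_bandpass, btype="bandpass",
                            fs=fs, output="sos")
        x = sps.sosfiltfilt(sos_bp, x, axis=1)
    sos_hp = sps.butter(cfg.butterworth_order, cfg.emg_highpass_cutoff, btype="highpass",
                        fs=fs, output="sos")
    signed = sps.sosfiltfilt(sos_hp, x, axis=1)
    n_smooth = max(1, int(round(cfg.emg_smooth_window_ms / 1000.0 * fs)))
    envelope = uniform_filter1d(np.abs(signed), size=n_smooth, axis=1, mode="nearest")
    out = dataclasses.replace(trial, signals=signed, bandpassed=True)
    out.envelope = envelope
    return out


def tangential_speed(
    position: np.ndarray,
    sampling_rate: float,
    cfg: FilterConfig | None = None,
) -> np.ndarray:
    """Tangential (Euclidean) hand speed from a (2, n) position trace.

    The trace is zero-phase low-pass filtered at 15 Hz and centrally
    differenced; the result is nonnegative by construction.
    """
    cfg = cfg or FilterConfig()
    position = np.asarray(position, dtype=float)
    if position.ndim != 2 or position.shape[0] != 2:
        raise ConfigError("position must be a (2, n_samples) array")
    if position.shape[1] < 3:
        raise ConfigError("need at least 3 position samples")
    cfg.validate(sampling_rate)
    sos = sps.butter(cfg.butterworth_order, cfg.pos_lowpass_cutoff, btype="lowpass",
                     fs=sampling_rate, output="sos")
    smooth = sps.sosfiltfilt(sos, position, axis=1)
    velocity = np.gradient(smooth, axis=1) * sampling_rate
    return np.linalg.norm(velocity, axis=0)


def detect_onset(
    speed: np.ndarray,
    sampling_rate: float = 1000.0,
    threshold_fraction: float = 0.05,
    hold_ms: float = 50.0,
) -> tuple[int, int]:
    """Movement onset and completion from a tangential speed series.

    Onset is the first sample before the global speed peak from which the
    speed stays above ``threshold_fraction`` of the peak all the way to the
    peak (the crossing that leads monotonically into the movement, robust to
    baseline noise).  Completion is the first post-peak sample where speed
    drops below threshold and stays below for at least ``hold_ms``.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0 or not np.any(speed > 0):
        raise NoMovementError("no movement detected: speed has no positive peak")
    peak = int(np.argmax(speed))
    thr = threshold_fraction * speed[peak]

    below = np.nonzero(speed[: peak + 1] <= thr)[0]
    onset = int(below[-1]) + 1 if below.size else 0

    hold = max(1, int(round(hold_ms / 1000.0 * sampling_rate)))
    after = speed[peak:]
    below_after = after < thr
    completion = len(speed) - 1
    idx = np.nonzero(below_after)[0]
    for i in idx:
        run = below_after[i : i + hold]
        # accept a shorter run only if it reaches the end of the recording
        if run.all():
            completion = peak + int(i)
            break
    return onset, completion


def extract_window(
    trial: EmgTrial,
    onset: int | None = None,
    half_width_ms: float = 100.0,
) -> Window:
    """Extract the [-100, +100) ms window around movement onset.

    Half-open sample range ``[onset - 0.1*fs, onset + 0.1*fs)``: exactly
    200 samples at 1000 Hz, 300 at 1500 Hz.
    """
    if onset is None:
        onset = trial.onset_sample
    if onset is None:
        raise ConfigError("no onset provided and trial.onset_sample is unset")
    half = int(round(half_width_ms / 1000.0 * trial.sampling_rate))
    start, stop = onset - half, onset + half
    if start < 0 or stop > trial.n_samples:
        raise TrialTooShortError(
            f"trial too short: window [{start}, {stop}) outside 0..{trial.n_samples}"
        )
    return Window(
        signals=trial.signals[:, start:stop].copy(),
        sampling_rate=trial.sampling_rate,
        channel_names=trial.channel_names,
        direction_deg=trial.direction_deg,
        onset_sample=int(onset),
        envelope=None if trial.envelope is None else trial.envelope[:, start:stop].copy(),
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        duration_ms=trial.duration_ms,
    )


def drop_channels(session: Sequence[EmgTrial], names: Sequence[str]) -> list[EmgTrial]:
    """Remove the listed channels from every trial, preserving the order of
    the remaining channels (e.g. discarding a detached electrode)."""
    out = []
    names = list(names)
    for trial in session:
        unknown = [n for n in names if n not in trial.channel_names]
        if unknown:
            raise ChannelMismatchError(f"unknown channel(s): {unknown}")
        keep = [i for i, ch in enumerate(trial.channel_names) if ch not in names]
        new = dataclasses.replace(
            trial,
            signals=trial.signals[keep],
            channel_names=tuple(trial.channel_names[i] for i in keep),
        )
        if trial.envelope is not None:
            new.envelope = trial.envelope[keep]
        out.append(new)
    return out


def window_session(
    session: Sequence[EmgTrial],
    cfg: FilterConfig | None = None,
    use_detected_onset: bool = True,
) -> list[Window]:
    """Filter every trial and extract its analysis window.

    When kinematics are present and ``use_detected_onset`` is set, onset is
    detected from the tangential speed; otherwise the trial's stored
    ``onset_sample`` is used.
    """
    cfg = cfg or FilterConfig()
    windows = []
    for trial in session:
        filtered = filter_emg(trial, cfg)
        onset = trial.onset_sample
        if use_detected_onset and trial.position is not None:
            speed = tangential_speed(trial.position, trial.sampling_rate, cfg)
            onset, _ = detect_onset(speed, trial.sampling_rate)
        windows.append(extract_window(filtered, onset))
    return windows
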