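"""Synthetic multichannel surface-EMG sessions for planar reaching.

This module generates trial recordings with the statistical structure the
downstream analysis assumes, so the whole pipeline can be exercised without
any recorded human data.  Each virtual subject is a set of muscles with
cosine-power directional tuning: a muscle fires a burst whose amplitude
scales with ``max(0, cos(theta - preferred))**width`` for a reach toward
angle ``theta``.  The burst is realised as band-limited (20-450 Hz) Gaussian
noise amplitude-modulated by a smooth envelope that rises 50 ms before the
kinematic movement onset — surface EMG leads action initiation by tens of
milliseconds — and the hand follows a minimum-jerk path to the target.

Stroke-like virtual subjects add, in proportion to a ``severity`` knob:

* a shift of each muscle's preferred activation direction,
* a raised antagonist co-contraction floor,
* agonist-antagonist synergy coupling (shared-drive injection of the
  partner's burst),
* tonic trunk-muscle activity, and
* inflated inter-trial per-channel gain variance.

All randomness flows from explicit integer seeds; identical
(subject, design) pairs produce bit-identical sessions.
"""

from __future__ import annotations

import functools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import ConfigError

__all__ = [
    "CARDINAL_DIRECTIONS",
    "EMG_BAND_HZ",
    "EmgTrial",
    "Impairment",
    "MuscleModel",
    "SessionDesign",
    "SubjectModel",
    "agonists_for",
    "healthy_protocol",
    "load_generator_config",
    "make_healthy_subject",
    "make_stroke_subject",
    "minimum_jerk_displacement",
    "patient_protocol",
    "read_session",
    "simulate_session",
    "simulate_trial",
    "write_session",
]

#: Acquisition bandwidth of surface EMG, Hz.
EMG_BAND_HZ = (20.0, 450.0)

#: Cardinal target angles in degrees, mathematical convention
#: (East = 0 deg, counterclockwise positive).
CARDINAL_DIRECTIONS: dict[str, float] = {"N": 90.0, "E": 0.0, "S": 270.0, "W": 180.0}

#: Preferred activation directions (degrees) of the seven-muscle arm set:
#: triceps drives North, the medial/posterior deltoids East, upper trapezius
#: and biceps South, pectoralis and anterior deltoid West.
HEALTHY_PREFERRED_DEG: dict[str, float] = {
    "PM": 180.0,
    "DP": 350.0,
    "DM": 10.0,
    "DA": 200.0,
    "BI": 260.0,
    "TR": 90.0,
    "UT": 280.0,
}

# Relative burst-amplitude factors; pairs sharing a quadrant are split so the
# strongest channel per direction is unambiguous in expectation.
_HEALTHY_GAIN_FACTOR = {
    "PM": 1.00,
    "DP": 0.85,
    "DM": 1.00,
    "DA": 0.80,
    "BI": 0.90,
    "TR": 1.00,
    "UT": 1.00,
}

#: Muscles acting on the trunk / shoulder girdle (receive tonic drive in
#: impaired subjects) and the back subset used by the relevance profiles.
TRUNK_MUSCLES = frozenset({"UT", "MT", "LT", "TM"})
BACK_MUSCLES = frozenset({"MT", "LT", "TM"})

# Generator amplitude scale, volts, on the *recorded* signal (the
# acquisition chain amplifies electrode-scale EMG by 1000x, so a ~120 uV
# burst is recorded as ~0.12 V); the 0.025 V zero-crossing threshold is
# defined on this scale.
_BASE_TUNING_GAIN_V = 0.12
_BASE_NOISE_SD_V = 8.0e-3
_HEALTHY_ANTAGONIST_FLOOR = 0.05

# Burst-envelope timing, seconds.
_ENVELOPE_LEAD_S = 0.050   # burst starts this long before kinematic onset
_ENVELOPE_RISE_S = 0.100
_ENVELOPE_DECAY_S = 0.150
_PRE_HOLD_S = 0.400        # quiet hold before movement onset
_POST_HOLD_S = 0.300

# Always-on per-trial per-channel gain jitter (electrode/skin variability).
_CHANNEL_JITTER_CV = 0.05


@dataclass(frozen=True)
class MuscleModel:
    """Directional tuning model of one recorded muscle.

    Parameters
    ----------
    name : channel label (PM, DP, DM, DA, BI, TR, UT, MT, LT, TM).
    preferred_direction : degrees in [0, 360); reach angle of maximal drive.
    tuning_gain : burst amplitude at the preferred direction, volts.
    tuning_width_exponent : cosine-power tuning exponent, >= 1.
    antagonist_floor : co-contraction level in [0, 1], fraction of
        ``tuning_gain`` present during any burst regardless of direction.
    baseline_noise_sd : resting-noise standard deviation, volts.
    """

    name: str
    preferred_direction: float
    tuning_gain: float
    tuning_width_exponent: float = 2.0
    antagonist_floor: float = _HEALTHY_ANTAGONIST_FLOOR
    baseline_noise_sd: float = _BASE_NOISE_SD_V

    def __post_init__(self) -> None:
        if self.tuning_gain < 0:
            raise ConfigError(f"{self.name}: tuning_gain must be >= 0")
        if not 0.0 <= self.antagonist_floor <= 1.0:
            raise ConfigError(f"{self.name}: antagonist_floor must be in [0, 1]")
        if self.baseline_noise_sd <= 0:
            raise ConfigError(f"{self.name}: baseline_noise_sd must be > 0")
        if self.tuning_width_exponent < 1:
            raise ConfigError(f"{self.name}: tuning_width_exponent must be >= 1")
        object.__setattr__(self, "preferred_direction", float(self.preferred_direction) % 360.0)


@dataclass(frozen=True)
class Impairment:
    """Stroke-like perturbation descriptor applied on top of healthy tuning.

    ``direction_shift`` maps muscle name to a preferred-direction shift in
    degrees; ``coactivation_coupling`` lists ``(muscle_a, muscle_b, gain)``
    shared-drive pairs; ``trial_gain_cv`` is the coefficient of variation of
    the per-channel inter-trial gain; ``tonic_trunk_gain`` (volts) adds a
    direction-independent tonic drive to trunk muscles.
    """

    direction_shift: Mapping[str, float] = field(default_factory=dict)
    coactivation_coupling: tuple[tuple[str, str, float], ...] = ()
    trial_gain_cv: float = 0.0
    tonic_trunk_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.trial_gain_cv < 0:
            raise ConfigError("trial_gain_cv must be >= 0")
        if self.tonic_trunk_gain < 0:
            raise ConfigError("tonic_trunk_gain must be >= 0")


@dataclass(frozen=True)
class SubjectModel:
    """A virtual subject: ordered muscle set plus an impairment descriptor."""

    muscles: tuple[MuscleModel, ...]
    impairment: Impairment = field(default_factory=Impairment)
    seed: int = 0
    subject_id: str = "S0"
    group: str = "healthy"

    def __post_init__(self) -> None:
        names = [m.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise ConfigError("muscle names must be unique")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    def muscle(self, name: str) -> MuscleModel:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass(frozen=True)
class SessionDesign:
    """Targets, movement durations, repetitions and sampling rate of a session."""

    directions: tuple[float, ...]
    durations: tuple[float, ...]          # movement times, ms
    repetitions: int
    target_distance: float = 0.14          # meters, center-to-target
    sampling_rate: float = 1000.0          # Hz

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if any(d <= 0 for d in self.durations):
            raise ConfigError("all durations must be > 0")
        dirs = [float(d) % 360.0 for d in self.directions]
        if len(set(dirs)) != len(dirs):
            raise ConfigError("directions must be distinct modulo 360")
        if self.sampling_rate <= 2 * EMG_BAND_HZ[1]:
            raise ConfigError("sampling_rate must exceed twice the EMG band edge")
        object.__setattr__(self, "directions", tuple(dirs))
        object.__setattr__(self, "durations", tuple(float(d) for d in self.durations))

    @property
    def n_trials(self) -> int:
        return len(self.directions) * len(self.durations) * self.repetitions


@dataclass
class EmgTrial:
    """One reaching trial: channel x sample EMG plus optional kinematics.

    ``signals`` is a (n_channels, n_samples) array in volts; ``position``
    (when present) is a (2, n_samples) array in meters.  ``onset_sample``
    is the index of kinematic movement onset and, when set, must leave at
    least 100 ms of recording on each side.
    """

    signals: np.ndarray
    sampling_rate: float
    direction_deg: float
    channel_names: tuple[str, ...]
    onset_sample: int | None = None
    position: np.ndarray | None = None
    duration_ms: float | None = None
    trial_id: str = ""
    subject_id: str = ""
    group: str = "healthy"
    bandpassed: bool = True
    envelope: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ConfigError("signals must be a 2-D channel x sample array")
        if self.signals.shape[0] != len(self.channel_names):
            raise ConfigError("signals row count must equal the number of channel names")
        if self.onset_sample is not None:
            margin = int(round(0.1 * self.sampling_rate))
            if not (margin <= self.onset_sample <= self.n_samples - margin):
                raise ConfigError("onset_sample must leave a 100 ms margin on each side")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def healthy_protocol(sampling_rate: float = 1000.0) -> SessionDesign:
    """The healthy-subject protocol: 4 cardinal targets x 3 movement
    durations (1000/600/300 ms) x 5 repetitions = 60 trials."""
    return SessionDesign(
        directions=(90.0, 0.0, 270.0, 180.0),
        durations=(1000.0, 600.0, 300.0),
        repetitions=5,
        sampling_rate=sampling_rate,
    )


def patient_protocol(sampling_rate: float = 1000.0) -> SessionDesign:
    """The patient protocol: 8 targets, self-paced (one nominal duration),
    10 repetitions per direction (5 per electrode block, two blocks) for a
    full session of 80 trials."""
    return SessionDesign(
        directions=tuple(float(a) for a in range(0, 360, 45)),
        durations=(1000.0,),
        repetitions=10,
        sampling_rate=sampling_rate,
    )


def make_healthy_subject(seed: int) -> SubjectModel:
    """Build the seven-muscle healthy model (PM, DP, DM, DA, BI, TR, UT).

    Preferred directions are fixed across seeds (they encode the normal
    directional map); the seed only jitters per-muscle burst gains by
    +/-10%, emulating inter-subject amplitude differences.
    """
    rng = np.random.default_rng(seed)
    muscles = []
    for name, pref in HEALTHY_PREFERRED_DEG.items():
        jitter = rng.uniform(0.9, 1.1)
        muscles.append(
            MuscleModel(
                name=name,
                preferred_direction=pref,
                tuning_gain=_BASE_TUNING_GAIN_V * _HEALTHY_GAIN_FACTOR[name] * jitter,
            )
        )
    return SubjectModel(
        muscles=tuple(muscles), seed=int(seed), subject_id=f"H{seed}", group="healthy"
    )


def make_stroke_subject(seed: int, severity: float) -> SubjectModel:
    """Build a stroke-like subject by perturbing the healthy model.

    ``severity`` in [0, 1] scales every abnormality linearly: preferred-
    direction shifts (idiosyncratic, 30-90 deg at severity 1), the
    antagonist co-contraction floor, agonist-antagonist synergy coupling
    (BI-TR and DP-DA), inter-trial per-channel gain variance and tonic
    trunk drive.  ``severity=0`` returns the healthy model unchanged.
    """
    if not 0.0 <= severity <= 1.0:
        raise ConfigError("severity must be in [0, 1]")
    healthy = make_healthy_subject(seed)
    rng = np.random.default_rng([int(seed), 0x57C0])

    shifts: dict[str, float] = {}
    for m in healthy.muscles:
        magnitude = rng.uniform(30.0, 90.0) * rng.choice([-1.0, 1.0])
        if severity > 0:
            shifts[m.name] = severity * magnitude

    coupling = []
    for pair in (("BI", "TR"), ("DP", "DA")):
        gain = rng.uniform(0.6, 0.95)
        if severity > 0:
            coupling.append((pair[0], pair[1], severity * gain))

    muscles = tuple(
        replace(m, antagonist_floor=_HEALTHY_ANTAGONIST_FLOOR + 0.35 * severity)
        for m in healthy.muscles
    )
    impairment = Impairment(
        direction_shift=shifts,
        coactivation_coupling=tuple(coupling),
        trial_gain_cv=0.5 * severity,
        tonic_trunk_gain=0.06 * severity,
    )
    group = "healthy" if severity == 0 else "stroke"
    subject_id = f"H{seed}" if severity == 0 else f"P{seed}"
    return SubjectModel(
        muscles=muscles, impairment=impairment, seed=int(seed),
        subject_id=subject_id, group=group,
    )


def minimum_jerk_displacement(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement 10 t^3 - 15 t^4 + 6 t^5 on [0, 1].

    Its speed profile peaks at 1.875 x distance / duration at mid-movement.
    """
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


@functools.lru_cache(maxsize=8)
def _band_sos(sampling_rate: float) -> np.ndarray:
    low, high = EMG_BAND_HZ
    return sps.butter(4, (low, high), btype="bandpass", fs=sampling_rate, output="sos")


def _band_limited_noise(n: int, sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise shaped to the 20-450 Hz EMG band."""
    white = rng.standard_normal(n)
    shaped = sps.sosfiltfilt(_band_sos(sampling_rate), white)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _burst_envelope(n: int, onset: int, n_move: int, fs: float) -> np.ndarray:
    """Smooth 0->1->0 burst envelope rising 50 ms before kinematic onset."""
    t = np.arange(n, dtype=float)
    start = onset - _ENVELOPE_LEAD_S * fs
    rise = _ENVELOPE_RISE_S * fs
    env = _smoothstep((t - start) / rise)
    move_end = onset + n_move
    decay = _ENVELOPE_DECAY_S * fs
    env = env * (1.0 - _smoothstep((t - move_end) / decay))
    return env


def _directional_amplitudes(subject: SubjectModel, direction_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-muscle tuned and total burst amplitudes (volts) toward a direction."""
    imp = subject.impairment
    tuned = np.empty(len(subject.muscles))
    floor = np.empty(len(subject.muscles))
    for i, m in enumerate(subject.muscles):
        pref = m.preferred_direction + imp.direction_shift.get(m.name, 0.0)
        delta = np.deg2rad(direction_deg - pref)
        tuned[i] = m.tuning_gain * max(0.0, np.cos(delta)) ** m.tuning_width_exponent
        floor[i] = m.antagonist_floor * m.tuning_gain
    return tuned, floor


def simulate_trial(
    subject: SubjectModel,
    direction: float,
    duration: float,
    rng: np.random.Generator,
    sampling_rate: float = 1000.0,
    target_distance: float = 0.14,
    trial_id: str = "",
) -> EmgTrial:
    """Simulate one reaching trial toward ``direction`` (degrees).

    ``duration`` is the movement time in ms.  The recording holds 400 ms of
    rest, the movement, and 300 ms of rest; ``onset_sample`` marks the true
    kinematic start.  The hand follows a minimum-jerk path of length
    ``target_distance`` and each EMG channel is band-limited noise
    amplitude-modulated by the muscle's directional burst envelope.
    """
    if duration <= 0:
        raise ConfigError("duration must be > 0")
    fs = float(sampling_rate)
    n_pre = int(round(_PRE_HOLD_S * fs))
    n_move = int(round(duration / 1000.0 * fs))
    n_post = int(round(_POST_HOLD_S * fs))
    n = n_pre + n_move + n_post
    onset = n_pre

    env = _burst_envelope(n, onset, n_move, fs)
    tuned, floor = _directional_amplitudes(subject, direction)
    imp = subject.impairment
    names = subject.channel_names
    index = {name: i for i, name in enumerate(names)}

    # Per-trial gains: impairment-scaled inter-trial variance plus a small
    # always-on electrode/skin jitter.  Draw order is fixed for determinism.
    if imp.trial_gain_cv > 0:
        sigma = np.sqrt(np.log1p(imp.trial_gain_cv**2))
        g_trial = rng.lognormal(-0.5 * sigma**2, sigma, size=len(names))
    else:
        g_trial = np.ones(len(names))
    sigma_j = np.sqrt(np.log1p(_CHANNEL_JITTER_CV**2))
    g_trial = g_trial * rng.lognormal(-0.5 * sigma_j**2, sigma_j, size=len(names))

    carriers = np.stack([_band_limited_noise(n, fs, rng) for _ in names])

    signals = np.empty((len(names), n))
    for i, m in enumerate(subject.muscles):
        amp = subject.muscles[i].baseline_noise_sd + g_trial[i] * (tuned[i] + floor[i]) * env
        if m.name in TRUNK_MUSCLES and imp.tonic_trunk_gain > 0:
            amp = amp + imp.tonic_trunk_gain
        signals[i] = amp * carriers[i]
    # Shared-drive synergy coupling: inject the partner's tuned burst with
    # the partner's own carrier so coupled channels are correlated.
    for a, b, gain in imp.coactivation_coupling:
        ia, ib = index[a], index[b]
        signals[ia] = signals[ia] + gain * g_trial[ib] * tuned[ib] * env * carriers[ib]
        signals[ib] = signals[ib] + gain * g_trial[ia] * tuned[ia] * env * carriers[ia]

    tau = (np.arange(n) - onset) / max(n_move, 1)
    path = target_distance * minimum_jerk_displacement(tau)
    theta = np.deg2rad(direction)
    position = np.stack([path * np.cos(theta), path * np.sin(theta)])

    return EmgTrial(
        signals=signals,
        sampling_rate=fs,
        direction_deg=float(direction) % 360.0,
        channel_names=names,
        onset_sample=onset,
        position=position,
        duration_ms=float(duration),
        trial_id=trial_id,
        subject_id=subject.subject_id,
        group=subject.group,
        bandpassed=True,
    )


def simulate_session(subject: SubjectModel, design: SessionDesign) -> list[EmgTrial]:
    """Simulate a full session in randomized trial order.

    Order and noise are reproducible from ``subject.seed``.
    """
    conditions = [
        (d, dur)
        for dur in design.durations
        for d in design.directions
        for _ in range(design.repetitions)
    ]
    rng = np.random.default_rng([subject.seed, 0x5E55])
    order = rng.permutation(len(conditions))
    trials = []
    for k, idx in enumerate(order):
        direction, dur = conditions[idx]
        trials.append(
            simulate_trial(
                subject,
                direction,
                dur,
                rng,
                sampling_rate=design.sampling_rate,
                target_distance=design.target_distance,
                trial_id=f"{subject.subject_id}_t{k:03d}",
            )
        )
    return trials


def agonists_for(subject: SubjectModel, direction: float, tolerance: float = 45.0) -> list[str]:
    """Muscle names whose (shifted) preferred direction lies within
    ``tolerance`` degrees of ``direction`` — the generator's ground-truth
    agonist set for that reach."""
    out = []
    for m in subject.muscles:
        pref = m.preferred_direction + subject.impairment.direction_shift.get(m.name, 0.0)
        delta = (direction - pref + 180.0) % 360.0 - 180.0
        if abs(delta) <= tolerance:
            out.append(m.name)
    return out


# ---------------------------------------------------------------------------
# Session I/O: one CSV per trial plus a TSV manifest.

def write_session(trials: Sequence[EmgTrial], outdir: str | Path) -> Path:
    """Write one CSV per trial (time_s, channels, pos_x, pos_y) plus a
    ``manifest.tsv``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, tr in enumerate(trials):
        name = f"{tr.trial_id or f'trial{k:03d}'}.csv"
        data = {"time_s": tr.times}
        for i, ch in enumerate(tr.channel_names):
            data[ch] = tr.signals[i]
        if tr.position is not None:
            data["pos_x"] = tr.position[0]
            data["pos_y"] = tr.position[1]
        pd.DataFrame(data).to_csv(outdir / name, index=False)
        rows.append(
            {
                "trial_file": name,
                "direction_deg": tr.direction_deg,
                "duration_ms": tr.duration_ms if tr.duration_ms is not None else "",
                "onset_sample": tr.onset_sample if tr.onset_sample is not None else "",
                "subject_id": tr.subject_id,
                "group": tr.group,
                "sampling_rate": tr.sampling_rate,
                "bandpassed": int(tr.bandpassed),
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_session(manifest_path: str | Path) -> list[EmgTrial]:
    """Read a session written by :func:`write_session`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, sep="\t")
    trials = []
    for _, row in table.iterrows():
        frame = pd.read_csv(base / row["trial_file"])
        pos_cols = [c for c in ("pos_x", "pos_y") if c in frame.columns]
        channels = [c for c in frame.columns if c not in ("time_s", "pos_x", "pos_y")]
        position = frame[pos_cols].to_numpy().T if len(pos_cols) == 2 else None
        onset = row.get("onset_sample")
        trials.append(
            EmgTrial(
                signals=frame[channels].to_numpy().T,
                sampling_rate=float(row["sampling_rate"]),
                direction_deg=float(row["direction_deg"]),
                channel_names=tuple(channels),
                onset_sample=None if pd.isna(onset) else int(onset),
                position=position,
                duration_ms=None if pd.isna(row.get("duration_ms")) else float(row["duration_ms"]),
                trial_id=str(Path(row["trial_file"]).stem),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                bandpassed=bool(int(row.get("bandpassed", 1))),
            )
        )
    return trials


def load_generator_config(path: str | Path) -> tuple[SubjectModel, SessionDesign]:
    """Build a subject and session design from a YAML generator config.

    The config mirrors the model fields::

        subject:
          kind: healthy | stroke
          seed: 1
          severity: 0.5        # stroke only
        design:
          protocol: healthy | patient   # or explicit fields below
          directions: [90, 0, 270, 180]
          durations: [1000, 600, 300]
          repetitions: 5
          sampling_rate: 1000
          target_distance: 0.14
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    sub = cfg.get("subject", {})
    kind = sub.get("kind", "healthy")
    seed = int(sub.get("seed", 0))
    if kind == "healthy":
        subject = make_healthy_subject(seed)
    elif kind == "stroke":
        subject = make_stroke_subject(seed, float(sub.get("severity", 1.0)))
    else:
        raise ConfigError(f"unknown subject kind: {kind!r}")

    des = cfg.get("design", {})
    protocol = des.get("protocol")
    fs = float(des.get("sampling_rate", 1000.0))
    if protocol == "healthy":
        design = healthy_protocol(sampling_rate=fs)
    elif protocol == "patient":
        design = patient_protocol(sampling_rate=fs)
    elif protocol is None:
        design = SessionDesign(
            directions=tuple(des.get("directions", (90.0, 0.0, 270.0, 180.0))),
            durations=tuple(des.get("durations", (1000.0, 600.0, 300.0))),
            repetitions=int(des.get("repetitions", 5)),
            target_distance=float(des.get("target_distance", 0.14)),
            sampling_rate=fs,
        )
    else:
        raise ConfigError(f"unknown protocol: {protocol!r}")
    return subject, design
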