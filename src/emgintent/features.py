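"""Time-domain EMG feature families: IAV, AR(4), thresholded ZC, 9-bin HIST.

Each family maps the signed analysis-window samples of one muscle to a small
numeric descriptor; per-trial feature vectors concatenate the descriptors of
all muscles in a fixed order (e.g. HIST on 7 muscles -> 63 components).

Which signal each feature consumes: all four families operate on the signed
(band/high-passed, unrectified) window — IAV rectifies internally, ZC and
HIST are defined on signed data.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .errors import ChannelMismatchError, ConfigError, DegenerateSignalError
from .preprocess import Window

__all__ = [
    "FEATURE_KINDS",
    "FeatureVector",
    "HistConfig",
    "ar_coefficients",
    "build_feature_matrix",
    "compute_reference_max",
    "feature_matrix",
    "hist_feature",
    "iav",
    "zero_crossings",
]

FEATURE_KINDS = ("hist", "zc", "ar", "iav")


@dataclass(frozen=True)
class HistConfig:
    """Histogram-feature configuration.

    ``reference_max`` maps each muscle to its maximal absolute activation
    (volts) over the calibration set; the 9 equal bins span the symmetric
    range [-reference_max, +reference_max].  The bin count is odd so a
    center bin straddles the baseline.  The calibration set should be the
    training split only, to avoid leakage into held-out trials.
    """

    n_bins: int = 9
    reference_max: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_bins < 3 or self.n_bins % 2 == 0:
            raise ConfigError("n_bins must be odd and >= 3")
        for name, value in self.reference_max.items():
            if not value > 0:
                raise ConfigError(f"reference_max for {name} must be > 0")


@dataclass(frozen=True)
class FeatureVector:
    """Per-trial concatenated feature values with provenance.

    ``layout`` pairs each component with its (muscle, component-name)
    origin, e.g. ``("TR", "hist_1")``.
    """

    values: np.ndarray
    layout: tuple[tuple[str, str], ...]
    trial_id: str
    direction_deg: float
    subject_id: str = ""


def iav(samples: np.ndarray) -> float:
    """Integral of absolute value: (1/N) sum |x_i|."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ConfigError("iav requires at least one sample")
    return float(np.mean(np.abs(samples)))


def ar_coefficients(samples: np.ndarray, order: int = 4) -> np.ndarray:
    """Autoregressive coefficients a_1..a_order of x_i ~ sum a_k x_{i-k}.

    Estimated by the Yule-Walker autocorrelation method (biased/MLE
    autocovariances), which is deterministic and order-stable.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size <= order:
        raise ConfigError(f"need more than {order} samples")
    if np.ptp(samples) == 0 or np.std(samples) < 1e-300:
        raise DegenerateSignalError("constant signal: degenerate autocorrelation")
    rho, _sigma = yule_walker(samples, order=order, method="mle")
    return np.asarray(rho, dtype=float)


def zero_crossings(samples: np.ndarray, threshold: float = 0.025) -> int:
    """Thresholded zero-crossing count.

    Counts indices i where ``-x_i * x_{i+1} > threshold``: a sign change
    whose product magnitude exceeds the threshold (literal form; the
    threshold applies to the product, in V^2 for volt-scale input).
    Set ``threshold=0`` for plain sign-change counting.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ConfigError("zero_crossings requires at least 2 samples")
    product = -samples[:-1] * samples[1:]
    return int(np.count_nonzero(product > threshold))


def zero_crossings_amplitude(samples: np.ndarray, threshold: float = 0.025) -> int:
    """Amplitude-difference ZC variant: sign change and |x_i - x_{i+1}| >
    threshold (volts).  Alternative to the literal product form."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ConfigError("zero_crossings requires at least 2 samples")
    sign_change = samples[:-1] * samples[1:] < 0
    big_step = np.abs(np.diff(samples)) > threshold
    return int(np.count_nonzero(sign_change & big_step))


def hist_feature(samples: np.ndarray, cfg: HistConfig, muscle: str) -> np.ndarray:
    """Relative-frequency histogram over the muscle's symmetric voltage range.

    The range [-reference_max, +reference_max] is split into ``n_bins``
    equal bins; out-of-range samples clamp to the outermost bins.  Returns
    frequencies summing to 1.
    """
    if muscle not in cfg.reference_max:
        raise ConfigError(f"reference_max missing for muscle {muscle!r}")
    ref = cfg.reference_max[muscle]
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ConfigError("hist_feature requires at least one sample")
    edges = np.linspace(-ref, ref, cfg.n_bins + 1)
    clamped = np.clip(samples, -ref, ref)
    counts, _ = np.histogram(clamped, bins=edges)
    return counts / samples.size


def compute_reference_max(windows: Sequence[Window]) -> dict[str, float]:
    """Per-muscle maximal absolute signed value across the calibration set."""
    if not windows:
        raise ConfigError("empty calibration set")
    names = windows[0].channel_names
    ref = {name: 0.0 for name in names}
    for w in windows:
        if w.channel_names != names:
            raise ChannelMismatchError("heterogeneous channel sets in calibration set")
        peaks = np.max(np.abs(w.signals), axis=1)
        for name, p in zip(names, peaks):
            ref[name] = max(ref[name], float(p))
    return {name: (v if v > 0 else 1e-12) for name, v in ref.items()}


def _trial_features(
    window: Window, kind: str, hist_cfg: HistConfig | None, ar_order: int, zc_threshold: float
) -> tuple[np.ndarray, tuple[tuple[str, str], ...]]:
    values: list[float] = []
    layout: list[tuple[str, str]] = []
    for i, muscle in enumerate(window.channel_names):
        x = window.signals[i]
        if kind == "hist":
            h = hist_feature(x, hist_cfg, muscle)
            values.extend(h)
            layout.extend((muscle, f"hist_{b + 1}") for b in range(len(h)))
        elif kind == "ar":
            a = ar_coefficients(x, order=ar_order)
            values.extend(a)
            layout.extend((muscle, f"ar_{k + 1}") for k in range(len(a)))
        elif kind == "zc":
            values.append(float(zero_crossings(x, threshold=zc_threshold)))
            layout.append((muscle, "zc"))
        elif kind == "iav":
            values.append(iav(x))
            layout.append((muscle, "iav"))
        else:
            raise ConfigError(f"unknown feature kind: {kind!r}")
    return np.asarray(values, dtype=float), tuple(layout)


def build_feature_matrix(
    windows: Sequence[Window],
    kind: str,
    hist_cfg: HistConfig | None = None,
    ar_order: int = 4,
    zc_threshold: float = 0.025,
) -> list[FeatureVector]:
    """Per-trial feature vectors for one feature family.

    All windows must share the same channel set; components are concatenated
    in fixed muscle order (HIST on 7 muscles -> 63 components per trial).
    For ``kind="hist"`` a :class:`HistConfig` with calibrated
    ``reference_max`` is required.
    """
    if kind not in FEATURE_KINDS:
        raise ConfigError(f"unknown feature kind: {kind!r} (expected one of {FEATURE_KINDS})")
    if not windows:
        return []
    names = windows[0].channel_names
    if kind == "hist" and hist_cfg is None:
        hist_cfg = HistConfig(reference_max=compute_reference_max(windows))
    out = []
    for w in windows:
        if w.channel_names != names:
            raise ChannelMismatchError("heterogeneous channel sets across trials")
        values, layout = _trial_features(w, kind, hist_cfg, ar_order, zc_threshold)
        out.append(
            FeatureVector(
                values=values,
                layout=layout,
                trial_id=w.trial_id,
                direction_deg=w.direction_deg,
                subject_id=w.subject_id,
            )
        )
    return out


def feature_matrix(vectors: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into (X, y) arrays for model fitting."""
    X = np.stack([fv.values for fv in vectors])
    y = np.asarray([fv.direction_deg for fv in vectors])
    return X, y
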