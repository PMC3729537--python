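"""Coefficient of Expressiveness (CoE): PCA-based muscle-relevance index.

For each trial, PCA is applied to the channel covariance of the signed
filtered EMG inside the [-100, +100] ms window.  With eigenvalues
lambda_1 >= ... >= lambda_p and c_il the magnitude of the Pearson
correlation between the i-th principal-component score series and the
signal of muscle l, the per-muscle index is

    k_l = sum_{i <= n} c_il * lambda_i / sum_m lambda_m

where n is the smallest number of components reaching 80% of the total
variance.  CoE_l = k_l / max_l k_l, so exactly one muscle scores 1 per
trial; muscles with CoE <= 0.7 are judged non-relevant and set to 0.
Directional profiles average the thresholded values across trials (and
subjects) and carry 1.96 * SE half-widths.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .errors import ChannelMismatchError, ConfigError, DegenerateSignalError
from .preprocess import Window
from .synth import BACK_MUSCLES

__all__ = [
    "CoeProfile",
    "CoeTrial",
    "MuscleFindings",
    "abnormality_flags",
    "coe_profile",
    "coe_trial",
]


@dataclass(frozen=True)
class CoeTrial:
    """Per-trial muscle-relevance decomposition.

    ``coe_values`` are the thresholded coefficients (non-relevant muscles
    set to 0); ``raw_coe`` the pre-threshold normalized values;
    ``correlations`` the |Pearson r| matrix of PC scores x muscle signals.
    """

    channel_names: tuple[str, ...]
    direction_deg: float
    k_values: np.ndarray
    raw_coe: np.ndarray
    coe_values: np.ndarray
    relevant: np.ndarray
    n_components: int
    eigenvalues: np.ndarray
    correlations: np.ndarray
    trial_id: str = ""
    subject_id: str = ""


@dataclass(frozen=True)
class CoeProfile:
    """Directional CoE summary: per (muscle, direction) mean and 1.96*SE.

    ``coe_m`` and ``half_width`` are (n_muscles, n_directions) arrays; a NaN
    half-width marks a direction with fewer than 2 trials.
    """

    muscles: tuple[str, ...]
    directions: tuple[float, ...]
    coe_m: np.ndarray
    half_width: np.ndarray
    n_trials: np.ndarray

    def for_muscle(self, muscle: str) -> dict[float, tuple[float, float]]:
        i = self.muscles.index(muscle)
        return {
            d: (float(self.coe_m[i, j]), float(self.half_width[i, j]))
            for j, d in enumerate(self.directions)
        }


@dataclass(frozen=True)
class MuscleFindings:
    """Abnormality flags for one muscle relative to a reference profile."""

    muscle: str
    preferred_shift: bool = False
    loss_of_tuning: bool = False
    antagonist_coactivation: bool = False
    trunk_involvement: bool = False

    @property
    def any(self) -> bool:
        return (self.preferred_shift or self.loss_of_tuning
                or self.antagonist_coactivation or self.trunk_involvement)


def coe_trial(
    window: Window,
    variance_threshold: float = 0.80,
    relevance_threshold: float = 0.70,
) -> CoeTrial:
    """Compute the CoE decomposition of one analysis window.

    Requires at least 2 channels and more samples than channels.  A
    constant channel contributes zero correlation (its relevance cannot be
    estimated).
    """
    X = np.asarray(window.signals, dtype=float)
    if X.shape[0] < 2:
        raise ConfigError("coe_trial requires at least 2 channels")
    if X.shape[1] <= X.shape[0]:
        raise ConfigError("coe_trial requires more samples than channels")

    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / (X.shape[1] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0:
        raise DegenerateSignalError("all channels constant: degenerate covariance")

    scores = eigvecs.T @ Xc  # (p, n_samples) PC score series

    p = eigvals.size
    corr = np.zeros((p, X.shape[0]))
    ch_sd = Xc.std(axis=1)
    sc_sd = scores.std(axis=1)
    for i in range(p):
        if sc_sd[i] == 0:
            continue
        for l in range(X.shape[0]):
            if ch_sd[l] == 0:
                continue  # constant channel: correlation defined as 0
            r = np.mean(scores[i] * Xc[l]) / (sc_sd[i] * ch_sd[l])
            corr[i, l] = abs(r)

    fractions = np.cumsum(eigvals) / total
    n = int(np.searchsorted(fractions, variance_threshold - 1e-12) + 1)

    k = (corr[:n] * eigvals[:n, None]).sum(axis=0) / total
    k_max = k.max()
    if k_max <= 0:
        raise DegenerateSignalError("degenerate CoE: all k indices are zero")
    raw = k / k_max
    coe = np.where(raw > relevance_threshold, raw, 0.0)
    return CoeTrial(
        channel_names=window.channel_names,
        direction_deg=window.direction_deg,
        k_values=k,
        raw_coe=raw,
        coe_values=coe,
        relevant=raw > relevance_threshold,
        n_components=n,
        eigenvalues=eigvals,
        correlations=corr,
        trial_id=window.trial_id,
        subject_id=window.subject_id,
    )


def coe_profile(trials: Sequence[CoeTrial]) -> CoeProfile:
    """Aggregate per-trial CoE values into a directional profile.

    Pools all given trials (across repetitions and, if mixed, subjects) per
    direction; the half-width is 1.96 * sd / sqrt(n) of the thresholded
    values, NaN where a direction has fewer than 2 trials.
    """
    if not trials:
        raise ConfigError("coe_profile requires at least one trial")
    muscles = trials[0].channel_names
    for tr in trials:
        if tr.channel_names != muscles:
            raise ChannelMismatchError("heterogeneous channel sets across CoE trials")
    directions = tuple(sorted({tr.direction_deg for tr in trials}))
    n_m, n_d = len(muscles), len(directions)
    coe_m = np.zeros((n_m, n_d))
    half = np.zeros((n_m, n_d))
    n_trials = np.zeros(n_d, dtype=int)
    for j, d in enumerate(directions):
        values = np.stack([tr.coe_values for tr in trials if tr.direction_deg == d])
        if values.shape[0] == 0:
            raise ConfigError(f"empty direction group: {d}")
        n_trials[j] = values.shape[0]
        coe_m[:, j] = values.mean(axis=0)
        if values.shape[0] >= 2:
            half[:, j] = 1.96 * values.std(axis=0, ddof=1) / np.sqrt(values.shape[0])
        else:
            half[:, j] = np.nan
    return CoeProfile(muscles=muscles, directions=directions,
                      coe_m=coe_m, half_width=half, n_trials=n_trials)


def abnormality_flags(
    profile_patient: CoeProfile,
    profile_reference: CoeProfile,
    flatness_bound: float = 0.2,
    relevance_level: float = 0.5,
    trunk_reference_max: float = 0.3,
    trunk_muscles: frozenset[str] = BACK_MUSCLES,
) -> dict[str, MuscleFindings]:
    """Flag abnormal directional activation patterns against a reference.

    Per muscle: *preferred-direction shift* (the direction of maximal CoE_M
    differs from the reference, both profiles being tuned), *loss of tuning*
    (patient's CoE_M range below ``flatness_bound`` where the reference is
    tuned), *antagonist co-activation* (CoE_M at or above
    ``relevance_level`` in two opposite directions), and *trunk involvement*
    (a back muscle active where the reference shows CoE_M below
    ``trunk_reference_max``).
    """
    if profile_patient.muscles != profile_reference.muscles:
        raise ChannelMismatchError("muscle sets differ between profiles")
    if profile_patient.directions != profile_reference.directions:
        raise ChannelMismatchError("direction sets differ between profiles")
    directions = np.asarray(profile_patient.directions)

    findings: dict[str, MuscleFindings] = {}
    for i, muscle in enumerate(profile_patient.muscles):
        pat = profile_patient.coe_m[i]
        ref = profile_reference.coe_m[i]
        pat_tuned = (pat.max() - pat.min()) >= flatness_bound
        ref_tuned = (ref.max() - ref.min()) >= flatness_bound

        loss = ref_tuned and not pat_tuned
        shift = bool(
            pat_tuned and ref_tuned
            and directions[int(np.argmax(pat))] != directions[int(np.argmax(ref))]
        )
        coact = False
        for j, d in enumerate(directions):
            opposite = (d + 180.0) % 360.0
            jj = np.nonzero(np.isclose(directions, opposite))[0]
            if jj.size and pat[j] >= relevance_level and pat[jj[0]] >= relevance_level:
                coact = True
                break
        trunk = bool(
            muscle in trunk_muscles
            and pat.max() >= relevance_level
            and ref.max() < trunk_reference_max
        )
        findings[muscle] = MuscleFindings(
            muscle=muscle,
            preferred_shift=shift,
            loss_of_tuning=loss,
            antagonist_coactivation=coact,
            trunk_involvement=trunk,
        )
    return findings
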