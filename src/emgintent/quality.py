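"""Feature-space class separability via the Davies-Bouldin index.

For classes (here: movement directions) with mean vectors m_i, the index
averages each class's worst-case overlap ratio with any other class:

    DB = (1/K) * sum_i max_{j != i} R_ij,      R_ij = (S_i + S_j) / D_ij

where D_ij = ||m_i - m_j|| and S_i is the class dispersion.  Lower DB means
better separated classes.  The dispersion is implemented literally as the
*mean squared* distance of the class points to their mean (no square root);
``classic=True`` switches to the textbook RMS dispersion, which makes the
index scale-invariant.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateSeparationError
from .features import HistConfig, build_feature_matrix, feature_matrix
from .preprocess import Window

__all__ = ["DbResult", "LabeledCloud", "davies_bouldin", "dispersion", "rank_features"]


@dataclass(frozen=True)
class LabeledCloud:
    """A labeled point cloud: feature vectors grouped into K >= 2 classes."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        points = np.atleast_2d(np.asarray(self.points, dtype=float))
        labels = np.asarray(self.labels)
        if points.shape[0] != labels.shape[0]:
            raise ConfigError("points and labels must have equal length")
        if np.unique(labels).size < 2:
            raise ConfigError("need at least 2 classes")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "labels", labels)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_points(self, label) -> np.ndarray:
        return self.points[self.labels == label]


@dataclass(frozen=True)
class DbResult:
    """DB score with per-class worst ratios and the full pairwise R matrix."""

    db: float
    per_class_worst: np.ndarray
    pairwise_r: np.ndarray
    classes: np.ndarray


def dispersion(points: np.ndarray, classic: bool = False) -> float:
    """Class dispersion: mean squared distance to the class mean.

    ``classic=True`` returns the root of that mean (textbook form).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ConfigError("dispersion of an empty class is undefined")
    mean = points.mean(axis=0)
    msd = float(np.mean(np.sum((points - mean) ** 2, axis=1)))
    return float(np.sqrt(msd)) if classic else msd


def davies_bouldin(cloud: LabeledCloud, classic: bool = False) -> DbResult:
    """Davies-Bouldin index of a labeled cloud (lower = better separated).

    Raises :class:`DegenerateSeparationError` when two class means coincide.
    """
    classes = cloud.classes
    K = classes.size
    means = np.stack([cloud.class_points(c).mean(axis=0) for c in classes])
    disps = np.array([dispersion(cloud.class_points(c), classic=classic) for c in classes])

    diffs = means[:, None, :] - means[None, :, :]
    D = np.sqrt(np.sum(diffs**2, axis=2))
    off = ~np.eye(K, dtype=bool)
    if np.any(D[off] == 0):
        raise DegenerateSeparationError("degenerate separation: coincident class means")

    with np.errstate(divide="ignore", invalid="ignore"):
        R = (disps[:, None] + disps[None, :]) / D
    np.fill_diagonal(R, -np.inf)
    worst = R.max(axis=1)
    return DbResult(db=float(worst.mean()), per_class_worst=worst, pairwise_r=R, classes=classes)


def rank_features(
    windows: Sequence[Window],
    kinds: Sequence[str] = ("hist", "zc", "ar", "iav"),
    hist_cfg: HistConfig | None = None,
    standardize: bool = True,
    classic: bool = False,
) -> list[tuple[str, float]]:
    """Rank feature families by DB separability, best (lowest) first.

    One cloud per family: points are the per-trial all-muscle concatenated
    feature vectors, classes are the movement directions.  Each feature
    dimension is z-scored before scoring (``standardize=True``) so families
    living on different physical scales (volt-scale IAV vs unit-scale HIST)
    are compared on a common footing.
    """
    if len(kinds) < 2:
        raise ConfigError("need at least 2 feature kinds to rank")
    results = []
    for kind in kinds:
        vectors = build_feature_matrix(windows, kind, hist_cfg=hist_cfg)
        X, y = feature_matrix(vectors)
        if standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        result = davies_bouldin(LabeledCloud(X, y), classic=classic)
        results.append((kind, result.db))
    return sorted(results, key=lambda item: item[1])
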