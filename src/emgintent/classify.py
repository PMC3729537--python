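"""RBF-SVM direction decoding under the study's validation designs.

The classifier is a one-vs-one multiclass support vector machine with a
Gaussian kernel exp(-||u - v||^2 / (2 sigma^2)), sigma = 2.  Four validation
designs are supported:

* ``individual_holdout`` — stratified 70/30 split within each subject
  (calibrate on the person being decoded);
* ``pooled_holdout`` — stratified 70/30 split of all subjects' pooled trials
  (one general map for the cohort);
* ``leave_subjects_out`` — train on the cohort minus the held-out subjects,
  test on the held-out subjects;
* ``cross_group`` — train on one cohort (e.g. healthy), test per-subject on
  another (e.g. stroke).

The HIST reference range is recalibrated from the training split of every
iteration, so no information from held-out trials leaks into the features.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError
from .features import (
    FeatureVector,
    HistConfig,
    build_feature_matrix,
    compute_reference_max,
    feature_matrix,
)
from .preprocess import Window

__all__ = [
    "ConfusionMatrix",
    "SplitSpec",
    "ValidationResult",
    "confusion_matrix",
    "run_validation",
    "train_svm",
]

DESIGNS = ("individual_holdout", "pooled_holdout", "leave_subjects_out", "cross_group")


@dataclass(frozen=True)
class SplitSpec:
    """A validation design: how trials are partitioned and how often."""

    design: str = "pooled_holdout"
    train_fraction: float = 0.70
    n_iterations: int = 20
    held_out_subjects: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ConfigError(f"unknown design {self.design!r} (expected one of {DESIGNS})")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Column-stochastic percentage table: columns = actual direction,
    rows = predicted direction; each column sums to 100."""

    classes: tuple[float, ...]
    table: np.ndarray          # percentages, rows predicted x cols actual
    n_per_class: np.ndarray    # actual-trial counts per column

    def as_rows(self) -> list[dict]:
        out = []
        for i, predicted in enumerate(self.classes):
            row = {"predicted": predicted}
            for j, actual in enumerate(self.classes):
                row[f"actual_{actual:g}"] = round(float(self.table[i, j]), 1)
            out.append(row)
        return out


@dataclass(frozen=True)
class ValidationResult:
    """Aggregated decoding outcome of one validation design."""

    mean_accuracy: float               # percent
    accuracy_sd: float                 # percent, across iterations
    confusion: ConfusionMatrix
    per_iteration: tuple[float, ...] = ()
    per_subject: Mapping[str, float] = field(default_factory=dict)


def train_svm(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence | None = None,
    C: float = 1.0,
    sigma: float = 2.0,
) -> SVC:
    """Fit the one-vs-one RBF SVM (kernel exp(-||u-v||^2 / (2 sigma^2))).

    Accepts either a list of :class:`FeatureVector` (labels taken from their
    direction) or an (X, labels) pair.  Deterministic given its inputs; the
    misclassification cost C defaults to 1.
    """
    if labels is None:
        X, y = feature_matrix(features)  # type: ignore[arg-type]
    else:
        X, y = np.asarray(features, dtype=float), np.asarray(labels)
    if np.unique(y).size < 2:
        raise ConfigError("need at least 2 classes to train")
    if X.shape[0] < 2:
        raise ConfigError("need at least 2 training samples")
    model = SVC(C=C, kernel="rbf", gamma=1.0 / (2.0 * sigma**2),
                decision_function_shape="ovo")
    model.fit(X, y)
    return model


def confusion_matrix(predictions: Sequence, labels: Sequence,
                     classes: Sequence | None = None) -> ConfusionMatrix:
    """Column-normalized percentage confusion table (columns = actual)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape[0] != labels.shape[0]:
        raise ConfigError("predictions and labels must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([labels, predictions]))
    classes = np.asarray(classes)
    counts = _confusion_counts(predictions, labels, classes)
    return _counts_to_confusion(counts, classes)


def _confusion_counts(predictions, labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((classes.size, classes.size))
    for pred, actual in zip(predictions, labels):
        counts[index[pred], index[actual]] += 1
    return counts


def _counts_to_confusion(counts: np.ndarray, classes) -> ConfusionMatrix:
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        table = np.where(totals > 0, 100.0 * counts / totals, 0.0)
    return ConfusionMatrix(classes=tuple(float(c) for c in classes),
                           table=table, n_per_class=totals)


def _fit_predict(
    train: list[Window],
    test: list[Window],
    feature_kind: str,
    hist_bins: int,
    C: float,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Featurize (calibrating on the training split only), fit, predict."""
    hist_cfg = None
    if feature_kind == "hist":
        hist_cfg = HistConfig(n_bins=hist_bins, reference_max=compute_reference_max(train))
    train_fv = build_feature_matrix(train, feature_kind, hist_cfg=hist_cfg)
    test_fv = build_feature_matrix(test, feature_kind, hist_cfg=hist_cfg)
    X_train, y_train = feature_matrix(train_fv)
    X_test, y_test = feature_matrix(test_fv)
    if feature_kind != "hist":
        # HIST frequencies are already commensurate in [0, 1]; the other
        # families need per-feature standardization for an RBF kernel.
        scaler = StandardScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    model = train_svm(X_train, y_train, C=C, sigma=sigma)
    return model.predict(X_test), y_test


def _stratified_split(windows, labels, train_fraction, rng, max_retries: int = 5):
    """70/30 stratified split guaranteeing every class in the training set."""
    for _ in range(max_retries):
        seed = int(rng.integers(0, 2**31 - 1))
        idx_train, idx_test = train_test_split(
            np.arange(len(windows)), train_size=train_fraction,
            random_state=seed, stratify=labels,
        )
        if set(labels[idx_train]) == set(labels):
            return list(idx_train), list(idx_test)
    raise ConfigError("could not build a split containing every class in training")


def run_validation(
    sessions: Mapping[str, Sequence[Window]],
    split: SplitSpec,
    feature_kind: str = "hist",
    hist_bins: int = 9,
    test_sessions: Mapping[str, Sequence[Window]] | None = None,
    C: float = 1.0,
    sigma: float = 2.0,
    shuffle_labels: bool = False,
    test_on_train: bool = False,
) -> ValidationResult:
    """Run one validation design over per-subject windowed sessions.

    ``sessions`` maps subject id to that subject's analysis windows.  For
    the ``cross_group`` design ``sessions`` is the training cohort and
    ``test_sessions`` the tested one.  ``shuffle_labels`` permutes the
    direction labels before splitting (chance-level control);
    ``test_on_train`` evaluates on the training trials (optimistic-bias
    control, holdout designs only).  Returns the accuracy averaged over
    iterations (and subjects, where the design is per-subject) plus the
    iteration-aggregated confusion matrix.
    """
    if split.design == "cross_group" and test_sessions is None:
        raise ConfigError("cross_group design requires test_sessions")
    all_labels = np.concatenate(
        [[w.direction_deg for w in ws] for ws in sessions.values()]
        + ([[w.direction_deg for w in ws] for ws in test_sessions.values()]
           if test_sessions else [])
    )
    classes = np.unique(all_labels)

    iter_accuracies: list[float] = []
    subject_acc: dict[str, list[float]] = {}
    counts = np.zeros((classes.size, classes.size))

    for it in range(split.n_iterations):
        rng = np.random.default_rng([split.seed, it])
        predictions: list = []
        actuals: list = []

        def run_block(train: list[Window], test: list[Window], tag: str | None = None):
            pred, actual = _fit_predict(train, test, feature_kind, hist_bins, C, sigma)
            predictions.extend(pred)
            actuals.extend(actual)
            if tag is not None:
                subject_acc.setdefault(tag, []).append(100.0 * float(np.mean(pred == actual)))

        if split.design in ("individual_holdout", "pooled_holdout"):
            groups = (
                {sid: list(ws) for sid, ws in sessions.items()}
                if split.design == "individual_holdout"
                else {"pooled": [w for ws in sessions.values() for w in ws]}
            )
            for sid, windows in groups.items():
                labels = np.asarray([w.direction_deg for w in windows])
                if shuffle_labels:
                    labels = rng.permutation(labels)
                    windows = [
                        _relabel(w, lab) for w, lab in zip(windows, labels)
                    ]
                idx_train, idx_test = _stratified_split(
                    windows, labels, split.train_fraction, rng
                )
                if test_on_train:
                    idx_test = idx_train
                run_block([windows[i] for i in idx_train], [windows[i] for i in idx_test],
                          tag=sid if split.design == "individual_holdout" else None)
        elif split.design == "leave_subjects_out":
            held = set(split.held_out_subjects)
            missing = held - set(sessions)
            if missing:
                raise ConfigError(f"held-out subjects not in sessions: {sorted(missing)}")
            if not held or held == set(sessions):
                raise ConfigError("held_out_subjects must be a proper nonempty subset")
            train = [w for sid, ws in sessions.items() if sid not in held for w in ws]
            for sid in sorted(held):
                run_block(train, list(sessions[sid]), tag=sid)
        else:  # cross_group
            train = [w for ws in sessions.values() for w in ws]
            for sid in sorted(test_sessions):
                run_block(train, list(test_sessions[sid]), tag=sid)

        predictions_arr = np.asarray(predictions)
        actuals_arr = np.asarray(actuals)
        iter_accuracies.append(100.0 * float(np.mean(predictions_arr == actuals_arr)))
        counts += _confusion_counts(predictions_arr, actuals_arr, classes)

    return ValidationResult(
        mean_accuracy=float(np.mean(iter_accuracies)),
        accuracy_sd=float(np.std(iter_accuracies, ddof=1)) if len(iter_accuracies) > 1 else 0.0,
        confusion=_counts_to_confusion(counts, classes),
        per_iteration=tuple(iter_accuracies),
        per_subject={sid: float(np.mean(a)) for sid, a in subject_acc.items()},
    )


def _relabel(window: Window, direction: float) -> Window:
    import dataclasses

    return dataclasses.replace(window, direction_deg=float(direction))
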