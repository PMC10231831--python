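"""Two-stage linear-SVM tissue classification.

Stage one reduces the >900-bin fingerprints to fewer than 20 informative
bins with an L1-penalized linear SVM (hyperparameter C1); stage two trains
an L2-penalized linear SVM on the retained bins (hyperparameter C2).  Both
hyperparameters are chosen by grid search with fivefold cross-validation
on a stratified 60% training/validation partition, minimizing the total
false-positive plus false-negative count across validation folds; the
remaining 40% hold-out is touched only at final evaluation.  Calibrated
class-membership probabilities come from a monotone sigmoid (Platt) map
fitted on out-of-fold decision values.

Three tasks are supported: the six-class tissue model (task I), bone
versus spinal cord (task II, other soft tissues excluded), and bone
versus all soft tissue (task III).  For the binary tasks the probability
orientation is 1 = spinal cord / soft tissue, 0 = bone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .bands import TISSUES
from .preprocess import DegenerateInputError, Fingerprint
from .synth import InvalidArgumentError, SpectralAxis

SOFT_TISSUES = ("cartilage", "fat", "ligament", "muscle", "spinal_cord")


@dataclass(frozen=True)
class TaskSpec:
    """Mapping from the six tissue labels to the classes of one task."""

    name: str                       # "I", "II" or "III"
    class_map: dict[str, str]       # tissue -> task class; absent = excluded

    @property
    def classes(self) -> tuple[str, ...]:
        # negative (bone) class first, positive (cord/soft) class last
        seen = sorted(set(self.class_map.values()))
        if self.name in ("II", "III"):
            pos = "spinal_cord" if self.name == "II" else "soft"
            seen = [c for c in seen if c != pos] + [pos]
        return tuple(seen)

    def apply(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (mask of retained samples, mapped task labels)."""
        labels = np.asarray(labels)
        mask = np.array([lb in self.class_map for lb in labels])
        mapped = np.array([self.class_map[lb] for lb in labels[mask]])
        return mask, mapped


TASK_I = TaskSpec(name="I", class_map={t: t for t in TISSUES})
TASK_II = TaskSpec(name="II", class_map={"bone": "bone",
                                         "spinal_cord": "spinal_cord"})
TASK_III = TaskSpec(name="III", class_map={"bone": "bone",
                                           **{t: "soft" for t in SOFT_TISSUES}})
TASKS = {"I": TASK_I, "II": TASK_II, "III": TASK_III}


@dataclass
class GridConfig:
    """Hyperparameter search space and data-partition settings."""

    C1_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.005, 0.05, 10))
    C2_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.1, 5.0, 10))
    folds: int = 5
    max_features: int = 20
    train_fraction: float = 0.6
    seed: int = 0


@dataclass
class FeatureSet:
    """Bins retained by the L1 selection stage."""

    bin_indices: np.ndarray
    wavenumbers: np.ndarray
    weights: np.ndarray         # max |coefficient| over one-vs-rest problems

    def __len__(self) -> int:
        return self.bin_indices.size

    @property
    def top_wavenumber(self) -> float:
        """Wavenumber of the bin with the largest selection weight."""
        return float(self.wavenumbers[np.argmax(self.weights)])


@dataclass
class CVRecord:
    C1: float
    C2: float
    errors: int                 # summed FP+FN over validation folds
    feature_sizes: list[int]    # per-fold selected-bin counts


@dataclass
class TrainedModel:
    task: TaskSpec
    features: FeatureSet
    classes: tuple[str, ...]
    coef: np.ndarray            # (n_classes or 1, n_selected)
    intercept: np.ndarray
    calibration: list[tuple[float, float]]   # per decision column (a, b)
    C1: float
    C2: float
    cv_records: list[CVRecord] = field(default_factory=list)
    axis_wavenumbers: np.ndarray | None = None


def split_train_holdout(labels: np.ndarray, train_fraction: float = 0.6,
                        seed: int = 0, folds: int = 5
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified disjoint train/hold-out index split.

    Per-class counts follow a largest-remainder allocation whose total is
    ``ceil(train_fraction * n)``, so 162 balanced spectra split 98/64.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 0 < train_fraction < 1:
        raise InvalidArgumentError("train_fraction must lie in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < folds):
        raise InvalidArgumentError(
            f"every class needs at least {folds} members")
    target_total = int(np.ceil(train_fraction * n))
    quotas = train_fraction * counts
    take = np.floor(quotas).astype(int)
    remainder = target_total - take.sum()
    # distribute leftovers by largest fractional part, class order breaking ties
    order = np.argsort(-(quotas - take), kind="stable")
    for j in order[:remainder]:
        take[j] += 1
    rng = np.random.default_rng(seed)
    train_idx, hold_idx = [], []
    for cls, k in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        train_idx.extend(idx[:k])
        hold_idx.extend(idx[k:])
    return np.sort(np.array(train_idx)), np.sort(np.array(hold_idx))


def stack_fingerprints(fps: list[Fingerprint]) -> tuple[np.ndarray, np.ndarray]:
    """(n_spectra, n_bins) matrix and label vector from fingerprints."""
    X = np.vstack([fp.intensities for fp in fps])
    y = np.array([fp.tissue_label for fp in fps])
    return X, y


def _fit_l1(X: np.ndarray, y: np.ndarray, C1: float) -> LinearSVC:
    clf = LinearSVC(penalty="l1", dual=False, C=C1, max_iter=50000, tol=1e-5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def select_features(X: np.ndarray, y: np.ndarray, C1: float,
                    axis: SpectralAxis | None = None) -> FeatureSet:
    """L1-penalized linear-SVM sparse selection (one-vs-rest union).

    Returns the bins with any nonzero coefficient; the per-bin weight is
    the largest coefficient magnitude across the one-vs-rest problems.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise InvalidArgumentError("need at least two classes")
    if not np.any(X.std(axis=0) > 0):
        raise DegenerateInputError("all feature columns are constant")
    clf = _fit_l1(X, y, C1)
    mags = np.max(np.abs(np.atleast_2d(clf.coef_)), axis=0)
    idx = np.flatnonzero(mags > 0)
    wn = (axis.wavenumbers[idx] if axis is not None
          else idx.astype(float))
    return FeatureSet(bin_indices=idx, wavenumbers=wn, weights=mags[idx])


def _fit_l2(X: np.ndarray, y: np.ndarray, C2: float) -> LinearSVC:
    if C2 <= 0:
        raise InvalidArgumentError("C2 must be positive")
    if np.unique(y).size < 2:
        raise InvalidArgumentError("need at least two classes")
    clf = LinearSVC(penalty="l2", dual=False, C=C2, max_iter=50000, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def train_classifier(X_selected: np.ndarray, y: np.ndarray, C2: float,
                     task: TaskSpec, features: FeatureSet) -> TrainedModel:
    """L2 linear SVM on the selected bins only (uncalibrated)."""
    clf = _fit_l2(X_selected, y, C2)
    classes = _ordered_classes(task, clf.classes_)
    coef, intercept = _reorder_decision(clf, classes)
    return TrainedModel(task=task, features=features, classes=classes,
                        coef=coef, intercept=intercept, calibration=[],
                        C1=np.nan, C2=C2)


def _ordered_classes(task: TaskSpec, fitted: np.ndarray) -> tuple[str, ...]:
    want = [c for c in task.classes if c in set(fitted)]
    return tuple(want)


def _reorder_decision(clf: LinearSVC, classes: tuple[str, ...]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients as decision columns matching *classes* order.

    Binary LinearSVC exposes one row oriented toward ``classes_[1]``; we
    orient it toward the positive (last) task class.
    """
    fitted = list(clf.classes_)
    if len(fitted) == 2:
        sign = 1.0 if fitted[1] == classes[-1] else -1.0
        return sign * np.atleast_2d(clf.coef_), sign * np.atleast_1d(clf.intercept_)
    rows = [fitted.index(c) for c in classes]
    return clf.coef_[rows], clf.intercept_[rows]


def _decision_values(coef, intercept, X):
    return X @ coef.T + intercept


def _platt(scores: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    """Monotone sigmoid map from decision value to probability."""
    if np.ptp(scores) == 0:
        raise DegenerateInputError("decision scores are constant")
    lr = LogisticRegression(C=1e6, max_iter=10000)
    lr.fit(scores.reshape(-1, 1), targets.astype(int))
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def calibrate_probabilities(model: TrainedModel, oof_scores: np.ndarray,
                            oof_labels: np.ndarray) -> TrainedModel:
    """Fit per-class Platt sigmoids on held-back (out-of-fold) scores."""
    oof_scores = np.atleast_2d(oof_scores.T).T  # (n, n_cols)
    calib = []
    if len(model.classes) == 2:
        targets = (oof_labels == model.classes[-1])
        calib.append(_platt(oof_scores[:, 0], targets))
    else:
        for j, cls in enumerate(model.classes):
            calib.append(_platt(oof_scores[:, j], oof_labels == cls))
    model.calibration = calib
    return model


def _sigmoid(z):
    return expit(z)


def predict(model: TrainedModel, X: np.ndarray | list[Fingerprint]
            ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and calibrated per-class probabilities (rows sum to 1)."""
    if isinstance(X, list):
        if model.axis_wavenumbers is not None:
            for fp in X:
                if (len(fp.axis) != model.axis_wavenumbers.size or
                        not np.allclose(fp.axis.wavenumbers,
                                        model.axis_wavenumbers)):
                    raise InvalidArgumentError("fingerprint axis mismatch")
        X, _ = stack_fingerprints(X)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.axis_wavenumbers is not None:
        if X.shape[1] != model.axis_wavenumbers.size:
            raise InvalidArgumentError("axis mismatch with trained model")
    Xs = X[:, model.features.bin_indices]
    scores = _decision_values(model.coef, model.intercept, Xs)
    if not model.calibration:
        raise InvalidArgumentError("model is not calibrated")
    if len(model.classes) == 2:
        a, b = model.calibration[0]
        p_pos = _sigmoid(a * scores[:, 0] + b)
        probs = np.column_stack([1 - p_pos, p_pos])
    else:
        raw = np.column_stack([_sigmoid(a * scores[:, j] + b)
                               for j, (a, b) in enumerate(model.calibration)])
        probs = raw / raw.sum(axis=1, keepdims=True)
    labels = np.array([model.classes[i] for i in np.argmax(probs, axis=1)])
    return labels, probs


@dataclass
class GridSearchResult:
    model: TrainedModel
    records: list[CVRecord]
    surviving_feature_sizes: list[int]


def grid_search(X: np.ndarray, y: np.ndarray, task: TaskSpec,
                grid: GridConfig | None = None,
                axis: SpectralAxis | None = None) -> GridSearchResult:
    """Joint (C1, C2) grid search with fivefold cross-validation.

    For every C1, features are selected independently on each fold's
    training part; C1 values whose selection exceeds the feature budget or
    selects nothing on any fold are discarded.  The winning (C1, C2) pair
    minimizes summed validation misclassifications (FP+FN for the binary
    tasks; total off-diagonal count for the six-class task), breaking ties
    toward fewer features, then smaller C2, then smaller C1.  The final
    model is refit on all supplied data at the winning pair and Platt
    calibrated on out-of-fold decision values.
    """
    grid = grid or GridConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=grid.folds, shuffle=True,
                          random_state=grid.seed)
    fold_splits = list(skf.split(X, y))

    records: list[CVRecord] = []
    surviving_sizes: list[int] = []
    best = None  # (errors, mean_size, C2, C1, record)
    for C1 in grid.C1_grid:
        fold_feats = []
        ok = True
        for tr, va in fold_splits:
            fs = select_features(X[tr], y[tr], C1, axis)
            if len(fs) == 0 or len(fs) >= grid.max_features:
                ok = False
                break
            fold_feats.append(fs)
        if not ok:
            continue
        sizes = [len(fs) for fs in fold_feats]
        surviving_sizes.extend(sizes)
        for C2 in grid.C2_grid:
            errors = 0
            for (tr, va), fs in zip(fold_splits, fold_feats):
                clf = _fit_l2(X[tr][:, fs.bin_indices], y[tr], C2)
                pred = clf.predict(X[va][:, fs.bin_indices])
                errors += int(np.sum(pred != y[va]))
            rec = CVRecord(C1=float(C1), C2=float(C2), errors=errors,
                           feature_sizes=sizes)
            records.append(rec)
            key = (errors, float(np.mean(sizes)), C2, C1)
            if best is None or key < best[0]:
                best = (key, rec)
    if best is None:
        raise InvalidArgumentError(
            "no C1 in the grid satisfied the feature budget")
    chosen = best[1]

    features = select_features(X, y, chosen.C1, axis)
    if len(features) >= grid.max_features:
        # fall back to per-fold behaviour: refuse to exceed the budget
        raise InvalidArgumentError("refit selection exceeded the feature budget")
    model = train_classifier(X[:, features.bin_indices], y, chosen.C2,
                             task, features)
    model.C1 = chosen.C1
    model.cv_records = records
    if axis is not None:
        model.axis_wavenumbers = axis.wavenumbers.copy()

    # out-of-fold decision values for probability calibration
    n_cols = 1 if len(model.classes) == 2 else len(model.classes)
    oof = np.zeros((len(y), n_cols))
    for tr, va in fold_splits:
        clf = _fit_l2(X[tr][:, features.bin_indices], y[tr], chosen.C2)
        coef, intercept = _reorder_decision(clf, model.classes)
        oof[va] = _decision_values(coef, intercept,
                                   X[va][:, features.bin_indices])
    calibrate_probabilities(model, oof, y)
    return GridSearchResult(model=model, records=records,
                            surviving_feature_sizes=surviving_sizes)
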