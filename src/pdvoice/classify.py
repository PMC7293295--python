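"""Subject-paired ON/OFF difference classification with repeated subject-wise CV.

Each subject contributes two antisymmetric samples — the ON-OFF feature
difference labelled +1 and its negation labelled -1 — giving a balanced
problem whose chance level is exactly 0.5.  Folds partition *subjects*, so a
subject's two samples never straddle the train/test boundary.  Inside every
training fold (and only there) features are standardized, the top-k features
are selected by paired-t p-value, and hyperparameters are tuned — the
nested arrangement that keeps the reported accuracy honest.

Classifiers: elastic-net logistic regression (EN), l1-regularised logistic
regression (LR-l1), Gaussian naive Bayes (NB) and random forest (RF).
Linear models are fitted without an intercept because the antisymmetric
sample distribution is origin-symmetric.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB

from .errors import ParameterError

__all__ = [
    "DifferenceSample",
    "CVConfig",
    "CVReport",
    "CLASSIFIERS",
    "FEATURE_SETS_BY_TASK",
    "feature_category",
    "build_difference_samples",
    "standardize",
    "select_top_k",
    "train_classifier",
    "predict",
    "cross_validate",
    "run_cv_grid",
]

CLASSIFIERS = ("EN", "LR-l1", "NB", "RF")

#: feature-set combinations evaluated per task
FEATURE_SETS_BY_TASK = {
    "picture": ("NS", "SF", "NS+SF", "MFCC", "MFCC+NS", "MFCC+SF", "MFCC+SF+NS"),
    "counting": ("NS", "MFCC", "MFCC+NS"),
    "ddk": ("NS", "MFCC", "MFCC+NS"),
}

META_COLUMNS = ("subject", "task", "state")


@dataclass
class DifferenceSample:
    """One signed state-difference vector for a subject."""

    subject: str
    x: np.ndarray
    label: int  # +1 = ON - OFF, -1 = OFF - ON


@dataclass(frozen=True)
class CVConfig:
    """Repeated subject-wise cross-validation settings."""

    n_folds: int = 10
    n_runs: int = 50
    k_selected: int | None = 5  # None = use all features
    classifiers: tuple[str, ...] = CLASSIFIERS
    rng_seed: int = 0
    inner_folds: int = 5
    en_l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    en_penalties: tuple[float, ...] = (0.01, 0.1, 1.0)
    lr_penalties: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    rf_trees: int = 100
    rf_depths: tuple = (2, 4, None)

    def __post_init__(self) -> None:
        for name in ("classifiers", "en_l1_ratios", "en_penalties", "lr_penalties", "rf_depths"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.n_folds < 2 or self.n_runs < 1 or self.inner_folds < 2:
            raise ParameterError("n_folds, inner_folds >= 2 and n_runs >= 1 required")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ParameterError(f"unknown classifiers {sorted(unknown)}")


@dataclass
class CVReport:
    """Accuracy mean +/- sd over repeated subject-wise CV runs."""

    task: str
    feature_set: str
    classifier: str
    accuracy_mean: float
    accuracy_sd: float
    n_runs: int
    n_folds: int
    run_accuracies: np.ndarray = field(repr=False, default=None)


def feature_category(name: str) -> str:
    """MFCC / NS / SF bucket for a feature name."""
    if name.startswith("MFCC"):
        return "MFCC"
    if name.startswith("NS"):
        return "NS"
    return "SF"


def _feature_set_columns(columns, feature_set: str) -> list[str]:
    wanted = set(feature_set.split("+"))
    unknown = wanted - {"MFCC", "NS", "SF"}
    if unknown:
        raise ParameterError(f"unknown feature set components {sorted(unknown)}")
    return [c for c in columns if feature_category(c) in wanted]


def build_difference_samples(
    table: pd.DataFrame, task: str, feature_set: str = "MFCC+SF+NS"
) -> tuple[list[DifferenceSample], list[str]]:
    """Two antisymmetric samples per subject with both states present.

    Subjects missing a state, or with missing values in the selected feature
    columns, are excluded with a warning.
    """
    sub = table[table["task"] == task]
    columns = _feature_set_columns(
        [c for c in table.columns if c not in META_COLUMNS], feature_set
    )
    if not columns:
        raise ParameterError(f"no features in set {feature_set!r} for task {task!r}")
    samples: list[DifferenceSample] = []
    for subject, grp in sub.groupby("subject", sort=True):
        states = set(grp["state"])
        if states != {"ON", "OFF"}:
            warnings.warn(f"subject {subject} missing a state; excluded", stacklevel=2)
            continue
        on = grp.loc[grp["state"] == "ON", columns].iloc[0].to_numpy(dtype=np.float64)
        off = grp.loc[grp["state"] == "OFF", columns].iloc[0].to_numpy(dtype=np.float64)
        d = on - off
        if not np.all(np.isfinite(d)):
            warnings.warn(
                f"subject {subject} has missing features in {feature_set}; excluded",
                stacklevel=2,
            )
            continue
        samples.append(DifferenceSample(subject, d, +1))
        samples.append(DifferenceSample(subject, -d, -1))
    return samples, columns


def standardize(train: np.ndarray, *apply_to: np.ndarray):
    """Z-score columns by TRAIN statistics only; zero-sd columns become 0.

    Returns the standardized train matrix, then each ``apply_to`` matrix.
    """
    train = np.asarray(train, dtype=np.float64)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dead = sd == 0.0
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} constant feature(s) standardized to 0", stacklevel=2)
        sd = np.where(dead, 1.0, sd)
    out = [(train - mean) / sd]
    out[0][:, dead] = 0.0
    for X in apply_to:
        Z = (np.asarray(X, dtype=np.float64) - mean) / sd
        Z[:, dead] = 0.0
        out.append(Z)
    return out[0] if not apply_to else tuple(out)


def select_top_k(samples: list[DifferenceSample], k: int | None = 5) -> np.ndarray:
    """Indices of the k features ranked by paired-test p-value on TRAIN data.

    Computed as a one-sample t-test of the per-subject ON-OFF differences
    (the +1-labelled samples) against zero — equivalent to the paired ON vs
    OFF test.  ``k=None`` or ``k`` above the feature count selects all, with
    a warning in the latter case.
    """
    diffs = np.stack([s.x for s in samples if s.label == +1])
    n, m = diffs.shape
    if k is None:
        return np.arange(m)
    if k > m:
        warnings.warn(f"k={k} exceeds {m} available features; using all", stacklevel=2)
        return np.arange(m)
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    p = np.where(np.isfinite(p), p, np.inf)  # zero-variance columns rank last
    order = np.lexsort((np.arange(m), -np.abs(t), p))
    return np.sort(order[:k])


def _inner_folds(subjects: np.ndarray, n_folds: int, rng: np.random.Generator):
    uniq = np.unique(subjects)
    order = rng.permutation(uniq)
    for chunk in np.array_split(order, min(n_folds, uniq.size)):
        yield np.isin(subjects, chunk)


def _grid_search(models, X, y, subjects, n_folds, rng):
    """Pick the model factory with the best subject-wise inner-CV accuracy."""
    masks = list(_inner_folds(subjects, n_folds, rng))
    best_score, best_factory = -1.0, None
    for factory in models:  # fixed order; first wins ties
        correct = total = 0
        for test_mask in masks:
            if test_mask.all() or (~test_mask).all():
                continue
            m = factory().fit(X[~test_mask], y[~test_mask])
            correct += int((m.predict(X[test_mask]) == y[test_mask]).sum())
            total += int(test_mask.sum())
        score = correct / total if total else 0.0
        if score > best_score:
            best_score, best_factory = score, factory
    return best_factory().fit(X, y)


def train_classifier(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray | None = None,
    config: CVConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Fit one classifier on (standardized, selected) training data.

    EN and LR-l1 tune their penalties by subject-wise inner CV; RF tunes its
    depth by out-of-bag score; NB has nothing to tune.
    """
    config = config or CVConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    if np.unique(y).size < 2:
        raise ParameterError("training data must contain both classes")
    if subjects is None:
        subjects = np.arange(len(y))
    if kind == "NB":
        return GaussianNB().fit(X, y)
    if kind == "RF":
        seed = int(rng.integers(2**31 - 1))
        best_score, best_model = -np.inf, None
        for depth in config.rf_depths:
            m = RandomForestClassifier(
                n_estimators=config.rf_trees,
                max_depth=depth,
                oob_score=True,
                random_state=seed,
            ).fit(X, y)
            if m.oob_score_ > best_score:
                best_score, best_model = m.oob_score_, m
        return best_model
    if kind == "EN":
        factories = [
            (lambda r=r, C=C: LogisticRegression(
                C=C, l1_ratio=r, solver="saga", fit_intercept=False, max_iter=5000, tol=1e-3
            ))
            for r in config.en_l1_ratios
            for C in (1.0 / np.asarray(config.en_penalties))
        ]
    elif kind == "LR-l1":
        factories = [
            (lambda C=C: LogisticRegression(
                C=C, l1_ratio=1.0, solver="liblinear", fit_intercept=False, max_iter=1000
            ))
            for C in (1.0 / np.asarray(config.lr_penalties))
        ]
    else:
        raise ParameterError(f"unknown classifier kind {kind!r}")
    return _grid_search(factories, X, y, subjects, config.inner_folds, rng)


def predict(model, X: np.ndarray) -> np.ndarray:
    """Class labels (+1/-1) for samples."""
    return model.predict(np.atleast_2d(X))


def cross_validate(
    samples: list[DifferenceSample],
    config: CVConfig,
    task: str = "",
    feature_set: str = "",
) -> list[CVReport]:
    """Repeated subject-wise k-fold CV; one report per classifier.

    For every run a fresh subject partition is drawn; within each fold the
    training half is standardized, feature-selected and tuned with no access
    to the held-out subjects.  The run accuracy pools correct predictions
    over the folds; mean and sd are taken over runs.
    """
    subjects_all = np.array([s.subject for s in samples])
    uniq = np.unique(subjects_all)
    if uniq.size < 3:
        raise ParameterError("need at least 3 subjects")
    n_folds = config.n_folds
    if uniq.size < n_folds:
        warnings.warn(
            f"only {uniq.size} subjects; reducing folds from {n_folds}", stacklevel=2
        )
        n_folds = uniq.size
    X_all = np.stack([s.x for s in samples])
    y_all = np.array([s.label for s in samples])
    run_acc = {kind: np.zeros(config.n_runs) for kind in config.classifiers}
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.rng_seed & 0x7FFFFFFF, run])
        order = rng.permutation(uniq)
        folds = np.array_split(order, n_folds)
        correct = {kind: 0 for kind in config.classifiers}
        for fold_subjects in folds:
            test_mask = np.isin(subjects_all, fold_subjects)
            train_idx = np.flatnonzero(~test_mask)
            Z_train, Z_test = standardize(X_all[train_idx], X_all[test_mask])
            train_samples = [
                DifferenceSample(samples[i].subject, Z_train[j], samples[i].label)
                for j, i in enumerate(train_idx)
            ]
            sel = select_top_k(train_samples, config.k_selected)
            Xtr, Xte = Z_train[:, sel], Z_test[:, sel]
            for kind in config.classifiers:
                model = train_classifier(
                    kind, Xtr, y_all[train_idx], subjects_all[train_idx], config, rng
                )
                correct[kind] += int((predict(model, Xte) == y_all[test_mask]).sum())
        for kind in config.classifiers:
            run_acc[kind][run] = correct[kind] / len(samples)
    return [
        CVReport(
            task=task,
            feature_set=feature_set,
            classifier=kind,
            accuracy_mean=float(run_acc[kind].mean()),
            accuracy_sd=float(run_acc[kind].std(ddof=1)) if config.n_runs > 1 else 0.0,
            n_runs=config.n_runs,
            n_folds=n_folds,
            run_accuracies=run_acc[kind],
        )
        for kind in config.classifiers
    ]


def run_cv_grid(
    table: pd.DataFrame,
    config: CVConfig,
    tasks: tuple[str, ...] | None = None,
    feature_sets: dict[str, tuple[str, ...]] | None = None,
) -> list[CVReport]:
    """Evaluate every (task, feature set, classifier) combination in the grid."""
    tasks = tasks or tuple(t for t in FEATURE_SETS_BY_TASK if t in set(table["task"]))
    feature_sets = feature_sets or FEATURE_SETS_BY_TASK
    reports: list[CVReport] = []
    for task in tasks:
        for fs in feature_sets[task]:
            samples, _ = build_difference_samples(table, task, fs)
            reports.extend(cross_validate(samples, config, task=task, feature_set=fs))
    return reports


def reports_to_frame(reports: list[CVReport]) -> pd.DataFrame:
    """CVReport list as a tidy DataFrame (task, feature_set, classifier, mean, sd)."""
    return pd.DataFrame(
        {
            "task": r.task,
            "feature_set": r.feature_set,
            "classifier": r.classifier,
            "accuracy_mean": r.accuracy_mean,
            "accuracy_sd": r.accuracy_sd,
            "n_runs": r.n_runs,
            "n_folds": r.n_folds,
        }
        for r in reports
    )
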