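"""Class-weighted RBF-SVM decoding with exhaustive hyperparameter search.

The decoder is a support vector machine with a radial-basis kernel. Class
imbalance (errors are the rare positive class) is handled twice, as is common
in this literature: class weights inversely proportional to the training
class frequencies, and random downsampling of the majority class in every
training split (test splits stay imbalanced). Cost and gamma are selected by
exhaustive search over a log-spaced grid, scored by mean balanced accuracy
under inner stratified cross-validation.

Three evaluation regimes are provided: subject-specific (repeated stratified
k-fold within one subject), leave-one-subject-out, and generic (train once on
pooled simulated subjects, freeze, apply without adaptation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import features as feat
from .evaluate import balanced_accuracy
from .simulator import EpochsData

__all__ = [
    "SvmGrid",
    "CvConfig",
    "TrainedModel",
    "CvResult",
    "ErrPSvmClassifier",
    "downsample_majority",
    "grid_search_train",
    "evaluate_subject_specific",
    "evaluate_loso",
    "train_generic",
    "apply_model",
]

POSITIVE = "error"
NEGATIVE = "correct"


@dataclass(frozen=True)
class SvmGrid:
    """Log-spaced hyperparameter grid (13 cost x 11 gamma values by default)."""

    cost_values: tuple = tuple(10.0 ** np.arange(-6, 7))
    gamma_values: tuple = tuple(10.0 ** np.arange(-5, 6))

    def __post_init__(self):
        if min(self.cost_values) <= 0 or min(self.gamma_values) <= 0:
            raise ValueError("grid values must be strictly positive")

    def __len__(self) -> int:
        return len(self.cost_values) * len(self.gamma_values)

    def pairs(self):
        """(cost, gamma) pairs ordered for the documented tie-break:
        smallest cost first, then smallest gamma."""
        return list(itertools.product(sorted(self.cost_values), sorted(self.gamma_values)))

    @classmethod
    def reduced(cls) -> "SvmGrid":
        """7 x 6 desk-scale grid covering the center of the full ranges."""
        return cls(cost_values=tuple(10.0 ** np.arange(-3, 4)),
                   gamma_values=tuple(10.0 ** np.arange(-4, 2)))


@dataclass
class CvConfig:
    """Settings shared by the evaluation regimes."""

    grid: SvmGrid = field(default_factory=SvmGrid)
    inner_folds: int = 5  # model-selection folds inside each training split
    n_folds: int = 10  # outer CV folds (subject-specific regime)
    n_repeats: int = 10  # outer CV repeats (subject-specific regime)
    channels: tuple = feat.DEFAULT_CHANNELS
    windows: tuple = feat.DEFAULT_WINDOWS_MS
    #: optional stratified-subsample bound on hyperparameter-search trials
    #: (the final model is refit on the full training pool)
    max_search_trials: int | None = None
    seed: int = 0


def downsample_majority(labels: np.ndarray, rng) -> np.ndarray:
    """Kept trial indices after balancing: the minority class entirely plus a
    uniformly random equally-sized subset of the majority class (sorted)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to downsample")
    if counts.min() == counts.max():
        return np.arange(labels.size)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min = counts.min()
    keep_min = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels == majority)
    keep_maj = rng.choice(maj_idx, size=n_min, replace=False)
    return np.sort(np.concatenate([keep_min, keep_maj]))


def _inverse_frequency_weights(labels: np.ndarray) -> dict:
    """Class weights inversely proportional to class frequencies, computed on
    the pre-downsampling training labels (n / (2 * n_class))."""
    classes, counts = np.unique(labels, return_counts=True)
    n = labels.size
    return {c: n / (len(classes) * k) for c, k in zip(classes, counts)}


class ErrPSvmClassifier(BaseEstimator, ClassifierMixin):
    """RBF SVM with built-in downsampling, normalization and grid search.

    ``fit`` runs inner stratified cross-validation over all (cost, gamma)
    pairs: inside each inner training fold the majority class is downsampled
    and the feature normalizer refit; candidates are scored by mean balanced
    accuracy on the untouched (imbalanced) inner validation folds. Ties break
    toward the smallest cost, then the smallest gamma. The final model is
    refit on the full downsampled training set.

    Fitted attributes: ``cost_``, ``gamma_``, ``normalizer_``, ``svc_``,
    ``class_weights_``, ``grid_scores_`` (DataFrame), ``classes_``.
    """

    def __init__(self, grid: SvmGrid | None = None, inner_folds: int = 5,
                 random_state: int | None = 0,
                 max_search_trials: int | None = None):
        self.grid = grid
        self.inner_folds = inner_folds
        self.random_state = random_state
        # bound on the trials used for hyperparameter scoring (stratified
        # subsample); the final model is always refit on the full data
        self.max_search_trials = max_search_trials

    def _rng(self):
        return np.random.default_rng(self.random_state)

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2 or counts.min() < 2:
            raise ValueError("need at least 2 trials of each of the two classes")
        grid = self.grid if self.grid is not None else SvmGrid()
        rng = self._rng()
        self.class_weights_ = _inverse_frequency_weights(y)
        pairs = grid.pairs()

        Xs, ys = X, y
        if self.max_search_trials is not None and y.size > self.max_search_trials:
            frac = self.max_search_trials / y.size
            keep = np.sort(np.concatenate([
                rng.choice(np.flatnonzero(y == c),
                           size=max(2, int(round(frac * np.count_nonzero(y == c)))),
                           replace=False)
                for c in classes
            ]))
            Xs, ys = X[keep], y[keep]

        n_folds = min(self.inner_folds, counts.min())
        if n_folds < 2:
            raise ValueError("degenerate inner folds: too few minority trials")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        scores = np.zeros((len(pairs), n_folds))
        for f, (tr, va) in enumerate(skf.split(Xs, ys)):
            keep = downsample_majority(ys[tr], rng)
            Xtr, ytr = Xs[tr][keep], ys[tr][keep]
            norm = feat.FeatureNormalizer().fit(Xtr)
            Xtr_s, Xva_s = norm.transform(Xtr), norm.transform(Xs[va])
            for p, (cost, gamma) in enumerate(pairs):
                svc = SVC(kernel="rbf", C=cost, gamma=gamma,
                          class_weight=self.class_weights_, cache_size=300)
                svc.fit(Xtr_s, ytr)
                scores[p, f] = balanced_accuracy(ys[va], svc.predict(Xva_s)).bacc

        mean_scores = scores.mean(axis=1)
        best = int(np.argmax(mean_scores))  # pairs() order implements tie-break
        self.cost_, self.gamma_ = pairs[best]
        self.grid_scores_ = pd.DataFrame(
            {"cost": [c for c, _ in pairs], "gamma": [g for _, g in pairs],
             "mean_bacc": mean_scores}
        )

        keep = downsample_majority(y, rng)
        Xb, yb = X[keep], y[keep]
        self.normalizer_ = feat.FeatureNormalizer().fit(Xb)
        self.svc_ = SVC(kernel="rbf", C=self.cost_, gamma=self.gamma_,
                        class_weight=self.class_weights_, cache_size=300)
        self.svc_.fit(self.normalizer_.transform(Xb), yb)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(self.normalizer_.transform(np.asarray(X, float)))


@dataclass
class TrainedModel:
    """A frozen decoder: fitted classifier plus training provenance."""

    estimator: ErrPSvmClassifier
    training_subjects: list[str]
    seed: int | None = None
    kernel: str = "radial"

    @property
    def cost(self) -> float:
        return self.estimator.cost_

    @property
    def gamma(self) -> float:
        return self.estimator.gamma_

    @property
    def class_weights(self) -> dict:
        return self.estimator.class_weights_

    def predict(self, fm: feat.FeatureMatrix | np.ndarray) -> np.ndarray:
        X = fm.values if isinstance(fm, feat.FeatureMatrix) else fm
        return self.estimator.predict(X)

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        import joblib

        return joblib.load(path)


@dataclass
class CvResult:
    """Fold-level detail of a repeated-CV evaluation."""

    frame: pd.DataFrame  # columns: repeat, fold, tpr, tnr, bacc, cost, gamma
    subject_id: str = ""

    @property
    def mean_bacc(self) -> float:
        return float(self.frame["bacc"].mean())

    @property
    def mean_tpr(self) -> float:
        return float(self.frame["tpr"].mean())

    @property
    def mean_tnr(self) -> float:
        return float(self.frame["tnr"].mean())


def _as_features(data: EpochsData | feat.FeatureMatrix, cfg: CvConfig) -> feat.FeatureMatrix:
    if isinstance(data, feat.FeatureMatrix):
        return data
    return feat.window_mean_features(data, cfg.channels, cfg.windows)


def grid_search_train(X, y, grid: SvmGrid | None = None, inner_folds: int = 5,
                      rng=None, max_search_trials: int | None = None
                      ) -> ErrPSvmClassifier:
    """Fit a grid-searched classifier on one training set (thin wrapper over
    :class:`ErrPSvmClassifier`)."""
    seed = (int(rng.integers(2 ** 31)) if isinstance(rng, np.random.Generator)
            else rng if rng is not None else 0)
    return ErrPSvmClassifier(grid=grid, inner_folds=inner_folds,
                             random_state=seed,
                             max_search_trials=max_search_trials).fit(X, y)


def evaluate_subject_specific(subject: EpochsData | feat.FeatureMatrix,
                              cfg: CvConfig | None = None) -> CvResult:
    """Repeated stratified k-fold CV within one subject.

    Downsampling, normalization and hyperparameter search happen inside each
    training fold; metrics are computed on the untouched imbalanced test
    folds and reported per fold.
    """
    cfg = cfg or CvConfig()
    fm = _as_features(subject, cfg)
    y = fm.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("subject must contain both classes")
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"only {counts.min()} minority trials for {cfg.n_folds} folds; use fewer folds"
        )
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(cfg.n_repeats):
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for fold, (tr, te) in enumerate(skf.split(fm.values, y)):
            clf = grid_search_train(fm.values[tr], y[tr], cfg.grid,
                                    cfg.inner_folds, rng)
            m = balanced_accuracy(y[te], clf.predict(fm.values[te]))
            rows.append({"repeat": rep, "fold": fold, "tpr": m.tpr, "tnr": m.tnr,
                         "bacc": m.bacc, "cost": clf.cost_, "gamma": clf.gamma_})
    return CvResult(frame=pd.DataFrame(rows), subject_id=fm.subject_id)


def pool_features(subjects, cfg: CvConfig) -> feat.FeatureMatrix:
    fms = [_as_features(s, cfg) for s in subjects]
    return feat.FeatureMatrix(
        values=np.concatenate([f.values for f in fms]),
        window_defs=fms[0].window_defs,
        channel_subset=fms[0].channel_subset,
        labels=np.concatenate([f.labels for f in fms]),
        subject_id="+".join(f.subject_id for f in fms),
    )


def evaluate_loso(subjects, cfg: CvConfig | None = None,
                  max_train_trials: int | None = None) -> pd.DataFrame:
    """Leave-one-subject-out: per held-out subject, pool the others, fit the
    grid-searched decoder, test on the full held-out subject.

    ``cfg.max_search_trials`` bounds only the hyperparameter search (the
    final model refits on the full pool); ``max_train_trials`` additionally
    subsamples the pooled training trials themselves (stratified by label).
    """
    cfg = cfg or CvConfig()
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out")
    fms = [_as_features(s, cfg) for s in subjects]
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i, held in enumerate(fms):
        rest = [f for j, f in enumerate(fms) if j != i]
        X = np.concatenate([f.values for f in rest])
        y = np.concatenate([f.labels for f in rest])
        if max_train_trials is not None and y.size > max_train_trials:
            frac = max_train_trials / y.size
            keep = []
            for c in np.unique(y):
                idx = np.flatnonzero(y == c)
                keep.append(rng.choice(idx, size=max(2, int(round(frac * idx.size))),
                                       replace=False))
            keep = np.sort(np.concatenate(keep))
            X, y = X[keep], y[keep]
        clf = grid_search_train(X, y, cfg.grid, cfg.inner_folds, rng,
                                cfg.max_search_trials)
        m = balanced_accuracy(held.labels, clf.predict(held.values))
        rows.append({"subject": held.subject_id or str(i), "tpr": m.tpr,
                     "tnr": m.tnr, "bacc": m.bacc, "cost": clf.cost_,
                     "gamma": clf.gamma_})
    return pd.DataFrame(rows)


def train_generic(training_subjects, cfg: CvConfig | None = None) -> TrainedModel:
    """Train the generic decoder once on pooled simulated training subjects
    and freeze it; applying it later performs no adaptation."""
    cfg = cfg or CvConfig()
    pooled = pool_features(training_subjects, cfg)
    rng = np.random.default_rng(cfg.seed)
    clf = grid_search_train(pooled.values, pooled.labels, cfg.grid,
                            cfg.inner_folds, rng, cfg.max_search_trials)
    ids = [getattr(s, "subject_id", "") or str(i)
           for i, s in enumerate(training_subjects)]
    return TrainedModel(estimator=clf, training_subjects=ids, seed=cfg.seed)


def apply_model(model: TrainedModel, subject: EpochsData | feat.FeatureMatrix,
                cfg: CvConfig | None = None):
    """Apply a frozen decoder to one subject; returns (TPR, TNR, bACC)."""
    cfg = cfg or CvConfig()
    fm = _as_features(subject, cfg)
    return balanced_accuracy(fm.labels, model.predict(fm))
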