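"""Wrapper feature selection driven by the swarm optimizers.

The selector optimizes a continuous position in [0, 1]^n_features; a
threshold turns the position into a binary mask, and the mask is scored by

    fitness = α · (mean cross-validated classification error)
            + (1 − α) · (n_selected / n_features)

with α = 0.99 by default, so the error term dominates and the feature-ratio
term breaks ties toward sparser subsets.  Cross-validation folds partition
*subjects* (one row per subject; 70 subjects with 5 folds gives 14 test
subjects per fold), label-stratified where class counts permit, and are
frozen per run so the fitness landscape is deterministic.

The public face is :class:`SwarmFeatureSelector`, a scikit-learn selector
(``fit`` / ``transform`` / ``get_support``) that accepts a ``groups``
argument for subject identifiers and composes with sklearn pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from .exceptions import ConfigurationError, DimensionError, EvaluationError, FormatError
from .problems import BoundedProblem
from .stats import accuracy, confusion_counts, f1_and_auc, sensitivity
from .swarm import OPSOParams, PSOParams, run_opso, run_pso

__all__ = [
    "FeatureDataset",
    "FSConfig",
    "FoldMetrics",
    "FSResult",
    "binarize_position",
    "subject_grouped_folds",
    "wrapper_fitness",
    "evaluate_mask",
    "run_feature_selection",
    "SwarmFeatureSelector",
    "dataset_from_dataframe",
]


@dataclass
class FeatureDataset:
    """Subjects × features matrix with binary labels and subject identifiers."""

    X: np.ndarray
    y: np.ndarray
    subject_id: np.ndarray
    task_name: str = ""
    truth_mask: Optional[np.ndarray] = None
    feature_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y).astype(int)
        self.subject_id = np.asarray(self.subject_id)
        n = self.X.shape[0]
        if self.y.shape != (n,) or self.subject_id.shape != (n,):
            raise DimensionError("X, y and subject_id must agree on row count")
        if set(np.unique(self.y)) - {0, 1}:
            raise ConfigurationError("labels must be binary 0/1")
        if len(np.unique(self.y)) < 2:
            raise ConfigurationError("both classes must be present")
        if len(np.unique(self.subject_id)) != n:
            raise ConfigurationError("expected exactly one row per subject")
        if self.feature_names is None:
            self.feature_names = [f"f{j:03d}" for j in range(self.X.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def dataset_from_dataframe(df: pd.DataFrame, task_name: str = "") -> FeatureDataset:
    """Build a dataset from a table with reserved columns subject_id, label."""
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise FormatError(f"dataset is missing required column '{col}'")
    feats = [c for c in df.columns if c not in ("subject_id", "label")]
    return FeatureDataset(
        X=df[feats].to_numpy(dtype=float),
        y=df["label"].to_numpy(),
        subject_id=df["subject_id"].to_numpy(),
        task_name=task_name,
        feature_names=list(feats),
    )


@dataclass
class FSConfig:
    """Wrapper-fitness configuration.

    ``alpha`` weights classification error against the selected-feature
    ratio; ``threshold`` binarizes continuous positions; ``classifier`` is
    any sklearn-style fit/predict estimator (default 5-nearest-neighbours).
    """

    alpha: float = 0.99
    threshold: float = 0.5
    n_folds: int = 5
    classifier: object = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.n_folds < 2:
            raise ConfigurationError("need at least 2 folds")

    def make_classifier(self):
        if self.classifier is None:
            return KNeighborsClassifier(n_neighbors=5)
        return clone(self.classifier)


@dataclass
class FoldMetrics:
    fold: int
    accuracy: float
    sensitivity: float
    f1: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class FSResult:
    """Outcome of one feature-selection run."""

    mask: np.ndarray
    fitness: float
    n_selected: int
    fold_metrics: list[FoldMetrics]
    mean_metrics: dict
    std_metrics: dict
    history: np.ndarray
    seed: int
    optimizer: str


def binarize_position(x: np.ndarray, theta: float = 0.5) -> np.ndarray:
    """mask[d] = 1 iff x[d] > theta."""
    if not 0.0 < theta < 1.0:
        raise ConfigurationError("theta must be in (0, 1)")
    return (np.asarray(x, dtype=float) > theta).astype(int)


def subject_grouped_folds(dataset: FeatureDataset, k: int, seed: int) -> np.ndarray:
    """Assign each subject to exactly one test fold (label-stratified).

    Returns an integer fold label per row.  Fold sizes differ by at most
    one; 70 subjects with k = 5 gives five test folds of 14.
    """
    if k > dataset.n_subjects:
        raise ConfigurationError(
            f"k={k} folds exceed {dataset.n_subjects} subjects"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(dataset.n_subjects, dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(dataset.X, dataset.y)):
        folds[test_idx] = f
    return folds


def _cv_error(mask: np.ndarray, dataset: FeatureDataset, cfg: FSConfig,
              folds: np.ndarray) -> float:
    """Mean held-out error of the configured classifier on selected columns."""
    cols = np.flatnonzero(mask)
    errors = []
    for f in range(folds.max() + 1):
        test = folds == f
        y_tr = dataset.y[~test]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {f}: single-class training split skipped")
            continue
        clf = cfg.make_classifier()
        clf.fit(dataset.X[~test][:, cols], y_tr)
        pred = clf.predict(dataset.X[test][:, cols])
        errors.append(float(np.mean(pred != dataset.y[test])))
    if not errors:
        raise EvaluationError("all cross-validation folds were degenerate")
    return float(np.mean(errors))


def wrapper_fitness(mask: np.ndarray, dataset: FeatureDataset, cfg: FSConfig,
                    folds: Optional[np.ndarray] = None) -> float:
    """α·(CV error) + (1−α)·(selected ratio); the empty mask scores 1.0."""
    mask = np.asarray(mask).astype(int)
    if mask.shape != (dataset.n_features,):
        raise DimensionError(
            f"mask length {mask.shape} does not match {dataset.n_features} features"
        )
    n_sel = int(mask.sum())
    if n_sel == 0:
        return 1.0
    if folds is None:
        folds = subject_grouped_folds(dataset, cfg.n_folds, cfg.seed)
    err = _cv_error(mask, dataset, cfg, folds)
    return cfg.alpha * err + (1.0 - cfg.alpha) * (n_sel / dataset.n_features)


def evaluate_mask(mask: np.ndarray, dataset: FeatureDataset, cfg: FSConfig,
                  folds: Optional[np.ndarray] = None) -> tuple[list[FoldMetrics], dict, dict]:
    """Per-fold confusion counts, accuracy, sensitivity, F1 and AUC.

    The classifier score for AUC is its positive-class probability — for
    k-NN the fraction of positive neighbours.
    """
    mask = np.asarray(mask).astype(int)
    if mask.sum() == 0:
        raise EvaluationError("cannot evaluate an empty feature mask")
    if folds is None:
        folds = subject_grouped_folds(dataset, cfg.n_folds, cfg.seed)
    cols = np.flatnonzero(mask)
    out: list[FoldMetrics] = []
    for f in range(folds.max() + 1):
        test = folds == f
        y_tr, y_te = dataset.y[~test], dataset.y[test]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            warnings.warn(f"fold {f}: degenerate split skipped in evaluation")
            continue
        clf = cfg.make_classifier()
        clf.fit(dataset.X[~test][:, cols], y_tr)
        Xte = dataset.X[test][:, cols]
        pred = clf.predict(Xte)
        if hasattr(clf, "predict_proba"):
            pos = list(clf.classes_).index(1)
            scores = clf.predict_proba(Xte)[:, pos]
        else:  # fall back to a decision-function squashed to [0, 1]
            raw = clf.decision_function(Xte)
            scores = 1.0 / (1.0 + np.exp(-raw))
        c = confusion_counts(y_te, pred)
        f1, auc = f1_and_auc(scores, y_te)
        out.append(FoldMetrics(fold=f, accuracy=accuracy(c),
                               sensitivity=sensitivity(c), f1=f1, auc=auc,
                               tp=c.TP, tn=c.TN, fp=c.FP, fn=c.FN))
    if not out:
        raise EvaluationError("all folds degenerate; no metrics computed")
    keys = ("accuracy", "sensitivity", "f1", "auc")
    mean = {k: float(np.mean([getattr(m, k) for m in out])) for k in keys}
    std = {k: float(np.std([getattr(m, k) for m in out])) for k in keys}
    return out, mean, std


class _MaskObjective:
    """Continuous-position objective with a mask-level evaluation cache."""

    def __init__(self, dataset: FeatureDataset, cfg: FSConfig, folds: np.ndarray):
        self.dataset = dataset
        self.cfg = cfg
        self.folds = folds
        self.cache: dict[bytes, float] = {}

    def __call__(self, x: np.ndarray) -> float:
        mask = binarize_position(x, self.cfg.threshold)
        key = np.packbits(mask).tobytes()
        if key not in self.cache:
            self.cache[key] = wrapper_fitness(mask, self.dataset, self.cfg, self.folds)
        return self.cache[key]

    def batch(self, X: np.ndarray) -> np.ndarray:
        return np.array([self(x) for x in np.atleast_2d(X)])


def _default_opt_params(optimizer: str, n_features: int):
    """Wrapper-FS optimizer budget: small swarms suffice for subset search."""
    if optimizer == "opso":
        return OPSOParams(population=20, t_max=40)
    if optimizer == "pso":
        return PSOParams(population=20, t_max=40)
    raise ConfigurationError(f"optimizer must be 'opso' or 'pso', got {optimizer!r}")


def run_feature_selection(
    dataset: FeatureDataset,
    optimizer: str = "opso",
    fs_cfg: Optional[FSConfig] = None,
    opt_params=None,
) -> FSResult:
    """Optimize the wrapper fitness over [0, 1]^n_features.

    The initial population always contains one particle at the all-ones
    position, so the trivial use-everything mask is considered; the final
    fitness therefore never exceeds the all-features fitness.
    """
    cfg = fs_cfg or FSConfig()
    if opt_params is None:
        opt_params = _default_opt_params(optimizer, dataset.n_features)
    folds = subject_grouped_folds(dataset, cfg.n_folds, cfg.seed)
    obj = _MaskObjective(dataset, cfg, folds)
    problem = BoundedProblem(
        dimension=dataset.n_features,
        lower=np.zeros(dataset.n_features),
        upper=np.ones(dataset.n_features),
        objective=obj,
        name=f"fs-{dataset.task_name or 'dataset'}",
        batch_objective=obj.batch,
    )
    all_ones = np.ones((1, dataset.n_features))
    runner = run_opso if optimizer == "opso" else run_pso
    if optimizer not in ("opso", "pso"):
        raise ConfigurationError(f"optimizer must be 'opso' or 'pso', got {optimizer!r}")
    result = runner(problem, opt_params, seed=cfg.seed, init_positions=all_ones)
    mask = binarize_position(result.best_position, cfg.threshold)
    fold_metrics, mean, std = evaluate_mask(mask, dataset, cfg, folds)
    # leakage guard: every subject is tested exactly once, in balanced folds
    counts = np.bincount(folds, minlength=cfg.n_folds)
    if counts.sum() != dataset.n_subjects or counts.max() - counts.min() > 1:
        raise EvaluationError("fold assignment violated the subject partition")
    return FSResult(
        mask=mask,
        fitness=float(result.best_fitness),
        n_selected=int(mask.sum()),
        fold_metrics=fold_metrics,
        mean_metrics=mean,
        std_metrics=std,
        history=result.history,
        seed=cfg.seed,
        optimizer=optimizer,
    )


class SwarmFeatureSelector(SelectorMixin, BaseEstimator):
    """Swarm-driven wrapper feature selector with a scikit-learn interface.

    Parameters
    ----------
    optimizer : {"opso", "pso"}
        Which swarm optimizer searches mask space.
    estimator : sklearn classifier, optional
        Wrapped classifier scored inside the fitness; default 5-NN.
    alpha : float
        Weight of the cross-validated error term (1 − alpha weights the
        selected-feature ratio).
    threshold : float
        Continuous-to-binary cutoff on particle positions.
    n_folds : int
        Subject-grouped stratified folds used inside the fitness.
    population, n_iterations : int
        Swarm budget for the mask search.
    random_state : int
        Seed for folds and the optimizer run.

    Attributes
    ----------
    support_mask_ : ndarray of bool, shape (n_features,)
        Selected features.
    fitness_ : float
        Best wrapper fitness reached.
    fold_metrics_, mean_metrics_, std_metrics_ :
        Held-out metrics of the final mask (accuracy, sensitivity, F1, AUC).
    """

    def __init__(self, optimizer: str = "opso", estimator=None, alpha: float = 0.99,
                 threshold: float = 0.5, n_folds: int = 5, population: int = 20,
                 n_iterations: int = 40, random_state: int = 0):
        self.optimizer = optimizer
        self.estimator = estimator
        self.alpha = alpha
        self.threshold = threshold
        self.n_folds = n_folds
        self.population = population
        self.n_iterations = n_iterations
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X, y = check_X_y(X, y)
        if groups is None:
            groups = np.arange(len(y))
        dataset = FeatureDataset(X=X, y=y, subject_id=np.asarray(groups))
        cfg = FSConfig(alpha=self.alpha, threshold=self.threshold,
                       n_folds=self.n_folds, classifier=self.estimator,
                       seed=self.random_state)
        if self.optimizer == "opso":
            params = OPSOParams(population=self.population, t_max=self.n_iterations)
        elif self.optimizer == "pso":
            params = PSOParams(population=self.population, t_max=self.n_iterations)
        else:
            raise ConfigurationError(
                f"optimizer must be 'opso' or 'pso', got {self.optimizer!r}"
            )
        result = run_feature_selection(dataset, self.optimizer, cfg, params)
        self.n_features_in_ = X.shape[1]
        self.support_mask_ = result.mask.astype(bool)
        self.fitness_ = result.fitness
        self.n_selected_ = result.n_selected
        self.fold_metrics_ = result.fold_metrics
        self.mean_metrics_ = result.mean_metrics
        self.std_metrics_ = result.std_metrics
        self.history_ = result.history
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
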