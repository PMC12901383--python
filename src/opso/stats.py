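"""Classification metrics and rank-based comparison of algorithms.

Covers the evaluation surface of the dyslexia-detection experiments:
confusion-matrix metrics (accuracy, sensitivity), threshold/rank metrics
(F1 at a 0.5 score threshold, AUC in the Mann–Whitney midrank formulation),
the Friedman test over a datasets × algorithms metric table, and the
Nemenyi post-hoc critical difference

    CD = q_{α,k} · sqrt(k(k+1) / (6n)),

with the critical values q_{α,k} (studentized range at infinite df divided
by √2) shipped as a static table for k = 2..20 and α ∈ {0.05, 0.10}.

Ranking convention: within each dataset row, algorithms receive midrank ties
on the raw metric in ascending order, so for a higher-is-better metric the
best algorithm holds rank k, and for a lower-is-better one it holds rank 1.
This matches how mean ranks are conventionally printed for accuracy-like and
fitness-like tables respectively; the ``higher_is_better`` flag records
which direction is "best" and flips the Nemenyi "better-than" direction,
while leaving the Friedman statistic (direction-invariant) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import f1_score, roc_auc_score

from .exceptions import ConfigurationError, FormatError

__all__ = [
    "ConfusionCounts",
    "MetricTable",
    "accuracy",
    "sensitivity",
    "f1_and_auc",
    "FriedmanResult",
    "friedman_mean_ranks",
    "NemenyiResult",
    "nemenyi_posthoc",
    "load_fixture_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Counts with label 1 as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ConfigurationError("accuracy undefined for zero total count")
    return (c.TP + c.TN) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise ConfigurationError("sensitivity undefined with no positive cases")
    return c.TP / (c.TP + c.FN)


def f1_and_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """F1 at the 0.5 score threshold and midrank Mann–Whitney AUC.

    ``scores`` are positive-class scores in [0, 1]; both classes must be
    present in ``labels``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ConfigurationError("F1/AUC undefined with a single-class label vector")
    preds = (scores >= 0.5).astype(int)
    f1 = float(f1_score(labels, preds, zero_division=0.0))
    auc = float(roc_auc_score(labels, scores))
    return f1, auc


@dataclass
class MetricTable:
    """A datasets × algorithms table of one metric."""

    values: pd.DataFrame
    higher_is_better: bool = True

    def __post_init__(self):
        if self.values.isna().any().any():
            raise FormatError("metric table has missing cells")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise FormatError("metric table needs >= 2 rows and >= 2 columns")

    @classmethod
    def from_csv(cls, path: str | Path, higher_is_better: bool = True) -> "MetricTable":
        try:
            df = pd.read_csv(path, index_col=0)
        except (OSError, pd.errors.ParserError) as exc:
            raise FormatError(f"cannot read metric table {path}: {exc}") from exc
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric cells in metric table {path}") from exc
        return cls(values=df, higher_is_better=higher_is_better)


@dataclass
class FriedmanResult:
    mean_ranks: pd.Series      # per algorithm, midrank ties
    statistic: float           # tie-corrected Friedman chi-square
    pvalue: float
    n_datasets: int
    n_algorithms: int
    ranks: pd.DataFrame        # per-row ranks (ascending in the raw metric)


def friedman_mean_ranks(table: MetricTable) -> FriedmanResult:
    """Friedman mean ranks and tie-corrected chi-square test.

    Ranks are assigned ascending in the raw metric with midranks for ties
    (so each row's ranks sum to k(k+1)/2 exactly).  The statistic uses the
    standard tie correction 1 − Σ(t³−t) / (n·k·(k²−1)).
    """
    values = table.values.to_numpy(dtype=float)
    n, k = values.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, values)
    rank_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0:                      # every row fully tied
        chisq, pvalue = 0.0, 1.0
    else:
        chisq = chisq / correction
        pvalue = float(sps.chi2.sf(chisq, k - 1))
    return FriedmanResult(
        mean_ranks=pd.Series(ranks.mean(axis=0), index=table.values.columns),
        statistic=float(chisq),
        pvalue=pvalue,
        n_datasets=n,
        n_algorithms=k,
        ranks=pd.DataFrame(ranks, index=table.values.index,
                           columns=table.values.columns),
    )


@dataclass
class NemenyiResult:
    critical_difference: float
    mean_ranks: pd.Series
    significant: pd.DataFrame   # boolean pairwise matrix |r_i - r_j| >= CD
    alpha: float


def _load_q_table() -> pd.DataFrame:
    with resources.files("opso.data").joinpath("nemenyi_qtable.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def nemenyi_posthoc(
    mean_ranks: Sequence[float] | pd.Series,
    k: Optional[int] = None,
    n: int = None,
    alpha: float = 0.05,
) -> NemenyiResult:
    """Nemenyi critical difference and pairwise significance matrix.

    Two algorithms differ significantly when their Friedman mean ranks
    differ by at least ``CD = q_{α,k}·sqrt(k(k+1)/(6n))`` with ``n`` the
    number of datasets.
    """
    if isinstance(mean_ranks, pd.Series):
        ranks = mean_ranks
    else:
        ranks = pd.Series(np.asarray(mean_ranks, dtype=float))
    if k is None:
        k = len(ranks)
    if k != len(ranks):
        raise ConfigurationError(f"k={k} does not match {len(ranks)} mean ranks")
    if n is None or n < 2:
        raise ConfigurationError("n (number of datasets) must be >= 2")
    qtab = _load_q_table()
    col = f"q_{alpha:g}"
    if col not in qtab.columns:
        raise ConfigurationError(
            f"no critical values for alpha={alpha}; available: 0.05, 0.10"
        )
    if k not in qtab.index:
        raise ConfigurationError(f"k={k} outside the shipped q-table range 2..20")
    q = float(qtab.loc[k, col])
    cd = q * np.sqrt(k * (k + 1) / (6.0 * n))
    diff = np.abs(ranks.to_numpy()[:, None] - ranks.to_numpy()[None, :])
    sig = pd.DataFrame(diff >= cd, index=ranks.index, columns=ranks.index)
    np.fill_diagonal(sig.values, False)
    return NemenyiResult(critical_difference=float(cd), mean_ranks=ranks,
                         significant=sig, alpha=alpha)


_FIXTURES = {
    "table3_accuracy": ("table3_accuracy.csv", True),
    "table3_sensitivity": ("table3_sensitivity.csv", True),
    "table4_auc": ("table4_auc.csv", True),
    "table4_f1": ("table4_f1.csv", True),
    "table5_fitness_mean": ("table5_fitness_mean.csv", False),
}


def load_fixture_table(name: str) -> MetricTable:
    """Load one of the shipped datasets × algorithms result tables.

    Available: table3_accuracy, table3_sensitivity, table4_auc, table4_f1,
    table5_fitness_mean.  The fitness table is lower-is-better.
    """
    if name not in _FIXTURES:
        raise ConfigurationError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    fname, hib = _FIXTURES[name]
    with resources.files("opso.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, index_col=0).astype(float)
    return MetricTable(values=df, higher_is_better=hib)
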