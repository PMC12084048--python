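"""Study measurement protocol: encoding, splits, CV search, metric panels.

The protocol mirrors standard perioperative prediction practice: an initial
80:20 outcome-stratified split; hyperparameters chosen by 10-fold
cross-validated grid search on the training partition only; the frozen
model then scored over 10 independent test runs, each on a random 90%
subsample of the held-out test partition, reporting each metric as mean with
a t-based 95% confidence interval over the runs.

Partition objects carry a ``role`` tag; fitting a preprocessing transform or
selecting a model on a partition tagged ``test`` raises, which is how the
no-leakage contract is enforced mechanically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Partition",
    "Preprocessor",
    "LeakageError",
    "MetricReport",
    "stratified_split",
    "grid_search_cv",
    "repeated_test_evaluation",
    "confusion_metrics",
    "roc_auc",
    "pr_curve",
]

METRICS = ("accuracy", "auc", "f1", "sensitivity", "specificity", "ppv", "npv")


class LeakageError(RuntimeError):
    """A test-tagged partition reached a fit/selection step."""


@dataclass
class Partition:
    """A view of the cohort with a data-flow role tag."""

    X: pd.DataFrame
    y: np.ndarray
    role: str = "train"  # train | validation | test

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must be aligned")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(y, ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-stratified random split; returns (indices_A, indices_B).

    ``|A| = round(ratio * n)`` (half-up), with per-class counts allocated by
    largest remainder so prevalence matches within one sample per class.
    """
    y = np.asarray(y)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members")
    n_a = _round_half_up(ratio * n)
    ideal = ratio * counts
    base = np.floor(ideal).astype(int)
    short = n_a - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    for i in range(int(short)):
        base[order[i % len(base)]] += 1
    rng = np.random.default_rng(seed)
    take_a, take_b = [], []
    for cls, quota in zip(classes, base):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        take_a.append(idx[:quota])
        take_b.append(idx[quota:])
    a = np.sort(np.concatenate(take_a))
    b = np.sort(np.concatenate(take_b))
    return a, b


class Preprocessor:
    """Binary passthrough, one-hot for non-ordinal categoricals, 0-1 min-max
    for continuous features; parameters learned on train only.

    Out-of-range continuous values at apply time are *not* clipped (a test
    value above the train max maps above 1) but are counted and warned
    about; unseen categories map to all-zero indicators with a warning.
    """

    def __init__(self, categorical: list[str] | None = None,
                 binary: list[str] | None = None):
        self.categorical = list(categorical or [])
        self.binary = list(binary or [])
        self.fitted_ = False

    def fit(self, partition: Partition) -> "Preprocessor":
        if partition.role == "test":
            raise LeakageError("cannot fit a transform on the test partition")
        X = partition.X
        self.columns_ = list(X.columns)
        self.categories_ = {c: sorted(pd.unique(X[c]).tolist())
                            for c in self.categorical}
        self.continuous_ = [c for c in self.columns_
                            if c not in self.categorical and c not in self.binary]
        self.min_ = X[self.continuous_].min()
        self.max_ = X[self.continuous_].max()
        self.fitted_ = True
        return self

    def transform(self, partition: Partition) -> pd.DataFrame:
        if not self.fitted_:
            raise RuntimeError("transform before fit")
        X = partition.X
        pieces = []
        span = (self.max_ - self.min_).replace(0, 1.0)
        cont = (X[self.continuous_] - self.min_) / span
        out_of_range = int(((cont < 0) | (cont > 1)).to_numpy().sum())
        if out_of_range and partition.role != "train":
            warnings.warn(f"{out_of_range} transformed values fall outside "
                          "[0, 1] (train range exceeded); not clipped")
        pieces.append(cont)
        if self.binary:
            pieces.append(X[self.binary].astype(float))
        for col in self.categorical:
            known = self.categories_[col]
            indicators = pd.DataFrame(
                {f"{col}={lvl}": (X[col] == lvl).astype(float) for lvl in known},
                index=X.index)
            unseen = int((~X[col].isin(known)).sum())
            if unseen:
                warnings.warn(f"{unseen} unseen categories in {col!r} mapped "
                              "to all-zero indicators")
            pieces.append(indicators)
        return pd.concat(pieces, axis=1)

    def to_dict(self) -> dict:
        return {
            "continuous": {c: [float(self.min_[c]), float(self.max_[c])]
                           for c in self.continuous_},
            "binary": self.binary,
            "categorical": {c: list(map(str, v))
                            for c, v in self.categories_.items()},
        }


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(probabilities, labels) -> float:
    """AUC as tie-corrected pairwise concordance (ties count one half).

    Computed via mid-ranks (Mann-Whitney), which is algebraically the
    concordance sum; requires both classes present.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = p[y == 1]
    neg = p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def pr_curve(probabilities, labels) -> pd.DataFrame:
    """Precision-recall pairs at every distinct score threshold."""
    from sklearn.metrics import precision_recall_curve
    precision, recall, thresholds = precision_recall_curve(labels, probabilities)
    return pd.DataFrame({
        "threshold": np.concatenate([thresholds, [np.inf]]),
        "precision": precision,
        "recall": recall,
    })


def confusion_metrics(probabilities, labels, threshold: float = 0.5) -> dict:
    """Full panel at a fixed decision threshold; undefined entries are NaN.

    Returns the metric dict plus confusion counts tp/fp/tn/fn.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = (2 * ppv * sens / (ppv + sens)
          if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
          else float("nan"))
    try:
        auc = roc_auc(p, y)
    except ValueError:
        auc = float("nan")
    return {
        "accuracy": ratio(tp + tn, len(y)), "auc": auc, "f1": f1,
        "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


@dataclass
class MetricReport:
    """Mean and 95% CI per metric over repeated test runs."""

    runs: pd.DataFrame                      # one row per run, metric columns
    mean: dict[str, float] = field(default_factory=dict)
    ci_halfwidth: dict[str, float] = field(default_factory=dict)
    undefined_counts: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def from_runs(runs: pd.DataFrame) -> "MetricReport":
        mean, ci, undef = {}, {}, {}
        n = len(runs)
        for metric in METRICS:
            vals = runs[metric].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            undef[metric] = int((~ok).sum())
            if ok.sum() == 0:
                mean[metric] = float("nan")
                ci[metric] = float("nan")
                continue
            m = float(vals[ok].mean())
            mean[metric] = m
            if ok.sum() < 2:
                ci[metric] = float("nan")
            elif np.ptp(vals[ok]) == 0:
                ci[metric] = 0.0   # identical runs: zero-width interval
            else:
                sd = float(vals[ok].std(ddof=1))
                tcrit = stats.t.ppf(0.975, df=ok.sum() - 1)
                ci[metric] = float(tcrit * sd / math.sqrt(ok.sum()))
        return MetricReport(runs=runs, mean=mean, ci_halfwidth=ci,
                            undefined_counts=undef)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_halfwidth": self.ci_halfwidth,
            "undefined_counts": self.undefined_counts,
            "runs": self.runs.to_dict(orient="records"),
        }


def repeated_test_evaluation(predict_proba, test: Partition, n_runs: int = 10,
                             fraction: float = 0.9, seed: int = 0,
                             threshold: float = 0.5) -> MetricReport:
    """Score a frozen model over repeated random test subsamples.

    Each run draws ``floor(fraction * |test|)`` rows without replacement and
    computes the full panel; metrics with a zero denominator in a run are
    flagged undefined and excluded from that metric's mean.
    """
    if test.role != "test":
        warnings.warn("repeated_test_evaluation expects a test-tagged partition")
    rng = np.random.default_rng(seed)
    n = len(test.X)
    m = int(math.floor(fraction * n))
    rows = []
    for _ in range(n_runs):
        idx = (np.arange(n) if m == n
               else np.sort(rng.choice(n, size=m, replace=False)))
        p = np.asarray(predict_proba(test.X.iloc[idx]), dtype=float)
        if p.ndim == 2:
            p = p[:, 1]
        rows.append(confusion_metrics(p, test.y[idx], threshold))
    return MetricReport.from_runs(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cross-validated grid search
# ---------------------------------------------------------------------------

def _stratified_folds(y, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        assignments[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignments == f) for f in range(folds)]


def grid_search_cv(factory, grid: list[dict], partition: Partition,
                   folds: int = 10, seed: int = 0, metric: str = "auc"):
    """Score every configuration by mean validation metric across folds.

    ``factory(**params)`` must return an estimator with ``fit`` and
    ``predict_proba``.  Ties go to the earlier configuration in the declared
    grid order (the documented simplicity order).  Returns
    ``(best_params, cv_table)``.
    """
    if partition.role == "test":
        raise LeakageError("model selection must not touch the test partition")
    if not grid:
        raise ValueError("empty grid")
    X, y = partition.X, np.asarray(partition.y)
    fold_idx = _stratified_folds(y, folds, seed)
    records = []
    scores = []
    for gi, params in enumerate(grid):
        fold_scores = []
        for f, val_idx in enumerate(fold_idx):
            if len(val_idx) == 0 or len(np.unique(y[val_idx])) < 2:
                continue
            train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
            est = factory(**params)
            est.fit(X.iloc[train_idx], y[train_idx])
            p = np.asarray(est.predict_proba(X.iloc[val_idx]))
            if p.ndim == 2:
                p = p[:, 1]
            value = (roc_auc(p, y[val_idx]) if metric == "auc"
                     else confusion_metrics(p, y[val_idx])[metric])
            fold_scores.append(value)
            records.append({"config": gi, "fold": f, metric: value, **params})
        scores.append(float(np.mean(fold_scores)) if fold_scores else -np.inf)
    best = int(np.argmax(scores))  # argmax keeps the first (simplest) on ties
    return grid[best], pd.DataFrame(records)
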