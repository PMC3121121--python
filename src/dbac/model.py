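"""Hot-spot classification with an RBF-kernel SVM under nested
leave-one-out cross-validation.

A residue is a *hot spot* when its experimental alanine-scanning binding
free energy change satisfies ddG >= 2.0 kcal/mol (boundary inclusive).
The classifier is evaluated with a strictly nested protocol: each record in
turn is held out; on the remaining records a grid search over (cost, gamma)
picks the pair maximising mean F1 under an inner stratified 5-fold
cross-validation; an SVM with those parameters is fitted to the training
records and applied to the held-out one.  The held-out label is never read
before the prediction is made.  Features are min-max scaled to [0, 1] using
training-fold statistics only.

The public surface follows the model/results convention: build a
:class:`HotspotSVM` from a feature table and ddG values (or labels), call
``fit`` to run the protocol, and read predictions, the confusion matrix, the
five performance metrics and the Mann-Whitney significance off the returned
:class:`HotspotResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DDG_THRESHOLD = 2.0  # kcal/mol, hot spot iff ddG >= threshold

#: Canonical (cost, gamma) grid: powers of two with step 2^2.
DEFAULT_COSTS = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMAS = tuple(2.0 ** k for k in range(-15, 4, 2))


def label_hotspots(ddg, threshold: float = DDG_THRESHOLD) -> np.ndarray:
    """Boolean hot-spot labels from ddG values (kcal/mol), boundary inclusive."""
    ddg = np.asarray(ddg, dtype=float)
    if np.isnan(ddg).any():
        raise ValueError("missing ddG values")
    return ddg >= threshold


@dataclass
class EvaluationReport:
    """Confusion counts and the five classification metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    precision: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        n = tp + fp + tn + fn
        if n == 0:
            raise ValueError("empty confusion matrix")
        self.sensitivity = tp / (tp + fn) if tp + fn else 0.0
        self.precision = tp / (tp + fp) if tp + fp else 0.0
        self.specificity = tn / (tn + fp) if tn + fp else 0.0
        self.accuracy = (tp + tn) / n
        denom = self.precision + self.sensitivity
        self.f1 = 2 * self.precision * self.sensitivity / denom if denom else 0.0

    def as_series(self) -> pd.Series:
        return pd.Series({
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity, "precision": self.precision,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "F1": self.f1,
        })


def evaluate(predictions, labels) -> EvaluationReport:
    """Confusion counts and metrics from boolean predictions vs labels."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if len(pred) != len(lab):
        raise ValueError("prediction/label length mismatch")
    if len(pred) == 0:
        raise ValueError("empty input")
    return EvaluationReport(
        tp=int(np.sum(pred & lab)), fp=int(np.sum(pred & ~lab)),
        tn=int(np.sum(~pred & ~lab)), fn=int(np.sum(~pred & lab)))


def mann_whitney(group_a, group_b) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small tie-free samples)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and max(len(a), len(b)) <= 25 else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def feature_significance(features: pd.DataFrame, labels) -> pd.Series:
    """Per-feature two-sided Mann-Whitney p-value between the two classes."""
    lab = np.asarray(labels, dtype=bool)
    if not (lab.any() and (~lab).any()):
        raise ValueError("both classes must be present")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(f"feature {col!r} is constant; p-value set to 1")
            out[col] = 1.0
        else:
            out[col] = mann_whitney(x[lab], x[~lab])
    return pd.Series(out)


def _minmax_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo, span


def _inner_f1(x, y, cost, gamma, seed) -> float:
    """Mean F1 of an SVM over a stratified 5-fold split of (x, y)."""
    n_splits = min(5, int(y.sum()), int((~y).sum()))
    if n_splits < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(x, y):
        if len(np.unique(y[tr])) < 2:
            scores.append(0.0)
            continue
        lo, span = _minmax_fit(x[tr])
        clf = SVC(C=cost, gamma=gamma, kernel="rbf")
        clf.fit((x[tr] - lo) / span, y[tr])
        pred = clf.predict((x[te] - lo) / span).astype(bool)
        scores.append(evaluate(pred, y[te]).f1)
    return float(np.mean(scores))


def grid_search(features, labels,
                costs=DEFAULT_COSTS, gammas=DEFAULT_GAMMAS,
                seed: int = 0) -> tuple[float, float]:
    """Pick (cost, gamma) maximising inner 5-fold F1 on the training data.

    Ties are broken towards the smaller cost, then the smaller gamma, so the
    search is deterministic for a fixed seed.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes in the training set")
    best, best_score = None, -1.0
    for cost in sorted(costs):
        for gamma in sorted(gammas):
            score = _inner_f1(x, y, cost, gamma, seed)
            if score > best_score + 1e-12:
                best, best_score = (cost, gamma), score
    return best


def nested_loocv(features, labels, costs=DEFAULT_COSTS, gammas=DEFAULT_GAMMAS,
                 seed: int = 0, leave_n: int = 1
                 ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Nested leave-one-out (or leave-n-out) predictions.

    Returns one prediction per record plus the (cost, gamma) chosen for the
    fold that held the record out.  ``leave_n > 1`` partitions the records
    into seeded random blocks of that size (the robustness-check protocol).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 records")
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    if leave_n <= 1:
        folds = [[i] for i in range(n)]
    else:
        order = rng.permutation(n)
        folds = [order[k:k + leave_n].tolist() for k in range(0, n, leave_n)]
    pred = np.zeros(n, dtype=bool)
    chosen: list[tuple[float, float] | None] = [None] * n
    for fold in folds:
        tr = np.setdiff1d(np.arange(n), fold)
        if len(np.unique(y[tr])) < 2:
            warnings.warn("training fold lost a class; majority prediction")
            majority = bool(y[tr].sum() * 2 > len(tr))
            for i in fold:
                pred[i] = majority
                chosen[i] = (float("nan"), float("nan"))
            continue
        cost, gamma = grid_search(x[tr], y[tr], costs, gammas, seed=seed)
        lo, span = _minmax_fit(x[tr])
        clf = SVC(C=cost, gamma=gamma, kernel="rbf")
        clf.fit((x[tr] - lo) / span, y[tr])
        out = clf.predict((x[fold] - lo) / span).astype(bool)
        for i, p in zip(fold, out):
            pred[i] = p
            chosen[i] = (cost, gamma)
    return pred, chosen


class HotspotSVM:
    """Hot-spot classifier over a residue feature table.

    Parameters
    ----------
    features : DataFrame
        One row per mutation, DBAC (6) or AC (12) feature columns.
    ddg : array-like, optional
        Experimental ddG in kcal/mol; labels are derived with ``threshold``.
    labels : array-like, optional
        Boolean hot-spot labels, if ddG is not available.
    """

    def __init__(self, features: pd.DataFrame, ddg=None, labels=None,
                 threshold: float = DDG_THRESHOLD,
                 costs=DEFAULT_COSTS, gammas=DEFAULT_GAMMAS) -> None:
        self.features = pd.DataFrame(features)
        if ddg is None and labels is None:
            raise ValueError("provide ddg or labels")
        self.ddg = None if ddg is None else np.asarray(ddg, dtype=float)
        self.threshold = threshold
        self.labels = (label_hotspots(self.ddg, threshold)
                       if labels is None else np.asarray(labels, dtype=bool))
        if len(self.labels) != len(self.features):
            raise ValueError("feature/label length mismatch")
        self.costs, self.gammas = costs, gammas

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_columns,
                       ddg_column: str = "ddG", **kw) -> "HotspotSVM":
        return cls(df[list(feature_columns)], ddg=df[ddg_column], **kw)

    def fit(self, protocol: str = "loocv", leave_n: int = 1,
            seed: int = 0) -> "HotspotResults":
        if protocol not in ("loocv", "leave-n-out"):
            raise ValueError(f"unknown protocol {protocol!r}")
        n_out = 1 if protocol == "loocv" else leave_n
        pred, chosen = nested_loocv(self.features, self.labels,
                                    self.costs, self.gammas,
                                    seed=seed, leave_n=n_out)
        return HotspotResults(self, pred, chosen, protocol, seed)


class HotspotResults:
    """Cross-validated predictions, metrics and significance tests."""

    def __init__(self, model: HotspotSVM, predictions: np.ndarray,
                 fold_params, protocol: str, seed: int) -> None:
        self.model = model
        self.predictions = predictions
        self.fold_params = fold_params
        self.protocol = protocol
        self.seed = seed
        self.report = evaluate(predictions, model.labels)

    @property
    def mann_whitney_p(self) -> float:
        """Significance of the ddG split between predicted groups."""
        if self.model.ddg is None:
            raise ValueError("no ddG values attached to the model")
        pos = self.model.ddg[self.predictions]
        neg = self.model.ddg[~self.predictions]
        return mann_whitney(pos, neg)

    def feature_significance(self) -> pd.Series:
        return feature_significance(self.model.features, self.model.labels)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Hot-spot SVM (RBF), nested cross-validation",
            f"protocol: {self.protocol}   records: {len(self.predictions)}"
            f"   seed: {self.seed}",
            f"hot spots: {int(self.model.labels.sum())}   "
            f"non hot spots: {int((~self.model.labels).sum())}"
            f"   ddG threshold: {self.model.threshold} kcal/mol",
            "-" * 58,
            f"TP {r.tp:4d}  FP {r.fp:4d}  TN {r.tn:4d}  FN {r.fn:4d}",
            f"sensitivity  {r.sensitivity:8.4f}",
            f"precision    {r.precision:8.4f}",
            f"specificity  {r.specificity:8.4f}",
            f"accuracy     {r.accuracy:8.4f}",
            f"F1           {r.f1:8.4f}",
        ]
        if self.model.ddg is not None and self.predictions.any() \
                and not self.predictions.all():
            lines.append(f"Mann-Whitney p (ddG split) {self.mann_whitney_p:.4g}")
        return "\n".join(lines)
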