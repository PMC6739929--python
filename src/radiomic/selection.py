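"""Filter feature selection: Fisher, POE+ACC, and mutual information.

Three classical filter criteria rank the 352 radiomic features for one
two-group comparison (class vs class or class vs rest):

* Fisher — ratio of (size-weighted) between-class variance of the class
  means to the pooled within-class variance; correlation-blind.
* POE+ACC — greedy: the first feature minimizes the probability of
  classification error of an optimal single-threshold rule; each further
  feature minimizes POE + mean |Pearson correlation| with the already
  selected set (equal 1:1 weighting), reducing redundancy.
* Mutual information — MI in bits between the feature discretized into 10
  equal-width bins over its observed range and the class label.

The retained subset size follows the one-feature-per-ten-samples rule with
nearest-integer (round-half-up) rounding, which is what reproduces the
printed per-comparison feature counts (e.g. n=57+11 -> 7, n=91 -> 9).
Selection is performed once on all samples of the comparison, outside any
cross-validation; this mirrors the original protocol and is optimistically
biased — see docs/methods.md.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "subset_size",
    "fisher_score",
    "poe",
    "mutual_information",
    "poe_acc_select",
    "select",
]

CRITERIA = ("fisher", "poe_acc", "mi")


@dataclass(frozen=True)
class SelectionResult:
    criterion: str
    k: int
    features: tuple[str, ...]
    scores: tuple[float, ...]
    pair: tuple[str, str]

    def __post_init__(self):
        if len(self.features) != self.k or len(self.scores) != self.k:
            raise ValueError("ranked list length must equal k")

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "k": self.k,
            "features": list(self.features),
            "scores": list(self.scores),
            "pair": list(self.pair),
        }


def subset_size(n_samples: int) -> int:
    """One feature for every ten samples, rounded half-up (floor 1)."""
    if n_samples < 10:
        warnings.warn(f"only {n_samples} samples; using a single feature")
        return 1
    return int(math.floor(n_samples / 10 + 0.5))


def fisher_score(values, labels) -> float:
    """Between-class variance of class means over pooled within-class variance.

    Class contributions are weighted by class size (population variances).
    Zero within-class variance with distinct class means returns +inf, a
    sentinel that ranks the feature first.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("fisher_score needs >= 2 classes")
    n = len(values)
    grand = values.mean()
    between = 0.0
    within = 0.0
    for c in classes:
        v = values[labels == c]
        if len(v) < 2:
            raise ValueError(f"class {c!r} has < 2 samples")
        between += len(v) * (v.mean() - grand) ** 2
        within += len(v) * v.var()
    between /= n
    within /= n
    if within == 0.0:
        return float("inf") if between > 0 else 0.0
    return float(between / within)


def poe(values, labels) -> float:
    """Probability of classification error of the best 1-D rule.

    Two classes: minimum misclassification fraction of a single-threshold
    rule over all thresholds between sorted values, either polarity.  More
    classes: error of the nearest-class-mean rule in 1-D.  A constant
    feature scores the majority-class error.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n = len(values)
    majority_err = 1.0 - max((labels == c).sum() for c in classes) / n
    if values.min() == values.max():
        return float(majority_err)
    if len(classes) == 2:
        y = (labels == classes[1]).astype(np.int64)
        order = np.argsort(values, kind="stable")
        ys = y[order]
        n1 = ys.sum()
        n0 = n - n1
        # below threshold after i samples: i - cum1 zeros... evaluate both
        # polarities at every cut point (including the trivial cuts)
        cum1 = np.concatenate([[0], np.cumsum(ys)])
        idx = np.arange(n + 1)
        cum0 = idx - cum1
        # polarity A: predict class0 below the cut, class1 above
        err_a = (cum1 + (n0 - cum0)) / n
        # polarity B: predict class1 below the cut, class0 above
        err_b = (cum0 + (n1 - cum1)) / n
        # only cuts between distinct values (plus the two trivial cuts)
        vs = values[order]
        valid = np.concatenate([[True], vs[1:] != vs[:-1], [True]])
        best = min(err_a[valid].min(), err_b[valid].min())
        return float(best)
    means = {c: values[labels == c].mean() for c in classes}
    centers = np.array([means[c] for c in classes])
    pred = classes[np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)]
    return float((pred != labels).mean())


def mutual_information(values, labels) -> float:
    """MI in bits between a 10-bin discretized feature and the class label."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    lo, hi = values.min(), values.max()
    if lo == hi:
        return 0.0
    t = np.round((values - lo) / (hi - lo), 12)
    bins = np.minimum(np.floor(t * 10).astype(np.int64), 9)
    classes, y = np.unique(labels, return_inverse=True)
    joint = np.zeros((10, len(classes)))
    np.add.at(joint, (bins, y), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = (joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum()
    return float(max(mi, 0.0))


def poe_acc_select(table: pd.DataFrame, labels, k: int) -> tuple[list[str], list[float]]:
    """Greedy POE + average-correlation selection of k features.

    Ties break by column (registry) order.  The reported score of each
    pick is the criterion value at the time of its selection (POE for the
    first pick, POE + ACC thereafter); lower is better.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels)
    cols = list(table.columns)
    X = table.to_numpy(dtype=np.float64)
    poes = np.array([poe(X[:, j], labels) for j in range(X.shape[1])])
    sd = X.std(axis=0)
    selected: list[int] = []
    scores: list[float] = []
    for _ in range(min(k, len(cols))):
        best_j, best_score = None, np.inf
        for j in range(len(cols)):
            if j in selected:
                continue
            score = poes[j]
            if selected:
                acc = 0.0
                for s in selected:
                    if sd[j] == 0 or sd[s] == 0:
                        corr = 0.0  # correlation with a constant feature
                    else:
                        corr = abs(np.corrcoef(X[:, j], X[:, s])[0, 1])
                    acc += corr
                score = poes[j] + acc / len(selected)
            if score < best_score - 1e-15:
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(float(best_score))
    return [cols[j] for j in selected], scores


def _group_mask(labels: np.ndarray, group: str) -> np.ndarray:
    if group == "rest":
        raise ValueError("'rest' is only valid as the second group of a pair")
    return labels == group


def select(
    table: pd.DataFrame,
    labels,
    criterion: str,
    pair: tuple[str, str],
) -> SelectionResult:
    """Rank features for one two-group comparison and keep the top k.

    ``pair`` is (class_a, class_b) or (class_a, "rest").  The subset size
    k follows the per-ten-samples rule applied to the pooled sample count
    of the comparison.  Fisher and MI rank by score (descending, ties by
    registry order); POE+ACC follows its greedy path.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    labels = np.asarray(labels)
    a, b = pair
    mask_a = _group_mask(labels, a)
    mask_b = ~mask_a if b == "rest" else _group_mask(labels, b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"comparison {pair}: each group needs >= 2 samples")
    keep = mask_a | mask_b
    sub = table.loc[keep]
    y = np.where(mask_a[keep], a, b)
    k = subset_size(int(keep.sum()))

    feature_cols = [c for c in sub.columns if c != "sample_id"]
    k = min(k, len(feature_cols))
    sub = sub[feature_cols]
    if criterion == "poe_acc":
        feats, scores = poe_acc_select(sub, y, k)
    else:
        scorer = fisher_score if criterion == "fisher" else mutual_information
        raw = np.array([scorer(sub[c].to_numpy(), y) for c in feature_cols])
        order = np.argsort(-raw, kind="stable")  # stable: ties by registry order
        feats = [feature_cols[j] for j in order[:k]]
        scores = [float(raw[j]) for j in order[:k]]
    return SelectionResult(
        criterion=criterion, k=k, features=tuple(feats), scores=tuple(scores), pair=(a, b)
    )
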