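"""LDA most-discriminating-feature projection, k-NN leave-one-out
classification, frozen-feature validation, and IHC subtype mapping.

The classifier reproduces the classical texture-analysis protocol: the
selected features are z-scored, projected onto the generalized
eigenvectors of the between-class vs within-class scatter ("most
discriminating features", MDF), and a held-out sample is assigned by
Euclidean k-nearest neighbors in MDF space.  Leave-one-out
cross-validation refits the z-scoring, the LDA, and the projection on the
n-1 training samples of every fold, so no information from the held-out
sample leaks into its own fold.

The number of retained MDFs is the number of eigenvalues individually
exceeding 97% of their sum (floor 1); for a two-group comparison the
between-class scatter has rank 1, so a single MDF is always retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .selection import CRITERIA, select, subset_size

__all__ = [
    "MDFProjection",
    "ComparisonReport",
    "map_receptors_to_subtype",
    "SUBTYPE_TO_RECEPTORS",
    "lda_fit",
    "knn_loocv",
    "frozen_evaluate",
    "comparison_matrix",
]

MDF_RETENTION = 0.97
_RIDGE = 1e-6

#: IHC surrogate definition of the molecular subtypes.  HR+ = ER or PR
#: positive (> 1% staining).
_SUBTYPE_RULE = {
    (True, False): "LuminalA",  # HR+/HER2-
    (True, True): "LuminalB",  # HR+/HER2+
    (False, True): "HER2E",  # HR-/HER2+
    (False, False): "TN",  # HR-/HER2-
}

#: A representative receptor triplet (er, pr, her2) per subtype, used when
#: synthesizing manifests; the forward map of each triplet returns the
#: subtype.
SUBTYPE_TO_RECEPTORS = {
    "LuminalA": ("pos", "pos", "neg"),
    "LuminalB": ("pos", "pos", "pos"),
    "HER2E": ("neg", "neg", "pos"),
    "TN": ("neg", "neg", "neg"),
}


def map_receptors_to_subtype(er: str, pr: str, her2: str) -> str:
    """Map an IHC receptor triplet to its surrogate molecular subtype.

    Any unknown status yields "unknown" (the sample is then excluded from
    receptor-derived groupings).
    """
    triplet = (er, pr, her2)
    if any(s not in ("pos", "neg") for s in triplet):
        return "unknown"
    hr_pos = er == "pos" or pr == "pos"
    return _SUBTYPE_RULE[(hr_pos, her2 == "pos")]


@dataclass(frozen=True)
class MDFProjection:
    """Generalized LDA eigensystem and the 97%-rule retention count."""

    eigenvalues: np.ndarray  # descending, clipped at 0
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    n_retained: int
    class_labels: tuple
    class_means: np.ndarray  # in projected space, (n_classes, n_retained)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.eigenvectors[:, : self.n_retained]


def lda_fit(X, y) -> MDFProjection:
    """Solve the between- vs within-class generalized scatter eigenproblem.

    ``X`` is assumed standardized by the caller (z-scored on the fitting
    set).  The within-class scatter receives a small ridge
    (1e-6 * trace/dim) when singular.  Eigenvalues are clipped at zero,
    sorted descending, and truncated at the rank bound n_classes - 1;
    retention follows the 97%-of-the-sum rule with floor 1.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("lda_fit needs >= 2 classes")
    n, d = X.shape
    grand = X.mean(axis=0)
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    if n < 2:
        raise ValueError("lda_fit needs >= 2 samples")
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)  # singleton classes contribute no within-scatter
        diff = (mu - grand)[:, None]
        Sb += len(Xc) * (diff @ diff.T)
        Sw += (Xc - mu).T @ (Xc - mu)
    Sb /= n
    Sw /= n
    try:
        np.linalg.cholesky(Sw)
    except np.linalg.LinAlgError:
        Sw = Sw + (_RIDGE * np.trace(Sw) / d + 1e-12) * np.eye(d)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = min(len(classes) - 1, d)
    evals, evecs = evals[:rank], evecs[:, :rank]
    total = evals.sum()
    if total > 0:
        n_retained = int((evals > MDF_RETENTION * total).sum())
    else:
        n_retained = 0
    n_retained = max(n_retained, 1)
    proj = MDFProjection(
        eigenvalues=evals,
        eigenvectors=evecs,
        n_retained=n_retained,
        class_labels=tuple(classes),
        class_means=np.zeros((len(classes), n_retained)),
    )
    means = np.vstack([proj.transform(X[y == c]).mean(axis=0) for c in classes])
    object.__setattr__(proj, "class_means", means)
    return proj


@dataclass(frozen=True)
class ComparisonReport:
    """Outcome of one pairwise LOOCV comparison."""

    pair: tuple[str, str]
    criterion: str | None
    k_features: int
    accuracy: float
    n_mdf: int
    n_samples: int
    misclassified_per_group: dict[str, int]
    fold_predictions: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "criterion": self.criterion,
            "k_features": self.k_features,
            "accuracy": self.accuracy,
            "n_mdf": self.n_mdf,
            "n_samples": self.n_samples,
            "misclassified_per_group": dict(self.misclassified_per_group),
            "fold_predictions": list(self.fold_predictions),
        }


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _knn_predict(train_proj, train_labels, test_point, k_neighbors: int):
    """k-NN vote; ties by nearest neighbor, then lower sample index."""
    d = np.linalg.norm(train_proj - test_point[None, :], axis=1)
    order = np.lexsort((np.arange(len(d)), d))  # distance, then index
    top = order[:k_neighbors]
    votes: dict = {}
    for idx in top:
        votes[train_labels[idx]] = votes.get(train_labels[idx], 0) + 1
    best = max(votes.values())
    tied = [c for c, v in votes.items() if v == best]
    if len(tied) == 1:
        return tied[0]
    for idx in top:  # nearest neighbor among the tied classes decides
        if train_labels[idx] in tied:
            return train_labels[idx]
    return tied[0]


def knn_loocv(
    features: pd.DataFrame,
    labels,
    feature_names,
    k_neighbors: int = 1,
    pair: tuple[str, str] = ("A", "B"),
    criterion: str | None = None,
) -> ComparisonReport:
    """Leave-one-out k-NN classification in per-fold MDF space.

    For each fold the z-scoring parameters, the LDA scatter eigensystem,
    and the MDF projection are fit on the n-1 training samples only; the
    held-out sample is standardized with the training parameters,
    projected, and classified by Euclidean k-NN against the training
    projections.
    """
    labels = np.asarray(labels)
    X = features[list(feature_names)].to_numpy(dtype=np.float64)
    n = len(labels)
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n={n}")
    preds = []
    n_mdfs = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        mu, sd = _zscore_fit(X[tr])
        Xtr = (X[tr] - mu) / sd
        proj = lda_fit(Xtr, labels[tr])
        n_mdfs.append(proj.n_retained)
        train_proj = proj.transform(Xtr)
        test_proj = proj.transform(((X[i] - mu) / sd)[None, :])[0]
        preds.append(_knn_predict(train_proj, labels[tr], test_proj, k_neighbors))
    preds = np.asarray(preds)
    correct = preds == labels
    mis = {
        str(c): int((~correct)[labels == c].sum()) for c in np.unique(labels)
    }
    return ComparisonReport(
        pair=pair,
        criterion=criterion,
        k_features=len(list(feature_names)),
        accuracy=float(correct.mean()),
        n_mdf=int(np.max(n_mdfs)),
        n_samples=n,
        misclassified_per_group=mis,
        fold_predictions=tuple(str(p) for p in preds),
    )


def frozen_evaluate(
    validation_table: pd.DataFrame,
    labels,
    featureset: dict,
    k_neighbors: int = 1,
    pair: tuple[str, str] | None = None,
) -> ComparisonReport:
    """Apply a previously frozen feature set to a new cohort (no re-selection)."""
    names = featureset["features"]
    missing = [f for f in names if f not in validation_table.columns]
    if missing:
        raise ValueError(f"validation table lacks frozen feature(s): {missing}")
    if pair is None:
        pair = tuple(featureset.get("pair", ("A", "B")))
    return knn_loocv(
        validation_table,
        labels,
        names,
        k_neighbors=k_neighbors,
        pair=pair,
        criterion=featureset.get("criterion"),
    )


def _restrict(table: pd.DataFrame, labels: np.ndarray, pair: tuple[str, str]):
    a, b = pair
    mask_a = labels == a
    mask_b = ~mask_a if b == "rest" else labels == b
    keep = mask_a | mask_b
    y = np.where(mask_a[keep], a, "rest" if b == "rest" else b)
    return table.loc[keep].reset_index(drop=True), y


def _format_cell(report: ComparisonReport) -> str:
    crit = {"fisher": "Fisher", "poe_acc": "POE", "mi": "MI"}.get(
        report.criterion, report.criterion
    )
    acc = report.accuracy * 100
    acc_s = f"{acc:.1f}".rstrip("0").rstrip(".")
    return f"{acc_s}% ({crit}; {report.k_features})"


def comparison_matrix(
    feature_table: pd.DataFrame,
    labels,
    criteria=CRITERIA,
    k_neighbors: int = 1,
    min_group: int = 2,
) -> dict:
    """Run every pairwise and class-vs-rest comparison for each criterion.

    Returns ``{"reports": {(a, b, criterion): ComparisonReport}, "cells":
    DataFrame, "misclassification": DataFrame}``.  For each comparison the
    cell keeps the best-accuracy criterion, formatted ``acc% (criterion;
    k)`` as in the published result tables; groups smaller than
    ``min_group`` yield ``NA(small)``.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 groups")
    pairs = [(a, b) for a, b in itertools.combinations(classes, 2)]
    if len(classes) > 2:
        pairs += [(c, "rest") for c in classes]
    reports: dict = {}
    groups = classes + (["rest"] if len(classes) > 2 else [])
    cells = pd.DataFrame("-", index=groups, columns=groups, dtype=object)
    mis_rows = []
    for a, b in pairs:
        size_a = int((labels == a).sum())
        size_b = int((labels != a).sum()) if b == "rest" else int((labels == b).sum())
        if min(size_a, size_b) < min_group:
            cells.loc[a, b] = cells.loc[b, a] = "NA(small)"
            continue
        best = None
        for crit in criteria:
            sel = select(feature_table, labels, crit, (a, b))
            sub, y = _restrict(feature_table, labels, (a, b))
            rep = knn_loocv(
                sub, y, sel.features, k_neighbors=k_neighbors, pair=(a, b), criterion=crit
            )
            reports[(a, b, crit)] = rep
            if best is None or rep.accuracy > best.accuracy:
                best = rep
            mis_rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "criterion": crit,
                    "n": rep.n_samples,
                    "misclassified": sum(rep.misclassified_per_group.values()),
                    "rate": 1.0 - rep.accuracy,
                }
            )
        cells.loc[a, b] = cells.loc[b, a] = _format_cell(best)
    return {
        "reports": reports,
        "cells": cells,
        "misclassification": pd.DataFrame(mis_rows),
    }
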