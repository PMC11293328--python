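"""Chained multilabel classification.

The multilabel task over the five phenotypes is decomposed into five binary
L2-regularized logistic regressions linked in a chain: the k-th classifier
sees the spectral features plus the labels of the k-1 phenotypes earlier in
the chain — the *true* labels when training, the predecessors' *predicted*
(thresholded) labels when predicting.  An un-chained variant fits five
independent one-vs-rest classifiers.  The chain order itself is a
hyperparameter; :func:`search_chain_order` scores every permutation by
cross-validated exact match ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .containers import PHENOTYPES
from . import metrics as _metrics

__all__ = [
    "ChainModel",
    "DEFAULT_ORDER",
    "fit_binary",
    "fit_chain",
    "predict_chain",
    "fit_independent",
    "predict_independent",
    "search_chain_order",
    "project_feasible",
]

#: Default chain order when the permutation search is skipped: the healthy
#: label, being fully determined by the other four, is classified last.
DEFAULT_ORDER: tuple[str, ...] = (
    "dyslipidemia", "hypertension", "prediabetes", "t2d", "healthy",
)


class DegenerateLabelError(ValueError):
    pass


def fit_binary(
    X: np.ndarray, y: np.ndarray, lam: float = 1.0
) -> LogisticRegression:
    """L2-penalized logistic regression (deterministic, convex).

    ``lam`` is the ridge penalty weight; the solver's inverse-regularization
    is C = 1/lam.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if y.all() or not y.any():
        raise DegenerateLabelError("both classes must be present")
    # fit on standardized features (training statistics) so the penalty
    # treats all wavenumbers alike, then fold the scaling back into the
    # coefficients: the returned model operates on raw features
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0.0] = 1.0
    model = LogisticRegression(
        C=1.0 / lam, solver="lbfgs", max_iter=5000, tol=1e-8
    )
    model.fit((X - mu) / sigma, y)
    model.coef_ = model.coef_ / sigma
    model.intercept_ = model.intercept_ - (model.coef_ @ mu)
    return model


@dataclass
class ChainModel:
    """Ordered sequence of binary classifiers with label-augmented features.

    ``order`` is a permutation of label names; the model for ``order[k]``
    consumes ``[X | labels of order[0..k-1]]``.  ``threshold`` binarizes
    probabilities (strictly greater than: a probability equal to the
    threshold is classified negative).  ``propagate_probabilities`` switches
    the prediction-time label features from hard 0/1 predictions (default)
    to raw predecessor probabilities.
    """

    order: tuple[str, ...]
    models: list[LogisticRegression]
    lam: float = 1.0
    threshold: float = 0.5
    labels: tuple[str, ...] = PHENOTYPES
    propagate_probabilities: bool = False

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(set(self.order)) or set(
            self.order
        ) != set(self.labels):
            raise ValueError(
                f"order must be a permutation of {self.labels}"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "order": list(self.order),
            "labels": list(self.labels),
            "lam": self.lam,
            "threshold": self.threshold,
            "propagate_probabilities": self.propagate_probabilities,
            "links": [
                {
                    "coef": m.coef_[0].tolist(),
                    "intercept": float(m.intercept_[0]),
                }
                for m in self.models
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ChainModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(
            source
        )
        payload = json.loads(text)
        models = []
        for link in payload["links"]:
            m = LogisticRegression()
            m.coef_ = np.asarray([link["coef"]], dtype=float)
            m.intercept_ = np.asarray([link["intercept"]], dtype=float)
            m.classes_ = np.array([False, True])
            models.append(m)
        return cls(
            order=tuple(payload["order"]),
            models=models,
            lam=payload["lam"],
            threshold=payload["threshold"],
            labels=tuple(payload["labels"]),
            propagate_probabilities=payload["propagate_probabilities"],
        )


def _label_columns(
    Y: np.ndarray, labels: Sequence[str], names: Sequence[str]
) -> np.ndarray:
    idx = [list(labels).index(n) for n in names]
    return np.asarray(Y, dtype=float)[:, idx]


def fit_chain(
    X: np.ndarray,
    Y: np.ndarray,
    order: Sequence[str] = DEFAULT_ORDER,
    lam: float = 1.0,
    labels: Sequence[str] = PHENOTYPES,
    threshold: float = 0.5,
    propagate_probabilities: bool = False,
) -> ChainModel:
    """Fit the chain: link k trains on [X | true labels of order[:k]].

    The first link sees the spectral features only.
    """
    order = tuple(order)
    labels = tuple(labels)
    if sorted(order) != sorted(set(order)) or set(order) != set(labels):
        raise ValueError(f"order must be a permutation of {labels}")
    Y = np.asarray(Y, dtype=bool)
    X = np.asarray(X, dtype=float)
    models = []
    for k, name in enumerate(order):
        aug = (
            X
            if k == 0
            else np.hstack([X, _label_columns(Y, labels, order[:k])])
        )
        y_k = Y[:, list(labels).index(name)]
        models.append(fit_binary(aug, y_k, lam))
    return ChainModel(
        order=order,
        models=models,
        lam=lam,
        threshold=threshold,
        labels=labels,
        propagate_probabilities=propagate_probabilities,
    )


def predict_chain(
    model: ChainModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential prediction along the chain.

    Returns ``(probabilities, predictions)`` with columns in ``model.labels``
    order.  Each link consumes its predecessors' predictions — hard
    thresholded labels by default — since true labels are hidden at test
    time.  Raw outputs are reported as-is, without feasibility projection.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_labels = len(model.labels)
    proba = np.zeros((n, n_labels))
    pred = np.zeros((n, n_labels), dtype=bool)
    passed = np.zeros((n, 0))
    for k, name in enumerate(model.order):
        aug = X if k == 0 else np.hstack([X, passed])
        m = model.models[k]
        if aug.shape[1] != m.coef_.shape[1]:
            raise ValueError(
                f"link {k} expects {m.coef_.shape[1]} features, got "
                f"{aug.shape[1]}"
            )
        p = 1.0 / (1.0 + np.exp(-(aug @ m.coef_[0] + m.intercept_[0])))
        # keep probabilities numerically inside the open unit interval
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        hard = p > model.threshold  # ties resolve negative
        col = model.labels.index(name)
        proba[:, col] = p
        pred[:, col] = hard
        feat = p if model.propagate_probabilities else hard.astype(float)
        passed = np.hstack([passed, feat[:, None]])
    return proba, pred


def project_feasible(proba: np.ndarray, pred: np.ndarray,
                     labels: Sequence[str] = PHENOTYPES) -> np.ndarray:
    """Optional post-hoc projection onto the feasible label set.

    Resolves prediabetes ∧ t2d in favor of the higher probability and forces
    healthy ⇔ all four condition labels negative.  Off by default in the
    pipeline; provided for consumers that require feasible outputs.
    """
    labels = list(labels)
    out = np.asarray(pred, dtype=bool).copy()
    i_pre, i_t2d = labels.index("prediabetes"), labels.index("t2d")
    i_h = labels.index("healthy")
    both = out[:, i_pre] & out[:, i_t2d]
    prefer_t2d = proba[:, i_t2d] >= proba[:, i_pre]
    out[both & prefer_t2d, i_pre] = False
    out[both & ~prefer_t2d, i_t2d] = False
    cond = [i for i in range(out.shape[1]) if i != i_h]
    out[:, i_h] = ~out[:, cond].any(axis=1)
    return out


def fit_independent(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float = 1.0,
    labels: Sequence[str] = PHENOTYPES,
) -> dict[str, LogisticRegression]:
    """Un-chained variant: one independent one-vs-rest model per label."""
    Y = np.asarray(Y, dtype=bool)
    return {
        name: fit_binary(X, Y[:, i], lam) for i, name in enumerate(labels)
    }


def predict_independent(
    models: dict[str, LogisticRegression],
    X: np.ndarray,
    threshold: float = 0.5,
    labels: Sequence[str] = PHENOTYPES,
) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    proba = np.column_stack(
        [models[name].predict_proba(X)[:, 1] for name in labels]
    )
    return proba, proba > threshold


def search_chain_order(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float = 1.0,
    k_folds: int = 10,
    objective: Callable[[np.ndarray, np.ndarray], float] | None = None,
    seed: int = 0,
    labels: Sequence[str] = PHENOTYPES,
) -> tuple[tuple[str, ...], list[dict]]:
    """Exhaustive permutation search over chain orders.

    Every one of the k! orders of ``labels`` is scored by k-fold
    cross-validated objective (exact match ratio by default) on the supplied
    set.  Returns the argmax order — ties broken toward the lexicographically
    smallest order — and the full score table (one row per permutation).
    """
    from sklearn.model_selection import KFold

    objective = objective or _metrics.exact_match_ratio
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=bool)
    if X.shape[0] < k_folds:
        raise ValueError("need at least k_folds samples")
    splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X))
    table = []
    for order in sorted(permutations(labels)):
        fold_scores = []
        for tr, te in splits:
            model = fit_chain(X[tr], Y[tr], order=order, lam=lam,
                              labels=labels)
            _, pred = predict_chain(model, X[te])
            fold_scores.append(objective(Y[te], pred))
        table.append({
            "order": order,
            "mean_score": float(np.mean(fold_scores)),
            "sd_score": float(np.std(fold_scores, ddof=1)),
        })
    # table is in lexicographic order and max() keeps the first row among
    # equals, so ties break toward the lexicographically smallest order
    best = max(table, key=lambda r: r["mean_score"])
    return tuple(best["order"]), table
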