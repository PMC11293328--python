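"""Multilabel evaluation metrics and the stochastic chance benchmark.

Three metrics score a predicted binary label matrix against the truth:

* exact match ratio  — fraction of samples whose whole 5-vector is correct;
* Hamming score      — per-sample Jaccard similarity of the positive-label
                       sets, |y ∩ ŷ| / |y ∪ ŷ|, averaged over samples;
* 1 − Hamming loss   — one minus the fraction of discordant label cells.

The chance benchmark draws two independent samples of label vectors from the
empirical distribution over observed (clinically feasible) label
combinations, pairs them, and scores the pair with the same three metrics —
the performance of a predictor that knows the label distribution but nothing
about any individual sample.  Analytic expectations accompany the draws:
E[EMR] = sum_k p_k^2 over combination probabilities p_k, and
E[1 − HL] = 1 − (1/L) sum_j 2 q_j (1 − q_j) over label marginals q_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import PhenotypeMatrix, validate_label_row

__all__ = [
    "MultilabelScore",
    "ChanceBenchmark",
    "exact_match_ratio",
    "hamming_score",
    "one_minus_hamming_loss",
    "score_multilabel",
    "roc_auc",
    "chance_benchmark",
]


class UndefinedAUCError(ValueError):
    pass


@dataclass
class MultilabelScore:
    exact_match_ratio: float
    hamming_score: float
    one_minus_hamming_loss: float
    n_samples: int
    n_labels: int

    def as_dict(self) -> dict:
        return {
            "exact_match_ratio": self.exact_match_ratio,
            "hamming_score": self.hamming_score,
            "one_minus_hamming_loss": self.one_minus_hamming_loss,
            "n_samples": self.n_samples,
            "n_labels": self.n_labels,
        }


def _check(Y: np.ndarray, Yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=bool)
    Yhat = np.asarray(Yhat, dtype=bool)
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("label matrices must be nonempty and 2-D")
    return Y, Yhat


def exact_match_ratio(Y, Yhat) -> float:
    """(1/n) sum_i I(y_i == yhat_i) over whole label vectors."""
    Y, Yhat = _check(Y, Yhat)
    return float(np.mean(np.all(Y == Yhat, axis=1)))


def hamming_score(Y, Yhat) -> float:
    """Mean per-sample Jaccard similarity of positive-label sets.

    A row where both truth and prediction are all-negative contributes 1
    (with a warning): there is nothing to get wrong.  This cannot occur for
    feasible phenotype vectors, which always contain a positive entry.
    """
    Y, Yhat = _check(Y, Yhat)
    inter = (Y & Yhat).sum(axis=1).astype(float)
    union = (Y | Yhat).sum(axis=1).astype(float)
    empty = union == 0
    if np.any(empty):
        warnings.warn(
            "rows with empty truth and prediction sets score 1 by convention"
        )
        inter[empty] = 1.0
        union[empty] = 1.0
    return float(np.mean(inter / union))


def one_minus_hamming_loss(Y, Yhat) -> float:
    """1 - fraction of discordant cells over all samples and labels."""
    Y, Yhat = _check(Y, Yhat)
    return float(1.0 - np.mean(Y != Yhat))


def score_multilabel(Y, Yhat) -> MultilabelScore:
    Y, Yhat = _check(Y, Yhat)
    return MultilabelScore(
        exact_match_ratio=exact_match_ratio(Y, Yhat),
        hamming_score=hamming_score(Y, Yhat),
        one_minus_hamming_loss=one_minus_hamming_loss(Y, Yhat),
        n_samples=Y.shape[0],
        n_labels=Y.shape[1],
    )


def roc_auc(y, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over grouped score thresholds) and trapezoid AUC.

    The trapezoid rule over tie-grouped thresholds equals the tie-corrected
    Mann-Whitney U probability estimator
    P(s+ > s-) + 0.5 P(s+ = s-).
    """
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape or y.ndim != 1:
        raise ValueError("y and scores must be equal-length vectors")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined with a single class")
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class ChanceBenchmark:
    n_draws: int
    seed: int
    sampled: MultilabelScore
    expected_exact_match_ratio: float
    expected_one_minus_hamming_loss: float
    se_exact_match_ratio: float
    se_one_minus_hamming_loss: float


def chance_benchmark(
    Y_population: PhenotypeMatrix | np.ndarray,
    n_draws: int = 100_000,
    seed: int = 0,
) -> ChanceBenchmark:
    """Stochastic chance benchmark over the empirical label distribution.

    Two independent samples of ``n_draws`` label vectors are drawn from the
    distribution of observed label combinations and scored against each
    other, estimating each metric's value for an uninformed predictor.
    Standard errors are those of the Monte-Carlo means of the per-sample
    scores.
    """
    if isinstance(Y_population, PhenotypeMatrix):
        Y = Y_population.known().values
    else:
        Y = np.asarray(Y_population, dtype=bool)
        for i, row in enumerate(Y):
            validate_label_row(row)  # raises on infeasible input rows
    if Y.shape[0] == 0:
        raise ValueError("population label matrix is empty")

    combos, counts = np.unique(Y, axis=0, return_counts=True)
    p = counts / counts.sum()
    rng = np.random.default_rng(seed)
    draw_a = combos[rng.choice(p.size, size=n_draws, p=p)]
    draw_b = combos[rng.choice(p.size, size=n_draws, p=p)]
    sampled = score_multilabel(draw_a, draw_b)

    q = (combos * p[:, None]).sum(axis=0)  # label marginals
    expected_emr = float(np.sum(p**2))
    n_labels = Y.shape[1]
    expected_omhl = float(1.0 - np.mean(2.0 * q * (1.0 - q)))

    # MC standard errors of the sampled means
    se_emr = float(np.sqrt(expected_emr * (1 - expected_emr) / n_draws))
    percell = 2.0 * q * (1.0 - q)
    per_sample_var = float(
        np.var(1.0 - np.mean((draw_a != draw_b), axis=1), ddof=1)
    )
    se_omhl = float(np.sqrt(per_sample_var / n_draws))
    if se_omhl == 0.0:  # degenerate population
        se_omhl = float(
            np.sqrt(np.sum(percell * (1 - percell)) / (n_labels**2 * n_draws))
        )
    return ChanceBenchmark(
        n_draws=n_draws,
        seed=seed,
        sampled=sampled,
        expected_exact_match_ratio=expected_emr,
        expected_one_minus_hamming_loss=expected_omhl,
        se_exact_match_ratio=se_emr,
        se_one_minus_hamming_loss=se_omhl,
    )
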