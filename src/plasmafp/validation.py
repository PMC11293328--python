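"""Validation regimes, leakage-safe fold plans, and matched cohorts.

Three regimes are supported, mirroring a two-visit study design:

* ``cv_set1`` / ``cv_set2`` — 10-fold cross-validation within one sample set
  (stratified by label combination where group sizes allow);
* ``set_independent`` — train on visit-1 samples, test on visit-2 samples of
  held-out individuals: the individuals who attended both visits are
  partitioned into k disjoint groups, and iteration i trains on all set-1
  samples excluding group-i individuals and tests on group i's set-2
  samples.  No individual ever appears on both sides of a fold.

Experiments run a model spec over a plan and aggregate test-fold metrics.
Pair matching builds case-control cohorts balanced on sex, age and BMI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chain as _chain
from . import metrics as _metrics
from .containers import PHENOTYPES, PhenotypeMatrix, SpectraMatrix

__all__ = [
    "FoldPlan",
    "ModelSpec",
    "MatchedCohort",
    "make_cv_folds",
    "make_independent_plan",
    "run_multilabel_experiment",
    "run_binary_experiment",
    "pair_match",
    "audit_leakage",
]


@dataclass
class FoldPlan:
    regime: str  # cv_set1 | cv_set2 | set_independent
    folds: list[tuple[list, list]]  # (train sample_ids, test sample_ids)
    k: int
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "regime": self.regime,
            "k": self.k,
            "seed": self.seed,
            "folds": [
                {"train": list(tr), "test": list(te)}
                for tr, te in self.folds
            ],
        })
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FoldPlan":
        p = Path(str(source))
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            regime=payload["regime"],
            folds=[(f["train"], f["test"]) for f in payload["folds"]],
            k=payload["k"],
            seed=payload["seed"],
        )


def audit_leakage(plan: FoldPlan, individual_of: Mapping) -> None:
    """Assert that no individual contributes to both sides of any fold."""
    for i, (train, test) in enumerate(plan.folds):
        tr = {individual_of[s] for s in train}
        te = {individual_of[s] for s in test}
        shared = tr & te
        if shared:
            raise AssertionError(
                f"fold {i} of {plan.regime} shares individuals: "
                f"{sorted(shared)[:5]}"
            )


def make_cv_folds(
    sample_ids: Sequence,
    k: int = 10,
    seed: int = 0,
    labels: PhenotypeMatrix | None = None,
) -> FoldPlan:
    """k-fold CV plan on one sample set.

    Test folds partition the set with sizes differing by at most one.  When
    a label matrix is given, folds are stratified by label combination;
    combinations with fewer than k members are pooled and spread
    unstratified.
    """
    ids = list(sample_ids)
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)

    if labels is not None:
        lab = labels.subset(ids)
        keys = [
            "?" if lab.unknown[i] else "".join(
                "1" if v else "0" for v in lab.values[i]
            )
            for i in range(n)
        ]
        counts: dict[str, int] = {}
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        strata = [key if counts[key] >= k else "__rare__" for key in keys]
    else:
        strata = ["__all__"] * n

    # shuffle within stratum, concatenate strata, deal fold ids cyclically:
    # near-stratified and globally balanced to within one sample
    order: list[int] = []
    for stratum in sorted(set(strata)):
        members = [i for i in range(n) if strata[i] == stratum]
        rng.shuffle(members)
        order.extend(members)
    fold_of = np.empty(n, dtype=int)
    for pos, i in enumerate(order):
        fold_of[i] = pos % k

    folds = []
    for f in range(k):
        test = [ids[i] for i in range(n) if fold_of[i] == f]
        train = [ids[i] for i in range(n) if fold_of[i] != f]
        folds.append((train, test))
    return FoldPlan(regime="cv", folds=folds, k=k, seed=seed)


def make_independent_plan(
    set1: pd.DataFrame,
    set2: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Sample-set-independent plan from two (sample_id, individual_id) tables.

    The overlap individuals are partitioned into k disjoint near-equal
    groups (each about 1/k of the overlap pool); iteration i tests on the
    set-2 samples of group i and trains on every set-1 sample whose
    individual is not in group i.
    """
    ind1 = set(set1["individual_id"])
    overlap = sorted(set(set2["individual_id"]) & ind1)
    if not overlap:
        raise ValueError("no overlapping individuals between the sets")
    rng = np.random.default_rng(seed)
    overlap = list(overlap)
    rng.shuffle(overlap)
    groups = np.array_split(np.asarray(overlap, dtype=object), k)

    s1_by_ind = set1.groupby("individual_id")["sample_id"].apply(list)
    s2_by_ind = set2.groupby("individual_id")["sample_id"].apply(list)
    folds = []
    for group in groups:
        held = set(group.tolist())
        test = [s for ind in sorted(held) for s in s2_by_ind.get(ind, [])]
        train = [
            s
            for ind, samples in s1_by_ind.items()
            if ind not in held
            for s in samples
        ]
        folds.append((train, test))
    return FoldPlan(regime="set_independent", folds=folds, k=k, seed=seed)


@dataclass
class ModelSpec:
    """What to fit on each training fold."""

    kind: str = "chain"  # chain | independent
    order: tuple[str, ...] = _chain.DEFAULT_ORDER
    lam: float = 1.0
    threshold: float = 0.5
    propagate_probabilities: bool = False
    labels: tuple[str, ...] = PHENOTYPES


def _feature_rows(X, sample_ids: Sequence) -> np.ndarray:
    """Row-select features for fold ids; spectra matrix or analyte table."""
    if isinstance(X, SpectraMatrix):
        return X.subset(sample_ids).absorbance
    if isinstance(X, pd.DataFrame):
        sub = X.set_index("sample_id").loc[list(sample_ids)]
        return sub.to_numpy(dtype=float)
    raise TypeError("features must be a SpectraMatrix or a sample_id-keyed "
                    "DataFrame")


def _known_ids(ids: Sequence, labels: PhenotypeMatrix) -> list:
    sub = labels.subset(ids)
    return [s for s, unk in zip(ids, sub.unknown) if not unk]


def run_multilabel_experiment(
    X,
    Y: PhenotypeMatrix,
    plan: FoldPlan,
    spec: ModelSpec | None = None,
) -> dict:
    """Fit per fold, score the three multilabel metrics on test rows only.

    Samples with unknown labels are excluded fold-wise.  Returns per-fold
    scores plus mean and SD of each metric across folds.
    """
    spec = spec or ModelSpec()
    fold_scores: list[_metrics.MultilabelScore] = []
    for train, test in plan.folds:
        train = _known_ids(train, Y)
        test = _known_ids(test, Y)
        Xtr, Xte = _feature_rows(X, train), _feature_rows(X, test)
        Ytr = Y.subset(train).values
        Yte = Y.subset(test).values
        if spec.kind == "chain":
            model = _chain.fit_chain(
                Xtr, Ytr, order=spec.order, lam=spec.lam,
                labels=spec.labels, threshold=spec.threshold,
                propagate_probabilities=spec.propagate_probabilities,
            )
            _, pred = _chain.predict_chain(model, Xte)
        elif spec.kind == "independent":
            models = _chain.fit_independent(
                Xtr, Ytr, lam=spec.lam, labels=spec.labels
            )
            _, pred = _chain.predict_independent(
                models, Xte, threshold=spec.threshold, labels=spec.labels
            )
        else:
            raise ValueError(f"unknown model kind {spec.kind!r}")
        fold_scores.append(_metrics.score_multilabel(Yte, pred))

    def _agg(name):
        vals = [getattr(s, name) for s in fold_scores]
        return {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }

    return {
        "regime": plan.regime,
        "folds": [s.as_dict() for s in fold_scores],
        "exact_match_ratio": _agg("exact_match_ratio"),
        "hamming_score": _agg("hamming_score"),
        "one_minus_hamming_loss": _agg("one_minus_hamming_loss"),
    }


def run_binary_experiment(
    X,
    y: pd.Series,
    plan: FoldPlan,
    lam: float = 1.0,
) -> dict:
    """Per-fold binary logistic experiment with ROC/AUC on the test rows.

    ``y`` is a sample_id-indexed boolean Series; fold samples missing from
    it (e.g. excluded records) are dropped fold-wise.
    """
    aucs = []
    curves = []
    for train, test in plan.folds:
        train = [s for s in train if s in y.index and not pd.isna(y[s])]
        test = [s for s in test if s in y.index and not pd.isna(y[s])]
        Xtr, Xte = _feature_rows(X, train), _feature_rows(X, test)
        ytr = y.loc[train].to_numpy(dtype=bool)
        yte = y.loc[test].to_numpy(dtype=bool)
        model = _chain.fit_binary(Xtr, ytr, lam)
        scores = model.predict_proba(Xte)[:, 1]
        fpr, tpr, auc = _metrics.roc_auc(yte, scores)
        aucs.append(auc)
        curves.append({"fpr": fpr.tolist(), "tpr": tpr.tolist()})
    return {
        "regime": plan.regime,
        "fold_auc": [float(a) for a in aucs],
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "curves": curves,
    }


@dataclass
class MatchedCohort:
    pairs: list[tuple[object, object]]  # (case sample_id, control sample_id)
    covariates: tuple[str, ...]
    distances: list[float]
    unmatched_cases: list = field(default_factory=list)


def pair_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "bmi"),
    caliper: float | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Sex is matched exactly; the remaining covariates are standardized over
    the pooled cases+controls and compared by Euclidean distance.  Cases
    with the fewest sex-compatible controls are processed first.  Cases
    without an available compatible control (or none within the caliper)
    are reported unmatched; an error is raised only if no pair forms.
    """
    if controls.empty:
        raise ValueError("controls table is empty")
    pooled = pd.concat([cases, controls], ignore_index=True)
    mu = pooled[list(covariates)].mean()
    sd = pooled[list(covariates)].std(ddof=1).replace(0.0, 1.0)

    def _z(df):
        return ((df[list(covariates)] - mu) / sd).to_numpy(dtype=float)

    case_z = _z(cases)
    ctrl_z = _z(controls)
    ctrl_sex = controls["sex"].to_numpy()
    ctrl_ids = controls["sample_id"].to_numpy(dtype=object)
    available = np.ones(len(controls), dtype=bool)

    # scarcity: fewest compatible controls first
    n_compat = cases["sex"].map(
        controls["sex"].value_counts()
    ).fillna(0).to_numpy()
    case_order = np.argsort(n_compat, kind="stable")

    pairs, distances, unmatched = [], [], []
    for ci in case_order:
        sex = cases["sex"].iloc[ci]
        mask = available & (ctrl_sex == sex)
        if not mask.any():
            unmatched.append(cases["sample_id"].iloc[ci])
            continue
        d = np.linalg.norm(ctrl_z[mask] - case_z[ci], axis=1)
        j_local = int(np.argmin(d))
        if caliper is not None and d[j_local] > caliper:
            unmatched.append(cases["sample_id"].iloc[ci])
            continue
        j = np.flatnonzero(mask)[j_local]
        available[j] = False
        pairs.append((cases["sample_id"].iloc[ci], ctrl_ids[j]))
        distances.append(float(d[j_local]))
    if not pairs:
        raise ValueError("no case could be matched to any control")
    return MatchedCohort(
        pairs=pairs,
        covariates=("sex",) + tuple(covariates),
        distances=distances,
        unmatched_cases=unmatched,
    )
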