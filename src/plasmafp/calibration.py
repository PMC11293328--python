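"""Chemometric calibration of clinical analytes from IR fingerprints.

Ridge regression maps the preprocessed absorbance matrix to analyte
concentrations (or analyte ratios, or anthropometric targets), evaluated by
10-fold cross-validated out-of-sample R^2 and RMSE.  Per-wavenumber Pearson
correlation maps give the univariate counterpart: which spectral positions
individually track a given analyte.

R^2 here is the out-of-sample coefficient of determination,
1 - SSE/SST with SST about the test-fold mean, so a model no better than
the fold mean scores <= 0.  Features are standardized with statistics from
the training fold only; the ridge penalty applies to slopes, never to the
intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import validation as _validation
from .containers import SpectraMatrix

__all__ = [
    "CalibrationResult",
    "CorrelationMap",
    "fit_ridge",
    "quantify_analyte",
    "quantify_ratio",
    "wavenumber_correlation",
    "anthropometric_models",
]


class UndefinedR2Error(ValueError):
    pass


@dataclass
class CalibrationResult:
    target: str
    fold_r2: list[float]
    fold_rmse: list[float]
    r2_mean: float
    r2_sd: float
    rmse_mean: float
    rmse_sd: float
    predictions: pd.DataFrame  # sample_id, true, predicted (test folds)

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
        }


@dataclass
class CorrelationMap:
    target: str
    grid: np.ndarray
    r: np.ndarray            # NaN where undefined
    undefined: np.ndarray    # zero-variance columns flagged


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float = 1.0) -> Ridge:
    """Penalized least squares with an unpenalized intercept.

    Note the penalty weights squared error summed over rows, so duplicating
    every row while doubling ``lam`` leaves the fit unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    model = Ridge(alpha=lam, solver="cholesky")
    model.fit(X, y)
    return model


def _cv_regression(
    ids: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    target: str,
    k: int = 10,
    lam: float = 1.0,
    seed: int = 0,
) -> CalibrationResult:
    from sklearn.model_selection import KFold

    if np.all(y == y[0]):
        raise UndefinedR2Error(f"target {target!r} is constant")
    fold_r2, fold_rmse, preds = [], [], []
    for tr, te in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("ridge", Ridge(alpha=lam, solver="cholesky")),
        ])
        pipe.fit(X[tr], y[tr])
        yhat = pipe.predict(X[te])
        resid = y[te] - yhat
        sst = float(np.sum((y[te] - y[te].mean()) ** 2))
        if sst == 0.0:
            raise UndefinedR2Error(
                f"target {target!r} constant within a test fold"
            )
        fold_r2.append(1.0 - float(np.sum(resid**2)) / sst)
        fold_rmse.append(float(np.sqrt(np.mean(resid**2))))
        preds.append(pd.DataFrame({
            "sample_id": ids[te], "true": y[te], "predicted": yhat,
        }))
    return CalibrationResult(
        target=target,
        fold_r2=fold_r2,
        fold_rmse=fold_rmse,
        r2_mean=float(np.mean(fold_r2)),
        r2_sd=float(np.std(fold_r2, ddof=1)),
        rmse_mean=float(np.mean(fold_rmse)),
        rmse_sd=float(np.std(fold_rmse, ddof=1)),
        predictions=pd.concat(preds, ignore_index=True),
    )


def _aligned(X: SpectraMatrix, conc: pd.Series):
    """Drop samples with missing target; return ids, features, target."""
    conc = conc.dropna()
    ids = [s for s in X.sample_ids if s in conc.index]
    sub = X.subset(ids)
    return np.asarray(ids, dtype=object), sub.absorbance, conc.loc[
        ids
    ].to_numpy(dtype=float)


def quantify_analyte(
    X: SpectraMatrix,
    conc: pd.Series,
    target: str = "analyte",
    k: int = 10,
    lam: float = 1.0,
    seed: int = 0,
) -> CalibrationResult:
    """Cross-validated ridge calibration of one analyte from spectra.

    ``conc`` is a sample_id-indexed Series; spectra from both sample sets
    are typically pooled before calling.
    """
    ids, Xa, y = _aligned(X, conc)
    if ids.size < k:
        raise ValueError(f"only {ids.size} samples with known {target!r}")
    return _cv_regression(ids, Xa, y, target, k=k, lam=lam, seed=seed)


def quantify_ratio(
    X: SpectraMatrix,
    numerator: pd.Series,
    denominator: pd.Series,
    target: str = "ratio",
    k: int = 10,
    lam: float = 1.0,
    seed: int = 0,
) -> CalibrationResult:
    """Calibration of an analyte ratio (e.g. TG/HDL) from spectra."""
    common = numerator.dropna().index.intersection(denominator.dropna().index)
    den = denominator.loc[common]
    if (den <= 0).any():
        raise ValueError("denominator must be strictly positive")
    ratio = numerator.loc[common] / den
    return quantify_analyte(X, ratio, target=target, k=k, lam=lam, seed=seed)


def wavenumber_correlation(
    X: SpectraMatrix, conc: pd.Series, target: str = "analyte"
) -> CorrelationMap:
    """Pearson r between the target and absorbance at each wavenumber."""
    ids, Xa, y = _aligned(X, conc)
    if ids.size < 3:
        raise ValueError("need at least 3 samples")
    if np.all(y == y[0]):
        raise UndefinedR2Error(f"target {target!r} is constant")
    Xc = Xa - Xa.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    sy = float(np.sqrt(np.sum(yc**2)))
    undefined = sx == 0.0
    r = np.full(Xa.shape[1], np.nan)
    ok = ~undefined
    r[ok] = (Xc[:, ok].T @ yc) / (sx[ok] * sy)
    return CorrelationMap(target=target, grid=X.grid, r=r, undefined=undefined)


def anthropometric_models(
    X: SpectraMatrix,
    records: pd.DataFrame,
    subset: str = "all",
    labels=None,
    k: int = 10,
    lam: float = 1.0,
    seed: int = 0,
) -> dict:
    """Sex (logistic, AUC), age and BMI (ridge, R^2/RMSE) from spectra.

    ``subset='healthy_only'`` restricts to samples whose phenotype vector is
    healthy (requires ``labels``), probing anthropometric signal free of any
    condition's contribution.
    """
    rec = records.set_index("sample_id")
    ids = [s for s in X.sample_ids if s in rec.index]
    if subset == "healthy_only":
        if labels is None:
            raise ValueError("healthy_only subset requires labels")
        lab = labels.subset(ids)
        healthy_col = list(lab.values[:, -1])
        ids = [
            s for s, h, unk in zip(ids, healthy_col, lab.unknown)
            if h and not unk
        ]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'healthy_only'")
    if not ids:
        raise ValueError("subset is empty")
    sub = X.subset(ids)
    rec = rec.loc[ids]

    male = (rec["sex"] == "male").to_numpy()
    if male.all() or not male.any():
        raise ValueError("single-sex subset; sex model undefined")
    plan = _validation.make_cv_folds(ids, k=k, seed=seed)
    sex_result = _validation.run_binary_experiment(
        sub, pd.Series(male, index=ids), plan, lam=lam
    )

    out = {"subset": subset, "n_samples": len(ids), "sex": sex_result}
    for name in ("age", "bmi"):
        out[name] = _cv_regression(
            np.asarray(ids, dtype=object),
            sub.absorbance,
            rec[name].to_numpy(dtype=float),
            name,
            k=k,
            lam=lam,
            seed=seed,
        )
    return out
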