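"""Metabolic-syndrome risk-factor scoring, cohorts, and incident forecasting.

MetS follows the harmonized IDF / AHA-NHLBI definition: it is present when
at least three of five risk factors hold —

1. waist circumference >= 94 cm (males) / >= 80 cm (females);
2. SBP >= 130 mmHg or DBP >= 85 mmHg, or antihypertensive treatment;
3. fasting glucose >= 100 mg/dL, or antidiabetic medication;
4. HDL cholesterol < 40 mg/dL (males) / < 50 mg/dL (females), or fibrates;
5. triglycerides >= 150 mg/dL, or fibrates.

One or two factors qualify as pre-MetS.  The clinical table stores HDL in
mmol/L and triglycerides in mg/dL; criteria 4-5 are evaluated in mg/dL via
the conversion helpers below.

The forecasting experiment trains exclusively on baseline (visit 1)
spectra of individuals MetS-negative at baseline, with outcomes read from
the follow-up visit: cases developed MetS by follow-up, controls did not.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from . import validation as _validation
from .containers import SpectraMatrix

__all__ = [
    "RiskFactorProfile",
    "ForecastCohort",
    "CHOLESTEROL_MG_PER_MMOL",
    "TRIGLYCERIDES_MG_PER_MMOL",
    "mmol_to_mgdl_cholesterol",
    "count_risk_factors",
    "risk_factor_table",
    "mets_status",
    "k_vs_zero_cohorts",
    "incident_mets_cohort",
    "forecast_experiment",
]

#: molar mass conversions for serum lipids (mg/dL per mmol/L)
CHOLESTEROL_MG_PER_MMOL = 38.67
TRIGLYCERIDES_MG_PER_MMOL = 88.57

RISK_FACTORS = ("waist", "bp", "glucose", "hdl", "tg")


def mmol_to_mgdl_cholesterol(x):
    return x * CHOLESTEROL_MG_PER_MMOL


@dataclass
class RiskFactorProfile:
    sample_id: object
    waist: bool
    bp: bool
    glucose: bool
    hdl: bool
    tg: bool
    any_missing: bool

    @property
    def count(self) -> int:
        if self.any_missing:
            raise ValueError("count undefined when any factor is missing")
        return int(self.waist) + int(self.bp) + int(self.glucose) + int(
            self.hdl
        ) + int(self.tg)


def risk_factor_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized risk-factor scoring for a clinical table.

    Returns a frame indexed like ``records`` with one boolean column per
    factor, the factor ``count`` (NA when any factor is missing) and the
    ``any_missing`` flag.  Medication flags are treated as always observed.
    """
    male = records["sex"] == "male"
    waist_cut = np.where(male, 94.0, 80.0)
    hdl_cut_mgdl = np.where(male, 40.0, 50.0)
    hdl_mgdl = records["hdl"] * CHOLESTEROL_MG_PER_MMOL
    fib = records["med_fibrates"].fillna(False).astype(bool)

    factors = pd.DataFrame(index=records.index)
    factors["waist"] = records["waist"] >= waist_cut
    factors["bp"] = (
        (records["sbp"] >= 130.0)
        | (records["dbp"] >= 85.0)
        | records["med_antihypertensive"].fillna(False).astype(bool)
    )
    factors["glucose"] = (
        (records["fasting_glucose"] >= 100.0)
        | records["med_antidiabetic"].fillna(False).astype(bool)
    )
    factors["hdl"] = (hdl_mgdl < hdl_cut_mgdl) | fib
    factors["tg"] = (records["triglycerides"] >= 150.0) | fib

    missing = (
        records["waist"].isna()
        | records[["sbp", "dbp"]].isna().any(axis=1)
        | records["fasting_glucose"].isna()
        | records["hdl"].isna()
        | records["triglycerides"].isna()
    )
    # medication overrides can decide a factor even when its lab value is
    # missing, but the harmonized count requires all five factors known
    out = factors.astype(bool)
    out["any_missing"] = missing
    count = out[list(RISK_FACTORS)].sum(axis=1).astype("Int64")
    count[missing] = pd.NA
    out["count"] = count
    out["sample_id"] = records["sample_id"].to_numpy()
    return out


def count_risk_factors(record: pd.Series | dict) -> RiskFactorProfile:
    """Score one clinical record against the five harmonized criteria."""
    row = pd.DataFrame([dict(record)])
    table = risk_factor_table(row).iloc[0]
    return RiskFactorProfile(
        sample_id=table["sample_id"],
        waist=bool(table["waist"]),
        bp=bool(table["bp"]),
        glucose=bool(table["glucose"]),
        hdl=bool(table["hdl"]),
        tg=bool(table["tg"]),
        any_missing=bool(table["any_missing"]),
    )


def mets_status(profile: RiskFactorProfile | pd.Series) -> bool:
    """MetS present iff at least three of the five factors hold."""
    if isinstance(profile, RiskFactorProfile):
        return profile.count >= 3
    if bool(profile["any_missing"]):
        raise ValueError("MetS status undefined with missing factors")
    return int(profile["count"]) >= 3


def k_vs_zero_cohorts(profiles: pd.DataFrame) -> dict[int, dict]:
    """Cohort pairs: cases with exactly k risk factors vs zero-factor controls.

    ``profiles`` is the output of :func:`risk_factor_table`.  Samples with
    missing factors appear in no cohort; empty strata are skipped with a
    warning.
    """
    known = profiles[~profiles["any_missing"]]
    controls = known.loc[known["count"] == 0, "sample_id"].tolist()
    if not controls:
        raise ValueError("no zero-risk-factor controls available")
    cohorts = {}
    for k in range(1, 6):
        cases = known.loc[known["count"] == k, "sample_id"].tolist()
        if not cases:
            warnings.warn(f"no samples with exactly {k} risk factors; "
                          "stratum skipped")
            continue
        cohorts[k] = {"cases": cases, "controls": list(controls)}
    return cohorts


@dataclass
class ForecastCohort:
    cases: list        # baseline sample_ids: MetS-free then converted
    controls: list     # baseline sample_ids: MetS-free at both visits
    n_baseline_negative: int

    def outcomes(self) -> pd.Series:
        ids = list(self.cases) + list(self.controls)
        return pd.Series(
            [True] * len(self.cases) + [False] * len(self.controls),
            index=ids,
        )


def incident_mets_cohort(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
) -> ForecastCohort:
    """Build the incident-MetS cohort from per-visit risk-factor tables.

    Both inputs come from :func:`risk_factor_table` and must carry an
    ``individual_id`` column.  Only individuals with known factor counts at
    both visits enter; cases are MetS-negative at baseline and positive at
    follow-up, controls negative at both.  |cases| + |controls| equals the
    number of baseline-negative individuals with a usable follow-up.
    """
    for name, df in (("baseline", baseline), ("followup", followup)):
        if "individual_id" not in df.columns:
            raise ValueError(f"{name} table needs an individual_id column")
    b = baseline[~baseline["any_missing"]].set_index("individual_id")
    f = followup[~followup["any_missing"]].set_index("individual_id")
    linked = b.index.intersection(f.index)
    if linked.empty:
        raise ValueError("no individuals with both visits")
    b, f = b.loc[linked], f.loc[linked]
    base_neg = b["count"].astype(int) < 3
    fu_pos = f["count"].astype(int) >= 3
    cases = b.loc[base_neg & fu_pos, "sample_id"].tolist()
    controls = b.loc[base_neg & ~fu_pos, "sample_id"].tolist()
    return ForecastCohort(
        cases=cases,
        controls=controls,
        n_baseline_negative=int(base_neg.sum()),
    )


def forecast_experiment(
    cohort: ForecastCohort,
    baseline_spectra: SpectraMatrix,
    k: int = 10,
    lam: float = 1.0,
    seed: int = 0,
) -> dict:
    """10-fold CV forecast of incident MetS from baseline fingerprints.

    Features are baseline spectra exclusively; follow-up data enter only
    through the binary outcome.
    """
    if not cohort.cases or not cohort.controls:
        raise ValueError("both cohort arms must be nonempty")
    ids = list(cohort.cases) + list(cohort.controls)
    baseline_ids = set(baseline_spectra.sample_ids.tolist())
    missing = [s for s in ids if s not in baseline_ids]
    if missing:
        raise ValueError(
            f"{len(missing)} cohort samples lack baseline spectra"
        )
    plan = _validation.make_cv_folds(ids, k=k, seed=seed)
    plan.regime = "forecast_cv_baseline"
    return _validation.run_binary_experiment(
        baseline_spectra, cohort.outcomes(), plan, lam=lam
    )
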