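"""Synthetic two-visit cohort generator.

Emulates a population study with two partially overlapping plasma sampling
visits: clinical records (anthropometrics, blood pressures, medication flags,
a 12-analyte panel), phenotype labels derived from the records by the same
clinical cutoffs used downstream, and forward-modeled FTIR absorbance spectra.

The spectral forward model is Beer-Lambert: each constituent contributes a
fixed set of Gaussian absorption bands scaled by its concentration, summed,
multiplied by a per-visit path-length factor, plus a gentle per-sample
baseline, minus a scaled pure-water profile (the "water deficit" that the
preprocessing step must undo), plus white noise.

Concentrations are log-normal with linear predictors on the log scale
(sex, age, BMI, a per-individual latent profile, and correlated metabolic
latent factors), which gives strictly positive, right-skewed values and
clinically plausible phenotype co-occurrence: a shared metabolic-load factor
couples the lipid, blood-pressure and glycemic axes, so conditions cluster
in individuals as they do in adult populations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ANALYTES, PhenotypeMatrix, Spectrum, SpectraMatrix

__all__ = [
    "SimulationConfig",
    "EffectSizes",
    "PhenotypeThresholds",
    "ComponentLibrary",
    "CohortData",
    "default_library",
    "default_cohort_config",
    "make_population",
    "assign_phenotypes",
    "synthesize_spectrum",
    "generate_cohort",
    "generate_dataset",
]


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# configuration

@dataclass
class EffectSizes:
    """Phenotype-to-analyte shift magnitudes (log-concentration units unless
    noted).  Larger values separate positives from negatives more strongly."""

    dyslipidemia: float = 0.20     # gamma of lipid factor on log non-HDL
    triglycerides: float = 0.30    # gamma of lipid factor on log TG
    glycemia: float = 0.16         # gamma of glycemic factor on log glucose
    hypertension: float = 13.0     # mmHg of systolic BP per unit BP factor
    sex_protein: float = 0.08      # male shift of log background protein
    mets_drift: float = 0.12       # mean metabolic-factor drift to visit 2


@dataclass
class PhenotypeThresholds:
    """Clinical cutoffs used to derive phenotype labels from records."""

    non_hdl_cutoff: float = 4.1    # mmol/L, dyslipidemia
    sbp_cutoff: float = 140.0      # mmHg
    dbp_cutoff: float = 90.0       # mmHg
    fasting_t2d: float = 126.0     # mg/dL
    ogtt_t2d: float = 200.0        # mg/dL, 2 h post-load
    fasting_pre: float = 110.0     # mg/dL
    ogtt_pre: float = 140.0        # mg/dL


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study design this generator emulates: sample set #1
    with 3044 samples, set #2 with 2140, and 2015 individuals participating
    in both visits.  :func:`default_cohort_config` returns the desk-scale
    cohort used by the test suite and the acceptance script.
    """

    n_set1: int = 3044
    n_set2: int = 2140
    n_overlap: int = 2015
    seed: int = 0
    effects: EffectSizes = field(default_factory=EffectSizes)
    thresholds: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    # spectral axis
    wn_min: float = 950.0
    wn_max: float = 3050.0
    wn_step: float = 2.0
    # noise and artifacts
    noise_sd: float = 5.0e-4            # AU, white spectral noise
    baseline_sd: float = 2.0e-3         # AU, per-sample baseline offset/tilt
    scale_jitter_sd: float = 0.05       # log-SD of per-sample dilution /
                                        # effective path-length factor
    water_deficit_range: tuple[float, float] = (0.0, 0.15)
    # per-visit batch effects
    path_length: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 1.04}
    )
    storage_tilt: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 6.0e-3}
    )
    # population structure
    age_range: tuple[float, float] = (32.0, 88.0)
    followup_years: float = 6.5
    missing_rate: float = 0.005
    profile_sd: float = 0.08            # per-analyte individual random effect
    visit_noise_sd: float = 0.12        # visit-level wobble of latent factors
    drift_sd: float = 0.28              # SD of metabolic drift to visit 2
    visit2_independent: bool = False    # if True, visit-2 latents are redrawn
                                        # fresh (removes forecastable signal)

    def __post_init__(self) -> None:
        if min(self.n_set1, self.n_set2) < 0 or self.n_overlap < 0:
            raise ConfigurationError("counts must be nonnegative")
        if self.n_overlap > min(self.n_set1, self.n_set2):
            raise ConfigurationError(
                "n_overlap cannot exceed min(n_set1, n_set2)"
            )
        if not 0 <= self.missing_rate <= 1:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        lo, hi = self.water_deficit_range
        if lo > hi:
            raise ConfigurationError("water_deficit_range must be ordered")

    def grid(self) -> np.ndarray:
        n = int(round((self.wn_max - self.wn_min) / self.wn_step)) + 1
        return self.wn_min + self.wn_step * np.arange(n)


def default_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The desk-scale default cohort: 2000 + 1400 samples, overlap 1000."""
    return SimulationConfig(
        n_set1=2000, n_set2=1400, n_overlap=1000, seed=seed, **overrides
    )


# --------------------------------------------------------------------------
# component library (Gaussian absorption bands)

#: Pseudo-constituent for the bulk non-albumin plasma protein background.
BACKGROUND = "background_protein"

# (center cm^-1, width cm^-1, amplitude AU per concentration unit)
_DEFAULT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    # glucose ring/C-O modes, 1000-1180 cm^-1
    "fasting_glucose": [
        (1035.0, 12.0, 6.0e-4),
        (1080.0, 15.0, 8.0e-4),
        (1110.0, 14.0, 5.4e-4),
        (1152.0, 12.0, 2.8e-4),
    ],
    "hba1c": [(1042.0, 18.0, 2.0e-3), (1625.0, 25.0, 1.2e-3)],
    # lipids: ester C=O 1725-1750, CH stretches 2800-2975
    "total_cholesterol": [
        (1740.0, 10.0, 4.0e-3),
        (2852.0, 18.0, 3.0e-3),
        (2925.0, 20.0, 5.0e-3),
        (2958.0, 14.0, 2.5e-3),
    ],
    "ldl": [
        (1738.0, 11.0, 3.0e-3),
        (2924.0, 22.0, 4.0e-3),
        (1466.0, 15.0, 1.0e-3),
    ],
    # HDL: weak, deliberately spread over many bands so that no single
    # wavenumber carries it (multivariate recovery, univariate obscurity)
    "hdl": [
        (1086.0, 25.0, 2.8e-3),
        (1242.0, 25.0, 2.5e-3),
        (1400.0, 20.0, 2.5e-3),
        (1555.0, 20.0, 2.0e-3),
        (1742.0, 12.0, 2.8e-3),
        (2868.0, 25.0, 2.5e-3),
        (2930.0, 25.0, 3.0e-3),
    ],
    # triglycerides: ester, carbohydrate-region C-O-C, CH stretches
    "triglycerides": [
        (1745.0, 10.0, 1.0e-4),
        (1162.0, 20.0, 6.0e-5),
        (1240.0, 18.0, 4.0e-5),
        (2855.0, 15.0, 8.0e-5),
        (2930.0, 18.0, 1.1e-4),
    ],
    "creatinine": [
        (1240.0, 15.0, 6.0e-3),
        (1604.0, 18.0, 4.5e-3),
        (1490.0, 12.0, 3.0e-3),
    ],
    # amide I/II protein bands, 1550-1700
    "albumin": [
        (1655.0, 28.0, 3.5e-3),
        (1552.0, 25.0, 2.6e-3),
        (1400.0, 18.0, 8.0e-4),
        (2960.0, 20.0, 5.0e-4),
    ],
    "leukocytes": [(1085.0, 18.0, 6.0e-4), (1244.0, 15.0, 4.0e-4)],
    "erythrocytes": [(1078.0, 20.0, 1.0e-3), (1560.0, 20.0, 8.0e-4)],
    "hematocrit": [(1076.0, 22.0, 8.0e-2), (1556.0, 20.0, 5.0e-2)],
    "platelets": [(1092.0, 20.0, 1.2e-6), (1558.0, 20.0, 8.0e-7)],
    BACKGROUND: [
        (1658.0, 30.0, 3.0e-3),
        (1556.0, 28.0, 2.2e-3),
        (1312.0, 25.0, 6.0e-4),
        (2935.0, 25.0, 7.0e-4),
    ],
}


def _gaussian(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def water_profile(grid: np.ndarray) -> np.ndarray:
    """Pure-water absorbance profile: bending mode near 1640, the broad
    association (combination) band near 2130, and the OH-stretch flank."""
    return (
        0.9 * _gaussian(grid, 1637.0, 60.0)
        + 0.25 * _gaussian(grid, 2130.0, 90.0)
        + 1.8 * _gaussian(grid, 3404.0, 160.0)
        + 0.05
    )


@dataclass
class ComponentLibrary:
    """Gaussian band library mapping constituents to molar absorptivities."""

    grid: np.ndarray
    bands: dict[str, list[tuple[float, float, float]]]
    water: np.ndarray  # W(nu) on grid

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        lo, hi = self.grid[0], self.grid[-1]
        for name, bl in self.bands.items():
            for center, width, amp in bl:
                if not lo <= center <= hi:
                    raise ConfigurationError(
                        f"band center {center} of {name!r} outside grid"
                    )

    def absorptivity(self, name: str) -> np.ndarray:
        """epsilon_m(nu): absorbance per unit concentration of constituent."""
        if name not in self.bands:
            raise ConfigurationError(f"no bands defined for {name!r}")
        eps = np.zeros_like(self.grid)
        for center, width, amp in self.bands[name]:
            eps += amp * _gaussian(self.grid, center, width)
        return eps

    def matrix(self, names: list[str]) -> np.ndarray:
        return np.stack([self.absorptivity(n) for n in names])


def default_library(grid: np.ndarray) -> ComponentLibrary:
    return ComponentLibrary(grid, dict(_DEFAULT_BANDS), water_profile(grid))


# --------------------------------------------------------------------------
# population and clinical records

# loadings of the shared metabolic factor on the lipid / BP / glycemic axes
_A_LIP, _A_BP, _A_GLY = 0.75, 0.95, 0.75

#: analyte log-scale model: ref level, residual SD, male shift,
#: per-decade-from-60 age slope, per-5-kg/m2-from-27 BMI slope,
#: lipid-factor gamma, glycemic-factor gamma
_CONC_MODEL: dict[str, tuple[float, float, float, float, float, str]] = {
    # name: (ref, sigma, b_male, b_age, b_bmi, factor)
    "hdl":             (1.44, 0.10, -0.18, 0.00, -0.05, "lip-"),
    "triglycerides":   (120.0, 0.18, 0.08, 0.04, 0.12, "lip"),
    "fasting_glucose": (95.0, 0.03, 0.01, 0.03, 0.04, "gly"),
    "glucose_2h":      (108.0, 0.035, 0.00, 0.04, 0.04, "gly2"),
    "hba1c":           (5.5, 0.03, 0.00, 0.03, 0.01, "glyw"),
    "creatinine":      (0.90, 0.10, 0.22, 0.04, 0.00, ""),
    "albumin":         (45.0, 0.04, 0.03, -0.03, 0.00, ""),
    "leukocytes":      (6.2, 0.20, 0.00, 0.00, 0.08, ""),
    "erythrocytes":    (4.8, 0.05, 0.10, -0.01, 0.00, ""),
    "hematocrit":      (0.42, 0.05, 0.12, -0.01, 0.00, ""),
    "platelets":       (250.0, 0.17, -0.04, 0.00, 0.00, ""),
    BACKGROUND:        (30.0, 0.05, 0.0, -0.01, 0.03, "sexfx"),
}

_MASKABLE_FIELDS = (
    "waist", "sbp", "dbp", "fasting_glucose", "glucose_2h",
    "hdl", "total_cholesterol", "ldl", "triglycerides",
)


def make_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate per-visit clinical records for the two-visit population.

    Returns one row per (individual, visit) pair; the union of visit-1 rows
    is sample set #1 and of visit-2 rows sample set #2, with ``n_overlap``
    individuals contributing to both.  Deterministic given ``config.seed``.

    The returned frame also carries the generator's ground-truth columns
    (latent factors, the background-protein level) prefixed with ``truth_``;
    :func:`generate_cohort` separates them from the clinical table proper.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    eff = config.effects
    n1, n2, nov = config.n_set1, config.n_set2, config.n_overlap
    n_unique = n1 + n2 - nov

    indiv = np.array([f"I{i:05d}" for i in range(n_unique)], dtype=object)
    # first nov individuals attend both visits, next n1-nov only visit 1,
    # the rest only visit 2
    in_set1 = np.zeros(n_unique, dtype=bool)
    in_set2 = np.zeros(n_unique, dtype=bool)
    in_set1[: n1] = True
    in_set2[: nov] = True
    in_set2[n1:] = True

    male = rng.random(n_unique) < 0.5
    lo, hi = config.age_range
    age0 = rng.uniform(lo, hi, n_unique)
    bmi0 = np.clip(rng.normal(26.8, 4.0, n_unique), 17.0, 48.0)

    # correlated latent factors: shared metabolic load + idiosyncrasies
    m1 = rng.normal(size=n_unique)
    e_lip = rng.normal(size=n_unique)
    e_bp = rng.normal(size=n_unique)
    e_gly = rng.normal(size=n_unique)
    drift = rng.normal(eff.mets_drift, config.drift_sd, n_unique)
    if config.visit2_independent:
        m2 = rng.normal(size=n_unique)
    else:
        m2 = m1 + drift

    comp_names = list(_CONC_MODEL) + ["non_hdl_base"]
    profile = {
        name: np.exp(rng.normal(0.0, config.profile_sd, n_unique))
        for name in comp_names
    }
    # the 2 h OGTT response shares the individual glycemic random effect
    profile["glucose_2h"] = profile["fasting_glucose"]

    rows = []
    for visit, member in ((1, in_set1), (2, in_set2)):
        idx = np.flatnonzero(member)
        nv = idx.size
        m = (m1 if visit == 1 else m2)[idx]
        z_lip = _A_LIP * m + np.sqrt(1 - _A_LIP**2) * e_lip[idx]
        z_bp = _A_BP * m + np.sqrt(1 - _A_BP**2) * e_bp[idx]
        z_gly = _A_GLY * m + np.sqrt(1 - _A_GLY**2) * e_gly[idx]
        vnoise = rng.normal(0.0, config.visit_noise_sd, (3, nv))
        z_lip, z_bp, z_gly = z_lip + vnoise[0], z_bp + vnoise[1], z_gly + vnoise[2]

        years = 0.0 if visit == 1 else config.followup_years
        age = age0[idx] + years
        bmi = bmi0[idx] + (
            0.0 if visit == 1 else rng.normal(0.2, 1.0, nv)
        )
        agec = (age - 60.0) / 10.0
        bmic = (bmi - 27.0) / 5.0
        sexm = male[idx].astype(float)

        rec: dict[str, np.ndarray] = {}
        factor_term = {
            "lip": eff.triglycerides * z_lip,
            "lip-": -0.06 * z_lip,
            "gly": eff.glycemia * z_gly,
            "gly2": 0.26 * z_gly,
            "glyw": 0.08 * z_gly,
            "sexfx": eff.sex_protein * sexm,
            "": 0.0,
        }
        for name, (ref, sig, b_m, b_a, b_b, fac) in _CONC_MODEL.items():
            logc = (
                np.log(ref)
                + b_m * sexm
                + b_a * agec
                + b_b * bmic
                + factor_term[fac]
                + np.log(profile[name][idx])
                + rng.normal(0.0, sig, nv)
            )
            rec[name] = np.exp(logc)

        # non-HDL cholesterol generated directly (ref 4.0 mmol/L) so that
        # total = non-HDL + HDL >= HDL holds by construction
        non_hdl = np.exp(
            np.log(4.00)
            + 0.02 * sexm
            + 0.06 * agec
            + 0.03 * bmic
            + eff.dyslipidemia * z_lip
            + np.log(profile["non_hdl_base"][idx])
            + rng.normal(0.0, 0.10, nv)
        )
        rec["total_cholesterol"] = non_hdl + rec["hdl"]
        rec["ldl"] = 0.80 * non_hdl * np.exp(rng.normal(0.0, 0.05, nv))

        bp_drive = eff.hypertension * z_bp + 5.0 * z_lip + 3.0 * z_gly
        sbp = (
            125.0 + 7.0 * agec + 4.0 * bmic
            + bp_drive + rng.normal(0.0, 3.0, nv)
        )
        dbp = (
            78.5 + 1.5 * agec + 1.5 * bmic
            + 0.6 * bp_drive + rng.normal(0.0, 2.5, nv)
        )
        waist = (
            np.where(male[idx], 96.0, 84.0)
            + 2.0 * (bmi - 27.0) + 2.0 * m + rng.normal(0.0, 5.0, nv)
        )

        def _sigmoid(x):
            return 1.0 / (1.0 + np.exp(-x))

        med_htn = rng.random(nv) < _sigmoid(-2.4 + 1.5 * z_bp + 0.5 * agec + 0.3 * z_lip)
        med_dm = rng.random(nv) < _sigmoid(-4.5 + 2.2 * z_gly + 0.3 * agec)
        med_fib = rng.random(nv) < _sigmoid(-3.6 + 1.2 * z_lip)

        frame = pd.DataFrame({
            "sample_id": [f"v{visit}_{s}" for s in indiv[idx]],
            "individual_id": indiv[idx],
            "visit": visit,
            "sex": np.where(male[idx], "male", "female"),
            "age": age,
            "bmi": bmi,
            "waist": waist,
            "sbp": sbp,
            "dbp": dbp,
            "med_antihypertensive": med_htn,
            "med_antidiabetic": med_dm,
            "med_fibrates": med_fib,
            "glucose_2h": rec["glucose_2h"],
        })
        for a in ANALYTES:
            frame[a] = rec[a]
        frame["truth_background_protein"] = rec[BACKGROUND]
        frame["truth_metabolic_factor"] = m
        frame["truth_z_lip"] = z_lip
        frame["truth_z_bp"] = z_bp
        frame["truth_z_gly"] = z_gly
        rows.append(frame)

    out = pd.concat(rows, ignore_index=True)
    assert out.duplicated(["individual_id", "visit"]).sum() == 0
    return out


def assign_phenotypes(
    clinical: pd.DataFrame,
    thresholds: PhenotypeThresholds | None = None,
) -> PhenotypeMatrix:
    """Derive the 5-label phenotype vector from each clinical record.

    dyslipidemia  : non-HDL cholesterol (total - HDL) > 4.1 mmol/L
    hypertension  : SBP >= 140 or DBP >= 90 mmHg, or antihypertensive meds
    t2d           : fasting >= 126 or 2 h >= 200 mg/dL, or antidiabetic meds
    prediabetes   : not t2d and (fasting >= 110 or 2 h >= 140 mg/dL)
    healthy       : none of the above

    Records with any determining field missing are flagged ``unknown``.
    """
    th = thresholds or PhenotypeThresholds()
    df = clinical
    non_hdl = df["total_cholesterol"] - df["hdl"]
    dys = (non_hdl > th.non_hdl_cutoff).to_numpy()
    hyp = (
        (df["sbp"] >= th.sbp_cutoff)
        | (df["dbp"] >= th.dbp_cutoff)
        | df["med_antihypertensive"].fillna(False).astype(bool)
    ).to_numpy()
    t2d = (
        (df["fasting_glucose"] >= th.fasting_t2d)
        | (df["glucose_2h"] >= th.ogtt_t2d)
        | df["med_antidiabetic"].fillna(False).astype(bool)
    ).to_numpy()
    pre = (
        ~t2d
        & (
            (df["fasting_glucose"] >= th.fasting_pre)
            | (df["glucose_2h"] >= th.ogtt_pre)
        ).to_numpy()
    )
    healthy = ~(dys | hyp | pre | t2d)
    unknown = (
        df[["total_cholesterol", "hdl"]].isna().any(axis=1)
        | df[["sbp", "dbp"]].isna().any(axis=1)
        | df[["fasting_glucose", "glucose_2h"]].isna().any(axis=1)
    ).to_numpy()
    values = np.column_stack([dys, hyp, pre, t2d, healthy])
    return PhenotypeMatrix(
        df["sample_id"].to_numpy(dtype=object), values, unknown
    )


# --------------------------------------------------------------------------
# spectra

def synthesize_spectrum(
    concentrations: Mapping[str, float],
    library: ComponentLibrary,
    path_length: float = 1.0,
    water_deficit: float = 0.0,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Beer-Lambert forward model for one sample.

    A(nu) = L * sum_m c_m eps_m(nu) + baseline(nu) - d * W(nu) + noise,
    where ``baseline`` is (offset, tilt-per-full-range) and d is the water
    deficit relative to the pure-water reference.
    """
    grid = library.grid
    absorb = np.zeros_like(grid)
    for name, conc in concentrations.items():
        absorb += conc * library.absorptivity(name)
    absorb *= path_length
    span = grid[-1] - grid[0]
    b0, b1 = baseline
    absorb += b0 + b1 * (grid - grid[0]) / span
    absorb -= water_deficit * library.water
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        absorb = absorb + rng.normal(0.0, noise_sd, grid.size)
    return Spectrum(grid, absorb)


# --------------------------------------------------------------------------
# full cohort

@dataclass
class CohortData:
    """In-memory bundle of everything the generator produces."""

    config: SimulationConfig
    clinical: pd.DataFrame              # one row per sample, NaN = missing
    labels: PhenotypeMatrix
    spectra: dict[int, SpectraMatrix]   # visit -> raw spectra
    water: Spectrum                     # pure-water reference
    ground_truth: pd.DataFrame          # true conc, deficits, latents

    def set_samples(self, visit: int) -> list:
        return self.spectra[visit].sample_ids.tolist()


def generate_cohort(config: SimulationConfig | None = None) -> CohortData:
    """Run the full generator: population, labels, spectra, ground truth."""
    config = config or SimulationConfig()
    grid = config.grid()
    library = default_library(grid)
    records = make_population(config)

    truth_cols = [c for c in records.columns if c.startswith("truth_")]
    clinical = records.drop(columns=truth_cols).copy()

    comp_names = list(ANALYTES) + [BACKGROUND]
    eps = library.matrix(comp_names)  # (n_comp, n_grid)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = len(records)
    conc = np.column_stack(
        [records[a].to_numpy() for a in ANALYTES]
        + [records["truth_background_protein"].to_numpy()]
    )
    lo, hi = config.water_deficit_range
    deficit = rng.uniform(lo, hi, n)
    scale = np.exp(rng.normal(0.0, config.scale_jitter_sd, n))
    b0 = rng.normal(0.0, config.baseline_sd, n)
    b1 = rng.normal(0.0, config.baseline_sd, n)

    span = grid[-1] - grid[0]
    ramp = (grid - grid[0]) / span
    path = records["visit"].map(dict(config.path_length)).to_numpy()
    tilt = records["visit"].map(dict(config.storage_tilt)).to_numpy()

    absorb = (path * scale)[:, None] * (conc @ eps)
    absorb += b0[:, None] + (b1 + tilt)[:, None] * ramp[None, :]
    absorb -= deficit[:, None] * library.water[None, :]
    absorb += rng.normal(0.0, config.noise_sd, absorb.shape)

    spectra = {}
    for visit in (1, 2):
        mask = (records["visit"] == visit).to_numpy()
        spectra[visit] = SpectraMatrix(
            records.loc[mask, "sample_id"].to_numpy(dtype=object),
            grid,
            absorb[mask],
        )

    ground_truth = records[["sample_id", "individual_id", "visit"]].copy()
    for a in ANALYTES:
        ground_truth[f"true_{a}"] = records[a]
    ground_truth["true_glucose_2h"] = records["glucose_2h"]
    ground_truth["true_background_protein"] = records[
        "truth_background_protein"]
    ground_truth["true_water_deficit"] = deficit
    ground_truth["true_scale_factor"] = scale
    for c in ("metabolic_factor", "z_lip", "z_bp", "z_gly"):
        ground_truth[c] = records[f"truth_{c}"]

    # missingness is applied to the reported clinical table only; labels are
    # derived from the reported table so that samples with missing
    # determining fields come out flagged unknown, as in the emulated study
    if config.missing_rate > 0:
        miss_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 303])
        )
        for col in _MASKABLE_FIELDS:
            mask = miss_rng.random(n) < config.missing_rate
            clinical.loc[mask, col] = np.nan

    labels = assign_phenotypes(clinical, config.thresholds)
    return CohortData(
        config=config,
        clinical=clinical,
        labels=labels,
        spectra=spectra,
        water=Spectrum(grid, library.water),
        ground_truth=ground_truth,
    )


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write the generated cohort to disk as CSV/JSON files.

    Produces ``spectra_set1.csv``, ``spectra_set2.csv``,
    ``water_reference.csv``, ``clinical.csv``, ``labels.csv`` and
    ``ground_truth.json``; returns the mapping of artifact name to path.
    """
    from .io import write_spectra_csv, write_water_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    paths = {}
    for visit in (1, 2):
        p = outdir / f"spectra_set{visit}.csv"
        write_spectra_csv(cohort.spectra[visit], p)
        paths[f"spectra_set{visit}"] = p
    p = outdir / "water_reference.csv"
    write_water_csv(cohort.water, p)
    paths["water_reference"] = p
    p = outdir / "clinical.csv"
    cohort.clinical.to_csv(p, index=False)
    paths["clinical"] = p
    p = outdir / "labels.csv"
    cohort.labels.to_frame().to_csv(p, index=False)
    paths["labels"] = p
    p = outdir / "ground_truth.json"
    gt = {
        "samples": cohort.ground_truth.set_index("sample_id").to_dict(
            orient="index"
        )
    }
    p.write_text(json.dumps(gt, default=float))
    paths["ground_truth"] = p
    return paths
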