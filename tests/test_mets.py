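import numpy as np
import pandas as pd
import pytest

from plasmafp import mets as M
from plasmafp.cohort import SimulationConfig, default_cohort_config, \
    generate_cohort


def _record(**overrides):
    base = dict(
        sample_id="s", sex="male", waist=85.0, sbp=115.0, dbp=75.0,
        med_antihypertensive=False, med_antidiabetic=False,
        med_fibrates=False, fasting_glucose=90.0, hdl=1.6,
        triglycerides=100.0,
    )
    base.update(overrides)
    return base


def oracle_profile(r):
    """Independent rule-table re-derivation of the five harmonized factors."""
    male = r["sex"] == "male"
    missing = any(
        r[f] is None or (isinstance(r[f], float) and np.isnan(r[f]))
        for f in ("waist", "sbp", "dbp", "fasting_glucose", "hdl",
                  "triglycerides")
    )
    hdl_mgdl = r["hdl"] * 38.67 if r["hdl"] is not None else np.nan
    return {
        "waist": r["waist"] >= (94 if male else 80),
        "bp": r["sbp"] >= 130 or r["dbp"] >= 85 or r["med_antihypertensive"],
        "glucose": r["fasting_glucose"] >= 100 or r["med_antidiabetic"],
        "hdl": hdl_mgdl < (40 if male else 50) or r["med_fibrates"],
        "tg": r["triglycerides"] >= 150 or r["med_fibrates"],
        "any_missing": missing,
    }


class TestRiskFactors:
    def test_male_waist_cutoff(self):
        p = M.count_risk_factors(_record(waist=95.0))
        assert p.waist and p.count == 1

    def test_female_waist_cutoff_is_lower(self):
        p = M.count_risk_factors(_record(sex="female", waist=81.0, hdl=1.6))
        assert p.waist

    def test_female_hdl_just_below_fifty_mgdl(self):
        # 49 mg/dL = 1.267 mmol/L, below the female cutoff
        p = M.count_risk_factors(
            _record(sex="female", waist=70.0, hdl=49.0 / 38.67)
        )
        assert p.hdl and p.count == 1

    def test_fibrates_flag_sets_both_lipid_factors(self):
        p = M.count_risk_factors(_record(med_fibrates=True))
        assert p.hdl and p.tg

    def test_missing_waist_flags_profile(self):
        p = M.count_risk_factors(_record(waist=np.nan))
        assert p.any_missing
        with pytest.raises(ValueError):
            _ = p.count

    def test_rule_table_oracle_agreement_on_random_records(self):
        rng = np.random.default_rng(0)
        n = 10_000
        records = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "waist": rng.uniform(60, 130, n),
            "sbp": rng.uniform(95, 180, n),
            "dbp": rng.uniform(55, 110, n),
            "med_antihypertensive": rng.random(n) < 0.15,
            "med_antidiabetic": rng.random(n) < 0.05,
            "med_fibrates": rng.random(n) < 0.05,
            "fasting_glucose": rng.uniform(60, 220, n),
            "hdl": rng.uniform(0.5, 3.0, n),
            "triglycerides": rng.uniform(40, 600, n),
        })
        # sprinkle missing values
        for col in ("waist", "hdl", "triglycerides"):
            mask = rng.random(n) < 0.02
            records.loc[mask, col] = np.nan
        table = M.risk_factor_table(records)
        for i in range(n):
            expect = oracle_profile(records.iloc[i].to_dict())
            row = table.iloc[i]
            assert bool(row["any_missing"]) == expect["any_missing"], i
            if expect["any_missing"]:
                continue
            for f in ("waist", "bp", "glucose", "hdl", "tg"):
                assert bool(row[f]) == bool(expect[f]), (i, f)

    def test_adding_a_factor_never_decreases_count(self):
        base = M.count_risk_factors(_record(waist=95.0, sbp=135.0))
        more = M.count_risk_factors(
            _record(waist=95.0, sbp=135.0, triglycerides=160.0)
        )
        assert more.count >= base.count
        assert not (M.mets_status(base) and not M.mets_status(more))


class TestMetsStatus:
    @pytest.mark.parametrize("n_factors, expect", [(0, False), (2, False),
                                                   (3, True), (5, True)])
    def test_three_of_five_rule(self, n_factors, expect):
        overrides = {}
        factor_settings = [
            {"waist": 100.0},
            {"sbp": 140.0},
            {"fasting_glucose": 110.0},
            {"hdl": 0.8},
            {"triglycerides": 200.0},
        ]
        for setting in factor_settings[:n_factors]:
            overrides.update(setting)
        p = M.count_risk_factors(_record(**overrides))
        assert p.count == n_factors
        assert M.mets_status(p) is expect


class TestCohorts:
    def test_k_vs_zero_membership_is_exact(self):
        rows = [
            _record(sample_id="zero"),
            _record(sample_id="two", waist=100.0, sbp=140.0),
            _record(sample_id="gone", waist=np.nan),
        ]
        profiles = M.risk_factor_table(pd.DataFrame(rows))
        with pytest.warns(UserWarning):
            cohorts = M.k_vs_zero_cohorts(profiles)
        assert cohorts[2]["cases"] == ["two"]
        assert cohorts[2]["controls"] == ["zero"]
        assert 1 not in cohorts  # empty stratum skipped
        for k in cohorts:
            assert "gone" not in cohorts[k]["cases"]
            assert "gone" not in cohorts[k]["controls"]

    def test_classification_strengthens_with_factor_count(
        self, small_cohort, small_preprocessed
    ):
        """More concurrent risk factors leave a stronger fingerprint: the
        k-vs-0 AUC at the top stratum beats the k=1 stratum."""
        from plasmafp import validation as V

        cl = small_cohort.clinical
        profiles = M.risk_factor_table(cl)
        cohorts = M.k_vs_zero_cohorts(profiles)
        x = small_preprocessed["pooled"]
        have = set(x.sample_ids.tolist())
        aucs = {}
        for k in (1, max(cohorts)):
            ids = [s for s in cohorts[k]["cases"] + cohorts[k]["controls"]
                   if s in have]
            y = pd.Series(
                [s in set(cohorts[k]["cases"]) for s in ids], index=ids
            )
            plan = V.make_cv_folds(ids, k=4, seed=0)
            aucs[k] = V.run_binary_experiment(x, y, plan)["auc_mean"]
        assert aucs[max(cohorts)] > aucs[1]


class TestIncidentCohort:
    def _profiles(self, counts, visit, missing=()):
        rows = []
        for ind, c in counts.items():
            rec = _record(sample_id=f"v{visit}_{ind}")
            settings = [
                {"waist": 100.0}, {"sbp": 140.0},
                {"fasting_glucose": 110.0}, {"hdl": 0.8},
                {"triglycerides": 200.0},
            ]
            for s in settings[:c]:
                rec.update(s)
            if ind in missing:
                rec["waist"] = np.nan
            rows.append(rec)
        table = M.risk_factor_table(pd.DataFrame(rows))
        table["individual_id"] = list(counts)
        return table

    def test_partition_identity_and_exclusions(self):
        baseline = self._profiles(
            {"a": 0, "b": 2, "c": 4, "d": 1, "e": 0}, visit=1
        )
        followup = self._profiles(
            {"a": 3, "b": 1, "c": 5, "d": 1}, visit=2  # e lacks follow-up
        )
        cohort = M.incident_mets_cohort(baseline, followup)
        # c was MetS-positive at baseline: excluded entirely
        assert "v1_c" not in cohort.cases + cohort.controls
        assert cohort.cases == ["v1_a"]
        assert sorted(cohort.controls) == ["v1_b", "v1_d"]
        assert (
            len(cohort.cases) + len(cohort.controls)
            == cohort.n_baseline_negative
        )

    def test_missing_factors_exclude_individual(self):
        baseline = self._profiles({"a": 0, "b": 0}, visit=1, missing={"b"})
        followup = self._profiles({"a": 3, "b": 3}, visit=2)
        cohort = M.incident_mets_cohort(baseline, followup)
        assert cohort.cases == ["v1_a"]
        assert cohort.n_baseline_negative == 1

    def test_partition_identity_on_synthetic_cohort(self, small_cohort):
        cl = small_cohort.clinical
        rf = M.risk_factor_table(cl)
        rf["individual_id"] = cl["individual_id"].to_numpy()
        rf["visit"] = cl["visit"].to_numpy()
        cohort = M.incident_mets_cohort(
            rf[rf["visit"] == 1], rf[rf["visit"] == 2]
        )
        assert (
            len(cohort.cases) + len(cohort.controls)
            == cohort.n_baseline_negative
        )


class TestForecast:
    def test_features_are_baseline_only(self, small_cohort,
                                        small_preprocessed):
        cl = small_cohort.clinical
        rf = M.risk_factor_table(cl)
        rf["individual_id"] = cl["individual_id"].to_numpy()
        rf["visit"] = cl["visit"].to_numpy()
        cohort = M.incident_mets_cohort(
            rf[rf["visit"] == 1], rf[rf["visit"] == 2]
        )
        assert all(s.startswith("v1_") for s in cohort.cases)
        assert all(s.startswith("v1_") for s in cohort.controls)
        # handing only visit-2 spectra must fail: no baseline features leak
        with pytest.raises(ValueError):
            M.forecast_experiment(cohort, small_preprocessed[2], k=3)

    def test_informative_drift_is_forecastable(self):
        from plasmafp import preprocess as P

        cfg = default_cohort_config(seed=5)
        data = generate_cohort(cfg)
        x1, _ = P.preprocess_matrix(data.spectra[1], data.water)
        cl = data.clinical
        rf = M.risk_factor_table(cl)
        rf["individual_id"] = cl["individual_id"].to_numpy()
        rf["visit"] = cl["visit"].to_numpy()
        cohort = M.incident_mets_cohort(
            rf[rf["visit"] == 1], rf[rf["visit"] == 2]
        )
        report = M.forecast_experiment(cohort, x1, k=5, seed=0)
        assert report["auc_mean"] > 0.65

    def test_independent_followup_is_not_forecastable(self):
        from plasmafp import preprocess as P

        cfg = SimulationConfig(
            n_set1=700, n_set2=700, n_overlap=700, seed=6,
            visit2_independent=True, missing_rate=0.0,
        )
        data = generate_cohort(cfg)
        x1, _ = P.preprocess_matrix(data.spectra[1], data.water)
        cl = data.clinical
        rf = M.risk_factor_table(cl)
        rf["individual_id"] = cl["individual_id"].to_numpy()
        rf["visit"] = cl["visit"].to_numpy()
        cohort = M.incident_mets_cohort(
            rf[rf["visit"] == 1], rf[rf["visit"] == 2]
        )
        report = M.forecast_experiment(cohort, x1, k=5, seed=0)
        assert abs(report["auc_mean"] - 0.5) < 0.1
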