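import numpy as np
import pandas as pd
import pytest

from plasmafp import metrics as M
from plasmafp import validation as V
from plasmafp.containers import PhenotypeMatrix, enumerate_feasible_vectors


def _two_visit_tables(n1, n2, nov, prefix="I"):
    """Sample/individual id tables mimicking the two-visit design."""
    n_unique = n1 + n2 - nov
    ind = [f"{prefix}{i:04d}" for i in range(n_unique)]
    set1 = ind[:n1]
    set2 = ind[:nov] + ind[n1:]
    s1 = pd.DataFrame({
        "sample_id": [f"v1_{i}" for i in set1], "individual_id": set1,
    })
    s2 = pd.DataFrame({
        "sample_id": [f"v2_{i}" for i in set2], "individual_id": set2,
    })
    return s1, s2


class TestCvFolds:
    def test_balanced_partition(self):
        plan = V.make_cv_folds([f"s{i}" for i in range(100)], k=10, seed=0)
        sizes = [len(te) for _, te in plan.folds]
        assert sizes == [10] * 10
        tests = [s for _, te in plan.folds for s in te]
        assert sorted(tests) == sorted(f"s{i}" for i in range(100))

    def test_uneven_sizes_differ_by_at_most_one(self):
        plan = V.make_cv_folds([f"s{i}" for i in range(103)], k=10, seed=0)
        sizes = sorted(len(te) for _, te in plan.folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(50)]
        a = V.make_cv_folds(ids, k=5, seed=9)
        b = V.make_cv_folds(ids, k=5, seed=9)
        assert a.folds == b.folds

    def test_stratification_spreads_common_combinations(self):
        combos = np.array(enumerate_feasible_vectors(), dtype=bool)
        values = np.tile(combos[0], (40, 1))
        values = np.vstack([values, np.tile(combos[5], (40, 1))])
        ids = [f"s{i}" for i in range(80)]
        labels = PhenotypeMatrix(np.array(ids, dtype=object), values)
        plan = V.make_cv_folds(ids, k=4, seed=0, labels=labels)
        for _, te in plan.folds:
            lab = labels.subset(te)
            # each fold carries both combinations in proportion
            assert lab.values[:, :].sum(axis=0).max() > 0
            n_first = sum(
                1 for row in lab.values if (row == combos[0]).all()
            )
            assert n_first == 10

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            V.make_cv_folds(["a", "b"], k=3)

    def test_serialization_round_trip(self, tmp_path):
        plan = V.make_cv_folds([f"s{i}" for i in range(20)], k=4, seed=1)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = V.FoldPlan.from_json(path)
        assert back.folds == plan.folds
        assert back.regime == plan.regime


class TestIndependentPlan:
    def test_study_scale_group_arithmetic(self):
        # 2015 overlap individuals in 10 groups: sizes 201 or 202
        s1, s2 = _two_visit_tables(3044, 2140, 2015)
        plan = V.make_independent_plan(s1, s2, k=10, seed=0)
        test_sizes = sorted(len(te) for _, te in plan.folds)
        assert set(test_sizes) <= {201, 202}
        assert sum(test_sizes) == 2015

    def test_no_shared_individuals_and_train_bookkeeping(self):
        s1, s2 = _two_visit_tables(120, 90, 60)
        plan = V.make_independent_plan(s1, s2, k=5, seed=3)
        indiv = dict(
            zip(
                pd.concat([s1, s2])["sample_id"],
                pd.concat([s1, s2])["individual_id"],
            )
        )
        V.audit_leakage(plan, indiv)
        for train, test in plan.folds:
            held = {indiv[s] for s in test}
            assert all(s.startswith("v2_") for s in test)
            assert all(s.startswith("v1_") for s in train)
            assert len(train) == 120 - len(held)

    def test_test_groups_partition_the_overlap_pool(self):
        s1, s2 = _two_visit_tables(50, 40, 30)
        plan = V.make_independent_plan(s1, s2, k=6, seed=0)
        tests = [s for _, te in plan.folds for s in te]
        assert len(tests) == len(set(tests)) == 30

    def test_empty_overlap_raises(self):
        s1, s2 = _two_visit_tables(10, 10, 0)
        with pytest.raises(ValueError):
            V.make_independent_plan(s1, s2)


class TestLeakageAudit:
    def test_random_configurations_are_leakage_free(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1 = int(rng.integers(20, 60))
            n2 = int(rng.integers(15, 50))
            nov = int(rng.integers(1, min(n1, n2)))
            s1, s2 = _two_visit_tables(n1, n2, nov)
            k = int(rng.integers(2, 6))
            indiv = dict(
                zip(
                    pd.concat([s1, s2])["sample_id"],
                    pd.concat([s1, s2])["individual_id"],
                )
            )
            plan = V.make_independent_plan(
                s1, s2, k=min(k, nov), seed=int(rng.integers(1000))
            )
            V.audit_leakage(plan, indiv)
            cv = V.make_cv_folds(
                s1["sample_id"].tolist(), k=min(k, n1),
                seed=int(rng.integers(1000)),
            )
            V.audit_leakage(cv, indiv)

    def test_audit_detects_a_planted_leak(self):
        plan = V.FoldPlan(
            regime="cv", folds=[(["a", "b"], ["c"])], k=1, seed=0
        )
        indiv = {"a": "I1", "b": "I2", "c": "I1"}
        with pytest.raises(AssertionError):
            V.audit_leakage(plan, indiv)


def _feature_frame(ids, X):
    df = pd.DataFrame(X)
    df.insert(0, "sample_id", ids)
    return df


class TestExperiments:
    def _perfect_multilabel(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        dys = X[:, 0] > 0
        hyp = X[:, 1] > 0.3
        t2d = X[:, 2] > 1.0
        pre = ~t2d & (X[:, 2] > 0.3)
        values = np.column_stack([
            dys, hyp, pre, t2d, ~(dys | hyp | pre | t2d)
        ])
        ids = [f"s{i}" for i in range(n)]
        Y = PhenotypeMatrix(np.array(ids, dtype=object), values)
        return ids, _feature_frame(ids, 10 * X), Y

    def test_separable_labels_reach_high_exact_match(self):
        # prediabetes is the middle glycemic band, linearly separable only
        # given the t2d label: order the chain with t2d first
        ids, F, Y = self._perfect_multilabel(n=300)
        plan = V.make_cv_folds(ids, k=4, seed=0, labels=Y)
        order = ("dyslipidemia", "hypertension", "t2d", "prediabetes",
                 "healthy")
        report = V.run_multilabel_experiment(
            F, Y, plan, V.ModelSpec(order=order, lam=1e-3)
        )
        assert report["exact_match_ratio"]["mean"] > 0.9

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(4)
        ids, F, Y = self._perfect_multilabel(n=400, seed=4)
        shuffled = PhenotypeMatrix(
            Y.sample_ids, Y.values[rng.permutation(len(ids))]
        )
        plan = V.make_cv_folds(ids, k=4, seed=0, labels=shuffled)
        report = V.run_multilabel_experiment(F, shuffled, plan)
        bench = M.chance_benchmark(shuffled, n_draws=100_000, seed=0)
        # the fitted model on shuffled labels cannot beat an uninformed
        # predictor by more than Monte-Carlo + fold noise
        assert (
            report["exact_match_ratio"]["mean"]
            < bench.expected_exact_match_ratio + 0.1
        )

    def test_binary_experiment_separable_and_null(self):
        rng = np.random.default_rng(5)
        n = 200
        ids = [f"s{i}" for i in range(n)]
        X = rng.normal(size=(n, 3))
        y = pd.Series(X[:, 0] > 0, index=ids)
        F = _feature_frame(ids, 10 * X)
        plan = V.make_cv_folds(ids, k=4, seed=0)
        good = V.run_binary_experiment(F, y, plan, lam=1e-3)
        assert good["auc_mean"] > 0.97
        null = V.run_binary_experiment(
            F, pd.Series(rng.random(n) < 0.5, index=ids), plan
        )
        assert abs(null["auc_mean"] - 0.5) < 0.12
        assert all(s >= 0 for s in [good["auc_sd"], null["auc_sd"]])

    def test_metrics_computed_on_test_rows_only(self):
        """A model that memorizes training rows cannot look perfect if
        scoring is confined to held-out rows."""
        rng = np.random.default_rng(6)
        n = 100
        ids = [f"s{i}" for i in range(n)]
        # pure-noise binary target: any apparent skill would mean leakage
        X = rng.normal(size=(n, 30))
        y = pd.Series(rng.random(n) < 0.5, index=ids)
        plan = V.make_cv_folds(ids, k=4, seed=0)
        report = V.run_binary_experiment(_feature_frame(ids, X), y, plan,
                                         lam=1e-6)
        assert report["auc_mean"] < 0.75  # would be ~1.0 on train rows


class TestPairMatch:
    def _tables(self):
        cases = pd.DataFrame({
            "sample_id": ["c1", "c2"],
            "sex": ["male", "male"],
            "age": [50.0, 70.0],
            "bmi": [25.0, 30.0],
        })
        controls = pd.DataFrame({
            "sample_id": ["k1"],
            "sex": ["male"],
            "age": [50.0],
            "bmi": [25.0],
        })
        return cases, controls

    def test_identical_covariates_give_zero_distance(self):
        cases, controls = self._tables()
        cohort = V.pair_match(cases.iloc[:1], controls)
        assert cohort.pairs == [("c1", "k1")]
        assert cohort.distances[0] == pytest.approx(0.0)

    def test_without_replacement_leaves_extra_case_unmatched(self):
        cases, controls = self._tables()
        cohort = V.pair_match(cases, controls)
        assert len(cohort.pairs) == 1
        assert len(cohort.unmatched_cases) == 1

    def test_sex_is_matched_exactly(self):
        cases = pd.DataFrame({
            "sample_id": ["c1"], "sex": ["female"],
            "age": [50.0], "bmi": [25.0],
        })
        controls = pd.DataFrame({
            "sample_id": ["k1", "k2"], "sex": ["male", "female"],
            "age": [50.0, 80.0], "bmi": [25.0, 35.0],
        })
        cohort = V.pair_match(cases, controls)
        assert cohort.pairs == [("c1", "k2")]  # despite larger distance

    def test_matching_reduces_confounder_gap(self):
        """On age-confounded synthetic groups, the matched cohort's mean
        case-control age gap shrinks versus the unmatched comparison."""
        rng = np.random.default_rng(7)
        n = 150
        cases = pd.DataFrame({
            "sample_id": [f"c{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "age": rng.normal(65, 8, n),
            "bmi": rng.normal(29, 3, n),
        })
        controls = pd.DataFrame({
            "sample_id": [f"k{i}" for i in range(3 * n)],
            "sex": rng.choice(["male", "female"], 3 * n),
            "age": rng.normal(55, 8, 3 * n),
            "bmi": rng.normal(26, 3, 3 * n),
        })
        cohort = V.pair_match(cases, controls)
        matched_ctrl = controls.set_index("sample_id").loc[
            [c for _, c in cohort.pairs]
        ]
        matched_case = cases.set_index("sample_id").loc[
            [c for c, _ in cohort.pairs]
        ]
        gap_matched = abs(
            matched_case["age"].mean() - matched_ctrl["age"].mean()
        )
        gap_raw = abs(cases["age"].mean() - controls["age"].mean())
        assert gap_matched < gap_raw

    def test_empty_controls_raise(self):
        cases, controls = self._tables()
        with pytest.raises(ValueError):
            V.pair_match(cases, controls.iloc[:0])


class TestRegimeConsistency:
    def test_independent_regime_no_easier_than_within_set_cv(
        self, small_cohort, small_preprocessed
    ):
        """With a visit-2 batch effect, testing on the other visit's
        measurements cannot beat within-set cross-validation."""
        lab = small_cohort.labels
        cl = small_cohort.clinical
        x1 = small_preprocessed[1]
        ids1 = [
            s for s, unk in zip(
                x1.sample_ids, lab.subset(x1.sample_ids.tolist()).unknown
            ) if not unk
        ]
        cv = V.make_cv_folds(ids1, k=5, seed=0, labels=lab)
        r_cv = V.run_multilabel_experiment(x1.subset(ids1),
                                           lab, cv)
        s1 = cl[cl.visit == 1][["sample_id", "individual_id"]]
        s2 = cl[cl.visit == 2][["sample_id", "individual_id"]]
        ip = V.make_independent_plan(s1, s2, k=5, seed=0)
        r_ip = V.run_multilabel_experiment(
            small_preprocessed["pooled"], lab, ip
        )
        assert (
            r_ip["exact_match_ratio"]["mean"]
            <= r_cv["exact_match_ratio"]["mean"] + 0.05
        )
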