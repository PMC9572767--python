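"""Grouped folds, cross-validation, and wrapper feature selection."""

import numpy as np
import pandas as pd
import pytest

from mentalload.crossval import (cross_validate, make_group_folds,
                                 repeated_cv, wrapper_select)
from mentalload.models import ModelSpec
from test_models import toy_table


class TestFoldPlans:
    def test_26_subjects_5_folds_mirror_protocol(self):
        ids = [f"S{i:03d}" for i in range(26)]
        plan = make_group_folds(ids, k=5, seed=0)
        test_sizes = sorted(len(te) for _, te in plan.folds)
        assert test_sizes == [5, 5, 5, 5, 6]
        for train, test in plan.folds:
            if len(test) == 5:
                assert len(train) == 21

    @pytest.mark.parametrize("seed", range(100))
    def test_no_train_test_overlap_across_seeds(self, seed):
        ids = [f"S{i}" for i in range(26)]
        plan = make_group_folds(ids, k=5, seed=seed)
        for train, test in plan.folds:
            assert not set(train) & set(test)

    def test_test_sets_partition_subjects(self):
        ids = [f"S{i}" for i in range(17)]
        plan = make_group_folds(ids, k=4, seed=3)
        pooled = [s for _, te in plan.folds for s in te]
        assert sorted(pooled) == sorted(ids)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_group_folds(["a", "b", "c"], k=5, seed=0)

    def test_plan_serializes_to_json(self):
        plan = make_group_folds([f"S{i}" for i in range(10)], k=2, seed=1)
        assert '"folds"' in plan.to_json()


class TestCrossValidate:
    def test_separable_table_scores_high(self, rng):
        table = toy_table(rng, n_subjects=26, sep=10.0)
        plan = make_group_folds(sorted(set(table["subject_id"])), 5, seed=0)
        res = cross_validate(ModelSpec("svm", "linear"), table, plan)
        assert res.accuracy >= 0.95

    def test_permuted_labels_fall_to_chance(self, rng):
        """Labels permuted within each subject (preserving the one-row-per-
        class design, hence balanced folds) give chance-level accuracy.

        A free permutation across all rows would instead unbalance
        train/test folds in anti-correlated ways and bias CV accuracy below
        chance -- the known pessimism of permutation tests under class
        imbalance -- so the within-subject swap is the null that matches
        the protocol.
        """
        table = toy_table(rng, n_subjects=26, sep=10.0)
        accs = []
        for seed in range(10):
            perm = table.copy()
            swap = rng.random(26) < 0.5
            labels = perm["label"].to_numpy().reshape(26, 2)
            labels[swap] = labels[swap][:, ::-1]
            perm["label"] = labels.ravel()
            plan = make_group_folds(sorted(set(perm["subject_id"])), 5,
                                    seed=seed)
            accs.append(cross_validate(ModelSpec("svm", "linear"),
                                       perm, plan).accuracy)
        n = 10 * len(table)
        half_width = 1.96 * np.sqrt(0.25 / n)
        assert abs(np.mean(accs) - 0.5) < half_width + 0.05

    def test_identical_runs_are_identical(self, rng):
        table = toy_table(rng, sep=1.0)
        plan = make_group_folds(sorted(set(table["subject_id"])), 5, seed=2)
        a = cross_validate(ModelSpec("ensemble", "bagged_trees"), table, plan)
        b = cross_validate(ModelSpec("ensemble", "bagged_trees"), table, plan)
        np.testing.assert_array_equal(a.predicted_labels, b.predicted_labels)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_unknown_subjects_rejected(self, rng):
        table = toy_table(rng)
        plan = make_group_folds(sorted(set(table["subject_id"]))[:-1],
                                5, seed=0)
        with pytest.raises(ValueError, match="absent"):
            cross_validate(ModelSpec("svm", "linear"), table, plan)

    def test_repeated_cv_returns_all_repetitions(self, rng):
        table = toy_table(rng, sep=2.0)
        mean_acc, results = repeated_cv(ModelSpec("svm", "linear"), table,
                                        repetitions=4, seed=0)
        assert len(results) == 4
        assert mean_acc == pytest.approx(
            np.mean([r.accuracy for r in results]))


class TestWrapperSelect:
    def test_single_feature_is_chosen(self, rng):
        table = toy_table(rng, n_features=1)
        plan = make_group_folds(sorted(set(table["subject_id"])), 5, seed=0)
        res = wrapper_select(ModelSpec("svm", "linear"), table, plan,
                             n_subsets=50, seed=0)
        assert res.chosen == ("f0",)

    def test_requested_subset_count_drawn_distinct(self, rng):
        table = toy_table(rng, n_features=24, sep=0.0)
        plan = make_group_folds(sorted(set(table["subject_id"])), 5, seed=0)
        res = wrapper_select(ModelSpec("decision_tree", "simple"), table,
                             plan, n_subsets=50, seed=1)
        subsets = [f for f, _ in res.evaluated]
        assert len(subsets) == 50
        assert len(set(subsets)) == 50

    def test_small_feature_space_enumerated(self, rng):
        table = toy_table(rng, n_features=3)
        plan = make_group_folds(sorted(set(table["subject_id"])), 5, seed=0)
        res = wrapper_select(ModelSpec("svm", "linear"), table, plan,
                             n_subsets=50, seed=0)
        assert res.n_subsets == 7  # all non-empty subsets of 3 features

    def test_chosen_subset_attains_maximum(self, rng):
        table = toy_table(rng, n_features=6, sep=1.0)
        plan = make_group_folds(sorted(set(table["subject_id"])), 5, seed=0)
        res = wrapper_select(ModelSpec("knn", "medium"), table, plan,
                             n_subsets=30, seed=5)
        best = max(a for _, a in res.evaluated)
        assert res.accuracy == best
        assert all(res.accuracy >= a for _, a in res.evaluated)

    def test_planted_informative_features_recovered(self):
        """Two informative features among eight noise features are both in
        the chosen subset in nearly every seeded run."""
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            rows = []
            for s in range(26):
                for cls in range(2):
                    feats = rng.normal(0.0, 1.0, 10)
                    feats[0] += cls * 2.5
                    feats[1] += cls * 2.5
                    rows.append({"subject_id": f"S{s:03d}", "task": "DST",
                                 "phase": str(cls), "label": cls,
                                 **{f"f{j}": feats[j] for j in range(10)}})
            table = pd.DataFrame(rows)
            plan = make_group_folds(sorted(set(table["subject_id"])), 5,
                                    seed=seed)
            res = wrapper_select(ModelSpec("svm", "linear"), table, plan,
                                 n_subsets=50, seed=seed)
            if {"f0", "f1"} <= set(res.chosen):
                hits += 1
        assert hits / n_runs >= 0.9


class TestNestedSelection:
    def test_nested_selection_runs_and_pools_all_rows(self, rng):
        from mentalload.crossval import cross_validate_with_nested_selection

        table = toy_table(rng, n_subjects=20, n_features=6, sep=3.0)
        plan = make_group_folds(sorted(set(table["subject_id"])), 4, seed=0)
        res = cross_validate_with_nested_selection(
            ModelSpec("discriminant", "linear"), table, plan,
            n_subsets=10, seed=0)
        assert res.true_labels.size == len(table)
        assert 0.0 <= res.accuracy <= 1.0

    def test_flat_selection_is_optimistic_nested_is_not(self):
        """On pure-noise features, flat wrapper selection (subset chosen on
        the full table, then re-scored on the same folds) reports
        above-chance accuracy, while nesting the selection inside each
        training fold stays at chance."""
        from mentalload.crossval import cross_validate_with_nested_selection

        flat_accs, nested_accs = [], []
        for seed in range(3):
            rng = np.random.default_rng(300 + seed)
            table = toy_table(rng, n_subjects=20, n_features=12, sep=0.0)
            ids = sorted(set(table["subject_id"]))
            plan = make_group_folds(ids, 4, seed=seed)
            spec = ModelSpec("discriminant", "linear")
            sel = wrapper_select(spec, table, plan, n_subsets=20, seed=seed)
            flat_accs.append(sel.accuracy)
            nested = cross_validate_with_nested_selection(
                spec, table, plan, n_subsets=20, seed=seed)
            nested_accs.append(nested.accuracy)
        assert np.mean(flat_accs) > 0.55        # selection optimism
        assert abs(np.mean(nested_accs) - 0.5) < 0.12
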