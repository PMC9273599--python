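"""Univariate selection, resampling grid search and binary forest training."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from primarysite.features.matrix import FeatureMatrix, default_metadata
from primarysite.training import (
    build_resampling_grid,
    choose_resampling,
    deterministic_folds,
    resample_indices,
    train_binary_rf,
    univariate_select,
)


def _matrix(data: dict, index=None) -> FeatureMatrix:
    frame = pd.DataFrame(data, index=index)
    if index is None:
        frame.index = [f"s{i}" for i in range(len(frame))]
    return FeatureMatrix(frame.astype(float))


class TestUnivariateSelect:
    def test_cap_applies_when_many_features_pass(self):
        rng = np.random.default_rng(0)
        n_case, n_ctrl = 80, 120
        y = np.array([True] * n_case + [False] * n_ctrl)
        data = {}
        for i in range(150):  # all engineered to pass
            shift = 1.0 + 0.01 * i
            data[f"sigs.f{i:03d}"] = np.concatenate(
                [rng.normal(shift, 0.5, n_case), rng.normal(0, 0.5, n_ctrl)]
            )
        result = univariate_select(_matrix(data), y, cap=100)
        assert len(result.selected) == 100
        assert result.table["passed"].sum() > 100

    def test_constant_feature_not_selected(self):
        rng = np.random.default_rng(1)
        y = np.array([True] * 30 + [False] * 30)
        data = {
            "sigs.flat": np.ones(60),
            "sigs.good": np.concatenate([rng.normal(2, 0.3, 30), rng.normal(0, 0.3, 30)]),
        }
        result = univariate_select(_matrix(data), y)
        assert result.selected == ["sigs.good"]

    def test_perfect_boolean_separator_selected_with_effect_one(self):
        y = np.array([True] * 25 + [False] * 75)
        data = {"gene.M.amp": np.array([1.0] * 25 + [0.0] * 75)}
        result = univariate_select(_matrix(data), y)
        assert result.selected == ["gene.M.amp"]
        assert result.table.loc["gene.M.amp", "effect_size"] == pytest.approx(1.0)

    def test_two_sided_family_detects_loss(self):
        rng = np.random.default_rng(2)
        y = np.array([True] * 40 + [False] * 60)
        data = {
            "chrom_arm.1p": np.concatenate(
                [rng.normal(0.5, 0.05, 40), rng.normal(1.0, 0.05, 60)]
            )
        }
        result = univariate_select(_matrix(data), y)
        assert result.selected == ["chrom_arm.1p"]
        assert result.table.loc["chrom_arm.1p", "effect_size"] < 0

    def test_no_informative_features_raises(self):
        y = np.array([True] * 20 + [False] * 20)
        data = {"sigs.noise": np.ones(40)}
        with pytest.raises(ValueError, match="no informative features"):
            univariate_select(_matrix(data), y)


class TestResamplingGrid:
    def test_worked_example_closed_form(self):
        over, under = build_resampling_grid(25, 400)
        np.testing.assert_array_equal(over, [25, 35, 50, 71, 100])
        np.testing.assert_array_equal(under, [400, 283, 200, 141, 100])

    def test_equal_group_sizes_degenerate(self):
        over, under = build_resampling_grid(50, 50)
        assert list(over) == [50]
        assert list(under) == [50]

    def test_single_point_grid_at_geometric_mean(self):
        over, under = build_resampling_grid(25, 400, k=1)
        assert list(over) == [100]
        assert list(under) == [100]

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(2, 200),
        st.integers(2, 2000),
        st.integers(2, 8),
    )
    def test_targets_monotone_between_endpoints(self, n_case, extra, k):
        n_control = n_case + extra
        over, under = build_resampling_grid(n_case, n_control, k=k)
        g = np.sqrt(n_case * n_control)
        assert len(over) == len(under) == k
        assert over[0] == n_case and under[0] == n_control
        assert (np.diff(over) >= 0).all()
        assert (np.diff(under) <= 0).all()
        assert abs(over[-1] - g) <= 0.5 + 1e-9
        assert abs(under[-1] - g) <= 0.5 + 1e-9

    def test_resample_indices_hit_targets(self):
        y = np.array([True] * 10 + [False] * 100)
        rng = np.random.default_rng(3)
        idx = resample_indices(y, 30, 60, rng)
        assert (y[idx]).sum() == 30
        assert (~y[idx]).sum() == 60
        # undersampling is without replacement
        ctrl = idx[~y[idx]]
        assert len(np.unique(ctrl)) == 60


class TestChooseResampling:
    def _separable(self, n_case=12, n_ctrl=60, seed=4):
        rng = np.random.default_rng(seed)
        y = np.array([True] * n_case + [False] * n_ctrl)
        X = pd.DataFrame(
            {
                "sigs.a": np.concatenate(
                    [rng.normal(3, 0.2, n_case), rng.normal(0, 0.2, n_ctrl)]
                )
            },
            index=[f"s{i}" for i in range(n_case + n_ctrl)],
        )
        return X, y

    def test_separable_data_tie_breaks_to_least_distorting(self):
        X, y = self._separable()
        choice = choose_resampling(X, y, folds=3, seed=5, n_trees=10)
        assert (choice.mean_auprc.to_numpy() == 1.0).all()
        assert choice.chosen == (int(y.sum()), int((~y).sum()))

    def test_same_seed_same_choice(self):
        X, y = self._separable(seed=6)
        a = choose_resampling(X, y, folds=3, seed=7, n_trees=10)
        b = choose_resampling(X, y, folds=3, seed=7, n_trees=10)
        assert a.chosen == b.chosen
        pd.testing.assert_frame_equal(a.mean_auprc, b.mean_auprc)


class TestBinaryForest:
    def test_memorizes_separable_training_data(self):
        rng = np.random.default_rng(8)
        y = np.array([1] * 20 + [0] * 40)
        X = pd.DataFrame(
            {"sigs.a": np.concatenate([rng.normal(4, 0.3, 20), rng.normal(0, 0.3, 40)])}
        )
        model = train_binary_rf(X, y, seed=9, n_trees=50)
        probs = model.predict_proba(X)
        assert probs[y == 1].min() > probs[y == 0].max()
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(10)
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]
        X = pd.DataFrame({"sigs.a": rng.normal(size=50), "sigs.b": rng.normal(size=50)})
        p1 = train_binary_rf(X, y, seed=11, n_trees=30).predict_proba(X)
        p2 = train_binary_rf(X, y, seed=11, n_trees=30).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"sigs.a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="single-class"):
            train_binary_rf(X, np.array([1, 1, 1]), seed=0)


class TestDeterministicFolds:
    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(12)
        y = np.array(["A"] * 45 + ["B"] * 105)
        ids = [f"s{i}" for i in range(150)]
        folds = deterministic_folds(ids, y, 5, seed=13)
        for f in range(5):
            in_fold = folds == f
            assert abs((y[in_fold] == "A").sum() - 9) <= 1
            assert abs((y[in_fold] == "B").sum() - 21) <= 1

    def test_reproducible_and_seed_sensitive(self):
        y = np.array([0, 1] * 20)
        ids = [f"s{i}" for i in range(40)]
        a = deterministic_folds(ids, y, 4, seed=1)
        b = deterministic_folds(ids, y, 4, seed=1)
        c = deterministic_folds(ids, y, 4, seed=2)
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()
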