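"""Preprocessing: cleaning, min-max scaling, splits, BR/LP transforms and
the association loss."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import expotox as ex
from expotox.prep import EmptyDatasetError


def _table(features: pd.DataFrame) -> ex.HealthTable:
    n = len(features)
    return ex.HealthTable(
        features=features,
        labels=pd.DataFrame({"l": np.zeros(n, dtype=int)}),
        timestamps=pd.Series(pd.date_range("2020-01-01", periods=n)),
    )


class TestCleanRecords:
    def test_drop_count_by_enumeration(self):
        # 10 rows, 3 of them missing 3/10 features (> 0.2 threshold)
        feats = pd.DataFrame(np.ones((10, 10)))
        for row in (1, 4, 7):
            feats.iloc[row, :3] = np.nan
        cleaned = ex.clean_records(_table(feats), 0.2)
        assert cleaned.n_dropped == 3
        assert len(cleaned) == 7

    def test_retained_row_not_modified(self):
        feats = pd.DataFrame(np.arange(20.0).reshape(4, 5))
        cleaned = ex.clean_records(_table(feats), 0.2)
        assert cleaned.n_dropped == 0
        np.testing.assert_allclose(cleaned.features.to_numpy(),
                                   feats.to_numpy())

    def test_subthreshold_missing_imputed_with_median(self):
        feats = pd.DataFrame({"a": [1.0, np.nan, 3.0, 5.0],
                              "b": [1.0, 1.0, 1.0, 1.0]})
        cleaned = ex.clean_records(_table(feats), 0.6)
        assert cleaned.features.loc[1, "a"] == 3.0  # median of 1,3,5
        assert not cleaned.features.isna().any().any()

    def test_all_rows_dropped_is_error(self):
        feats = pd.DataFrame(np.full((3, 4), np.nan))
        with pytest.raises(EmptyDatasetError):
            ex.clean_records(_table(feats), 0.2)


class TestMinMax:
    def test_basic_scaling(self):
        df = pd.DataFrame({"x": [1.0, 3.0, 5.0]})
        params = ex.minmax_fit(df)
        out = ex.minmax_apply(df, params)
        np.testing.assert_allclose(out["x"], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        df = pd.DataFrame({"x": [4.0, 4.0, 4.0]})
        out = ex.minmax_apply(df, ex.minmax_fit(df))
        np.testing.assert_allclose(out["x"], 0.0)

    def test_out_of_range_extrapolates(self):
        params = ex.minmax_fit(pd.DataFrame({"x": [0.0, 10.0]}))
        out = ex.minmax_apply(pd.DataFrame({"x": [12.0]}), params)
        assert out["x"].iloc[0] == pytest.approx(1.2)

    def test_training_split_output_in_unit_interval(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = ex.minmax_apply(df, ex.minmax_fit(df))
        assert (out.to_numpy() >= 0).all() and (out.to_numpy() <= 1).all()

    def test_idempotent_on_normalized_training_data(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 1, size=(30, 3)))
        once = ex.minmax_apply(df, ex.minmax_fit(df))
        twice = ex.minmax_apply(once, ex.minmax_fit(once))
        pd.testing.assert_frame_equal(once, twice)

    def test_yaml_round_trip(self, tmp_path):
        params = ex.minmax_fit(pd.DataFrame({"x": [1.0, 2.0], "y": [0., 9.]}))
        p = tmp_path / "norm.yaml"
        params.to_yaml(p)
        back = ex.NormalizationParams.from_yaml(p)
        pd.testing.assert_series_equal(params.minimum, back.minimum,
                                       check_names=False)


class TestSplit:
    def test_80_20_split_sizes(self, health_panel):
        train, test = ex.split_train_test(health_panel, 0.8, seed=0)
        assert len(train) == 4000 and len(test) == 1000

    def test_same_seed_identical(self, health_panel):
        a_tr, _ = ex.split_train_test(health_panel, 0.8, seed=4)
        b_tr, _ = ex.split_train_test(health_panel, 0.8, seed=4)
        pd.testing.assert_frame_equal(a_tr.features, b_tr.features)

    def test_invalid_fraction(self, health_panel):
        with pytest.raises(ValueError):
            ex.split_train_test(health_panel, 1.2)

    def test_stratified_proportions(self, health_panel):
        train, test = ex.split_train_test(health_panel, 0.8, seed=0,
                                          stratify_lp=True)
        lp_all = ex.lp_transform(ex.MultiLabelSet.from_table(health_panel))
        lp_tr = ex.lp_transform(ex.MultiLabelSet.from_table(train))
        # per-class training share within 1 record of the global fraction
        all_combos = {tuple(c): n for c, n in zip(
            *np.unique(lp_all.inverse(), axis=0, return_counts=True))}
        tr_combos = {tuple(c): n for c, n in zip(
            *np.unique(lp_tr.inverse(), axis=0, return_counts=True))}
        for combo, n_total in all_combos.items():
            n_tr = tr_combos.get(combo, 0)
            assert abs(n_tr - 0.8 * n_total) <= 1.0


class TestLabelTransforms:
    def test_br_yields_one_dataset_per_label(self, small_labels):
        br = ex.br_transform(small_labels)
        assert set(br.targets) == {"a", "b", "c"}
        np.testing.assert_array_equal(br.targets["a"],
                                      small_labels.matrix[:, 0])

    def test_lp_distinct_rows(self):
        labels = ex.MultiLabelSet(["a", "b"],
                                  np.array([[1, 0], [0, 1], [1, 1]]))
        lp = ex.lp_transform(labels)
        assert lp.n_classes == 3
        # first-occurrence ordering
        np.testing.assert_array_equal(lp.classes, [0, 1, 2])

    def test_lp_all_zero_rows_single_class(self):
        labels = ex.MultiLabelSet(["a", "b"], np.zeros((4, 2), dtype=int))
        assert ex.lp_transform(labels).n_classes == 1

    def test_lp_inverse_round_trip(self, small_labels):
        lp = ex.lp_transform(small_labels)
        np.testing.assert_array_equal(lp.inverse(), small_labels.matrix)

    def test_binary_matrix_enforced(self):
        with pytest.raises(ValueError):
            ex.MultiLabelSet(["a"], np.array([[2], [0]]))


class TestAssociationLoss:
    def test_identical_columns_alpha_one(self):
        m = np.array([[1, 1], [0, 0], [1, 1], [0, 0]])
        spec = ex.pearson_alpha(ex.MultiLabelSet(["a", "b"], m), anchor=0)
        assert spec.alpha[1] == pytest.approx(1.0)

    def test_complementary_columns_alpha_minus_one(self):
        m = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        spec = ex.pearson_alpha(ex.MultiLabelSet(["a", "b"], m), anchor=0)
        assert spec.alpha[1] == pytest.approx(-1.0)

    def test_orthogonal_balanced_alpha_zero(self):
        m = np.column_stack([[1, 1, 0, 0], [1, 0, 1, 0]])
        spec = ex.pearson_alpha(ex.MultiLabelSet(["a", "b"], m), anchor=0)
        assert spec.alpha[1] == pytest.approx(0.0)

    def test_zero_variance_label_warns_alpha_zero(self):
        m = np.column_stack([[1, 0, 1, 0], [1, 1, 1, 1]])
        with pytest.warns(RuntimeWarning):
            spec = ex.pearson_alpha(ex.MultiLabelSet(["a", "b"], m), anchor=0)
        assert spec.alpha[1] == 0.0

    @pytest.mark.parametrize("alpha,losses,expected", [
        (0.0, [1.0, 0.4], 1.0),
        (0.5, [1.0, 0.4], 1.2),
        (-0.5, [1.0, 0.4], 0.8),
    ])
    def test_combined_loss_values(self, alpha, losses, expected):
        spec = ex.AssociationLossSpec(anchor=0, alpha=np.array([0.0, alpha]))
        assert ex.association_loss(np.array(losses), spec) == \
            pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        spec = ex.AssociationLossSpec(anchor=0, alpha=np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            ex.association_loss(np.array([1.0, 0.4, 0.2]), spec)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 10), min_size=3, max_size=3),
           st.lists(st.floats(-1, 1), min_size=2, max_size=2))
    def test_linearity_in_losses(self, losses, alphas):
        """CL is linear with coefficients (1, alpha_1, ..., alpha_l)."""
        spec = ex.AssociationLossSpec(anchor=0,
                                      alpha=np.array([0.0] + alphas))
        losses = np.asarray(losses)
        expected = losses[0] + alphas[0] * losses[1] + alphas[1] * losses[2]
        assert ex.association_loss(losses, spec) == pytest.approx(expected)
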