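"""Filtering, quantile normalization, missingness labels and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_matrix
from kea import (classify_missingness, drop_underquantified, filter_sites,
                 impute, log2_transform, quantile_normalize)


def raw_matrix(values, conditions, loc_probs=None, reverse=None, contaminant=None):
    n = len(values)
    meta = pd.DataFrame(
        {
            "localization_prob": loc_probs if loc_probs is not None else [1.0] * n,
            "is_reverse": reverse if reverse is not None else [False] * n,
            "is_contaminant": contaminant if contaminant is not None else [False] * n,
        },
        index=pd.Index([f"G{i}_S{i + 1}_m1" for i in range(n)], name="site"),
    )
    return make_matrix(values, conditions, stage="raw", scale="linear", meta=meta)


class TestFilter:
    def test_localization_probability_boundary(self):
        m = raw_matrix([[8, 8], [8, 8]], ["a", "a"], loc_probs=[0.75, 0.749])
        out = filter_sites(m)
        assert list(out.data.index) == ["G0_S1_m1"]  # 0.75 kept, 0.749 removed

    def test_reverse_flag_overrides_probability(self):
        m = raw_matrix([[8, 8], [8, 8]], ["a", "a"], reverse=[True, False])
        out = filter_sites(m)
        assert list(out.data.index) == ["G1_S2_m1"]

    def test_clean_matrix_unchanged(self):
        m = raw_matrix([[8, 8], [8, 8]], ["a", "a"])
        out = filter_sites(m)
        assert out.data.equals(m.data)
        assert out.stage == "filtered"

    def test_all_removed_is_an_error(self):
        m = raw_matrix([[8, 8]], ["a", "a"], contaminant=[True])
        with pytest.raises(ValueError, match="empty"):
            filter_sites(m)

    def test_filtering_is_monotone_in_rows(self):
        base = raw_matrix([[8, 8], [8, 8]], ["a", "a"], loc_probs=[0.9, 0.95])
        kept_before = set(filter_sites(base).data.index)
        bigger = raw_matrix([[8, 8], [8, 8], [8, 8]], ["a", "a"],
                            loc_probs=[0.9, 0.95, 0.2])
        kept_after = set(filter_sites(bigger).data.index)
        assert kept_before <= kept_after


class TestLog2:
    def test_known_value_and_missing_passthrough(self):
        m = raw_matrix([[1024.0, np.nan]], ["a", "a"])
        m = filter_sites(m)
        out = log2_transform(m)
        assert out.data.iloc[0, 0] == 10.0
        assert np.isnan(out.data.iloc[0, 1])

    def test_roundtrip_inverts(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(10, 1, size=(50, 4))
        m = log2_transform(filter_sites(raw_matrix(vals, ["a", "a", "b", "b"])))
        back = 2.0 ** m.data.to_numpy()
        assert np.allclose(back, vals, rtol=1e-9)

    def test_nonpositive_value_rejected(self):
        m = filter_sites(raw_matrix([[0.0, 5.0]], ["a", "a"]))
        with pytest.raises(ValueError):
            log2_transform(m)


def qnorm(values, conditions):
    m = make_matrix(values, conditions, stage="filtered", scale="log2")
    return quantile_normalize(m)


class TestQuantileNormalize:
    def test_hand_computed_two_column_oracle(self):
        # sort: (1,3) and (2,4); row means (1.5, 3.5); restore by rank
        out = qnorm([[1, 2], [3, 4]], ["a", "b"])
        assert np.allclose(out.data.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_are_a_fixed_point(self):
        vals = np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        out = qnorm(vals, ["a", "b"])
        assert np.allclose(out.data.to_numpy(), vals)

    def test_columns_share_sorted_values_after_normalization(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 2, size=(40, 4)) * [1.0, 1.1, 0.9, 1.3]
        out = qnorm(vals, ["a", "a", "b", "b"]).data.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_idempotent_on_complete_data(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 2, size=(30, 3))
        once = qnorm(vals, ["a", "a", "b"])
        twice = quantile_normalize(once)
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy())

    def test_missing_cells_stay_missing(self):
        vals = np.array([[1.0, np.nan], [3.0, 4.0], [2.0, 6.0]])
        out = qnorm(vals, ["a", "b"])
        assert np.isnan(out.data.iloc[0, 1])
        assert out.data.notna().sum().sum() == 5


class TestMissingness:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((12.1, 11.8, np.nan), "MAR"),
            ((12.1, np.nan, np.nan), "MNAR"),
            ((np.nan, np.nan, np.nan), "MNAR"),
            ((12.1, 11.8, 12.0), "complete"),
        ],
    )
    def test_one_of_three_rule(self, row, expected):
        m = make_matrix([row], ["a", "a", "a"])
        labels = classify_missingness(m)
        assert labels.loc[m.data.index[0], "a"] == expected

    def test_labels_partition_all_pairs(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(30, 6))
        vals[rng.random(vals.shape) < 0.4] = np.nan
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        labels = classify_missingness(m)
        assert labels.shape == (30, 2)
        assert labels.isin(["complete", "MAR", "MNAR"]).all().all()


class TestDropUnderquantified:
    def test_single_observation_row_removed(self):
        vals = [[1.0] + [np.nan] * 5, [1.0, 2.0] + [np.nan] * 4]
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3, stage="filtered")
        out = drop_underquantified(m)
        assert list(out.data.index) == [m.data.index[1]]

    def test_fully_observed_unchanged(self):
        m = make_matrix(np.ones((4, 6)), ["a"] * 3 + ["b"] * 3, stage="filtered")
        assert drop_underquantified(m).data.equals(m.data)


class TestImpute:
    def norm_matrix(self, vals, conditions):
        return make_matrix(vals, conditions, stage="normalized", scale="log2")

    def test_complete_matrix_identity(self):
        m = self.norm_matrix(np.arange(18.0).reshape(3, 6) + 10, ["a"] * 3 + ["b"] * 3)
        out = impute(m, seed=0)
        assert out.data.equals(m.data)
        assert out.stage == "imputed"

    def test_observed_cells_never_altered_and_seed_determinism(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 2, size=(60, 6))
        vals[rng.random(vals.shape) < 0.25] = np.nan
        m = self.norm_matrix(vals, ["a"] * 3 + ["b"] * 3)
        out1 = impute(m, seed=1)
        out2 = impute(m, seed=1)
        out3 = impute(m, seed=2)
        obs = m.data.notna()
        assert out1.data[obs].equals(m.data[obs])
        assert out1.data.equals(out2.data)  # bit-identical for one seed
        # different seeds differ only in imputed cells
        assert out3.data[obs].equals(m.data[obs])
        assert not out1.data.equals(out3.data)
        assert out1.data.notna().all().all()

    def test_minprob_draw_mean_matches_low_quantile(self):
        # 10,000 MNAR cells in one sample: the draw mean must sit within
        # 3 standard errors of that sample's 0.01-quantile
        rng = np.random.default_rng(7)
        n = 20000
        vals = rng.normal(20, 2, size=(n, 4))
        mnar = np.zeros(n, dtype=bool)
        mnar[:10000] = True
        vals[mnar, 0] = np.nan
        vals[mnar, 1] = np.nan  # two missing of 4 -> MNAR condition
        m = self.norm_matrix(vals, ["a"] * 4)
        out = impute(m, seed=8)
        drawn = out.data.to_numpy()[mnar, 0]
        obs = vals[~mnar, 0]
        q = np.quantile(obs, 0.01)
        sigma = 0.3 * obs.std(ddof=1)
        se = sigma / np.sqrt(mnar.sum())
        assert abs(drawn.mean() - q) < 3 * se

    def test_mar_fill_uses_condition_structure(self):
        # strongly correlated replicates: the EM conditional mean should
        # land near the observed replicates, not the global mean
        rng = np.random.default_rng(9)
        base = rng.normal(20, 3, size=400)
        vals = np.column_stack([base + rng.normal(0, 0.1, 400) for _ in range(3)])
        vals[0, 2] = np.nan  # one MAR cell in a high-signal row
        vals[0, :2] = [27.0, 27.2]
        m = self.norm_matrix(vals, ["a"] * 3)
        out = impute(m, seed=10)
        assert abs(out.data.iloc[0, 2] - 27.1) < 0.5

    def test_zero_mode_sets_mnar_to_zero(self):
        vals = np.full((6, 6), 20.0)
        vals[0, 3:] = np.nan  # MNAR in condition b
        vals[1, 5] = np.nan  # MAR in condition b
        m = self.norm_matrix(vals, ["a"] * 3 + ["b"] * 3)
        out = impute(m, mode="zero", seed=0)
        assert (out.data.iloc[0, 3:] == 0.0).all()
        assert np.isfinite(out.data.iloc[1, 5]) and out.data.iloc[1, 5] != 0.0

    def test_sample_with_too_few_observations_rejected(self):
        vals = np.full((3, 4), np.nan)
        vals[:, 0] = [1.0, 2.0, 3.0]
        vals[0, 1] = 1.0
        vals[:2, 2] = [1.0, 2.0]
        vals[:2, 3] = [1.0, 2.0]
        m = self.norm_matrix(vals, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than 2 observed"):
            impute(m, seed=0)


@given(st.integers(min_value=0, max_value=3))
def test_missingness_label_follows_missing_count(n_missing):
    row = [15.0, 16.0, 17.0]
    for i in range(n_missing):
        row[i] = np.nan
    m = make_matrix([row], ["a", "a", "a"])
    label = classify_missingness(m).iloc[0, 0]
    expected = {0: "complete", 1: "MAR"}.get(n_missing, "MNAR")
    assert label == expected
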