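import numpy as np
import pytest

from mpcms1.preprocess import (
    build_missing_mask,
    compute_quartiles,
    filter_by_group_prevalence,
    impute_knn,
    log2_transform,
    normalize_median_ratio,
)
from mpcms1.types import DesignTable, IntensityMatrix


def _mat(values, **kw):
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    return IntensityMatrix(
        values=values,
        feature_ids=[f"f{i}" for i in range(nf)],
        sample_ids=[f"s{j}" for j in range(ns)],
        **kw,
    )


class TestQuartiles:
    def test_constant_data(self):
        q = compute_quartiles(_mat(np.full((2, 4), 7.0)))
        assert (q.q1, q.q2, q.q3) == (7, 7, 7)

    def test_linear_interpolation_on_1_to_8(self):
        q = compute_quartiles(_mat(np.arange(1.0, 9.0).reshape(2, 4)))
        assert (q.q1, q.q2, q.q3) == (2.75, 4.5, 6.25)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(15, 2, size=(10, 6))
        q1 = compute_quartiles(_mat(v))
        q2 = compute_quartiles(_mat(v[:, ::-1]))
        assert (q1.q1, q1.q2, q1.q3) == (q2.q1, q2.q2, q2.q3)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            compute_quartiles(_mat(np.full((2, 4), np.nan)))


class TestMissingMask:
    def test_zero_threshold_all_false(self):
        mask = build_missing_mask(_mat(np.ones((3, 3))), threshold=0.0)
        assert not mask.any()

    def test_q3_threshold_flags_three_quarters(self):
        v = np.arange(1.0, 101.0).reshape(10, 10)
        m = _mat(v)
        q = compute_quartiles(m)
        mask = build_missing_mask(m, threshold=q.q3, mode="filtering")
        assert mask.mean() == pytest.approx(0.75, abs=0.02)

    def test_strict_mode_ignores_threshold(self):
        v = np.array([[1.0, np.nan], [5.0, 6.0]])
        mask = build_missing_mask(_mat(v), threshold=100.0, mode="strict")
        np.testing.assert_array_equal(mask, np.isnan(v))


class TestPrevalenceFilter:
    def make(self, present_a, present_b):
        # 1 feature, groups of 4; mask True = missing
        mask = np.ones((1, 8), dtype=bool)
        mask[0, :present_a] = False
        mask[0, 4 : 4 + present_b] = False
        m = _mat(np.where(mask, np.nan, 5.0))
        design = DesignTable(
            sample_ids=[f"s{j}" for j in range(8)],
            condition=["A"] * 4 + ["B"] * 4,
        )
        return m, mask, design

    @pytest.mark.parametrize(
        "a,b,kept", [(2, 3, True), (1, 4, False), (4, 4, True), (2, 2, True), (0, 4, False)]
    )
    def test_fifty_percent_rule_per_group(self, a, b, kept):
        m, mask, design = self.make(a, b)
        out = filter_by_group_prevalence(m, mask, design, min_frac=0.5)
        assert (out.n_features == 1) is kept

    def test_min_frac_one_requires_completeness(self):
        m, mask, design = self.make(4, 3)
        assert filter_by_group_prevalence(m, mask, design, min_frac=1.0).n_features == 0

    def test_all_observed_nothing_dropped(self):
        rng = np.random.default_rng(1)
        m = _mat(rng.lognormal(15, 1, (20, 8)))
        design = DesignTable(
            sample_ids=m.sample_ids, condition=["A"] * 4 + ["B"] * 4
        )
        out = filter_by_group_prevalence(
            m, np.zeros(m.values.shape, bool), design, min_frac=1.0
        )
        assert out.n_features == 20

    def test_survivors_keep_subthreshold_values(self):
        # low observed values are flagged for filtering but retained afterwards
        v = np.array([[1.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]])
        mask = v < 50  # the low value counts as missing for filtering only
        m = _mat(v)
        design = DesignTable(
            sample_ids=m.sample_ids, condition=["A"] * 4 + ["B"] * 4
        )
        out = filter_by_group_prevalence(m, mask, design)
        assert out.values[0, 0] == 1.0


class TestImputeKnn:
    def test_twin_feature_supplies_value(self):
        v = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, np.nan, 4.0],
                [50.0, 60.0, 70.0, 80.0],
            ]
        )
        out = impute_knn(_mat(v), k=1)
        assert out.values[1, 2] == pytest.approx(3.0)

    def test_rowmax_fallback_uses_feature_mean(self):
        v = np.vstack(
            [
                np.array([np.nan, np.nan, np.nan, 2.0, 4.0]),  # 60% missing
                np.tile(np.array([1.0, 1.0, 2.0, 2.0, 3.0]), (4, 1)),
            ]
        )
        out = impute_knn(_mat(v), k=2, rowmax=0.5)
        np.testing.assert_allclose(out.values[0, :3], 3.0)

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(10, 1, (6, 5))
        out = impute_knn(_mat(v))
        np.testing.assert_array_equal(out.values, v)

    def test_colmax_violation_names_sample(self):
        v = np.array([[np.nan, 1.0], [np.nan, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="s0"):
            impute_knn(_mat(v), colmax=0.5)


class TestNormalization:
    def test_hand_computed_two_by_two(self):
        m = _mat([[2.0, 4.0], [8.0, 16.0]])
        out, sf = normalize_median_ratio(m)
        # geometric means: sqrt(8)=2.83, sqrt(128)=11.3; ratios col2/col1 = 2
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-12)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], rtol=1e-12)

    def test_single_sample_identity(self):
        m = _mat([[3.0], [5.0]])
        out, sf = normalize_median_ratio(m)
        assert sf[0] == pytest.approx(1.0)
        np.testing.assert_allclose(out.values, m.values)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(2, 1, (10, 6))
        out, sf = normalize_median_ratio(_mat(v))
        # independent brute-force: per-feature geometric mean, median of ratios
        ref = np.array([np.prod(row) ** (1 / len(row)) for row in v])
        sf_oracle = np.array(
            [np.median([v[i, j] / ref[i] for i in range(10)]) for j in range(6)]
        )
        np.testing.assert_allclose(sf, sf_oracle, rtol=1e-12)
        np.testing.assert_allclose(out.values, v / sf_oracle, rtol=1e-12)

    def test_removes_planted_scaling(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(3, 1, size=(30, 1))
        scales = np.array([1.0, 2.5, 0.3, 7.0])
        m = _mat(base * scales)
        out, _ = normalize_median_ratio(m)
        for j in range(1, 4):
            np.testing.assert_allclose(out.values[:, j], out.values[:, 0], rtol=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            normalize_median_ratio(_mat([[1.0, 0.0], [2.0, 3.0]]))


class TestLog2:
    def test_values_and_monotonicity(self):
        m = _mat([[8.0, 1.0], [2.0, 4.0]])
        out = log2_transform(m)
        np.testing.assert_allclose(out.values, [[3.0, 0.0], [1.0, 2.0]])
        rng = np.random.default_rng(5)
        v = rng.lognormal(2, 1, (10, 3))
        lo = log2_transform(_mat(v)).values
        for j in range(3):
            assert (np.argsort(lo[:, j]) == np.argsort(v[:, j])).all()

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log2_transform(_mat([[1.0, -2.0]]))
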