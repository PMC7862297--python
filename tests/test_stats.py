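"""Group statistics: oracle equivalence, correction, end-to-end contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

import qeegpain as qp
from qeegpain.errors import StatsError
from qeegpain.stats import DunnResult

from conftest import make_feature_dataset
from oracle_stats import brute_dunn, brute_kruskal_h, brute_welch

small_integer_groups = st.lists(
    st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=6),
    min_size=2,
    max_size=4,
).filter(lambda groups: sum(len(g) for g in groups) <= 12)


class TestWelch:
    def test_hand_arithmetic_oracle(self):
        """t and Welch-Satterthwaite df computed by direct formula."""
        result = qp.welch_t_test([1, 2, 3], [2, 4, 6])
        t_expected, df_expected = brute_welch([1, 2, 3], [2, 4, 6])
        assert result.statistic == pytest.approx(t_expected, abs=1e-12)
        assert result.df == pytest.approx(df_expected, abs=1e-12)
        assert result.statistic == pytest.approx(-1.549, abs=1e-3)

    def test_identical_samples(self):
        result = qp.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_undersized_rejected(self):
        with pytest.raises(StatsError):
            qp.welch_t_test([1.0], [1.0, 2.0])

    def test_reduces_to_student_t_for_equal_sizes(self):
        """Equal group sizes: Welch's statistic equals Student's exactly."""
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(20), rng.standard_normal(20) + 0.5
        welch = qp.welch_t_test(x, y)
        student = sstats.ttest_ind(x, y, equal_var=True)
        assert welch.statistic == pytest.approx(float(student.statistic), abs=1e-9)

    def test_type_i_error_rate(self):
        """Null simulation: rejection rate at alpha=0.05 within 0.05 +/- 0.02."""
        rng = np.random.default_rng(42)
        x = rng.standard_normal((50, 1000))
        y = rng.standard_normal((50, 1000))
        p = sstats.ttest_ind(x, y, equal_var=False, axis=0).pvalue
        # spot-check the vectorized nulls against our scalar implementation
        assert qp.welch_t_test(x[:, 0], y[:, 0]).p_value == pytest.approx(p[0])
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07


class TestKruskalWallis:
    def test_exhaustive_rank_oracle_value(self):
        h, _ = qp.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert brute_kruskal_h([[1, 2, 3], [4, 5, 6], [7, 8, 9]]) == pytest.approx(7.2)

    @settings(deadline=None, max_examples=60)
    @given(small_integer_groups)
    def test_matches_brute_force_on_small_integer_inputs(self, groups):
        pooled = [v for g in groups for v in g]
        h_oracle = brute_kruskal_h(groups)
        if all(v == pooled[0] for v in pooled):
            assert qp.kruskal_wallis(groups)[0] == 0.0
        else:
            h, _ = qp.kruskal_wallis(groups)
            assert h == pytest.approx(h_oracle, abs=1e-9)

    def test_all_identical_constants(self):
        h, p = qp.kruskal_wallis([[3, 3], [3, 3, 3], [3]])
        assert h == 0.0 and p == 1.0

    def test_group_order_symmetry(self):
        a = qp.kruskal_wallis([[1, 5, 3], [9, 2], [4, 4, 8]])
        b = qp.kruskal_wallis([[4, 4, 8], [1, 5, 3], [9, 2]])
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            qp.kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_four_groups_give_six_pairs(self):
        results = qp.dunn_posthoc([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert len(results) == 6
        assert [(r.group_i, r.group_j) for r in results] == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
        ]

    @settings(deadline=None, max_examples=60)
    @given(small_integer_groups)
    def test_matches_brute_force_on_small_integer_inputs(self, groups):
        results = qp.dunn_posthoc(groups)
        for got, (i, j, z, p) in zip(results, brute_dunn(groups)):
            assert (got.group_i, got.group_j) == (i, j)
            assert got.z == pytest.approx(z, abs=1e-9)
            assert got.p_value == pytest.approx(p, abs=1e-9)

    def test_well_separated_pair_has_largest_z(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5], [100, 101, 102]]
        results = qp.dunn_posthoc(groups)
        largest = max(results, key=lambda r: abs(r.z))
        assert (largest.group_i, largest.group_j) == (0, 3)

    def test_duplicate_group_z_zero(self):
        results = qp.dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert results[0].z == pytest.approx(0.0, abs=1e-12)
        assert results[0].p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            qp.dunn_posthoc([[1, 2], []])


class TestBonferroni:
    @pytest.mark.parametrize(
        ("p", "m", "expected"),
        [(0.001, 35, 0.035), (0.5, 35, 1.0), (0.2, 1, 0.2)],
    )
    def test_arithmetic(self, p, m, expected):
        assert qp.bonferroni([p], m)[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            qp.bonferroni([1.5], 10)

    def test_family_smaller_than_pvalues_rejected(self):
        with pytest.raises(StatsError):
            qp.bonferroni([0.1, 0.2, 0.3], 2)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20),
        st.integers(min_value=0, max_value=50),
    )
    def test_monotone_and_order_preserving(self, p_values, extra):
        m = len(p_values) + extra
        corrected = qp.bonferroni(p_values, m)
        assert np.all(corrected >= np.asarray(p_values))
        assert np.all(corrected <= 1.0)
        order = np.argsort(p_values, kind="stable")
        assert np.all(np.diff(np.asarray(corrected)[order]) >= -1e-15)


class TestPerFrequencyComparison:
    def two_group_dataset(self, n_per_group=40, boosted_hz=13, boost=4.0, seed=0):
        """Flat-spectrum windows; pain(+) boosted at one frequency."""
        rng = np.random.default_rng(seed)
        features = rng.chisquare(20, size=(2 * n_per_group, 35)) / 20.0
        features[n_per_group:, boosted_hz - 1] *= boost
        quartiles = ["none"] * n_per_group + ["moderate"] * n_per_group
        nrs = [0] * n_per_group + [5] * n_per_group
        return make_feature_dataset(features, quartiles, nrs=nrs)

    def test_single_boosted_frequency_detected(self):
        dataset = self.two_group_dataset()
        result = qp.per_frequency_comparison(dataset, scheme="pain-binary")
        assert result.shape[0] == 35
        boosted = result[result["frequency_hz"] == 13].iloc[0]
        assert boosted["significant"] and boosted["statistic"] > 0
        others = result[result["frequency_hz"] != 13]
        assert (~others["significant"]).sum() >= 30

    def test_null_calibration_permuted_labels(self):
        """Permuted labels: mean significant count stays near alpha level."""
        rng = np.random.default_rng(5)
        counts = []
        for r in range(40):
            features = rng.chisquare(20, size=(60, 35)) / 20.0
            quartiles = list(rng.permutation(["none"] * 30 + ["moderate"] * 30))
            nrs = [0 if q == "none" else 5 for q in quartiles]
            dataset = make_feature_dataset(features, quartiles, nrs=nrs)
            result = qp.per_frequency_comparison(dataset, scheme="pain-binary")
            counts.append(result["significant"].sum())
        assert np.mean(counts) <= 35 * 0.05 * 2

    def test_quartile_scheme_shape(self, default_dataset):
        result = qp.per_frequency_comparison(default_dataset, scheme="quartiles")
        assert result.shape[0] == 6 * 35
        assert result["contrast"].nunique() == 6
        assert set(result["test"]) == {"dunn"}
        assert result.equals(result.sort_values(["contrast", "frequency_hz"], kind="stable").reset_index(drop=True))

    def test_corrected_p_dominates_raw(self, default_dataset):
        result = qp.per_frequency_comparison(default_dataset, scheme="quartiles")
        assert np.all(result["p_corrected"] >= result["p_raw"] - 1e-15)
        assert np.all(result["p_corrected"] <= 1.0)

    def test_unprotected_significance_matches_alpha_rule(self, default_dataset):
        result = qp.per_frequency_comparison(
            default_dataset, scheme="quartiles", protected=False
        )
        np.testing.assert_array_equal(
            result["significant"], result["p_corrected"] < 0.05
        )

    def test_protected_mode_requires_omnibus(self, default_dataset):
        result = qp.per_frequency_comparison(
            default_dataset, scheme="quartiles", protected=True
        )
        gated = result[result["omnibus_p"] >= 0.05]
        assert not gated["significant"].any()

    def test_session_unit_reduces_rows(self, default_dataset):
        result = qp.per_frequency_comparison(
            default_dataset, scheme="pain-binary", unit="session"
        )
        # 46 sessions -> Welch df bounded by the smaller group sizes
        assert result.shape[0] == 35
        assert (result["df"] < 46).all()

    def test_empty_group_rejected(self):
        features = np.random.default_rng(0).random((10, 35))
        dataset = make_feature_dataset(features, ["none"] * 10, nrs=[0] * 10)
        with pytest.raises(StatsError):
            qp.per_frequency_comparison(dataset, scheme="pain-binary")
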