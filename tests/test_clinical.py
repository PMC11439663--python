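import numpy as np
import pytest

from pscdkit.clinical import (
    SubjectRecord,
    classify_decliner,
    cohen_d,
    group_compare,
    interaction_regression,
    match_controls,
    rank_correlation,
    voxelwise_logistic,
)
from pscdkit.imaging import LabeledVolume

from _oracles import fisher_exact_oracle, spearman_oracle


class TestClassifyDecliner:
    def test_group_median_profiles(self):
        # decliner medians: baseline 29, change -6.0, interval 68.3 months
        assert classify_decliner(29, 23, 68.3) == "decliner"
        # non-decliner medians: change 0 over 67.8 months
        assert classify_decliner(27, 27, 67.8) == "non_decliner"

    def test_slow_small_drop_is_non_decliner(self):
        # 2 points over 24 months: rate -1/yr and |drop| < 3
        assert classify_decliner(28, 26, 24) == "non_decliner"

    def test_moderate_drop_is_indeterminate(self):
        # 4 points over 48 months: rate -1/yr but drop in [3, 5)
        assert classify_decliner(29, 25, 48) == "indeterminate"

    def test_fast_rate_alone_suffices(self):
        assert classify_decliner(30, 26, 12) == "decliner"

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            classify_decliner(29, 25, 0)
        with pytest.raises(ValueError):
            classify_decliner(29, None, 12)


def _subject(sid, age, nihss, group="non_decliner"):
    return SubjectRecord(
        id=sid, group=group, age_years=age, sex="F", education_years=10,
        nihss_baseline=nihss, mmse_baseline=28,
    )


class TestMatching:
    def test_identical_pool_matches_at_distance_zero(self):
        decliners = [_subject(f"d{i}", 70 + i, 3, "decliner") for i in range(3)]
        pool = [_subject(f"c{i}", 70 + i, 3) for i in range(3)]
        table = match_controls(decliners, pool, seed=0)
        assert (table["distance"] == 0).all()
        assert set(table["control"]) == {"c0", "c1", "c2"}

    def test_tolerance_excludes_nearer_but_inadmissible(self):
        decliners = [_subject("d", 69, 3, "decliner")]
        pool = [_subject("c65", 65, 3), _subject("c71", 71, 3)]
        table = match_controls(decliners, pool, seed=0)
        assert table.loc[0, "control"] == "c71"

    def test_unmatched_reported_not_forced(self):
        decliners = [_subject("d", 69, 3, "decliner")]
        pool = [_subject("c", 80, 3)]
        table = match_controls(decliners, pool, seed=0)
        assert table.loc[0, "control"] is None

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            match_controls([_subject("d", 69, 3)], [], seed=0)


class TestGroupCompare:
    def test_fisher_p_is_one_for_identical_balanced_table(self):
        res = group_compare(np.array([[2, 2], [2, 2]]), variable_kind="categorical")
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 7], [8, 2]],
            [[1, 9], [5, 5]],
            [[0, 6], [4, 2]],
            [[2, 3], [3, 2]],
        ],
    )
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        res = group_compare(np.array(table), variable_kind="categorical")
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(fisher_exact_oracle(table), rel=1e-9)

    def test_chi_square_for_large_tables(self):
        res = group_compare(np.array([[30, 20], [18, 32]]), variable_kind="categorical")
        assert res.method == "chi_square"

    def test_large_shift_detected_by_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(2, 1, 200)
        res = group_compare(a, b, variable_kind="continuous")
        assert res.method == "t_test"
        assert res.p_value < 1e-10

    def test_small_groups_use_wilcoxon(self):
        res = group_compare([1, 2, 3, 4], [2, 3, 4, 5], variable_kind="continuous")
        assert res.method == "wilcoxon"

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            group_compare([1.0, 1.0, 1.0], [1.0, 1.0], variable_kind="continuous")


class TestCohenD:
    def test_identical_groups_zero(self):
        assert cohen_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohen_d([0, 0, 0, 0], [1, 1, 1, 1])

    def test_hand_formula(self):
        a, b = [1, 2, 3], [3, 4, 5]
        pooled = np.sqrt(((2 * 1.0) + (2 * 1.0)) / 4)
        assert cohen_d(a, b) == pytest.approx((2.0 - 4.0) / pooled)


class TestRankCorrelation:
    def test_monotone_gives_one(self):
        x = [1, 2, 3, 5, 9]
        y = [np.exp(v) for v in x]
        assert rank_correlation(x, y).estimate == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = [1, 2, 3, 5, 9]
        assert rank_correlation(x, x[::-1]).estimate == pytest.approx(-1.0)

    def test_matches_rank_formula_without_ties(self):
        x = [10, 4, 7, 1, 13]
        y = [2.0, 5.5, 1.1, 8.8, 3.3]
        assert rank_correlation(x, y).estimate == pytest.approx(spearman_oracle(x, y))

    def test_pearson_flag_matches_moment_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 2 * x + rng.normal(size=20)
        res = rank_correlation(x, y, method="pearson")
        assert res.method == "pearson"
        assert res.estimate == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestInteractionRegression:
    def test_identical_slopes_give_zero_interaction(self):
        x = np.linspace(0, 5, 20)
        g = np.repeat([0, 1], 10)
        y = 2.0 * x + 3.0 * g
        table = interaction_regression(y, x, g)
        assert abs(table.loc["x:group", "estimate"]) < 1e-10

    def test_slope_difference_recovered_exactly(self):
        x = np.tile(np.linspace(0, 4, 10), 2)
        g = np.repeat([0, 1], 10)
        y = np.where(g == 1, -2.0 * x, 0.0 * x) + 1.0
        table = interaction_regression(y, x, g)
        assert table.loc["x:group", "estimate"] == pytest.approx(-2.0, abs=1e-10)

    def test_swapping_group_coding_negates_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        g = (rng.random(30) < 0.5).astype(float)
        y = x + 0.8 * x * g + rng.normal(0, 0.3, 30)
        t1 = interaction_regression(y, x, g)
        t2 = interaction_regression(y, x, 1 - g)
        assert t2.loc["x:group", "estimate"] == pytest.approx(-t1.loc["x:group", "estimate"])
        assert t2.loc["x:group", "p"] == pytest.approx(t1.loc["x:group", "p"])

    def test_collinear_design_named(self):
        x = np.repeat([1.0], 10)
        g = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="collinear"):
            interaction_regression(np.arange(10.0), x, g)


class TestVoxelwiseLogistic:
    def _inputs(self, n=24, shape=(2, 2, 2), seed=0):
        rng = np.random.default_rng(seed)
        groups = np.array([1] * (n // 2) + [0] * (n // 2), float)
        age = rng.normal(68, 5, n)
        sex = rng.integers(0, 2, n).astype(float)
        edu = rng.normal(10, 3, n)
        return rng, groups, age, sex, edu, shape

    def test_null_voxel_not_in_mask_and_separating_voxel_flagged(self):
        rng, groups, age, sex, edu, shape = self._inputs()
        vols = []
        for gi in groups:
            data = rng.normal(1.2, 0.1, shape)
            data[0, 0, 0] = 1.3  # constant across subjects: pure null
            data[1, 1, 1] = gi + rng.normal(0, 1e-4)  # perfectly separating
            vols.append(LabeledVolume(data, space_tag="t"))
        brain = LabeledVolume(np.ones(shape, np.int8), space_tag="t")
        stat = voxelwise_logistic(vols, groups, age, sex, edu, brain)
        assert stat.non_converged[1, 1, 1] == 1
        assert stat.threshold_mask[1, 1, 1] == 0
        assert stat.threshold_mask[0, 0, 0] == 0

    def test_mask_respects_threshold_and_convergence(self):
        rng, groups, age, sex, edu, shape = self._inputs(seed=3)
        vols = [LabeledVolume(rng.normal(1.2, 0.1, shape), space_tag="t") for _ in groups]
        brain = LabeledVolume(np.ones(shape, np.int8), space_tag="t")
        stat = voxelwise_logistic(vols, groups, age, sex, edu, brain)
        inside = stat.threshold_mask == 1
        assert np.all(stat.p_values[inside] < 0.05)
        assert np.all(stat.non_converged[inside] == 0)

    def test_too_few_subjects_rejected(self):
        rng, groups, age, sex, edu, shape = self._inputs(n=4)
        vols = [LabeledVolume(rng.normal(1, 0.1, shape), space_tag="t") for _ in groups]
        brain = LabeledVolume(np.ones(shape, np.int8), space_tag="t")
        with pytest.raises(ValueError):
            voxelwise_logistic(vols, groups, age, sex, edu, brain)


def test_record_validation():
    with pytest.raises(ValueError, match="interval"):
        SubjectRecord(
            id="x", group="decliner", age_years=70, sex="F", education_years=8,
            nihss_baseline=2, mmse_baseline=29, mmse_final=24, interval_months=None,
        )
    with pytest.raises(ValueError, match="MMSE"):
        SubjectRecord(
            id="x", group="decliner", age_years=70, sex="F", education_years=8,
            nihss_baseline=2, mmse_baseline=33,
        )
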