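import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ovicount.stats import (
    SyntheticCountModel,
    apply_inclusion_rules,
    downsample_power,
    pairwise_tests,
    simulate_counts,
    summarize,
)


def tables(n_wells, alive_flags, counts=None, condition="c", day=1):
    counts = counts if counts is not None else [10] * n_wells
    surv = pd.DataFrame(
        {
            "plate_id": "p",
            "well_label": [f"W{i}" for i in range(n_wells)],
            "condition": condition,
            "day": day,
            "n_females_alive": alive_flags,
            "n_males_alive": 1,
        }
    )
    cnt = pd.DataFrame(
        {
            "plate_id": "p",
            "well_label": [f"W{i}" for i in range(n_wells)],
            "condition": condition,
            "day": day,
            "count": counts,
            "n_prefilter": counts,
            "flags": "",
        }
    )
    return surv, cnt


class TestInclusionRules:
    def test_condition_excluded_below_half(self):
        surv, cnt = tables(16, [2] * 7 + [1] * 9)
        kept, excluded = apply_inclusion_rules(surv, cnt)
        assert kept.empty
        assert excluded == [("c", 1)]

    def test_condition_kept_at_or_above_half(self):
        surv, cnt = tables(16, [2] * 9 + [1] * 7)
        kept, excluded = apply_inclusion_rules(surv, cnt)
        assert len(kept) == 9 and excluded == []

    def test_all_alive_is_identity(self):
        surv, cnt = tables(8, [2] * 8)
        kept, _ = apply_inclusion_rules(surv, cnt)
        pd.testing.assert_frame_equal(kept, cnt)

    def test_idempotent_and_subset(self):
        surv, cnt = tables(10, [2] * 6 + [0] * 4)
        kept, _ = apply_inclusion_rules(surv, cnt)
        again, _ = apply_inclusion_rules(surv, kept)
        pd.testing.assert_frame_equal(kept.reset_index(drop=True), again)
        assert set(kept["well_label"]) <= set(cnt["well_label"])

    def test_missing_survival_row_hard_error(self):
        surv, cnt = tables(4, [2] * 4)
        with pytest.raises(ValueError, match="without survival records"):
            apply_inclusion_rules(surv.iloc[:3], cnt)

    def test_odd_well_count_uses_ceiling(self):
        # 5 wells: needs >= 3 both-alive
        surv, cnt = tables(5, [2, 2, 1, 1, 1])
        kept, excluded = apply_inclusion_rules(surv, cnt)
        assert excluded == [("c", 1)]
        surv, cnt = tables(5, [2, 2, 2, 1, 1])
        kept, excluded = apply_inclusion_rules(surv, cnt)
        assert len(kept) == 3 and excluded == []


class TestSummarize:
    def test_constant_counts(self):
        _, cnt = tables(3, [2] * 3, counts=[10, 10, 10])
        (s,) = summarize(cnt)
        assert (s.mean, s.cv) == (10.0, 0.0)

    def test_hand_arithmetic(self):
        _, cnt = tables(3, [2] * 3, counts=[2, 4, 6])
        (s,) = summarize(cnt)
        assert (s.mean, s.sd, s.cv) == (4.0, 2.0, 0.5)

    def test_zero_mean_flags_cv_undefined(self):
        _, cnt = tables(3, [2] * 3, counts=[0, 0, 0])
        (s,) = summarize(cnt)
        assert s.cv is None

    def test_negative_binomial_law_of_large_numbers(self):
        model = SyntheticCountModel({"c": 36.0}, dispersion=5.0)
        _, cnt = simulate_counts(model, n_wells=5000, seed=0)
        (s,) = summarize(cnt)
        assert s.mean == pytest.approx(36.0, rel=0.02)


class TestPairwiseTests:
    def test_identical_groups(self):
        (r,) = pairwise_tests({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert (r.t, r.p_raw, r.p_adj) == (0.0, 1.0, 1.0)

    def test_bonferroni_multiplies_by_family_size(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(10, 2, 20) for k in "abc"}
        results = pairwise_tests(groups)
        assert all(r.m == 3 for r in results)
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, 3 * r.p_raw))
            assert r.p_adj >= r.p_raw

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(1)
        groups = {
            "d1": rng.normal(35, 15, 60),
            "d7": rng.normal(20, 15, 60),
            "x": rng.normal(35, 15, 60),
        }
        results = {(r.group_a, r.group_b): r for r in pairwise_tests(groups)}
        assert results[("d1", "d7")].p_adj < 0.001
        assert results[("d1", "d7")].stars == "***"

    def test_welch_vs_pooled_agree_with_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(10, 1, 15), rng.normal(11, 4, 25)
        (welch,) = pairwise_tests({"a": a, "b": b}, welch=True)
        (pooled,) = pairwise_tests({"a": a, "b": b}, welch=False)
        assert welch.p_raw == pytest.approx(sps.ttest_ind(a, b, equal_var=False).pvalue)
        assert pooled.p_raw == pytest.approx(sps.ttest_ind(a, b, equal_var=True).pvalue)

    def test_small_group_skipped_with_flag(self):
        results = pairwise_tests({"a": [1.0], "b": [2.0, 3.0, 4.0]})
        assert results[0].skipped


class TestDownsamplePower:
    def test_identical_constant_groups_never_significant(self):
        res = downsample_power([7.0] * 20, [7.0] * 20, k=8, n_iter=50, seed=0)
        assert (res.p_values == 1.0).all()
        assert res.fraction_significant == 0.0

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(30, 10, 40), rng.normal(20, 10, 40)
        r1 = downsample_power(a, b, k=8, n_iter=30, seed=42)
        r2 = downsample_power(a, b, k=8, n_iter=30, seed=42)
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_large_separation_high_power(self):
        rng = np.random.default_rng(4)
        a = rng.normal(36, 5, 60)
        b = rng.normal(2, 5, 60)
        res = downsample_power(a, b, k=8, n_iter=100, seed=0)
        assert res.fraction_significant >= 0.95

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample_power([1.0] * 5, [2.0] * 5, k=6)

    def test_p_vector_shape_and_range(self):
        rng = np.random.default_rng(5)
        res = downsample_power(rng.normal(10, 3, 30), rng.normal(12, 3, 30), 4, n_iter=25, seed=1)
        assert len(res.p_values) == 25
        assert ((res.p_values >= 0) & (res.p_values <= 1)).all()


class TestSimulateCounts:
    def test_full_survival_no_exclusions(self):
        model = SyntheticCountModel({"a": 20.0, "b": 10.0}, survival_p=1.0)
        surv, cnt = simulate_counts(model, n_wells=12, days=(1, 3), seed=1)
        kept, excluded = apply_inclusion_rules(surv, cnt)
        assert excluded == [] and len(kept) == len(cnt)

    def test_zero_mean_all_zero(self):
        model = SyntheticCountModel({"none": 0.0})
        _, cnt = simulate_counts(model, n_wells=10, seed=2)
        assert (cnt["count"] == 0).all()

    def test_dose_response_ordering_recovered(self):
        means = {"d0": 36.0, "d1": 25.0, "d2": 12.0, "d3": 3.0}
        hits = 0
        for seed in range(20):
            _, cnt = simulate_counts(SyntheticCountModel(means), n_wells=60, seed=seed)
            summary = {s.condition: s.mean for s in summarize(cnt)}
            ordered = [summary[c] for c in ("d0", "d1", "d2", "d3")]
            hits += ordered == sorted(ordered, reverse=True)
        assert hits == 20

    def test_reproducible(self):
        model = SyntheticCountModel({"a": 30.0}, survival_p=0.9)
        s1, c1 = simulate_counts(model, n_wells=16, seed=7)
        s2, c2 = simulate_counts(model, n_wells=16, seed=7)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(c1, c2)
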