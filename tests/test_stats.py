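import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import trunktrack as tt
from trunktrack import (AllZeroDifferences, DegenerateVariance,
                        LengthMismatch, MissingReference, SampleTooSmall,
                        SingleSexCohort, icc_band, icc_two_way_mixed,
                        mean_paired_difference, qc_filter,
                        sex_difference_summary, shapiro_wilk,
                        wilcoxon_signed_rank)
from trunktrack.stats import compare_models


def _flicker_trial(frac, n=200, n_markers=8):
    rng = np.random.default_rng(0)
    positions = {f"M{i}": rng.normal(size=(n, 3)) for i in range(n_markers)}
    occluded = {k: np.zeros(n, bool) for k in positions}
    frames = rng.choice(n, size=int(frac * n), replace=False)
    for k in occluded:
        occluded[k][frames] = True
    return tt.MarkerTrialSet(positions=positions, rate=240.0, kind="gait",
                             occluded=occluded)


class TestQcFilter:
    def test_clean_cohort_fully_retained(self):
        cohort = {f"S{i}": [_flicker_trial(0.0)] for i in range(5)}
        retained, excluded = qc_filter(cohort)
        assert len(retained) == 5 and not excluded

    def test_full_set_flicker_is_excluded(self):
        cohort = {"good": [_flicker_trial(0.05)], "bad": [_flicker_trial(0.3)]}
        retained, excluded = qc_filter(cohort)
        assert retained == ["good"]
        assert excluded[0][0] == "bad"

    def test_single_marker_occlusion_is_not_flicker(self):
        trial = _flicker_trial(0.0)
        trial.occluded["M0"][:] = True  # one marker fully occluded
        trial.positions["M0"][:] = np.nan
        retained, excluded = qc_filter({"S1": [trial]})
        assert retained == ["S1"]


class TestMeanPairedDifference:
    def test_worked_examples(self):
        assert mean_paired_difference([1, 3], [2, 2]) == 1.0
        assert mean_paired_difference([4, 4, 4], [4, 4, 4]) == 0.0

    def test_absolute_not_signed_convention(self):
        # alternating signs: the signed mean would vanish
        a = np.array([2.0, 0.0, 2.0, 0.0])
        b = np.array([1.0, 1.0, 1.0, 1.0])
        assert mean_paired_difference(a, b) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(LengthMismatch):
            mean_paired_difference([1, 2], [1, 2, 3])

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_at_least_group_mean_gap(self, pairs):
        """mean |a_i - b_i| >= |mean(a) - mean(b)| (triangle inequality)."""
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        assert mean_paired_difference(a, b) >= abs(a.mean() - b.mean()) - 1e-9


class TestWilcoxon:
    def test_five_positive_differences(self):
        w, p = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert w == 15.0
        assert p == pytest.approx(0.0625)

    def test_balanced_pair_is_uninformative(self):
        _, p = wilcoxon_signed_rank([1, -1])
        assert p == 1.0

    def test_all_zero_differences_warn(self):
        with pytest.warns(AllZeroDifferences):
            w, p = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert (w, p) == (0.0, 1.0)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            d = rng.normal(size=rng.integers(4, 20))
            _, p = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_matches_full_enumeration_with_ties(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 3.0])
        _, p = wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        stats = [np.sum(ranks[np.array(signs) > 0])
                 for signs in itertools.product([1, -1], repeat=5)]
        w = np.sum(ranks[d > 0])
        stats = np.array(stats)
        expected = min(1.0, 2 * min((stats <= w).mean(), (stats >= w).mean()))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, 60)
        _, p = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, correction=False, method="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestShapiroWilk:
    def test_seeded_normal_passes(self):
        rng = np.random.default_rng(10)
        _, p = shapiro_wilk(rng.normal(size=18))
        assert p > 0.05

    def test_extreme_outlier_fails(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.1, 17), [100.0]])
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateVariance):
            shapiro_wilk(np.ones(10))

    def test_tiny_sample_rejected(self):
        with pytest.raises(SampleTooSmall):
            shapiro_wilk([1.0, 2.0])


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.arange(1.0, 9.0)
        icc, lo, hi = icc_two_way_mixed(np.column_stack([x, x]))
        assert icc == 1.0 and lo == 1.0 and hi == 1.0

    def test_toy_columns_hand_computed_mean_squares(self):
        """(1,3,5) vs (2,4,6): MSR=8, MSC=1.5, MSE=0 in the two-way ANOVA."""
        ratings = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        icc_c, _, _ = icc_two_way_mixed(ratings, form="consistency")
        assert icc_c == pytest.approx(1.0)
        icc_a, lo, hi = icc_two_way_mixed(ratings, form="absolute")
        assert icc_a == pytest.approx(8.0 / 9.0)  # (MSR-MSE)/(MSR+(k/n)MSC)
        assert icc_a < 1.0
        assert lo <= icc_a <= hi

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(0)
        icc, _, _ = icc_two_way_mixed(rng.normal(size=(100, 2)))
        assert abs(icc) < 0.2

    def test_symmetric_in_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 2))
        a = icc_two_way_mixed(x)
        b = icc_two_way_mixed(x[:, ::-1])
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("form,pingouin_type", [
        ("absolute", "ICC(A,1)"), ("consistency", "ICC(C,1)")])
    def test_matches_pingouin_oracle(self, form, pingouin_type):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        base = rng.normal(0, 10, 18)
        ratings = np.column_stack([base + rng.normal(0, 2, 18),
                                   base + 1.5 + rng.normal(0, 2, 18)])
        icc, lo, hi = icc_two_way_mixed(ratings, form=form)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(18), 2),
            "rater": np.tile(["A", "B"], 18),
            "score": ratings.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        row = ref.loc[pingouin_type]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin reports the CI rounded to two decimals
        assert lo == pytest.approx(row["CI95"][0], abs=5.1e-3)
        assert hi == pytest.approx(row["CI95"][1], abs=5.1e-3)

    def test_no_between_participant_variance_raises(self):
        with pytest.raises(DegenerateVariance):
            icc_two_way_mixed(np.ones((10, 2)))

    @pytest.mark.parametrize("value,band", [
        (0.94, "excellent"), (0.65, "moderate"), (0.49999, "poor"),
        (0.90, "good"), (0.75, "good"), (0.50, "moderate"), (-0.2, "poor")])
    def test_band_edges(self, value, band):
        assert icc_band(value) == band


def _metric_table(n=8, models=None, rng=None, jitter=0.0):
    models = models or [m.value for m in tt.TrunkModel]
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n):
        sex = "F" if i % 2 else "M"
        for task in ("gait", "dvj"):
            base = {m: rng.normal(10 if task == "dvj" else 2, 3)
                    for m in ("mean", "max", "min", "rom")}
            for model in models:
                for metric, val in base.items():
                    rows.append({
                        "subject": f"S{i:02d}", "sex": sex, "model": model,
                        "task": task, "metric": metric,
                        "value": val + (rng.normal(0, jitter)
                                        if model != "definition" else 0.0),
                    })
    return pd.DataFrame(rows)


class TestCompareModels:
    def test_duplicated_definition_gives_perfect_agreement(self):
        table = _metric_table(jitter=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = compare_models(table)
        assert (out["mean_abs_diff"] == 0).all()
        assert (out["icc"] == 1.0).all()
        assert (out["band"] == "excellent").all()

    def test_missing_reference_raises(self):
        table = _metric_table()
        table = table[table["model"] != "definition"]
        with pytest.raises(MissingReference):
            compare_models(table)

    def test_row_order_matches_report_layout(self):
        out = compare_models(_metric_table(jitter=0.5))
        assert list(out["model"].unique()) == ["m-strn", "no-thorax",
                                               "no-sternum"]
        first_block = out.iloc[:4]
        assert list(first_block["metric"]) == ["mean", "max", "min", "rom"]

    def test_invariant_to_participant_permutation(self):
        table = _metric_table(jitter=0.5)
        shuffled = table.sample(frac=1.0, random_state=1)
        a = compare_models(table)
        b = compare_models(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestSexDifferences:
    def test_group_means_reproduce_fixed_inputs(self):
        rows = []
        targets = {"definition": (38.30, 52.81), "no-thorax": (42.98, 52.75),
                   "no-sternum": (39.06, 53.37)}
        for model, (f, m) in targets.items():
            for i in range(11):
                rows.append({"subject": f"F{i}", "sex": "F", "model": model,
                             "task": "dvj", "metric": "rom", "value": f})
            for i in range(7):
                rows.append({"subject": f"M{i}", "sex": "M", "model": model,
                             "task": "dvj", "metric": "rom", "value": m})
        out = sex_difference_summary(pd.DataFrame(rows)).set_index("model")
        assert out.loc["definition", "male_minus_female"] == pytest.approx(14.51)
        assert out.loc["no-thorax", "male_minus_female"] == pytest.approx(9.77)
        assert out.loc["no-sternum", "male_minus_female"] == pytest.approx(14.31)

    def test_equal_group_means_difference_zero(self):
        table = _metric_table()
        table["value"] = 5.0
        out = sex_difference_summary(table)
        assert (out["male_minus_female"] == 0).all()

    def test_single_sex_cohort_warns(self):
        table = _metric_table()
        table["sex"] = "F"
        with pytest.warns(SingleSexCohort):
            out = sex_difference_summary(table)
        assert out["male_minus_female"].isna().all()
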