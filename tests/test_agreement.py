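"""Tests for Pearson/ICC agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cvaffect as cv
from cvaffect.agreement import (InsufficientDataError, UndefinedCorrelationError,
                                condition_wise_evaluation, icc, pearson_ci,
                                variance_performance_association,
                                within_participant_performance)
from cvaffect.model import ModelSpec


def anova_icc_oracle(m: np.ndarray, model: int, unit: str) -> float:
    """Brute-force two-way ANOVA sums of squares, written independently."""
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_items = 0.0
    for i in range(n):
        ss_items += k * (m[i].mean() - grand) ** 2
    ss_raters = 0.0
    for j in range(k):
        ss_raters += n * (m[:, j].mean() - grand) ** 2
    ss_total = 0.0
    ss_within = 0.0
    for i in range(n):
        row_mean = m[i].mean()
        for j in range(k):
            ss_total += (m[i, j] - grand) ** 2
            ss_within += (m[i, j] - row_mean) ** 2
    msb = ss_items / (n - 1)
    msw = ss_within / (n * (k - 1))
    msr = msb
    msc = ss_raters / (k - 1)
    mse = (ss_total - ss_items - ss_raters) / ((n - 1) * (k - 1))
    if model == 1:
        return (msb - msw) / (msb + (k - 1) * msw) if unit == "single" else (msb - msw) / msb
    if model == 2:
        if unit == "single":
            return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        return (msr - mse) / (msr + (msc - mse) / n)
    if unit == "single":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / msr


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, ci = pearson_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        r, ci = pearson_ci(x, y)
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(oracle, abs=1e-12)
        # Fisher-z CI oracle
        z = np.arctanh(oracle)
        half = 1.959963984540054 / np.sqrt(len(x) - 3)
        assert ci[0] == pytest.approx(np.tanh(z - half), abs=1e-9)
        assert ci[1] == pytest.approx(np.tanh(z + half), abs=1e-9)
        assert ci[0] < r < ci[1]

    def test_zero_variance_signalled_not_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_ci(np.ones(5), np.arange(5.0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12))
        rxy, _ = pearson_ci(x, y)
        ryx, _ = pearson_ci(y, x)
        assert rxy == pytest.approx(ryx, abs=1e-13)


class TestICC:
    def test_identical_columns_give_one(self):
        m = np.tile(np.arange(6.0)[:, None], (1, 3))
        for model in (1, 2, 3):
            for unit in ("single", "average"):
                assert icc(m, model, unit).icc_value == pytest.approx(1.0)

    @pytest.mark.parametrize("model,unit", [(m, u) for m in (1, 2, 3)
                                            for u in ("single", "average")])
    def test_matches_anova_oracle_on_random_matrices(self, model, unit):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = rng.integers(3, 20)
            k = rng.integers(2, 6)
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            got = icc(m, model, unit).icc_value
            assert got == pytest.approx(anova_icc_oracle(m, model, unit), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        m = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        df = pd.DataFrame(m, columns=["a", "b", "c"]).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        ref = pingouin.intraclass_corr(data=df, targets="index", raters="rater",
                                       ratings="score").set_index("Type")["ICC"]
        pairs = {("ICC(1,1)", 1, "single"), ("ICC(A,1)", 2, "single"),
                 ("ICC(C,1)", 3, "single"), ("ICC(1,k)", 1, "average"),
                 ("ICC(A,k)", 2, "average"), ("ICC(C,k)", 3, "average")}
        for name, model, unit in pairs:
            assert icc(m, model, unit).icc_value == pytest.approx(ref[name], abs=1e-8)

    def test_negative_icc_reported_as_computed(self):
        # more disagreement within items than between items
        m = np.array([[1.0, 5.0], [2.0, 4.0], [1.5, 4.5], [1.2, 5.2]])
        val = icc(m, 1, "single").icc_value
        assert val < 0

    def test_additive_constant_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(8, 3))
        for model in (1, 2, 3):
            for unit in ("single", "average"):
                a = icc(m, model, unit).icc_value
                b = icc(m + 13.7, model, unit).icc_value
                assert a == pytest.approx(b, abs=1e-10)

    def test_per_rater_offsets_consistency_vs_agreement(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(12, 1)) + 0.1 * rng.normal(size=(12, 3))
        shifted = base + np.array([0.0, 2.0, -1.0])
        # ICC(3) measures consistency: per-rater offsets do not matter
        assert icc(shifted, 3, "average").icc_value == pytest.approx(
            icc(base, 3, "average").icc_value, abs=1e-10)
        # ICC(2) measures absolute agreement: offsets reduce it
        assert icc(shifted, 2, "average").icc_value < \
            icc(base, 2, "average").icc_value - 0.05

    def test_missing_cells_rejected(self):
        m = np.ones((4, 2))
        m[1, 1] = np.nan
        with pytest.raises(ValueError, match="missing|finite"):
            icc(m)

    def test_too_few_raters_rejected(self):
        with pytest.raises(ValueError, match="raters"):
            icc(np.ones((5, 1)))


class TestWithinParticipant:
    def test_perfect_predictions(self):
        ratings = np.tile(np.arange(1.0, 8.0), 3)
        pids = np.repeat(["a", "b", "c"], 7)
        table, med = within_participant_performance(ratings, ratings, pids)
        assert np.allclose(table["pearson_r"], 1.0)
        assert med["median_r"] == pytest.approx(1.0)
        assert med["median_icc1"] == pytest.approx(1.0)

    def test_zero_variance_participant_excluded_from_median(self):
        ratings = np.concatenate([np.ones(6), np.arange(6.0)])
        preds = np.concatenate([np.arange(6.0), np.arange(6.0)])
        pids = np.repeat(["flat", "ok"], 6)
        table, med = within_participant_performance(preds, ratings, pids)
        flat = table.set_index("participant_id").loc["flat"]
        assert np.isnan(flat["pearson_r"])
        assert med["median_r"] == pytest.approx(1.0)

    def test_medians_match_loop_oracle(self, pos_eval):
        table, med = within_participant_performance(
            pos_eval["pred"], pos_eval["outcome"], pos_eval["pids"])
        # independent per-group loop oracle
        df = pd.DataFrame({"p": np.asarray(pos_eval["pids"]),
                           "x": np.asarray(pos_eval["pred"], float),
                           "y": np.asarray(pos_eval["outcome"], float)})
        rs = []
        for _, g in df.groupby("p"):
            if g["x"].std() == 0 or g["y"].std() == 0:
                continue
            rs.append(np.corrcoef(g["x"], g["y"])[0, 1])
        assert med["median_r"] == pytest.approx(np.median(rs), abs=1e-12)
        assert med["median_r"] > 0.6


class TestVarianceAssociation:
    def test_positive_association_on_synthetic_data(self, pos_eval):
        table, _ = within_participant_performance(
            pos_eval["pred"], pos_eval["outcome"], pos_eval["pids"])
        sd = pos_eval["outcome"].groupby(np.asarray(pos_eval["pids"])).std()
        r, ci = variance_performance_association(
            table.set_index("participant_id")["pearson_r"], sd)
        assert r > 0

    def test_constant_sd_undefined(self):
        r = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5])
        sd = pd.Series([1.0] * 5)  # log SD = 0 for all: constant regressor
        with pytest.raises(UndefinedCorrelationError):
            variance_performance_association(r, sd)

    def test_too_few_participants(self):
        r = pd.Series([0.1, 0.2, np.nan])
        sd = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            variance_performance_association(r, sd)


class TestConditionWise:
    def test_three_conditions_three_rows_counts_partition(self, medium_study):
        features = medium_study["features"]
        outcome = cv.model.average_coder_ratings(
            medium_study["ratings"], "positive").loc[features.index]
        spec = ModelSpec(n_trees=100)
        table = condition_wise_evaluation(features, outcome, spec, seed=11)
        assert len(table) == 3
        assert set(table["condition"]) == {"enhance", "normal", "suppress"}
        assert table["n_recordings"].sum() == len(features)
        assert (table["n_train"] + table["n_test"] == table["n_recordings"]).all()

    def test_pooled_beats_average_condition_accuracy(self, medium_study, pos_eval):
        from cvaffect.agreement import agreement_report
        features = medium_study["features"]
        outcome = cv.model.average_coder_ratings(
            medium_study["ratings"], "positive").loc[features.index]
        pooled = agreement_report(pos_eval["pred"],
                                  pos_eval["outcome"].to_numpy()).pearson_r
        table = condition_wise_evaluation(features, outcome, ModelSpec(), seed=11)
        assert pooled > table["pearson_r"].mean()
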