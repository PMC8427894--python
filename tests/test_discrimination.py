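"""Box-Cox preprocessing, Wilks-lambda MANOVA and LDA behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memscape.datamodel import ValidationError
from memscape.discrimination import (
    boxcox_preprocess,
    lda_fit_predict,
    manova_wilks,
    rao_wilks_f,
)


def _frame(cols: dict, n=None) -> pd.DataFrame:
    n = n or len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


class TestBoxCox:
    def test_normal_column_keeps_identity_lambda(self):
        rng = np.random.default_rng(0)
        p = boxcox_preprocess(_frame({"a": rng.normal(10, 1, 400)}))
        assert abs(p.boxcox_lambda["a"] - 1.0) <= 0.3

    def test_lognormal_column_recovers_log(self):
        rng = np.random.default_rng(1)
        p = boxcox_preprocess(_frame({"a": np.exp(rng.normal(0, 1, 400))}))
        assert abs(p.boxcox_lambda["a"]) <= 0.2

    def test_output_standardised(self):
        rng = np.random.default_rng(2)
        p = boxcox_preprocess(_frame({"a": rng.gamma(2, 1, 100), "b": rng.normal(0, 3, 100)}))
        v = p.values
        assert np.allclose(v.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(v.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_non_positive_column_shifted(self):
        rng = np.random.default_rng(3)
        p = boxcox_preprocess(_frame({"a": rng.normal(-5, 1, 50)}))
        assert p.shift["a"] > 0

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            boxcox_preprocess(_frame({"flat": np.ones(10)}))


class TestWilksManova:
    def test_one_predictor_reduces_to_anova_hand_case(self):
        # groups {1,2,3} and {4,5,6}: SS_between 13.5, SS_within 4, F = 13.5
        df = _frame({"x": [1.0, 2, 3, 4, 5, 6]})
        res = manova_wilks(df, ["a", "a", "a", "b", "b", "b"])
        assert res.wilks_lambda == pytest.approx(4 / 17.5, abs=1e-12)
        assert res.f_value == pytest.approx(13.5, abs=1e-10)
        assert res.df1 == 1 and res.df2 == 4
        uni = res.univariate.iloc[0]
        assert uni["f_value"] == pytest.approx(13.5, abs=1e-10)
        assert uni["sum_sq"] == pytest.approx(13.5)

    def test_rao_df_for_study_shapes(self):
        # the fractional denominator df of the three-predictor four-class case
        _, df1, df2, _ = rao_wilks_f(0.5, p=2, g=4, n=23)
        assert (df1, df2) == (6, 36)
        _, df1, df2, _ = rao_wilks_f(0.5, p=3, g=4, n=23)
        assert df1 == 9
        assert df2 == pytest.approx(41.52, abs=0.005)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(4)
        x = rng.standard_normal((30, 3))
        labels = np.repeat(["a", "b", "c"], 10)
        x[labels == "b"] += 0.8
        res = manova_wilks(_frame({f"v{j}": x[:, j] for j in range(3)}), labels)
        sm_res = MANOVA(x, pd.get_dummies(labels, drop_first=False).to_numpy().astype(float))
        table = sm_res.mv_test(
            hypotheses=[("grp", np.array([[1, -1, 0], [0, 1, -1]]))]
        ).results["grp"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-8
        )
        assert res.f_value == pytest.approx(
            float(table.loc["Wilks' lambda", "F Value"]), rel=1e-6
        )

    def test_separated_classes_drive_lambda_to_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.01, (6, 2))
        b = rng.normal(5, 0.01, (6, 2))
        df = _frame({"x": np.r_[a[:, 0], b[:, 0]], "y": np.r_[a[:, 1], b[:, 1]]})
        res = manova_wilks(df, ["a"] * 6 + ["b"] * 6)
        assert res.wilks_lambda < 0.01

    def test_null_distribution_matches_f_approximation(self):
        """Under random labels, Rao-F p-values are uniform (KS over permutations)."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal((24, 2))
        base = np.repeat(["a", "b", "c"], 8)
        pvals = []
        for _ in range(400):
            res = manova_wilks(
                _frame({"x": x[:, 0], "y": x[:, 1]}), rng.permutation(base)
            )
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_sample_rejected(self):
        df = _frame({f"v{j}": np.random.default_rng(7).standard_normal(6) for j in range(4)})
        with pytest.raises(ValidationError):
            manova_wilks(df, ["a", "a", "a", "b", "b", "b"])


class TestLDA:
    def test_separated_classes_classified_perfectly(self):
        rng = np.random.default_rng(8)
        x = np.r_[rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)]
        res = lda_fit_predict(_frame({"x": x}), ["a"] * 10 + ["b"] * 10)
        assert res.accuracy == 1.0

    def test_uniform_priors_raise_rare_class_recall(self):
        rng = np.random.default_rng(9)
        x = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 8)]
        labels = ["common"] * 40 + ["rare"] * 8
        recalls = {}
        for mode in ("uniform", "frequency"):
            res = lda_fit_predict(_frame({"x": x}), labels, priors=mode)
            recalls[mode] = res.confusion.loc["rare", "rare"] / 8
        assert recalls["uniform"] > recalls["frequency"]

    def test_null_predictors_near_majority_rate(self):
        rng = np.random.default_rng(10)
        accs = []
        for rep in range(30):
            x = rng.standard_normal(40)
            labels = ["a"] * 30 + ["b"] * 10
            res = lda_fit_predict(
                _frame({"x": x}), labels, priors="frequency",
                split_fraction=0.5, seed=rep,
            )
            accs.append(res.accuracy)
        # majority prior 0.75; binomial noise at n_test = 20 over 30 reps
        assert abs(np.mean(accs) - 0.75) < 0.1

    def test_confusion_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(11)
        labels = ["a"] * 6 + ["b"] * 9 + ["c"] * 5
        res = lda_fit_predict(
            _frame({"x": rng.standard_normal(20), "y": rng.standard_normal(20)}), labels
        )
        assert res.confusion.sum(axis=1).tolist() == [6, 9, 5]

    def test_discriminant_axis_count_bounded(self):
        rng = np.random.default_rng(12)
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = lda_fit_predict(
            _frame({f"v{j}": rng.standard_normal(24) for j in range(5)}), labels
        )
        assert res.scores.shape[1] <= min(2, 5)

    def test_singleton_class_split_can_fail_loudly(self):
        rng = np.random.default_rng(13)
        labels = ["a"] * 10 + ["b"] * 10 + ["solo"]
        df = _frame({"x": rng.standard_normal(21)})
        raised = False
        for seed in range(30):
            try:
                lda_fit_predict(df, labels, split_fraction=0.5, seed=seed)
            except ValidationError as err:
                assert "solo" in str(err)
                raised = True
                break
        assert raised, "singleton class never excluded from training across seeds"

    def test_stratified_split_keeps_all_classes(self):
        rng = np.random.default_rng(14)
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6 + ["d"] * 5
        df = _frame({"x": rng.standard_normal(23), "y": rng.standard_normal(23)})
        for seed in range(10):
            res = lda_fit_predict(df, labels, split_fraction=0.5, seed=seed)
            assert set(np.unique(labels)) == set(res.classes)
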