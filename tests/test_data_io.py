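import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hcfc
from hcfc.data_io import (
    DataValidationError, cronbach_alpha, read_responses, score_correlations,
    score_factor, scale_scores, subgroup_table, significance_stars,
    write_responses,
)
from hcfc.instrument import FactorSpec, InstrumentSpec, ItemSpec


@pytest.fixture(scope="module")
def plain2():
    """Two-item, one-factor instrument with no reversals, 5 categories."""
    return InstrumentSpec(
        factors=(FactorSpec(name="f", items=(ItemSpec("a"), ItemSpec("b"))),),
    )


class TestReadWrite:
    def test_round_trip_with_missing(self, small_table, tmp_path):
        p = tmp_path / "resp.csv"
        write_responses(small_table, p)
        back = read_responses(p, small_table.spec)
        assert back.n_respondents == 62
        assert back.n_missing == small_table.n_missing
        pd.testing.assert_frame_equal(back.responses, small_table.responses)

    def test_empty_file(self, tmp_path, hcfc8):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises((DataValidationError, pd.errors.EmptyDataError)):
            read_responses(p, hcfc8)

    def test_out_of_range_category(self, tmp_path, plain2):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n6,3\n")
        with pytest.raises(DataValidationError, match="a"):
            read_responses(p, plain2)

    def test_missing_token_counted(self, tmp_path, plain2):
        p = tmp_path / "na.csv"
        p.write_text("a,b\n1,NA\n2,3\n")
        table = read_responses(p, plain2)
        assert table.n_missing == 1

    def test_non_numeric_age(self, tmp_path, plain2):
        p = tmp_path / "age.csv"
        p.write_text("a,b,age\n1,2,sixty\n")
        with pytest.raises(DataValidationError, match="age"):
            read_responses(p, plain2)

    def test_column_mismatch(self, plain2):
        with pytest.raises(DataValidationError, match="missing"):
            hcfc.ResponseTable(responses=pd.DataFrame({"a": [1]}), spec=plain2)


class TestScoring:
    @pytest.mark.parametrize("fill,expect", [(1, 0.0), (5, 100.0), (3, 50.0)])
    def test_scale_endpoints(self, plain2, fill, expect):
        df = pd.DataFrame({"a": [fill], "b": [fill]}, dtype=float)
        assert score_factor(df, plain2).iloc[0] == expect

    def test_two_item_midpoint(self, plain2):
        df = pd.DataFrame({"a": [1.0], "b": [5.0]})
        assert score_factor(df, plain2).iloc[0] == 50.0

    def test_all_missing_gives_missing(self, plain2):
        df = pd.DataFrame({"a": [np.nan], "b": [np.nan]})
        assert np.isnan(score_factor(df, plain2).iloc[0])

    def test_partial_missing_uses_available(self, plain2):
        df = pd.DataFrame({"a": [5.0], "b": [np.nan]})
        assert score_factor(df, plain2).iloc[0] == 100.0

    @given(resp=st.integers(1, 5))
    def test_reversal_equivariance(self, resp):
        """Scoring a reversed item at r equals scoring it unreversed at
        n+1-r, and double reversal changes nothing."""
        rev = InstrumentSpec(factors=(FactorSpec(
            name="f", items=(ItemSpec("a", reversed=True), ItemSpec("b"))),))
        plain = InstrumentSpec(factors=(FactorSpec(
            name="f", items=(ItemSpec("a"), ItemSpec("b"))),))
        df_rev = pd.DataFrame({"a": [float(resp)], "b": [3.0]})
        df_pln = pd.DataFrame({"a": [float(6 - resp)], "b": [3.0]})
        assert (score_factor(df_rev, rev).iloc[0]
                == score_factor(df_pln, plain).iloc[0])

    def test_scores_bounded(self, small_table):
        scores = scale_scores(small_table)
        arr = scores.to_numpy()
        assert np.nanmin(arr) >= 0 and np.nanmax(arr) <= 100


class TestCronbachAlpha:
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_duplicated_items_alpha_one(self, k):
        col = np.array([1, 2, 3, 4, 5, 2, 3], dtype=float)
        X = np.tile(col[:, None], (1, k))
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_toy_matrix_hand_value(self):
        # items [[1,2],[2,3],[3,4],[4,5]]: each item variance 5/3, total
        # variance 20/3 -> alpha = 2 * (1 - (10/3)/(20/3)) = 1 exactly
        X = np.array([[1, 2], [2, 3], [3, 4], [4, 5]], dtype=float)
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        # sampling sd of alpha for 2 independent items is ~2/sqrt(n);
        # n=100,000 puts 0.02 at ~3 sigma
        rng = np.random.default_rng(5)
        X = rng.integers(1, 6, size=(100_000, 2)).astype(float)
        assert abs(cronbach_alpha(X)) < 0.02

    def test_too_few_rows_warns_nan(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 1.0]})
        with pytest.warns(UserWarning):
            assert np.isnan(cronbach_alpha(X))

    def test_factor_alphas_positive_on_consistent_data(self, small_table):
        alphas = hcfc.factor_alphas(small_table)
        assert (alphas.dropna() > 0).all()


class TestSubgroupTable:
    def _scores(self, vals):
        return pd.DataFrame({"f1": vals})

    def test_identical_groups_p_one(self):
        scores = self._scores([50.0] * 10)
        cov = pd.DataFrame({"sex": ["a"] * 5 + ["b"] * 5})
        tab = subgroup_table(scores, cov, "sex")
        assert tab["p"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_separation(self):
        scores = self._scores([0.0] * 5 + [100.0] * 5)
        cov = pd.DataFrame({"sex": ["a"] * 5 + ["b"] * 5})
        tab = subgroup_table(scores, cov, "sex")
        assert tab["p"].iloc[0] == 0.0

    def test_small_group_sd_flagged(self):
        scores = self._scores([10.0, 20.0, 30.0, 40.0])
        cov = pd.DataFrame({"g": ["a", "a", "a", "b"]})
        tab = subgroup_table(scores, cov, "g")
        row_b = tab[tab["group"] == "b"].iloc[0]
        assert row_b["mean"] == 40.0 and np.isnan(row_b["sd"])

    def test_age_reports_correlation(self):
        rng = np.random.default_rng(0)
        age = rng.normal(60, 10, 200)
        scores = self._scores(age * 0.5 + rng.normal(0, 5, 200))
        cov = pd.DataFrame({"age": age})
        tab = subgroup_table(scores, cov, "age")
        assert "corr_coeff" in tab.columns
        assert tab["corr_coeff"].iloc[0] > 0.5
        assert tab["p"].iloc[0] < 0.001

    def test_multigroup_anova_path(self):
        rng = np.random.default_rng(1)
        scores = self._scores(rng.normal(50, 10, 90))
        cov = pd.DataFrame({"occ": ["x", "y", "z"] * 30})
        tab = subgroup_table(scores, cov, "occ")
        assert set(tab["group"]) == {"x", "y", "z"}
        assert 0 <= tab["p"].iloc[0] <= 1

    def test_power_at_unit_effect(self):
        """A standardized mean difference of 1.0 at n=200/group is detected
        at the 0.05 level in >99% of replicates (Monte-Carlo power check)."""
        rng = np.random.default_rng(7)
        rejected = 0
        n_rep = 300
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, 200)
            b = rng.normal(1.0, 1.0, 200)
            _, p = stats.ttest_ind(a, b, equal_var=False)
            rejected += p < 0.05
        assert rejected / n_rep > 0.99


class TestScoreCorrelations:
    def test_diagonal_and_symmetry(self, small_table):
        corr = score_correlations(scale_scores(small_table))
        r = corr.r.to_numpy()
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T, equal_nan=True)

    def test_independent_factors_near_zero(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["x", "y"])
        corr = score_correlations(scores)
        assert abs(corr.r.loc["x", "y"]) < 0.05

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        f = rng.normal(size=n)
        x = 0.6 * f + np.sqrt(1 - 0.36) * rng.normal(size=n)
        # light categorization noise
        xs = pd.DataFrame({"x": np.round(x * 2) / 2, "f": f})
        corr = score_correlations(xs)
        assert corr.r.loc["x", "f"] == pytest.approx(0.6, abs=0.1)

    def test_insufficient_pairs_flagged(self):
        scores = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan],
                               "y": [np.nan, np.nan, 1.0, 2.0]})
        corr = score_correlations(scores)
        assert np.isnan(corr.r.loc["x", "y"])

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == ""
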