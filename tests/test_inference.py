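import numpy as np
import pandas as pd
import pytest

from bacevol import inference
from oracles import spearman_oracle


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = inference.spearman([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        rho, _ = inference.spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_ties_match_midrank_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 40).astype(float)  # heavy ties
        y = rng.integers(0, 5, 40).astype(float)
        rho, _ = inference.spearman(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y))

    def test_missing_values_pairwise_complete(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        rho, _ = inference.spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            inference.spearman([1, 2], [3, 4])


class TestCorrelationScreen:
    def _table(self, **cols):
        return pd.DataFrame(cols)

    def test_feature_identical_to_er_is_max(self):
        rng = np.random.default_rng(0)
        er = rng.normal(size=50)
        table = self._table(ER=er, A=er.copy(), B=rng.normal(size=50))
        screen = inference.correlation_screen(table)
        assert screen.max_abs_feature == "A"
        assert screen.table.loc["A", "rho"] == pytest.approx(1.0)
        assert bool(screen.table.loc["A", "not_significant"]) is False

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        er = rng.normal(size=40)
        table = self._table(ER=er, A=er + rng.normal(size=40),
                            B=rng.normal(size=40), C=-er)
        s1 = inference.correlation_screen(table)
        s2 = inference.correlation_screen(table[["C", "ER", "B", "A"]])
        assert s1.max_abs_feature == s2.max_abs_feature
        for f in "ABC":
            assert s1.table.loc[f, "rho"] == s2.table.loc[f, "rho"]

    def test_entirely_missing_feature_blank(self):
        rng = np.random.default_rng(2)
        er = rng.normal(size=30)
        table = self._table(ER=er, A=er, B=np.full(30, np.nan))
        screen = inference.correlation_screen(table)
        assert np.isnan(screen.table.loc["B", "rho"])
        assert screen.table.loc["B", "n_used"] == 0
        assert screen.table["is_max_abs"].sum() == 1


class TestPCR:
    def test_single_feature_equals_squared_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        er = pd.Series(2 * x + rng.normal(size=60))
        res = inference.pcr_contributions(pd.DataFrame({"X": x}), er)
        r2 = np.corrcoef(x, er)[0, 1] ** 2
        assert res.contributions["X"] == pytest.approx(r2)
        assert res.total_r2 == pytest.approx(r2)

    def test_orthogonal_design_closed_form(self):
        # two exactly orthogonal (in-sample) features: contributions equal
        # their marginal squared correlations with ER
        n = 64
        t = np.arange(n)
        x1 = np.where(t % 2 == 0, 1.0, -1.0)
        x2 = np.where((t // 2) % 2 == 0, 1.0, -1.0)
        assert x1 @ x2 == 0
        rng = np.random.default_rng(4)
        er = pd.Series(1.5 * x1 - 0.5 * x2 + rng.normal(0, 0.4, n))
        res = inference.pcr_contributions(pd.DataFrame({"A": x1, "B": x2}), er)
        for name, x in (("A", x1), ("B", x2)):
            marginal = np.corrcoef(x, er)[0, 1] ** 2
            assert res.contributions[name] == pytest.approx(marginal, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_contributions_sum_to_ols_r2_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 80, 6
        X = rng.normal(size=(n, k))
        X[:, 1] = 0.8 * X[:, 0] + 0.2 * X[:, 1]  # induce collinearity
        beta = rng.normal(size=k)
        er = pd.Series(X @ beta + rng.normal(size=n))
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(k)])
        res = inference.pcr_contributions(frame, er)
        # OLS R2 by direct least squares on the centered design
        Xc = X - X.mean(axis=0)
        yc = (er - er.mean()).to_numpy()
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        r2 = 1 - ((yc - Xc @ coef) ** 2).sum() / (yc ** 2).sum()
        assert res.contributions.sum() == pytest.approx(r2)
        assert res.total_r2 == pytest.approx(r2)
        assert res.component_r2.sum() == pytest.approx(r2)
        assert (res.contributions >= -1e-12).all()
        assert res.proportions.sum() == pytest.approx(1.0)

    def test_affine_rescaling_and_order_invariance(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        er = pd.Series(X["a"] - X["b"] + rng.normal(size=50))
        base = inference.pcr_contributions(X, er)
        scaled = X.copy()
        scaled["a"] = 100 * scaled["a"] - 7
        res = inference.pcr_contributions(scaled, er)
        pd.testing.assert_series_equal(base.contributions, res.contributions)
        reordered = inference.pcr_contributions(X[["c", "a", "b"]], er)
        assert reordered.contributions["a"] == \
               pytest.approx(base.contributions["a"])

    def test_missing_rows_dropped_and_missing_feature_excluded(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        X["empty"] = np.nan
        X.loc[3, "a"] = np.nan
        er = pd.Series(X["a"] + rng.normal(size=40))
        res = inference.pcr_contributions(X, er)
        assert "empty" not in res.contributions.index
        assert res.n_used == 39

    def test_too_few_complete_cases_raise(self):
        X = pd.DataFrame(np.random.default_rng(8).normal(size=(4, 3)))
        er = pd.Series(np.arange(4.0))
        with pytest.raises(ValueError):
            inference.pcr_contributions(X, er)


class TestPCFeaturePlot:
    def test_perfectly_correlated_features_coincide(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        X = pd.DataFrame({"A": x, "B": 3 * x + 1, "C": rng.normal(size=50)})
        er = pd.Series(rng.normal(size=50))
        coords = inference.pc_feature_plot(X, er)
        assert np.allclose(coords.loc["A"], coords.loc["B"], atol=1e-8)

    def test_negated_er_feature_opposes_er(self):
        rng = np.random.default_rng(10)
        er = pd.Series(rng.normal(size=50))
        X = pd.DataFrame({"A": -er.to_numpy(),
                          "B": rng.normal(size=50)})
        coords = inference.pc_feature_plot(X, er)
        assert np.allclose(coords.loc["A"], -coords.loc["ER"], atol=1e-8)

    def test_loading_norms_bounded_by_one(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"f{i}" for i in range(5)])
        er = pd.Series(X.sum(axis=1) + rng.normal(size=60))
        coords = inference.pc_feature_plot(X, er)
        norms = (coords ** 2).sum(axis=1)
        assert (norms <= 1 + 1e-9).all()
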