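"""TPM conversion, expression-loop association and cross-tissue Z-scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from t2dnet.expression import (
    cross_tissue_zscores,
    expression_loop_contingency,
    loop_expression_spearman,
    loopcount_bins,
    quantile_normalize,
    rpkm_to_tpm,
    zscore_on_loopcount,
)


class TestRpkmToTpm:
    def test_reference_values(self):
        m = pd.DataFrame({"s1": [50.0]}, index=["g1"])
        assert rpkm_to_tpm(m).iloc[0, 0] == 1e6
        m = pd.DataFrame({"s1": [10.0, 30.0]}, index=["g1", "g2"])
        assert rpkm_to_tpm(m)["s1"].tolist() == [250_000.0, 750_000.0]

    def test_columns_sum_to_million(self, rng):
        m = pd.DataFrame(rng.gamma(2, 10, size=(50, 4)))
        out = rpkm_to_tpm(m)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_invariant_to_column_scaling(self, rng):
        m = pd.DataFrame(rng.gamma(2, 10, size=(30, 3)))
        scaled = m * np.array([3.0, 0.5, 100.0])
        pd.testing.assert_frame_equal(rpkm_to_tpm(m), rpkm_to_tpm(scaled))

    def test_all_zero_column_rejected(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]})
        with pytest.raises(ValueError, match="s2"):
            rpkm_to_tpm(m)


def _chi2_oracle(table):
    """Textbook Pearson chi-square without continuity correction."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    return chi2, stats.chi2.sf(chi2, df=1)


class TestContingency:
    @staticmethod
    def _series_for_table(table):
        """Expression / loop-count series realizing an exact 2x2 table."""
        tpm, loops, idx = [], [], []
        k = 0
        for expressed, looped, count in [
            (True, True, table[0][0]),
            (True, False, table[0][1]),
            (False, True, table[1][0]),
            (False, False, table[1][1]),
        ]:
            for _ in range(count):
                idx.append(f"g{k}")
                tpm.append(10.0 if expressed else 1.0)  # ln(10) > 1 > ln(1)
                loops.append(1 if looped else 0)
                k += 1
        return pd.Series(tpm, index=idx), pd.Series(loops, index=idx)

    def test_matches_formula_oracle(self):
        table = [[130, 870], [50, 950]]
        tpm, loops = self._series_for_table(table)
        got_table, chi2, p = expression_loop_contingency(tpm, loops)
        assert got_table.tolist() == table
        exp_chi2, exp_p = _chi2_oracle(table)
        assert chi2 == pytest.approx(exp_chi2)
        assert chi2 == pytest.approx(39.07, abs=0.01)
        assert p == pytest.approx(exp_p, rel=1e-9)
        assert p == pytest.approx(4.07e-10, rel=0.01)

    def test_independent_proportions_near_null(self):
        table = [[200, 200], [100, 100]]
        tpm, loops = self._series_for_table(table)
        _, chi2, p = expression_loop_contingency(tpm, loops)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        tpm = pd.Series([10.0, 10.0], index=["a", "b"])
        loops = pd.Series([1, 1], index=["a", "b"])
        with pytest.raises(ValueError):
            expression_loop_contingency(tpm, loops)

    def test_coupled_generator_detected(self):
        """With the generator's loop-expression coupling on, the 2x2 test is
        significant at 2000 genes."""
        from t2dnet.simulate import SimulationConfig, generate_expression

        cfg = SimulationConfig(seed=5)
        loops = pd.Series(
            np.random.default_rng(5).poisson(1.5, 2000).astype(float),
            index=[f"g{i}" for i in range(2000)],
        )
        rpkm, _ = generate_expression(cfg, loops)
        tpm = rpkm_to_tpm(rpkm).mean(axis=1)
        _, _, p = expression_loop_contingency(tpm, loops)
        assert p < 0.01


class TestSpearman:
    def test_perfect_monotone(self):
        v = pd.Series(np.arange(12, dtype=float), index=range(12))
        c = pd.Series(np.arange(12) ** 2, index=range(12))
        rho, _ = loop_expression_spearman(v, c)
        assert rho == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        idx = list("abcdefghijkl")
        v = pd.Series(
            [3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.5, 3.5, 7.0, 0.5], index=idx
        )
        c = pd.Series([2, 0, 1, 0, 3, 5, 1, 2, 4, 2, 3, 0], index=idx)
        rho, _ = loop_expression_spearman(v, c)
        rv = stats.rankdata(v)
        rc = stats.rankdata(c)
        expected = np.corrcoef(rv, rc)[0, 1]
        assert rho == pytest.approx(expected)

    def test_null_correlation_small(self, rng):
        v = pd.Series(rng.normal(size=1000), index=range(1000))
        c = pd.Series(rng.poisson(2, 1000), index=range(1000))
        rho, _ = loop_expression_spearman(v, c)
        assert abs(rho) < 0.1

    def test_invariant_to_monotone_transform(self, rng):
        v = pd.Series(rng.gamma(2, 3, 200), index=range(200))
        c = pd.Series(rng.poisson(2, 200), index=range(200))
        rho1, p1 = loop_expression_spearman(v, c)
        rho2, p2 = loop_expression_spearman(np.log(v + 1) ** 3, c)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_input_rejected(self):
        v = pd.Series(np.ones(20), index=range(20))
        c = pd.Series(np.arange(20), index=range(20))
        with pytest.raises(ValueError):
            loop_expression_spearman(v, c)


class TestCrossTissueZscores:
    def test_constant_gene_gets_zero_row(self):
        m = pd.DataFrame(
            {"t1": [5.0, 1.0], "t2": [5.0, 2.0], "t3": [5.0, 3.0]},
            index=["flat", "vary"],
        )
        z = cross_tissue_zscores(m)
        assert np.allclose(z.loc["flat"], 0.0)

    def test_rows_standardized(self, rng):
        m = pd.DataFrame(rng.gamma(2, 20, size=(100, 10)))
        z = cross_tissue_zscores(m)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        sds = z.std(axis=1, ddof=1)
        assert np.allclose(sds[sds > 0], 1.0)

    def test_matches_stepwise_oracle(self):
        # rank patterns differ across tissues so no row is constant after
        # quantile normalisation
        m = pd.DataFrame(
            {"t1": [1.0, 8.0, 3.0], "t2": [5.0, 2.0, 7.0], "t3": [4.0, 9.0, 6.0]},
            index=["a", "b", "c"],
        )
        # oracle: rank-map each column onto the mean sorted vector, then
        # log1p, then per-row standardisation -- computed independently here
        target = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        manual = np.empty((3, 3))
        for j, col in enumerate(m.columns):
            order = np.argsort(np.argsort(m[col].to_numpy()))
            manual[:, j] = target[order]
        manual = np.log1p(manual)
        mean = manual.mean(axis=1, keepdims=True)
        sd = manual.std(axis=1, ddof=1, keepdims=True)
        expected = (manual - mean) / sd
        z = cross_tissue_zscores(m)
        assert np.allclose(z.to_numpy(), expected)

    def test_requires_three_tissues(self):
        with pytest.raises(ValueError):
            cross_tissue_zscores(pd.DataFrame({"t1": [1.0], "t2": [2.0]}))


class TestQuantileNormalize:
    def test_columns_share_distribution(self, rng):
        m = pd.DataFrame({"a": rng.gamma(2, 5, 50), "b": rng.normal(10, 2, 50)})
        out = quantile_normalize(m)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_ties_get_average(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = quantile_normalize(m)
        assert out["a"].iloc[0] == out["a"].iloc[1]


class TestZscoreOnLoopcount:
    def test_exact_fit(self):
        idx = range(6)
        x = pd.Series([0, 1, 2, 3, 4, 5.0], index=idx)
        y = 0.5 * x
        res = zscore_on_loopcount(y, x)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        idx = range(6)
        x = pd.Series([0.0, 1, 1, 2, 4, 6], index=idx)
        y = pd.Series([0.1, 0.5, 0.3, 0.9, 1.4, 2.2], index=idx)
        res = zscore_on_loopcount(y, x)
        xc = x - x.mean()
        beta = float((xc * (y - y.mean())).sum() / (xc**2).sum())
        assert res.beta == pytest.approx(beta)

    def test_recovers_simulated_slope(self, rng):
        x = pd.Series(rng.poisson(2, 5000).astype(float), index=range(5000))
        y = 0.14 * x + pd.Series(rng.normal(0, 1, 5000), index=range(5000))
        res = zscore_on_loopcount(y, x)
        assert 0.10 <= res.beta <= 0.18

    def test_zero_variance_predictor_rejected(self):
        y = pd.Series([1.0, 2.0, 3.0], index=range(3))
        x = pd.Series([2.0, 2.0, 2.0], index=range(3))
        with pytest.raises(ValueError):
            zscore_on_loopcount(y, x)


def test_loopcount_bins_top_bin_open_ended():
    counts = pd.Series([0, 1, 5, 6, 9, 12])
    assert loopcount_bins(counts).tolist() == [0, 1, 5, 6, 6, 6]
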