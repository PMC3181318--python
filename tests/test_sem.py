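"""Recursive path-model engine: estimation, implied covariance, fit testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ratepath as rp
from ratepath.dags import PathDAG, RATE_NODES
from ratepath.sem import PathModel, compare_models, subset_analysis

from conftest import population_correlation, unit_residuals


def random_recursive_dag(rng, n_edges):
    """A random DAG over the six rate names with role constraints relaxed."""
    order = list(rng.permutation(RATE_NODES))
    pairs = [(order[i], order[j]) for i in range(6) for j in range(i + 1, 6)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    return PathDAG(f"rand{n_edges}", tuple(pairs[k] for k in sorted(chosen)))


def simulate_from(dag, coeff, n, seed, residual_sd=1.0):
    pars = rp.SEMParameters(
        dag, rp.uniform_edge_coefficients(dag, coeff),
        {v: residual_sd for v in dag.nodes}, n, seed,
    )
    return rp.sample_rate_sem(pars)


class TestFitEquations:
    def test_single_edge_equals_pearson_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(size=400)
        dag = PathDAG("xy", (("x", "y"),), nodes=("x", "y"))
        res = PathModel(dag, pd.DataFrame({"x": x, "y": y})).fit()
        r = stats.pearsonr(x, y).statistic
        assert res.coefficients[("x", "y")] == pytest.approx(r, abs=1e-12)

    def test_parentless_node_unit_residual_variance(self, b_dag4):
        data = simulate_from(b_dag4, 0.5, 200, 3)
        res = PathModel(b_dag4, data).fit()
        # dRES and dBCC are exogenous in B-DAG4: variance 1 on the z-scale
        assert res.residual_variances["dRES"] == pytest.approx(1.0)
        assert res.residual_variances["dBCC"] == pytest.approx(1.0)
        assert ("dRES" not in res.r2) and ("dBCC" not in res.r2)

    def test_r2_single_parent_is_squared_coefficient(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=300)
        y = 0.8 * x + 0.5 * rng.normal(size=300)
        dag = PathDAG("xy", (("x", "y"),), nodes=("x", "y"))
        res = PathModel(dag, pd.DataFrame({"x": x, "y": y})).fit()
        beta = res.coefficients[("x", "y")]
        assert res.r2["y"] == pytest.approx(beta**2, abs=1e-10)

    def test_parameter_recovery_within_3_se(self, b_dag4):
        # truth on the standardized scale comes from the population
        # correlation matrix implied by the generating parameters
        coeffs = rp.uniform_edge_coefficients(b_dag4, 0.7)
        truth_corr = population_correlation(b_dag4, coeffs, unit_residuals(b_dag4))
        truth, _, _ = rp.fit_equations(b_dag4, truth_corr)
        n = 5000
        data = simulate_from(b_dag4, 0.7, n, 42)
        res = PathModel(b_dag4, data).fit()
        for _, row in res.coef_table.iterrows():
            e = (row["parent"], row["child"])
            assert abs(row["coef"] - truth[e]) < 3 * row["se"], e

    def test_collinear_parents_raise_naming_node(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        dag = PathDAG("col", (("a", "c"), ("b", "c")), nodes=("a", "b", "c"))
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        with pytest.raises(np.linalg.LinAlgError, match="'c'"):
            PathModel(dag, df).fit()


class TestImpliedCovariance:
    def test_no_edges_gives_diagonal(self):
        dag = PathDAG("iso", (), nodes=("x", "y"))
        sigma = rp.implied_covariance(dag, {}, {"x": 2.0, "y": 3.0})
        np.testing.assert_allclose(sigma, np.diag([2.0, 3.0]))

    def test_chain_one_step_path_rule(self):
        dag = PathDAG("xy", (("x", "y"),), nodes=("x", "y"))
        sigma = rp.implied_covariance(dag, {("x", "y"): 0.5}, {"x": 1.0, "y": 0.75})
        assert sigma.loc["x", "y"] == pytest.approx(0.5)
        assert sigma.loc["y", "y"] == pytest.approx(0.25 + 0.75)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(12)
        dag = random_recursive_dag(rng, 6)
        coeffs = {e: float(rng.uniform(-0.8, 0.8)) for e in dag.edges}
        resid = {v: 1.0 for v in dag.nodes}
        sigma = rp.implied_covariance(dag, coeffs, resid).to_numpy()
        n = 400_000
        draws = rp.sample_rate_sem(
            rp.SEMParameters(dag, coeffs, resid, n, 99)
        ).to_numpy()
        emp = np.cov(draws, rowvar=False)
        # MC standard error of each covariance entry
        se = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n)
        assert (np.abs(emp - sigma) < 3.5 * se).all()

    def test_positive_definite(self, b_dag4):
        coeffs = rp.uniform_edge_coefficients(b_dag4, 0.7)
        sigma = rp.implied_covariance(b_dag4, coeffs, unit_residuals(b_dag4))
        assert (np.linalg.eigvalsh(sigma.to_numpy()) > 0).all()


class TestMLDiscrepancy:
    def test_zero_iff_equal(self):
        s = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert rp.ml_discrepancy(s, s) == 0.0

    def test_1x1_closed_form(self):
        f = rp.ml_discrepancy(np.array([[2.0]]), np.array([[1.0]]))
        assert f == pytest.approx(1.0 - np.log(2.0), abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 6))
        b = rng.normal(size=(6, 6))
        S = a @ a.T + 6 * np.eye(6)
        Sigma = b @ b.T + 6 * np.eye(6)
        # independent evaluation: F = sum(lam - ln lam) - p over eigenvalues
        # of Sigma^{-1/2} S Sigma^{-1/2}
        w, V = np.linalg.eigh(Sigma)
        inv_sqrt = V @ np.diag(w**-0.5) @ V.T
        lam = np.linalg.eigvalsh(inv_sqrt @ S @ inv_sqrt)
        oracle = float((lam - np.log(lam)).sum() - 6)
        assert rp.ml_discrepancy(S, Sigma) == pytest.approx(oracle, abs=1e-10)

    def test_rejects_non_pd(self):
        good = np.eye(2)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError):
            rp.ml_discrepancy(bad, good)
        with pytest.raises(ValueError):
            rp.ml_discrepancy(good, np.eye(3))


class TestPathModelFit:
    def test_saturated_model_perfect_fit(self):
        rng = np.random.default_rng(3)
        nodes = RATE_NODES
        sat = PathDAG("sat", tuple(
            (nodes[i], nodes[j]) for i in range(6) for j in range(i + 1, 6)))
        data = pd.DataFrame(rng.normal(size=(50, 6)), columns=nodes)
        res = PathModel(sat, data).fit()
        assert res.df == 0
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert not res.rejected

    def test_ols_equals_numerical_ml(self):
        rng = np.random.default_rng(21)
        for k in range(5):
            dag = random_recursive_dag(rng, int(rng.integers(3, 11)))
            data = simulate_from(dag, 0.5, 300, 500 + k)
            model = PathModel(dag, data)
            res = model.fit()
            coef_n, psi_n, f_n = model.fit_ml_numeric(jitter=0.3, rng=rng)
            for e, b in res.coefficients.items():
                assert abs(coef_n[e] - b) < 1e-6
            for v, p in res.residual_variances.items():
                assert abs(psi_n[v] - p) < 1e-6

    def test_statistic_chi_square_calibrated(self, b_dag4):
        stats_t = []
        for r in range(200):
            data = simulate_from(b_dag4, 0.5, 500, 3000 + r)
            stats_t.append(PathModel(b_dag4, data).fit().statistic)
        ks = stats.kstest(stats_t, stats.chi2(df=8).cdf)
        assert ks.pvalue > 0.01

    def test_nested_model_monotonicity(self):
        # adding an edge never increases the minimized discrepancy
        rng = np.random.default_rng(33)
        data = pd.DataFrame(rng.normal(size=(120, 6)), columns=RATE_NODES)
        small = PathDAG("s", (("dRES", "dSCC"), ("dSCC", "dPS"), ("dPS", "dBCM")))
        for extra in [("dRES", "dPS"), ("dSCC", "dBCM"), ("dBCC", "dPS")]:
            big = PathDAG("b", small.edges + (extra,))
            f_small = PathModel(small, data).fit().fml
            f_big = PathModel(big, data).fit().fml
            assert f_big <= f_small + 1e-12

    def test_statistic_invariant_to_consistent_relabeling(self):
        rng = np.random.default_rng(8)
        dag = PathDAG("xy", (("x", "y"), ("y", "z")), nodes=("x", "y", "z"))
        df = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x", "y", "z"])
        t1 = PathModel(dag, df).fit().statistic
        relabeled = PathDAG("uv", (("u", "v"), ("v", "w")), nodes=("u", "v", "w"))
        df2 = df.rename(columns={"x": "u", "y": "v", "z": "w"})
        t2 = PathModel(relabeled, df2).fit().statistic
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_summary_mentions_fit_and_edges(self, b_dag4):
        data = simulate_from(b_dag4, 0.7, 300, 9)
        text = PathModel(b_dag4, data).fit().summary()
        assert "B-DAG4" in text and "df = 8" in text and "dSCC -> dPS" in text

    def test_exog_free_cov_reduces_df_and_improves_fit(self, b_dag4):
        data = simulate_from(b_dag4, 0.7, 300, 10)
        fixed = PathModel(b_dag4, data).fit()
        free = PathModel(b_dag4, data, exog_free_cov=True).fit()
        assert free.df == fixed.df - 1  # one exogenous pair (dRES, dBCC)
        assert free.fml <= fixed.fml + 1e-12


class TestModelComparison:
    def test_generating_model_retained_and_ranked_first(self, library, b_dag4):
        data = simulate_from(b_dag4, 0.7, 2000, 77)
        comp = compare_models(library, data)
        assert "B-DAG4" in comp.retained
        assert comp.table.iloc[0]["model"] == comp.best

    def test_opposite_scenario_rejected_under_strong_truth(self, library, b_dag4):
        data = simulate_from(b_dag4, 0.7, 2000, 78)
        comp = compare_models(library, data)
        a_fits = comp.table[comp.table["scenario"] == "replacement"]
        assert a_fits["rejected"].all()

    def test_partition_orders_retained_before_rejected(self, library, b_dag4):
        data = simulate_from(b_dag4, 0.7, 500, 79)
        comp = compare_models(library, data)
        rej = comp.table["rejected"].to_numpy()
        assert not rej[: (~rej).sum()].any()


class TestSubsetAnalysis:
    def test_single_date_identical_to_full_report(self, library, b_dag4):
        data = simulate_from(b_dag4, 0.7, 40, 11)
        idx = pd.MultiIndex.from_product(
            [[f"T{i:02d}" for i in range(40)], ["jun"]],
            names=["transition_id", "date"])
        rt = rp.RateTable(data.set_index(idx))
        by_date = subset_analysis(rt, "by_date", library)
        full = compare_models(library, rt.sem_data())
        assert list(by_date) == ["jun"]
        pd.testing.assert_frame_equal(by_date["jun"].table, full.table)

    def test_median_split_equal_sizes(self, library, adjustment_rates):
        rt38 = rp.RateTable(adjustment_rates.table.iloc[:38])
        subs = subset_analysis(rt38, "by_intensity_median_split", library)
        low = rt38.table["dRES"].nsmallest(19)
        assert len(subs) == 2
        assert subs["low"].results["B-DAG4"].nobs == 19
        assert subs["high"].results["B-DAG4"].nobs == 19
        assert low.max() <= rt38.table["dRES"].nlargest(19).min()

    def test_single_resource_replaces_driver(self, library, adjustment_rates):
        subs = subset_analysis(
            adjustment_rates, "single_resource", library, single_resource="DOC")
        assert list(subs) == ["DOC"]
        assert subs["DOC"].results["B-DAG4"].nobs == 39

    def test_small_subsets_skipped(self, library, b_dag4, caplog):
        data = simulate_from(b_dag4, 0.7, 12, 13)
        idx = pd.MultiIndex.from_arrays(
            [[f"T{i:02d}" for i in range(12)], ["jun"] * 6 + ["jul"] * 6],
            names=["transition_id", "date"])
        rt = rp.RateTable(data.set_index(idx))
        subs = subset_analysis(rt, "by_date", library, min_n=10)
        assert subs == {}
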