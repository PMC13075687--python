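"""Path-model engine: fitting, fit indices, effects, VIF, Moran's I."""

import math

import numpy as np
import pandas as pd
import pytest

import divscape as dv
from divscape.path_models import (PathModel, _baseline, effect_decomposition,
                                  fit_indices, fit_path_model,
                                  information_criteria, morans_i,
                                  prepare_variables, spatial_weights, vif)


def simulate_dag(model: PathModel, betas: dict, n: int, seed: int) -> pd.DataFrame:
    """Draw standardized data from a recursive SEM with known coefficients."""
    rng = np.random.default_rng(seed)
    data = {}
    for v in model.topological_order():
        parents = model.parents(v)
        mean = sum(betas[(p, v)] * data[p] for p in parents) if parents else 0.0
        var = 1.0 - sum(betas[(p, v)] ** 2 for p in parents)
        assert var > 0, "standardized betas too large"
        data[v] = mean + rng.normal(0, np.sqrt(var), n)
    return pd.DataFrame(data)


def random_dag(n_vars: int, seed: int):
    """A random DAG over standardized variables with safe coefficient sizes."""
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n_vars)]
    edges, betas = [], {}
    for j in range(1, n_vars):
        parents = [i for i in range(j) if rng.uniform() < 0.5]
        if not parents and j == n_vars - 1:
            parents = [0]
        raw = rng.uniform(0.2, 0.8, len(parents)) * rng.choice([-1, 1], len(parents))
        norm = np.sqrt((raw ** 2).sum())
        if norm > 0.9:
            raw *= 0.9 / norm
        for i, b in zip(parents, raw):
            edges.append((names[i], names[j]))
            betas[(names[i], names[j])] = float(b)
    return PathModel(tuple(names), tuple(edges)), betas


class TestPrepareVariables:
    def _inputs(self, n=40, zero_rich=0):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(n)]
        rich = pd.Series(rng.integers(1, 50, n), index=idx, dtype=float)
        rich.iloc[:zero_rich] = 0
        env = pd.DataFrame({"temperature": rng.normal(20, 5, n),
                            "precipitation": rng.normal(1000, 100, n),
                            "npp": rng.uniform(1, 5, n)}, index=idx)
        ages = pd.Series(rng.uniform(1, 10, n), index=idx)
        rates = pd.Series(rng.uniform(0.1, 1, n), index=idx)
        return rich, env, ages, rates

    def test_z_scoring(self):
        table = prepare_variables(*self._inputs())
        z = table.data
        assert np.allclose(z.mean(), 0, atol=1e-8)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-8)

    def test_zero_richness_cells_dropped(self):
        table = prepare_variables(*self._inputs(zero_rich=5))
        assert table.n_dropped == 5
        assert table.n == 35

    def test_insufficient_cells(self):
        with pytest.raises(ValueError, match="insufficient"):
            prepare_variables(*self._inputs(n=20))


class TestFitPathModel:
    def test_saturated_model_zero_discrepancy(self):
        model, betas = random_dag(4, 1)
        # saturate: every earlier variable feeds every later one
        names = model.variables
        sat = PathModel(names, tuple((names[i], names[j])
                                     for j in range(1, 4) for i in range(j)))
        df = simulate_dag(model, betas, 500, 0)
        fit = fit_path_model(sat, df)
        assert fit.df == 0
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-8)
        assert fit.srmr == pytest.approx(0.0, abs=1e-8)

    def test_mediation_chain_recovery(self):
        model = PathModel(("x", "m", "y"), (("x", "m"), ("m", "y")))
        betas = {("x", "m"): 0.8, ("m", "y"): 0.5}
        fit = fit_path_model(model, simulate_dag(model, betas, 10_000, 3))
        assert fit.coefficient("x", "m") == pytest.approx(0.8, abs=0.05)
        assert fit.coefficient("m", "y") == pytest.approx(0.5, abs=0.05)

    def test_implied_covariance_matches_monte_carlo(self):
        model = PathModel(("x", "m", "y"), (("x", "m"), ("m", "y"), ("x", "y")))
        betas = {("x", "m"): 0.7, ("m", "y"): 0.4, ("x", "y"): 0.3}
        fit = fit_path_model(model, simulate_dag(model, betas, 5_000, 4))
        # draw fresh data from the fitted model (fitted betas AND fitted
        # error variances) and compare sample covariance with Sigma(theta)
        rng = np.random.default_rng(5)
        pos = {v: i for i, v in enumerate(model.variables)}
        n = 1_000_000
        data = {}
        for v in model.topological_order():
            parents = model.parents(v)
            mean = sum(fit.coefficient(p, v) * data[p] for p in parents)
            sd = np.sqrt(fit.psi[pos[v], pos[v]])
            data[v] = mean + rng.normal(0, sd, n)
        S_mc = np.cov(np.column_stack([data[v] for v in model.variables]),
                      rowvar=False)
        assert np.allclose(fit.sigma, S_mc, atol=1e-2)

    def test_collinear_parents_error(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x * 1.0, "y": rng.normal(size=200)})
        model = PathModel(("a", "b", "y"), (("a", "y"), ("b", "y")))
        with pytest.raises(ValueError, match="collinear"):
            fit_path_model(model, df)

    @pytest.mark.parametrize("seed", range(6))
    def test_loglik_gradient_zero_at_solution(self, seed):
        """Equation-wise least squares maximizes the multivariate-normal logL."""
        model, betas = random_dag(4, 20 + seed)
        df = simulate_dag(model, betas, 400, seed)
        fit = fit_path_model(model, df)
        X = df[list(model.variables)].to_numpy()
        n, p = X.shape
        S = np.cov(X, rowvar=False, ddof=1)
        pos = {v: i for i, v in enumerate(model.variables)}

        def negloglik(theta):
            B = np.zeros((p, p))
            k = 0
            for a, b in model.edges:
                B[pos[b], pos[a]] = theta[k]
                k += 1
            Psi = fit.psi.copy()
            for v in model.endogenous:
                iv = pos[v]
                ip = [pos[a] for a in model.parents(v)]
                bv = B[iv, ip]
                Psi[iv, iv] = S[iv, iv] - 2 * bv @ S[ip, iv] + bv @ S[np.ix_(ip, ip)] @ bv
            inv = np.linalg.inv(np.eye(p) - B)
            Sigma = inv @ Psi @ inv.T
            sign, logdet = np.linalg.slogdet(Sigma)
            return logdet + np.trace(S @ np.linalg.inv(Sigma))

        theta0 = np.array([fit.coefficient(a, b) for a, b in model.edges])
        f0 = negloglik(theta0)
        for k in range(len(theta0)):
            for h in (1e-5, -1e-5):
                t = theta0.copy()
                t[k] += h
                assert negloglik(t) >= f0 - 1e-9


class TestFitIndices:
    def test_perfect_fit(self):
        idx = fit_indices(10.0, 10, 500.0, 15, 101)
        assert idx["cfi"] == pytest.approx(1.0)
        assert idx["tli"] == pytest.approx(1.0)
        assert idx["rmsea"] == pytest.approx(0.0)

    def test_rmsea_closed_form(self):
        idx = fit_indices(20.0, 10, 500.0, 15, 101)
        assert idx["rmsea"] == pytest.approx(math.sqrt(10 / (10 * 100)))

    def test_degenerate_baseline_flagged(self):
        idx = fit_indices(12.0, 10, 10.0, 15, 101)
        assert math.isnan(idx["cfi"]) and math.isnan(idx["tli"])

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            fit_indices(1.0, 0, 10.0, 5, 100)


class TestInformationCriteria:
    def test_formulas(self):
        aic, bic = information_criteria(-100.0, 5, 100)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(-2 * -100 + 5 * math.log(100))

    def test_aic_differences_shift_invariant(self):
        a1, _ = information_criteria(-100.0, 5, 100)
        a2, _ = information_criteria(-110.0, 7, 100)
        b1, _ = information_criteria(-100.0 + 42, 5, 100)
        b2, _ = information_criteria(-110.0 + 42, 7, 100)
        assert a1 - a2 == pytest.approx(b1 - b2)

    def test_guards(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 0, 100)


class TestEffectDecomposition:
    def test_product_along_chain(self):
        model = PathModel(("temperature", "npp", "lnS"),
                          (("temperature", "npp"), ("npp", "lnS")))
        df = simulate_dag(model, {("temperature", "npp"): 0.6,
                                  ("npp", "lnS"): 0.5}, 200_000, 8)
        fit = fit_path_model(model, df)
        dec = effect_decomposition(fit, mediators=("npp",))
        assert dec.indirect["temperature"]["npp"] == pytest.approx(0.30, abs=0.02)
        assert dec.direct["temperature"] == 0.0

    def test_no_mediators_no_indirect(self):
        model = PathModel(("x", "lnS"), (("x", "lnS"),))
        fit = fit_path_model(model, simulate_dag(model, {("x", "lnS"): 0.5}, 500, 0))
        dec = effect_decomposition(fit, mediators=("npp", "age", "dr"))
        assert all(v == 0 for v in dec.indirect["x"].values())
        assert dec.total["x"] == pytest.approx(dec.direct["x"])

    def test_total_matches_matrix_inverse_oracle(self):
        """Total effects equal the (I-B)^-1 reduced form on the full model."""
        from divscape.scenario_framework import full_model
        model = full_model()
        rng = np.random.default_rng(9)
        betas = {}
        for e in model.edges:
            betas[e] = 0.0
        # assign modest coefficients keeping residual variances positive
        for e in model.edges:
            betas[e] = float(rng.uniform(-0.25, 0.25))
        df = simulate_dag(model, betas, 5_000, 10)
        fit = fit_path_model(model, df)
        dec = effect_decomposition(fit)
        p = len(model.variables)
        pos = {v: i for i, v in enumerate(model.variables)}
        B = np.zeros((p, p))
        for a, b in model.edges:
            B[pos[b], pos[a]] = fit.coefficient(a, b)
        total = np.linalg.inv(np.eye(p) - B)  # reduced-form effects
        for pred in model.variables:
            if pred == "lnS":
                continue
            want = total[pos["lnS"], pos[pred]]
            assert dec.total[pred] == pytest.approx(want, abs=1e-10)
            parts = dec.direct[pred] + sum(dec.indirect[pred].values())
            assert dec.total[pred] == pytest.approx(parts, abs=1e-10)


class TestVif:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20_000, 3)), columns=["a", "b", "c"])
        v = vif(df, ["a", "b", "c"])
        assert all(abs(x - 1) < 0.05 for x in v.values())

    def test_known_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200_000)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=200_000)
        v = vif(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert v["x"] == pytest.approx(1 / (1 - 0.64), rel=0.05)

    def test_duplicate_column_infinite(self):
        x = np.arange(50.0)
        v = vif(pd.DataFrame({"a": x, "b": x}), ["a", "b"])
        assert math.isinf(v["a"])


class TestMoransI:
    def test_checkerboard_exact(self):
        coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        values = [1, -1, -1, 1]
        assert morans_i(values, coords, scheme="rook") == pytest.approx(-1.0)

    def test_smooth_gradient_positive(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        values = xs.ravel() + 0.5 * ys.ravel()
        assert morans_i(values, coords, scheme="knn", k=8) > 0.5

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(0)
        xs, ys = np.meshgrid(np.arange(7), np.arange(7))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        values = rng.normal(size=49)
        W = spatial_weights(coords, "knn", 8)
        sims = [morans_i(rng.permutation(values), coords, weights=W)
                for _ in range(200)]
        assert np.mean(sims) == pytest.approx(-1 / 48, abs=0.03)

    def test_errors(self):
        coords = np.zeros((4, 2))
        with pytest.raises(ValueError, match="variance"):
            morans_i([1, 1, 1, 1], coords)
        with pytest.raises(ValueError):
            morans_i([1, 2], coords[:2])
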