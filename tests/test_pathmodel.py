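"""Path models: coefficients, implied moments, bootstraps, total effects."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from multifun.pathmodel import (
    PathModelSpec,
    _CompiledSpec,
    bollen_stine,
    bootstrap_pvalues,
    build_composite,
    fit_path_model,
    fit_statistics,
    implied_covariance,
    total_effects,
    total_effects_on,
)


def chain_data(n, a=0.6, b=0.5, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = a * x + rng.normal(size=n) * np.sqrt(1 - a**2)
    y = b * m + rng.normal(size=n) * np.sqrt(1 - b**2)
    return pd.DataFrame({"x": x, "m": m, "y": y})


CHAIN = PathModelSpec(edges=[("x", "m"), ("m", "y")])
SATURATED = PathModelSpec(edges=[("x", "m"), ("m", "y"), ("x", "y")])


def brute_force_total_effects(B: pd.DataFrame) -> pd.DataFrame:
    """Sum of path-coefficient products over every directed path."""
    variables = list(B.index)
    g = nx.DiGraph()
    for t, s in itertools.product(variables, variables):
        if B.loc[t, s] != 0:
            g.add_edge(s, t)
    g.add_nodes_from(variables)
    out = pd.DataFrame(0.0, index=variables, columns=variables)
    for s, t in itertools.product(variables, variables):
        if s == t or not (g.has_node(s) and g.has_node(t)):
            continue
        for path in nx.all_simple_paths(g, s, t):
            prod = 1.0
            for u, v in zip(path, path[1:]):
                prod *= B.loc[v, u]
            out.loc[t, s] += prod
    return out


class TestSpec:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModelSpec(edges=[("a", "b"), ("b", "a")])

    def test_yaml_round_trip(self, tmp_path):
        spec = PathModelSpec(
            edges=[("x", "m"), ("m", "y")],
            composites={"c": {"indicators": ["i1", "i2"], "target": "y"}},
            transforms={"x": "log"},
        )
        path = tmp_path / "model.yaml"
        spec.to_yaml(path)
        back = PathModelSpec.from_yaml(path)
        assert back.edges == spec.edges
        assert back.composites == spec.composites
        assert back.transforms == spec.transforms

    def test_variable_classification(self):
        assert CHAIN.exogenous == ["x"]
        assert CHAIN.endogenous == ["m", "y"]


class TestComposite:
    def test_single_indicator_is_standardized_indicator(self, rng):
        data = pd.DataFrame({"i": rng.normal(3, 2, 100), "t": rng.normal(size=100)})
        scores, w = build_composite(data, ["i"], "t")
        z = (data["i"] - data["i"].mean()) / data["i"].std(ddof=1)
        np.testing.assert_allclose(np.abs(scores), np.abs(z), atol=1e-10)

    def test_null_indicator_gets_near_zero_weight(self):
        rng = np.random.default_rng(1)
        n = 500
        i1 = rng.normal(size=n)
        i2 = rng.normal(size=n)
        t = 0.7 * i1 + rng.normal(size=n) * 0.5
        data = pd.DataFrame({"i1": i1, "i2": i2, "t": t})
        _, w = build_composite(data, ["i1", "i2"], "t")
        assert abs(w["i2"]) < 0.1
        assert w["i1"] > 0.4

    def test_collinear_indicators_rejected(self, rng):
        x = rng.normal(size=50)
        data = pd.DataFrame({"a": x, "b": 2 * x, "t": rng.normal(size=50)})
        with pytest.raises(ValueError, match="collinear"):
            build_composite(data, ["a", "b"], "t")


class TestFit:
    def test_chain_parameter_recovery(self):
        data = chain_data(2000, a=0.6, b=0.5, seed=3)
        fit = fit_path_model(data, CHAIN)
        assert fit.path_coefficient("x", "m") == pytest.approx(0.6, abs=0.05)
        assert fit.path_coefficient("m", "y") == pytest.approx(0.5, abs=0.05)

    def test_single_parent_equals_pearson_correlation(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_path_model(data, PathModelSpec(edges=[("x", "y")]))
        r = np.corrcoef(x, y)[0, 1]
        assert fit.path_coefficient("x", "y") == pytest.approx(r, abs=1e-10)

    def test_saturated_model_reproduces_sample_correlations(self):
        data = chain_data(300, seed=5)
        fit = fit_path_model(data, SATURATED)
        S = np.cov(fit.data.to_numpy(), rowvar=False, ddof=1)
        sigma = implied_covariance(fit).to_numpy()
        np.testing.assert_allclose(sigma, S, atol=1e-10)

    def test_rank_deficient_parents_named(self, rng):
        x = rng.normal(size=100)
        data = pd.DataFrame({"a": x, "b": x, "y": rng.normal(size=100)})
        spec = PathModelSpec(edges=[("a", "y"), ("b", "y")])
        with pytest.raises(ValueError, match="y"):
            fit_path_model(data, spec)

    def test_too_few_cases_rejected(self, rng):
        data = chain_data(10)
        with pytest.raises(ValueError, match="complete cases"):
            fit_path_model(data, CHAIN)

    def test_transforms_applied_before_standardization(self, rng):
        x = rng.lognormal(0, 1, 300)
        y = 0.6 * np.log(x) + rng.normal(size=300)
        data = pd.DataFrame({"x": x, "y": y})
        spec = PathModelSpec(edges=[("x", "y")], transforms={"x": "log"})
        fit = fit_path_model(data, spec)
        r = np.corrcoef(np.log(x), y)[0, 1]
        assert fit.path_coefficient("x", "y") == pytest.approx(r, abs=1e-10)


class TestImpliedCovariance:
    def test_b_zero_gives_psi(self, rng):
        data = pd.DataFrame({"x": rng.normal(size=100), "y": rng.normal(size=100),
                             "z": rng.normal(size=100)})
        spec = PathModelSpec(edges=[("x", "z"), ("y", "z")])
        fit = fit_path_model(data, spec)
        fit.B.loc[:, :] = 0.0
        sigma = implied_covariance(fit)
        np.testing.assert_allclose(sigma.to_numpy(), fit.psi.to_numpy(), atol=1e-12)

    def test_chain_implied_correlation_is_product(self):
        data = chain_data(5000, a=0.6, b=0.5, seed=7)
        fit = fit_path_model(data, CHAIN)
        a = fit.path_coefficient("x", "m")
        b = fit.path_coefficient("m", "y")
        sigma = implied_covariance(fit)
        assert sigma.loc["x", "y"] == pytest.approx(a * b, abs=1e-10)

    def test_matches_path_enumeration_on_random_dags(self, rng):
        # implied covariance of exogenously-uncorrelated DAGs equals
        # path-tracing: corr(i,j) = sum over paths through common sources
        for rep in range(5):
            data = chain_data(400, seed=20 + rep)
            fit = fit_path_model(data, CHAIN)
            te = brute_force_total_effects(fit.B)
            _, _, total = total_effects(fit)
            np.testing.assert_allclose(total.to_numpy(), te.to_numpy(), atol=1e-12)


class TestFitStatistics:
    def test_perfect_fit_zero_chi2(self):
        data = chain_data(300, seed=9)
        fit = fit_path_model(data, SATURATED)
        st = fit_statistics(fit)
        assert st["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert st["df"] == 0
        assert st["saturated"]
        assert st["rmsea"] == 0.0

    def test_chain_df_one(self):
        fit = fit_path_model(chain_data(300, seed=10), CHAIN)
        st = fit_statistics(fit)
        assert st["df"] == 1

    def test_misspecification_power(self):
        # strong omitted direct edge: chi2 rejects at 0.05 in >80% of reps
        rejections = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n = 1000
            x = rng.normal(size=n)
            m = 0.6 * x + rng.normal(size=n) * 0.8
            y = 0.5 * x + 0.3 * m + rng.normal(size=n) * 0.7
            data = pd.DataFrame({"x": x, "m": m, "y": y})
            st = fit_statistics(fit_path_model(data, CHAIN))
            rejections += st["p"] < 0.05
        assert rejections / reps > 0.8

    def test_overparameterized_rejected(self):
        spec = PathModelSpec(edges=[("x", "m"), ("m", "y"), ("x", "y")])
        data = chain_data(100, seed=11)
        fit = fit_path_model(data, spec)
        fit.spec.edges.append(("x", "y"))  # duplicate -> too many params
        with pytest.raises(ValueError, match="over-parameterized"):
            fit_statistics(fit)


class TestCompiledFastPath:
    def test_agrees_with_reference_fit(self):
        data = chain_data(250, seed=12)
        plan = _CompiledSpec(data, CHAIN)
        B, psi, V = plan.fit_arrays()
        ref = fit_path_model(data, CHAIN)
        np.testing.assert_allclose(B, ref.B.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(psi, ref.psi.to_numpy(), atol=1e-12)
        assert plan.chi2() == pytest.approx(fit_statistics(ref)["chi2"], abs=1e-9)

    def test_agrees_with_composites(self, rng):
        n = 300
        b = rng.normal(size=n)
        f = 0.5 * b + rng.normal(size=n)
        mf = 0.4 * b + 0.3 * f + rng.normal(size=n)
        x = rng.normal(size=n)
        data = pd.DataFrame({"b": b, "f": f, "mf": mf, "x": x})
        spec = PathModelSpec(
            edges=[("div", "mf"), ("x", "mf")],
            composites={"div": {"indicators": ["b", "f"], "target": "mf"}},
        )
        plan = _CompiledSpec(data, spec)
        B, _, _ = plan.fit_arrays()
        ref = fit_path_model(data, spec)
        np.testing.assert_allclose(B, ref.B.to_numpy(), atol=1e-12)


class TestBootstrap:
    def test_deterministic(self):
        data = chain_data(150, seed=13)
        a = bootstrap_pvalues(data, CHAIN, n_boot=199, seed=5)
        b = bootstrap_pvalues(data, CHAIN, n_boot=199, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_strong_effect_at_floor(self):
        data = chain_data(500, a=0.6, b=0.6, seed=14)
        p = bootstrap_pvalues(data, CHAIN, n_boot=499, seed=6)
        assert p["x->m"] == pytest.approx(2 / 500)
        assert p["m->y"] == pytest.approx(2 / 500)

    def test_null_coefficient_type_one_error(self):
        # x -> y edge with zero true effect; rejection near nominal 5%
        reps = 60
        rejections = 0
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            n = 120
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            data = pd.DataFrame({"x": x, "y": y})
            p = bootstrap_pvalues(
                data, PathModelSpec(edges=[("x", "y")]), n_boot=199, seed=rep
            )
            rejections += p["x->y"] < 0.05
        assert 0.0 <= rejections / reps <= 0.12

    def test_minimum_boot_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_pvalues(chain_data(100), CHAIN, n_boot=50, seed=0)


class TestBollenStine:
    def test_correct_model_high_p_misspecified_low_p(self):
        data = chain_data(400, seed=15)
        p_ok = bollen_stine(data, CHAIN, n_boot=199, seed=1)
        assert p_ok > 0.10
        rng = np.random.default_rng(16)
        n = 800
        x = rng.normal(size=n)
        m = 0.6 * x + rng.normal(size=n) * 0.8
        y = 0.6 * x + 0.3 * m + rng.normal(size=n) * 0.6
        bad = pd.DataFrame({"x": x, "m": m, "y": y})
        p_bad = bollen_stine(bad, CHAIN, n_boot=199, seed=2)
        assert p_bad < 0.05

    def test_transformed_data_chi2_centered_on_df(self):
        # after the Bollen-Stine rotation the model holds exactly, so
        # bootstrap chi2 should average about df
        data = chain_data(400, seed=17)
        fit = fit_path_model(data, CHAIN)
        from multifun.pathmodel import _matrix_power_sym

        Y = fit.data.to_numpy()
        Yc = Y - Y.mean(axis=0)
        S = np.cov(Yc, rowvar=False, ddof=1)
        sigma = implied_covariance(fit).to_numpy()
        Ystar = Yc @ _matrix_power_sym(S, -0.5) @ _matrix_power_sym(sigma, 0.5)
        star = pd.DataFrame(Ystar, columns=fit.variables)
        st = fit_statistics(fit_path_model(star, CHAIN))
        assert st["chi2"] == pytest.approx(0.0, abs=1e-8)
        plan = _CompiledSpec(star, CHAIN)
        rng = np.random.default_rng(3)
        chis = [plan.chi2(rng.integers(0, 400, 400)) for _ in range(300)]
        assert np.mean(chis) == pytest.approx(st["df"], abs=0.5)

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            bollen_stine(chain_data(200, seed=18), SATURATED, n_boot=199, seed=0)


class TestTotalEffects:
    def test_chain_plus_direct(self):
        rng = np.random.default_rng(19)
        n = 3000
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n) * 0.87
        y = 0.3 * x + 0.4 * m + rng.normal(size=n) * 0.8
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_path_model(data, SATURATED)
        direct, indirect, total = total_effects(fit)
        a = fit.path_coefficient("x", "m")
        b = fit.path_coefficient("m", "y")
        c = fit.path_coefficient("x", "y")
        assert total.loc["y", "x"] == pytest.approx(c + a * b, abs=1e-12)
        assert indirect.loc["y", "x"] == pytest.approx(a * b, abs=1e-12)

    def test_no_path_zero_effect(self, rng):
        data = pd.DataFrame(
            {"x": rng.normal(size=100), "y": rng.normal(size=100),
             "z": rng.normal(size=100)}
        )
        spec = PathModelSpec(edges=[("x", "y"), ("z", "y")])
        _, _, total = total_effects(fit_path_model(data, spec))
        assert total.loc["z", "x"] == 0.0

    def test_matches_enumeration_on_random_dags(self):
        rng = np.random.default_rng(20)
        for rep in range(10):
            k = 6
            names = [f"v{i}" for i in range(k)]
            B = pd.DataFrame(0.0, index=names, columns=names)
            for i in range(k):
                for j in range(i):
                    if rng.random() < 0.5:
                        B.iloc[i, j] = rng.normal()
            total = np.linalg.inv(np.eye(k) - B.to_numpy()) - np.eye(k)
            ref = brute_force_total_effects(B)
            np.testing.assert_allclose(total, ref.to_numpy(), atol=1e-10)

    def test_series_terminates_at_path_length(self):
        k = 5
        B = np.zeros((k, k))
        for i in range(1, k):
            B[i, i - 1] = 0.5  # pure chain
        total = np.linalg.inv(np.eye(k) - B) - np.eye(k)
        series = sum(np.linalg.matrix_power(B, p) for p in range(1, k))
        np.testing.assert_allclose(total, series, atol=1e-14)

    def test_total_equals_bivariate_correlation_with_uncorrelated_exog(self):
        # simulation designed with independent exogenous variables
        rng = np.random.default_rng(21)
        n = 5000
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        m = 0.5 * x + 0.3 * z + rng.normal(size=n) * 0.7
        y = 0.4 * m + rng.normal(size=n) * 0.84
        data = pd.DataFrame({"x": x, "z": z, "m": m, "y": y})
        spec = PathModelSpec(edges=[("x", "m"), ("z", "m"), ("m", "y")])
        fit = fit_path_model(data, spec)
        _, _, total = total_effects(fit)
        r = np.corrcoef(x, y)[0, 1]
        # implied bivariate corr = total effect when exog are uncorrelated
        assert total.loc["y", "x"] == pytest.approx(r, abs=0.05)

    def test_composite_split_over_indicators(self, rng):
        n = 400
        b = rng.normal(size=n)
        f = rng.normal(size=n)
        mf = 0.5 * b + 0.2 * f + rng.normal(size=n) * 0.8
        data = pd.DataFrame({"b": b, "f": f, "mf": mf})
        spec = PathModelSpec(
            edges=[("div", "mf")],
            composites={"div": {"indicators": ["b", "f"], "target": "mf"}},
        )
        fit = fit_path_model(data, spec)
        eff = total_effects_on(fit, "mf")
        assert "div:b" in eff.index and "div:f" in eff.index
        assert abs(eff["div:b"]) > abs(eff["div:f"])
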