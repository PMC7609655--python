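"""REML engine: closed-form oracles, brute-force likelihood maximization,
cross-checks against statsmodels, prediction and term tests."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import optimize

from xyloherit import (
    ModelSpec,
    VarianceConfig,
    aicc,
    average_annual_increment,
    extract_variance_components,
    fit_reml,
    predict_standardized,
    simulate_trait_panel,
    standardized_newdata,
    term_significance,
)
from xyloherit.lmm import LMMError, build_design
from xyloherit.synthio import _all_clonal_population, simulate_population


class TestBalancedOracle:
    def test_toy_matches_anova_method_of_moments(self, balanced_toy):
        spec = ModelSpec(response="y", fixed_terms=[], random_factor="group")
        fit = fit_reml(spec, balanced_toy)
        assert fit.sigma2_random == pytest.approx(7.0, abs=1e-5)
        assert fit.sigma2_R == pytest.approx(2.0, abs=1e-5)
        s2g, s2r = extract_variance_components(fit)
        assert (s2g, s2r) == (fit.sigma2_random, fit.sigma2_R)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_designs_match_closed_form(self, seed):
        """REML equals ANOVA estimators in balanced one-way designs."""
        rng = np.random.default_rng(seed)
        a, n = 6, 4
        groups = np.repeat([f"g{i}" for i in range(a)], n)
        y = (np.repeat(rng.normal(0, 2.0, a), n)
             + rng.normal(0, 1.0, a * n))
        data = pd.DataFrame({"y": y, "group": groups,
                             "tree_id": [f"t{i}" for i in range(a * n)],
                             "year": np.tile(np.arange(n), a)})
        msb = n * np.var([y[groups == g].mean()
                          for g in np.unique(groups)], ddof=1)
        msw = np.mean([np.var(y[groups == g], ddof=1)
                       for g in np.unique(groups)])
        if msb <= msw:
            pytest.skip("negative moment estimate; boundary case")
        fit = fit_reml(ModelSpec(response="y", fixed_terms=[],
                                 random_factor="group"), data)
        assert fit.sigma2_random == pytest.approx((msb - msw) / n, rel=1e-4)
        assert fit.sigma2_R == pytest.approx(msw, rel=1e-4)


def dense_restricted_loglik(theta, data, spec, het_levels):
    """Independent dense-matrix restricted log-likelihood."""
    s2rand = math.exp(theta[0])
    s2r = math.exp(theta[1])
    i = 2
    rho = math.tanh(theta[i]) if spec.ar1 else 0.0
    i += int(spec.ar1)
    mult = {het_levels[0]: 1.0} if het_levels else {}
    for j, lv in enumerate(het_levels[1:]):
        mult[lv] = math.exp(theta[i + j])

    X, _ = build_design(data, spec)
    y = data[spec.response].to_numpy(float)
    n, p = X.shape
    lev = data[spec.random_factor].to_numpy()
    tree = data["tree_id"].to_numpy()
    yr = data["year"].to_numpy(int)
    m = (np.array([mult[v] for v in data[spec.heteroscedastic_by]])
         if spec.heteroscedastic_by else np.ones(n))
    V = s2rand * (lev[:, None] == lev[None, :]).astype(float)
    same = tree[:, None] == tree[None, :]
    lag = np.abs(yr[:, None] - yr[None, :])
    V += np.where(same, s2r * np.outer(m, m) * rho ** lag, 0.0)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -1e12
    vi = np.linalg.inv(V)
    xtvix = X.T @ vi @ X
    sign2, logdet2 = np.linalg.slogdet(xtvix)
    if sign2 <= 0:
        return -1e12
    beta = np.linalg.solve(xtvix, X.T @ vi @ y)
    r = y - X @ beta
    return -0.5 * (logdet + logdet2 + r @ vi @ r
                   + (n - p) * math.log(2 * math.pi))


class TestBruteForceOracle:
    @pytest.mark.parametrize("ar1,het", [(False, False), (True, False),
                                         (True, True)])
    def test_small_instance_matches_numerical_maximum(self, ar1, het):
        """On <= 12 observations the fit matches brute-force maximization
        of the explicitly coded restricted likelihood to 1e-4."""
        rng = np.random.default_rng(7)
        rows = []
        for t, (grp, base) in enumerate([("a", 0.0), ("a", 0.5),
                                         ("b", 2.0)]):
            e = 0.0
            for k, year in enumerate(range(2007, 2011)):
                e = 0.5 * e + rng.normal(0, 1.0)
                rows.append({"y": base + 0.3 * year % 7 + e + rng.normal(),
                             "tree_id": f"t{t}", "year": year,
                             "group": grp, "cDBH": 10.0 + 0.1 * k})
        data = pd.DataFrame(rows)
        spec = ModelSpec(response="y", fixed_terms=["cDBH"],
                         random_factor="tree_id", ar1=ar1,
                         heteroscedastic_by="group" if het else None)
        fit = fit_reml(spec, data)

        het_levels = sorted(data["group"].unique()) if het else []
        n_theta = 2 + int(ar1) + max(len(het_levels) - 1, 0)
        res = optimize.differential_evolution(
            lambda th: -dense_restricted_loglik(th, data, spec, het_levels),
            bounds=[(-12, 6)] * n_theta, seed=11, tol=1e-10, maxiter=400,
            polish=True,
        )
        assert fit.logREML == pytest.approx(-res.fun, abs=1e-4)


class TestAICc:
    def test_direct_arithmetic(self):
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 3, 10 ** 9) == pytest.approx(26.0, abs=1e-6)

    def test_no_parameters_reduces_to_deviance(self):
        assert aicc(-10.0, 0, 20) == pytest.approx(20.0)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


@pytest.fixture(scope="module")
def structured_panel():
    trees = simulate_population(_all_clonal_population(8, 3, seed=1))
    vc = VarianceConfig(sigma2_tree=0.5, sigma2_R=1.0, rho=0.5,
                        beta_dbh=0.4,
                        year_effects={y: 0.2 * (y % 3)
                                      for y in range(2007, 2018)})
    return simulate_trait_panel(trees, vc, seed=2, trait="y")


@pytest.fixture(scope="module")
def fit_and_panel():
    trees = simulate_population(_all_clonal_population(6, 3, seed=4))
    vc = VarianceConfig(sigma2_G=0.5, sigma2_tree=0.2, sigma2_R=0.5,
                        beta_dbh=0.5)
    panel = simulate_trait_panel(trees, vc, seed=5, trait="y")
    spec = ModelSpec(response="y",
                     fixed_terms=["genetic_group", "year", "cDBH"],
                     random_factor="tree_id")
    return fit_reml(spec, panel), panel


class TestModelStructure:

    def test_free_ar1_parameter_never_decreases_logreml(self, structured_panel):
        panel = structured_panel
        base = ModelSpec(response="y", fixed_terms=["year", "cDBH"],
                         random_factor="tree_id", ar1=False)
        with_rho = ModelSpec(response="y", fixed_terms=["year", "cDBH"],
                             random_factor="tree_id", ar1=True)
        assert (fit_reml(with_rho, panel).logREML
                >= fit_reml(base, panel).logREML - 1e-6)

    def test_matches_statsmodels_random_intercept(self, structured_panel):
        panel = structured_panel
        fit = fit_reml(ModelSpec(response="y", fixed_terms=["cDBH"],
                                 random_factor="tree_id"), panel)
        sm = smf.mixedlm("y ~ cDBH", panel,
                         groups=panel["tree_id"]).fit(reml=True)
        assert fit.logREML == pytest.approx(sm.llf, abs=1e-4)
        assert fit.sigma2_random == pytest.approx(sm.cov_re.iloc[0, 0],
                                                  rel=1e-3)
        assert fit.sigma2_R == pytest.approx(sm.scale, rel=1e-3)

    def test_zero_group_structure_gives_zero_component(self, rng):
        n = 600
        data = pd.DataFrame({
            "y": rng.normal(0, 1, n),
            "tree_id": [f"t{i % 60}" for i in range(n)],
            "year": np.tile(np.arange(10), 60),
        })
        fit = fit_reml(ModelSpec(response="y", fixed_terms=[],
                                 random_factor="tree_id"), data)
        assert fit.sigma2_random < 0.02

    def test_singular_design_names_aliased_column(self, structured_panel):
        panel = structured_panel.copy()
        panel["dup"] = panel["cDBH"]
        spec = ModelSpec(response="y", fixed_terms=["cDBH", "dup"],
                         random_factor="tree_id")
        with pytest.raises(LMMError, match="aliased"):
            fit_reml(spec, panel)


class TestPrediction:

    def test_clone_mates_get_identical_standardized_predictions(
            self, fit_and_panel):
        fit, panel = fit_and_panel
        newdata = standardized_newdata(panel, fit.spec)
        preds = pd.Series(predict_standardized(fit, newdata),
                          index=pd.MultiIndex.from_frame(
                              newdata[["genetic_group", "year"]]))
        spread = preds.groupby(level=[0, 1]).agg(np.ptp)
        assert float(spread.max()) == pytest.approx(0.0, abs=1e-9)

    def test_unseen_level_raises(self, fit_and_panel):
        fit, panel = fit_and_panel
        bad = panel.copy()
        bad.loc[bad.index[0], "genetic_group"] = "martian"
        with pytest.raises(LMMError, match="unseen"):
            predict_standardized(fit, bad)

    def test_covariate_free_model_ignores_standardization(self):
        trees = simulate_population(_all_clonal_population(5, 3, seed=6))
        vc = VarianceConfig(sigma2_G=0.5, sigma2_R=0.5, beta_dbh=0.0)
        panel = simulate_trait_panel(trees, vc, seed=7, trait="y")
        spec = ModelSpec(response="y", fixed_terms=["genetic_group", "year"],
                         random_factor="tree_id")
        fit = fit_reml(spec, panel)
        raw = predict_standardized(fit, panel)
        std = predict_standardized(fit, standardized_newdata(panel, spec))
        assert np.allclose(raw, std)

    def test_average_annual_increment_worked_example(self):
        """DBH growing 11 -> 12 cm over a 10-year span is 0.1 cm/yr."""
        years = np.arange(2007, 2018)
        cdbh = np.linspace(11.0, 12.0, 11)
        assert average_annual_increment(cdbh, years) == pytest.approx(0.1)


class TestTermSignificance:
    def test_large_group_effect_is_detected(self):
        hits = 0
        for rep in range(20):
            trees = simulate_population(_all_clonal_population(6, 3,
                                                               seed=rep))
            vc = VarianceConfig(sigma2_G=5.0, sigma2_tree=0.1, sigma2_R=0.5)
            panel = simulate_trait_panel(trees, vc, seed=100 + rep,
                                         trait="y")
            fit = fit_reml(ModelSpec(
                response="y", fixed_terms=["genetic_group", "year", "cDBH"],
                random_factor="tree_id"), panel, n_restarts=1)
            an = term_significance(fit, panel)
            row = an.loc[an.term == "genetic_group"]
            hits += bool(row["significant"].iloc[0])
        assert hits == 20

    def test_single_level_factor_is_dropped(self):
        trees = simulate_population(_all_clonal_population(4, 3, seed=9))
        panel = simulate_trait_panel(trees, VarianceConfig(sigma2_R=1.0),
                                     seed=10, trait="y")
        panel["const"] = "only"
        fit = fit_reml(ModelSpec(response="y",
                                 fixed_terms=["const", "year"],
                                 random_factor="tree_id"), panel)
        an = term_significance(fit, panel)
        assert "const" not in set(an["term"])
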