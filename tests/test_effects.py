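"""Mixed-model effect estimation: design, fits, posterior contrasts, R2.

The GLMM fits run through the glmmTMB backend; to keep the suite fast all
fits for this module are performed in a single batched R session
(module-scoped fixture).  The gaussian fit is cross-checked against
statsmodels MixedLM as an independent oracle.
"""

import numpy as np
import pandas as pd
import pytest

import camoquant.effects as fx

BACKGROUNDS = ["dark_grey", "medium_orange", "light_grey"]
SPECIES = ["S_maderensis", "S_porcus"]
OBSERVERS = ["triplefin", "goby"]


# ---------------------------------------------------------------------------
# simulated datasets with known structure

def _simulate_gaussian(seed, fish_sd=0.05, resid_sd=0.01, effects=(0.0, 0.024, 0.054)):
    rng = np.random.default_rng(seed)
    eff = dict(zip(BACKGROUNDS, effects))
    rows = []
    for sp, n in zip(SPECIES, (24, 18)):
        for i in range(n):
            u = rng.normal(0, fish_sd)
            for bg in BACKGROUNDS:
                for ob in OBSERVERS:
                    rows.append(dict(fish_id=f"{sp}_{i}", species=sp, background=bg,
                                     observer=ob,
                                     y=0.1 + eff[bg] + u + rng.normal(0, resid_sd)))
    return pd.DataFrame(rows)


def _simulate_gamma(seed, mult=1.5, fish_sd_log=0.1, cv=0.05):
    rng = np.random.default_rng(seed)
    eff = {"dark_grey": 1.0, "medium_orange": mult, "light_grey": mult**2}
    shape = 1.0 / cv**2
    rows = []
    for sp, n in zip(SPECIES, (24, 18)):
        for i in range(n):
            u = rng.normal(0, fish_sd_log)
            for bg in BACKGROUNDS:
                for ob in OBSERVERS:
                    mu = 0.1 * eff[bg] * np.exp(u)
                    rows.append(dict(fish_id=f"{sp}_{i}", species=sp, background=bg,
                                     observer=ob, y=rng.gamma(shape, mu / shape)))
    return pd.DataFrame(rows)


def _simulate_variance_shares(seed, n_fish=150):
    # 40% fixed / 50% random / 10% residual variance on the identity scale
    rng = np.random.default_rng(seed)
    eff = dict(zip(BACKGROUNDS, (-np.sqrt(0.6), 0.0, np.sqrt(0.6))))  # var = 0.4
    rows = []
    for i in range(n_fish):
        u = rng.normal(0, np.sqrt(0.5))
        for bg in BACKGROUNDS:
            rows.append(dict(fish_id=f"f{i}", background=bg,
                             y=eff[bg] + u + rng.normal(0, np.sqrt(0.1))))
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def fits():
    """One R session for every model this module needs."""
    null_tab = _simulate_gaussian(1, fish_sd=0.0, resid_sd=0.01,
                                  effects=(0.0, 0.0, 0.0))
    gauss_tab = _simulate_gaussian(2)
    gamma_tab = _simulate_gamma(3)
    shares_tab = _simulate_variance_shares(4)
    specs = [
        {"table": null_tab, "response": "y", "family": "gaussian", "random": "intercept"},
        {"table": gauss_tab, "response": "y", "family": "gaussian", "random": "intercept"},
        {"table": gamma_tab, "response": "y", "family": "gamma", "random": "intercept"},
        {"table": shares_tab, "response": "y", "family": "gaussian",
         "random": "intercept", "factors": {"background": BACKGROUNDS}},
    ]
    fitted = fx.fit_glmm_multi(specs)
    return dict(zip(["null", "gaussian", "gamma", "shares"], fitted)), {
        "null": null_tab, "gaussian": gauss_tab, "gamma": gamma_tab,
        "shares": shares_tab}


class TestFactorDesign:
    def test_full_interaction_dimensions(self):
        d = fx.FactorDesign({"background": BACKGROUNDS, "species": SPECIES,
                             "observer": OBSERVERS})
        # 3*2*2 cells => 12 columns for the saturated design
        assert d.n_cols == 12
        assert d.colnames[0] == "Intercept"

    def test_rows_reproduce_cell_means_logic(self):
        d = fx.FactorDesign({"background": BACKGROUNDS, "species": SPECIES})
        cell = {"background": "medium_orange", "species": "S_porcus"}
        x = d.row(cell)
        # intercept + bg dummy + species dummy + their interaction
        np.testing.assert_array_equal(x, [1, 1, 0, 1, 1, 0])

    def test_matrix_matches_row_builder(self):
        d = fx.FactorDesign({"background": BACKGROUNDS, "observer": OBSERVERS})
        df = pd.DataFrame([{"background": bg, "observer": ob}
                           for bg in BACKGROUNDS for ob in OBSERVERS])
        X = d.matrix(df)
        for i, rec in df.iterrows():
            np.testing.assert_array_equal(X[i], d.row(rec.to_dict()))

    def test_partial_cell_expansion(self):
        d = fx.FactorDesign({"background": BACKGROUNDS, "species": SPECIES})
        cells = d.cells({"background": "dark_grey"})
        assert len(cells) == 2
        assert all(c["background"] == "dark_grey" for c in cells)


class TestFitGlmm:
    def test_null_effects_within_3se(self, fits):
        fit, _ = fits[0]["null"], fits[1]
        se = np.sqrt(np.diag(fit.cov))
        bg_cols = [j for j, n in enumerate(fit.design.colnames)
                   if n.startswith("background[") and ":" not in n]
        for j in bg_cols:
            assert abs(fit.beta[j]) < 3 * se[j]

    def test_gaussian_variance_components_recovered(self, fits):
        fit = fits[0]["gaussian"]
        assert fit.converged
        sd_fish = np.sqrt(fit.re_cov[0, 0])
        assert sd_fish == pytest.approx(0.05, rel=0.30)
        assert fit.dispersion == pytest.approx(0.01, rel=0.15)

    def test_gaussian_matches_statsmodels_mixedlm(self, fits):
        """Independent oracle: statsmodels MixedLM on the same design."""
        import statsmodels.formula.api as smf

        fit, tables = fits[0]["gaussian"], fits[1]["gaussian"]
        df = tables.copy()
        X = fit.design.matrix(df)
        for j in range(1, X.shape[1]):
            df[f"x{j}"] = X[:, j]
        formula = "y ~ " + " + ".join(f"x{j}" for j in range(1, X.shape[1]))
        sm_fit = smf.mixedlm(formula, df, groups=df["fish_id"]).fit(reml=False)
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params.to_numpy(),
                                   rtol=1e-3, atol=1e-5)
        sm_sd_fish = np.sqrt(sm_fit.cov_re.iloc[0, 0])
        assert np.sqrt(fit.re_cov[0, 0]) == pytest.approx(sm_sd_fish, rel=0.05)

    def test_gamma_multiplicative_effect_recovered(self, fits):
        fit = fits[0]["gamma"]
        j = fit.design.colnames.index("background[medium_orange]")
        se = np.sqrt(fit.cov[j, j])
        assert np.exp(fit.beta[j]) == pytest.approx(1.5, abs=3 * se * 1.5 + 0.02)

    def test_validation_errors(self):
        df = _simulate_gaussian(5).drop(columns=["observer"])
        with pytest.raises(ValueError, match="missing columns"):
            fx.fit_glmm(df, "y", factors={"background": BACKGROUNDS,
                                          "observer": OBSERVERS})
        with pytest.raises(ValueError, match="family"):
            fx.fit_glmm(df, "y", family="tweedie")


class TestPosteriorDraws:
    def test_seeded_determinism(self, fits):
        fit = fits[0]["gaussian"]
        d1 = fx.posterior_draws(fit, 500, seed=42)
        d2 = fx.posterior_draws(fit, 500, seed=42)
        np.testing.assert_array_equal(d1, d2)
        assert not np.array_equal(d1, fx.posterior_draws(fit, 500, seed=43))

    def test_moments_match_fit(self, fits):
        fit = fits[0]["gaussian"]
        draws = fx.posterior_draws(fit, 100_000, seed=0)
        se = np.sqrt(np.diag(fit.cov))
        np.testing.assert_allclose(draws.mean(axis=0), fit.beta, atol=4 * se.max() / 100)
        emp = np.cov(draws.T)
        frob = np.linalg.norm(emp - fit.cov) / np.linalg.norm(fit.cov)
        assert frob < 0.05


class TestMedianDifference:
    def test_identical_cells_give_zero(self, fits):
        fit = fits[0]["gaussian"]
        draws = fx.posterior_draws(fit, 1000, seed=0)
        cell = {"background": "dark_grey", "species": "S_porcus", "observer": "goby"}
        assert fx.median_difference_ci(fit, draws, cell, cell) == (0.0, 0.0, 0.0)

    def test_converges_to_plugin_difference_as_cov_shrinks(self, fits):
        import copy

        fit = copy.deepcopy(fits[0]["gaussian"])
        a = {"background": "light_grey", "species": "S_maderensis",
             "observer": "triplefin"}
        b = {"background": "dark_grey", "species": "S_maderensis",
             "observer": "triplefin"}
        plugin = fit.predict_cell(a) - fit.predict_cell(b)
        fit.cov = fit.cov * 1e-12
        draws = fx.posterior_draws(fit, 2000, seed=0)
        med, lo, hi = fx.median_difference_ci(fit, draws, a, b)
        assert med == pytest.approx(plugin, abs=1e-6)
        assert hi - lo < 1e-5

    def test_recovers_simulated_gaussian_effect(self, fits):
        fit = fits[0]["gaussian"]
        draws = fx.posterior_draws(fit, 4000, seed=1)
        med, lo, hi = fx.median_difference_ci(
            fit, draws, {"background": "medium_orange"}, {"background": "dark_grey"})
        assert lo < 0.024 < hi

    def test_inestimable_cell_error(self, fits):
        fit = fits[0]["gaussian"]
        draws = fx.posterior_draws(fit, 100, seed=0)
        with pytest.raises(ValueError, match="valid level"):
            fx.median_difference_ci(fit, draws, {"background": "plaid"},
                                    {"background": "dark_grey"})


class TestRSquared:
    def test_constructed_variance_shares(self, fits):
        fit = fits[0]["shares"]
        marg, cond = fx.r_squared(fit)
        assert marg == pytest.approx(0.40, abs=0.05)
        assert cond == pytest.approx(0.90, abs=0.04)

    def test_ordering_invariant(self, fits):
        for fit in fits[0].values():
            marg, cond = fx.r_squared(fit)
            assert 0.0 <= marg <= cond <= 1.0
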