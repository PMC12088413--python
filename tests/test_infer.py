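"""Statistical models: decay GLMM, predictions, contrasts, count models."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from meioquant import glmm, infer, synthgen


def _decay_cells(seed=1, plant_sd=0.15, plants=4, cells=40, genotypes=None):
    gts = genotypes or synthgen.default_genotypes()
    if plant_sd is not None:
        gts = [
            synthgen.GenotypeParams(
                name=g.name, beta0=g.beta0, beta1=g.beta1, plant_sd=plant_sd,
                gamma_shape=g.gamma_shape, total_axis_um=g.total_axis_um,
            )
            for g in gts
        ]
    tab = synthgen.simulate_cell_table(gts, plants, cells, seed=seed)
    return tab.rename(columns={"H_true": "accumulation_pct",
                               "asynapsis_true": "asy1_length_um",
                               "n_prominent_true": "n_prominent"})


def test_decay_fit_recovers_parameters(genotypes):
    cells = _decay_cells(seed=2)
    fit = infer.fit_gamma_decay(cells)
    true = {g.name: (g.beta0, g.beta1) for g in genotypes}
    for g in fit.genotypes:
        assert fit.beta0(g) == pytest.approx(true[g][0], abs=0.35)
        lo, hi = fit.beta1_ci(g)
        assert lo - 0.002 <= true[g][1] <= hi + 0.002
    assert 0.05 <= fit.sigma_u <= 0.3
    assert fit.shape == pytest.approx(4.0, rel=0.3)
    assert not fit.glm_fallback


def test_decay_zero_handling():
    cells = _decay_cells(seed=3)
    cells.loc[cells.index[:5], "asy1_length_um"] = 0.0
    fit = infer.fit_gamma_decay(cells)
    assert fit.zero_replacement is not None and fit.zero_replacement > 0


def test_single_plant_falls_back_to_glm():
    cells = _decay_cells(seed=4, plants=1, plant_sd=0.0)
    fit = infer.fit_gamma_decay(cells)
    assert fit.glm_fallback and fit.sigma_u == 0.0


def test_glmm_matches_glm_when_no_plant_variance():
    """sigma_u -> 0 limit: Laplace marginal likelihood equals the plain Gamma
    GLM ML log-likelihood and the coefficients agree within 1%."""
    cells = _decay_cells(seed=5, plant_sd=0.0, plants=4)
    mixed = infer.fit_gamma_decay(cells)
    plain = infer.fit_gamma_decay(cells, force_glm=True)
    assert mixed.sigma_u < 0.05
    assert mixed.loglik == pytest.approx(plain.loglik, rel=1e-4)
    np.testing.assert_allclose(mixed.params, plain.params, rtol=0.01)


def test_predict_asynapsis_closed_forms():
    cells = _decay_cells(seed=6)
    fit = infer.fit_gamma_decay(cells)
    # overwrite with exact coefficients: flat 200 µm and a known decay
    fit.params = np.array([math.log(200.0)] * 4 + [0.0] * 4)
    fit.cov = np.eye(8) * 1e-6
    pred = infer.predict_asynapsis(fit, 37.0)
    assert np.allclose(pred["mean_um"], 200.0, rtol=1e-9)
    fit.params = np.array([math.log(100.0)] * 4 + [-0.05] * 4)
    pred = infer.predict_asynapsis(fit, 20.0)
    assert pred["mean_um"].iloc[0] == pytest.approx(100.0 * math.exp(-1.0), rel=1e-9)
    with pytest.raises(ValueError):
        infer.predict_asynapsis(fit, 150.0)


def test_ci_width_shrinks_with_sample_size():
    wide = infer.fit_gamma_decay(_decay_cells(seed=7, cells=13))
    narrow = infer.fit_gamma_decay(_decay_cells(seed=7, cells=125))
    g = wide.genotypes[0]
    w1 = np.diff(wide.beta1_ci(g))[0]
    w2 = np.diff(narrow.beta1_ci(g))[0]
    assert w2 < w1


def test_wald_contrast_of_coefficient_with_itself():
    cells = _decay_cells(seed=8, plants=2, cells=20)
    fit = infer.fit_gamma_decay(cells)
    tab = infer.wald_contrasts(fit, {"self": {"b1[2X]": 1.0, "b1[2X]": -0.0}})
    # a zero-weight contrast: estimate 0, p = 1
    tab0 = infer.wald_contrasts(
        fit, {"null": np.zeros(len(fit.param_names))}
    )
    assert tab0["estimate"].iloc[0] == 0.0 and tab0["p_raw"].iloc[0] == 1.0


def test_holm_textbook_arithmetic():
    cells = _decay_cells(seed=8, plants=2, cells=20)
    fit = infer.fit_gamma_decay(cells)
    # check the adjustment math directly on the helper statsmodels uses
    adj = multipletests([0.01, 0.02, 0.20], method="holm")[1]
    np.testing.assert_allclose(adj, [0.03, 0.04, 0.20])


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_holm_properties(pvals):
    adj = multipletests(pvals, method="holm")[1]
    assert np.all(adj >= np.asarray(pvals) - 1e-15)
    assert np.all(adj <= 1.0)
    if len(pvals) == 1:
        assert adj[0] == pytest.approx(pvals[0])
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in the raw order


def test_unknown_contrast_coefficient_raises():
    cells = _decay_cells(seed=8, plants=2, cells=20)
    fit = infer.fit_gamma_decay(cells)
    with pytest.raises(ValueError, match="non-estimable"):
        infer.wald_contrasts(fit, {"bad": {"b1[nope]": 1.0}})


# ---------------------------------------------------------------------------
# Count models
# ---------------------------------------------------------------------------

def test_poisson_data_fitted_as_nb_reaches_poisson_limit():
    rng = np.random.default_rng(9)
    cells = pd.DataFrame(dict(
        genotype=np.repeat(["A", "B"], 400),
        y=rng.poisson(np.repeat([3.0, 6.0], 400)),
    ))
    nb = infer.fit_count_model(cells, "y", family="negbin")
    po = infer.fit_count_model(cells, "y", family="poisson")
    assert nb.theta > 50.0
    np.testing.assert_allclose(nb.params, po.params, rtol=0.02)


def test_quadrivalent_mean_recovery():
    g_means = {"NEO": 3.0, "HYB": 0.9, "EST": 0.3}
    gts = [synthgen.GenotypeParams(name=n, beta0=math.log(50), beta1=0.0,
                                   plant_sd=0.0, quad_mean=m, total_axis_um=400.0)
           for n, m in g_means.items()]
    tab = synthgen.simulate_cell_table(gts, 1, 200, seed=13)
    fit = infer.fit_count_model(tab, "n_quadrivalent_true", family="negbin",
                                covariate=None)
    for n, m in g_means.items():
        est = math.exp(fit.coef(f"b0[{n}]"))
        se_mc = math.sqrt((m + m * m / 5.0) / 200.0)
        assert abs(est - m) < 3.5 * se_mc


def test_all_zero_response_raises():
    cells = pd.DataFrame(dict(genotype=["A"] * 10, y=0))
    with pytest.raises(ValueError, match="all-zero"):
        infer.fit_count_model(cells, "y")


def test_scorability_covariate_enters_model():
    rng = np.random.default_rng(14)
    cells = pd.DataFrame(dict(
        genotype=np.repeat(["A", "B"], 300),
        scorability=rng.choice(list("ABC"), 600),
        y=rng.poisson(3.0, 600),
    ))
    fit = infer.fit_count_model(cells, "y", family="poisson",
                                scorability="scorability")
    assert any(n.startswith("scorability[") for n in fit.param_names)


def test_count_glmm_random_intercept_recovered():
    """Poisson GLMM with plant intercepts: sigma_u recovered, slopes unbiased."""
    rng = np.random.default_rng(15)
    rows = []
    for p in range(12):
        u = rng.normal(0, 0.4)
        x = rng.uniform(0, 2, 60)
        y = rng.poisson(np.exp(0.5 + 0.7 * x + u))
        rows.append(pd.DataFrame(dict(plant_id=f"p{p}", x=x, y=y, genotype="A")))
    cells = pd.concat(rows, ignore_index=True)
    fit = infer.fit_count_model(cells, "y", covariate="x", family="poisson",
                                random_intercept="plant_id")
    assert fit.sigma_u == pytest.approx(0.4, abs=0.15)
    assert fit.coef("b1[A]") == pytest.approx(0.7, abs=0.08)


def test_crossover_asynapsis_slope_recovery():
    rng = np.random.default_rng(16)
    asy = rng.uniform(0, 200, 600)
    y = rng.poisson(np.exp(math.log(17.0) + 0.0015 * asy))
    cells = pd.DataFrame(dict(asy1_length_um=asy, n_prominent=y))
    fit = infer.fit_co_asynapsis(cells)
    b = fit.coef("b1")
    se = fit.se("b1")
    assert b - 1.96 * se <= 0.0015 <= b + 1.96 * se
    assert fit.wald_p("b1") < 0.05
    # shuffling the covariate destroys the association
    cells2 = cells.assign(asy1_length_um=rng.permutation(asy))
    fit2 = infer.fit_co_asynapsis(cells2)
    assert infer.pseudo_r2(fit2)[0] < 0.15


def test_co_asynapsis_null_slope_not_significant():
    rng = np.random.default_rng(17)
    cells = pd.DataFrame(dict(asy1_length_um=rng.uniform(0, 200, 400),
                              n_prominent=rng.poisson(17.0, 400)))
    fit = infer.fit_co_asynapsis(cells)
    assert fit.wald_p("b1") > 0.01  # no real effect at this seed


def test_small_sample_warning_flag():
    rng = np.random.default_rng(18)
    cells = pd.DataFrame(dict(asy1_length_um=rng.uniform(0, 50, 10),
                              n_prominent=rng.poisson(10.0, 10)))
    fit = infer.fit_co_asynapsis(cells)
    assert "10 cells" in fit.warning


def test_parallels_model_ranks_low_coalignment_genotype_lowest():
    """A genotype generated with fewer coaligned pairs per µm of ASY1 is
    predicted lowest at ASY1 = 100 µm."""
    gts = []
    for name, a in (("2X", 0.9), ("NEO-4X", 0.2), ("HYB-4X", 0.9), ("EST-4X", 0.9)):
        gts.append(synthgen.GenotypeParams(
            name=name, beta0=math.log(80.0), beta1=0.0, plant_sd=0.0,
            parallel_intercept=a, parallel_slope=0.9, total_axis_um=400.0,
        ))
    tab = synthgen.simulate_cell_table(gts, 2, 100, seed=19)
    tab["asy1_per_100um"] = tab["asynapsis_true"] / 100.0
    fit = infer.fit_count_model(tab, "n_parallel_true", covariate="asy1_per_100um",
                                family="negbin")
    pred = {g: math.exp(fit.coef(f"b0[{g}]") + fit.coef(f"b1[{g}]") * 1.0)
            for g in ("2X", "NEO-4X", "HYB-4X", "EST-4X")}
    assert min(pred, key=pred.get) == "NEO-4X"


# ---------------------------------------------------------------------------
# Pseudo-R2 and family selection
# ---------------------------------------------------------------------------

def test_pseudo_r2_zero_fixed_variance():
    cells = _decay_cells(seed=20, plants=2, cells=30)
    fit = infer.fit_gamma_decay(cells)
    fit.var_components = {"fixed": 0.0, "random": 0.1, "residual": 0.3}
    marg, cond = infer.pseudo_r2(fit)
    assert marg == 0.0 and cond == pytest.approx(0.25)


def test_pseudo_r2_equal_when_no_random_effect():
    cells = _decay_cells(seed=21, plants=1, plant_sd=0.0)
    fit = infer.fit_gamma_decay(cells)
    marg, cond = infer.pseudo_r2(fit)
    assert marg == cond


def test_pseudo_r2_strong_signal_regime(sim_cells):
    fit = infer.fit_gamma_decay(sim_cells)
    assert fit.r2_conditional >= 0.6


def test_pseudo_r2_identity_link_rejected():
    rng = np.random.default_rng(22)
    cells = pd.DataFrame(dict(genotype="A", x=rng.uniform(0, 10, 200),
                              y=rng.poisson(2.0 + 1.0 * rng.uniform(0, 10, 200))))
    fit = infer.fit_count_model(cells, "y", covariate="x", family="poisson",
                                link="identity")
    with pytest.raises(ValueError, match="identity"):
        infer.pseudo_r2(fit)


def test_select_family_prefers_nb_when_overdispersed():
    g = synthgen.GenotypeParams(name="A", beta0=math.log(50), beta1=0.0,
                                plant_sd=0.0, quad_mean=4.0, nb_theta=2.0,
                                total_axis_um=400.0)
    tab = synthgen.simulate_cell_table([g], 1, 600, seed=23)
    best, table = infer.select_family(tab, [
        dict(label="poisson", response="n_quadrivalent_true", family="poisson"),
        dict(label="negbin", response="n_quadrivalent_true", family="negbin"),
    ])
    assert best.family == "negbin"
    assert table.loc[table["label"] == "poisson", "overdispersed"].iloc[0]


def test_select_family_prefers_simpler_when_equidispersed():
    rng = np.random.default_rng(24)
    cells = pd.DataFrame(dict(genotype="A", y=rng.poisson(4.0, 600)))
    best, _ = infer.select_family(cells, [
        dict(label="negbin", response="y", family="negbin"),
        dict(label="poisson", response="y", family="poisson"),
    ])
    assert best.family == "poisson"


def test_select_family_tie_takes_first_declared():
    rng = np.random.default_rng(25)
    cells = pd.DataFrame(dict(genotype="A", y=rng.poisson(4.0, 300)))
    best, table = infer.select_family(cells, [
        dict(label="first", response="y", family="poisson"),
        dict(label="second", response="y", family="poisson"),
    ])
    assert table[table["selected"]]["label"].iloc[0] == "first"


def test_crossovers_per_chromosome_pair():
    assert infer.crossovers_per_chromosome_pair(17.0, 16) == pytest.approx(1.0625)
    assert infer.crossovers_per_chromosome_pair(10.0, 8) == pytest.approx(1.25)
    with pytest.raises(ValueError):
        infer.crossovers_per_chromosome_pair(10.0, 0)
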