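"""Statistical models for synapsis dynamics and meiotic-stability counts.

The central model is an exponential decay of asynapsis (µm of ASY1) against
the HEI10 accumulation level H, fitted as a Gamma GLMM with log link,

    E[asynapsis | plant] = exp(beta0_g + beta1_g * H + u_plant),
    u_plant ~ Normal(0, sigma_u^2),

with per-genotype intercepts and decay exponents and a per-plant random
intercept (Laplace approximation, :mod:`meioquant.glmm`). Count responses
(quadrivalents, univalents, coalignment parallels, elongated ZYP1 segments,
crossover foci) are fitted as Poisson or negative-binomial regressions —
plain GLMs via statsmodels, mixed variants via the same Laplace machinery.
Inference uses Wald z statistics with Holm correction within each family of
contrasts, and Nakagawa-style variance-partition pseudo-R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from . import glmm

__all__ = [
    "DecayFit",
    "CountFit",
    "fit_gamma_decay",
    "predict_asynapsis",
    "wald_contrasts",
    "fit_count_model",
    "fit_co_asynapsis",
    "pseudo_r2",
    "select_family",
    "crossovers_per_chromosome_pair",
]


def crossovers_per_chromosome_pair(mean_foci: float, n_chromosome_pairs: int) -> float:
    """Crossovers per chromosome pair from a diakinesis-stage focus mean.

    Each late-prophase HEI10 focus marks one Class I crossover; dividing the
    per-cell mean by the number of chromosome pairs (8 in diploid, 16 in
    tetraploid *A. arenosa*) gives the per-pair crossover rate.
    """
    if n_chromosome_pairs <= 0:
        raise ValueError("n_chromosome_pairs must be positive")
    if mean_foci < 0:
        raise ValueError("mean_foci must be nonnegative")
    return mean_foci / n_chromosome_pairs


def _nakagawa(var_fixed: float, var_random: float, var_resid: float):
    denom = var_fixed + var_random + var_resid
    if denom <= 0:
        return 0.0, 0.0
    return var_fixed / denom, (var_fixed + var_random) / denom


@dataclass
class DecayFit:
    """Fitted exponential-decay Gamma-GLMM."""

    genotypes: list[str]
    param_names: list[str]
    params: np.ndarray
    cov: np.ndarray  # fixed-effect block
    sigma_u: float
    shape: float
    loglik: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    n_cells: int
    n_plants: int
    glm_fallback: bool = False
    zero_replacement: float | None = None
    var_components: dict = field(default_factory=dict)

    def __post_init__(self):
        cov = np.asarray(self.cov)
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance not symmetric")
        if np.linalg.eigvalsh((cov + cov.T) / 2).min() < -1e-8:
            raise ValueError("covariance not positive semi-definite")

    def _idx(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise ValueError(f"unknown coefficient {name!r}") from None

    def beta0(self, genotype: str) -> float:
        return float(self.params[self._idx(f"b0[{genotype}]")])

    def beta1(self, genotype: str) -> float:
        return float(self.params[self._idx(f"b1[{genotype}]")])

    def se(self, name: str) -> float:
        i = self._idx(name)
        return float(np.sqrt(self.cov[i, i]))

    def beta1_ci(self, genotype: str, level: float = 0.95) -> tuple[float, float]:
        z = -special.ndtri((1.0 - level) / 2.0)
        b = self.beta1(genotype)
        s = self.se(f"b1[{genotype}]")
        return b - z * s, b + z * s

    def slope_pvalues(self) -> dict[str, float]:
        """Two-sided Wald p for each genotype's decay exponent vs 0."""
        out = {}
        for g in self.genotypes:
            b = self.beta1(g)
            s = self.se(f"b1[{g}]")
            z = b / s if s > 0 else 0.0
            out[g] = float(2.0 * special.ndtr(-abs(z)))
        return out


def _decay_design(cells: pd.DataFrame, genotypes, acc_col: str):
    n = len(cells)
    X = np.zeros((n, 2 * len(genotypes)))
    names = [f"b0[{g}]" for g in genotypes] + [f"b1[{g}]" for g in genotypes]
    H = cells[acc_col].to_numpy(dtype=float)
    for k, g in enumerate(genotypes):
        m = (cells["genotype"] == g).to_numpy()
        X[m, k] = 1.0
        X[m, len(genotypes) + k] = H[m]
    return X, names


def fit_gamma_decay(
    cells: pd.DataFrame,
    response: str = "asy1_length_um",
    accumulation: str = "accumulation_pct",
    plant: str = "plant_id",
    force_glm: bool = False,
) -> DecayFit:
    """Fit the exponential-decay Gamma-GLMM with plant random intercepts.

    Exact-zero responses (fully synapsed cells) are incompatible with the
    Gamma likelihood and are replaced by half the smallest positive measured
    length, recorded in ``zero_replacement``. When every genotype has a
    single plant the random intercept is confounded with the genotype
    intercepts, so the model falls back to a plain Gamma GLM
    (``glm_fallback=True``), with the ML shape profiled afterwards.
    """
    cells = cells.copy()
    y = cells[response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError(f"negative values in {response!r}")
    zero_replacement = None
    if np.any(y == 0):
        pos = y[y > 0]
        if pos.size == 0:
            raise ValueError(f"all {response!r} values are zero")
        zero_replacement = float(pos.min() / 2.0)
        y = np.where(y == 0, zero_replacement, y)
    genotypes = list(pd.unique(cells["genotype"]))
    X, names = _decay_design(cells, genotypes, accumulation)
    plants = cells[plant].to_numpy()
    n_plants = len(np.unique(plants))
    plants_per_g = cells.groupby("genotype", sort=False)[plant].nunique()

    use_glm = force_glm or bool((plants_per_g <= 1).all())
    if use_glm:
        res = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit(
            scale="X2"
        )
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        mu = np.exp(X @ beta)
        shape, loglik = glmm.profile_gamma_shape(y, mu)
        sigma_u = 0.0
        aic = 2 * (len(beta) + 1) - 2 * loglik
    else:
        fit = glmm.fit_glmm(y, X, plants, family="gamma", param_names=names)
        beta = fit.params
        cov = fit.cov_fixed
        shape = fit.shape
        sigma_u = fit.sigma_u
        loglik = fit.loglik
        aic = fit.aic

    lp = X @ beta
    var_f = float(np.var(lp))
    var_u = sigma_u**2
    var_e = float(special.polygamma(1, shape))  # Gamma log-link residual variance
    r2m, r2c = _nakagawa(var_f, var_u, var_e)
    return DecayFit(
        genotypes=genotypes,
        param_names=names,
        params=np.asarray(beta, dtype=float),
        cov=(cov + cov.T) / 2.0,
        sigma_u=float(sigma_u),
        shape=float(shape),
        loglik=float(loglik),
        aic=float(aic),
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_cells=len(cells),
        n_plants=int(n_plants),
        glm_fallback=use_glm,
        zero_replacement=zero_replacement,
        var_components={"fixed": var_f, "random": var_u, "residual": var_e},
    )


def predict_asynapsis(fit: DecayFit, H: float, level: float = 0.95) -> pd.DataFrame:
    """Population-level predicted asynapsis (µm) per genotype at level H.

    The mean is exp(beta0_g + beta1_g * H) with the random effect at zero;
    the CI is a delta-method interval on the linear predictor, exponentiated.
    """
    if not 0.0 <= H <= 100.0:
        raise ValueError("H must lie in [0, 100]")
    z = -special.ndtri((1.0 - level) / 2.0)
    rows = []
    for g in fit.genotypes:
        i0 = fit.param_names.index(f"b0[{g}]")
        i1 = fit.param_names.index(f"b1[{g}]")
        lp = fit.params[i0] + fit.params[i1] * H
        var = fit.cov[i0, i0] + H * H * fit.cov[i1, i1] + 2 * H * fit.cov[i0, i1]
        se = float(np.sqrt(max(var, 0.0)))
        rows.append(
            dict(genotype=g, H=H, mean_um=float(np.exp(lp)),
                 ci_low_um=float(np.exp(lp - z * se)),
                 ci_high_um=float(np.exp(lp + z * se)))
        )
    return pd.DataFrame(rows)


def _contrast_vector(spec, param_names):
    c = np.zeros(len(param_names))
    if isinstance(spec, dict):
        for name, w in spec.items():
            if name not in param_names:
                raise ValueError(f"non-estimable contrast: unknown coefficient {name!r}")
            c[param_names.index(name)] = w
    else:
        spec = np.asarray(spec, dtype=float)
        if spec.size != len(param_names):
            raise ValueError("contrast vector length mismatch")
        c = spec
    return c


def wald_contrasts(fit, contrasts: dict) -> pd.DataFrame:
    """Wald z tests of linear coefficient combinations, Holm-adjusted.

    ``contrasts`` maps labels to either coefficient-weight dicts (e.g.
    ``{"b1[NEO-4X]": 1, "b1[2X]": -1}``) or full-length weight vectors. The
    Holm adjustment is applied within the requested family of contrasts.
    """
    names = list(fit.param_names)
    params = np.asarray(fit.params)
    cov = np.asarray(fit.cov if hasattr(fit, "cov") else fit.cov_fixed)
    rows = []
    for label, spec in contrasts.items():
        c = _contrast_vector(spec, names)
        est = float(c @ params)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        if se == 0.0:
            z = 0.0 if est == 0.0 else np.inf * np.sign(est)
        else:
            z = est / se
        p = float(2.0 * special.ndtr(-abs(z))) if np.isfinite(z) else 0.0
        rows.append(dict(label=label, estimate=est, se=se, z=float(z), p_raw=p))
    table = pd.DataFrame(rows)
    table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]
    return table


@dataclass
class CountFit:
    """Fitted count regression (GLM or GLMM)."""

    family: str  # 'poisson' | 'negbin'
    link: str
    param_names: list[str]
    params: np.ndarray
    cov: np.ndarray
    theta: float | None
    sigma_u: float
    loglik: float
    aic: float
    r2: float | None
    n_obs: int
    pearson_dispersion: float
    poisson_limit: bool = False
    warning: str = ""
    mu: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.family == "negbin" and self.theta is not None and self.theta <= 0:
            raise ValueError("negative-binomial theta must be > 0")

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def wald_p(self, name: str) -> float:
        s = self.se(name)
        z = self.coef(name) / s if s > 0 else 0.0
        return float(2.0 * special.ndtr(-abs(z)))


def _count_design(cells, covariate, genotype_col, scorability, per_genotype_slopes):
    genotypes = list(pd.unique(cells[genotype_col])) if genotype_col else []
    cols, names = [], []
    n = len(cells)
    if genotypes:
        for g in genotypes:
            cols.append((cells[genotype_col] == g).to_numpy(dtype=float))
            names.append(f"b0[{g}]")
    else:
        cols.append(np.ones(n))
        names.append("b0")
    if covariate is not None:
        x = cells[covariate].to_numpy(dtype=float)
        if genotypes and per_genotype_slopes:
            for g in genotypes:
                cols.append(x * (cells[genotype_col] == g).to_numpy(dtype=float))
                names.append(f"b1[{g}]")
        else:
            cols.append(x)
            names.append("b1")
    if scorability is not None:
        classes = sorted(pd.unique(cells[scorability]))
        for c in classes[1:]:  # first class is the reference
            cols.append((cells[scorability] == c).to_numpy(dtype=float))
            names.append(f"scorability[{c}]")
    return np.column_stack(cols), names, genotypes


def _nb_profile_glm(y, X, link, theta_grid_log=(-2.0, 12.0)):
    """NB2 GLM by profiling theta over a statsmodels GLM fit."""
    from scipy import optimize

    link_obj = sm.families.links.Log() if link == "log" else sm.families.links.Identity()

    def fit_at(log_theta):
        alpha = float(np.exp(-log_theta))  # statsmodels alpha = 1/theta
        fam = sm.families.NegativeBinomial(link=link_obj, alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam).fit(scale=1.0)
        return res

    def negll(log_theta):
        try:
            return -fit_at(float(log_theta)).llf
        except Exception:
            return 1e12

    opt = optimize.minimize_scalar(negll, bounds=theta_grid_log, method="bounded")
    theta = float(np.exp(opt.x))
    res = fit_at(float(opt.x))
    return res, theta


def fit_count_model(
    cells: pd.DataFrame,
    response: str,
    covariate: str | None = None,
    family: str = "negbin",
    link: str = "log",
    random_intercept: str | None = None,
    scorability: str | None = None,
    genotype_col: str | None = "genotype",
    per_genotype_slopes: bool = True,
) -> CountFit:
    """Poisson / negative-binomial regression for count responses.

    Genotype enters as per-genotype intercepts, the optional covariate as
    per-genotype slopes (interaction), scorability class as an additive fixed
    effect, and ``random_intercept`` (a column such as ``plant_id``) as a
    scalar random intercept (log link only, Laplace approximation). Used for
    quadrivalent/univalent counts, parallels vs ASY1 length, elongated-ZYP1
    segments vs total ZYP1 length, and crossover foci vs asynapsis.
    """
    y = cells[response].to_numpy(dtype=float)
    if np.any(y < 0) or not np.all(y == np.round(y)):
        raise ValueError(f"{response!r} must be nonnegative integers")
    if np.all(y == 0):
        raise ValueError(f"all-zero response {response!r}")
    X, names, _ = _count_design(cells, covariate, genotype_col, scorability,
                                per_genotype_slopes)

    warning = ""
    if random_intercept is not None:
        if link != "log":
            raise ValueError("random intercepts are supported with the log link only")
        fit = glmm.fit_glmm(y, X, cells[random_intercept].to_numpy(),
                            family=family, param_names=names)
        params, cov = fit.params, fit.cov_fixed
        theta = fit.theta
        sigma_u = fit.sigma_u
        loglik, aic = fit.loglik, fit.aic
        mu = np.exp(X @ params)  # population level
    else:
        sigma_u = 0.0
        if family == "poisson":
            link_obj = sm.families.links.Log() if link == "log" else sm.families.links.Identity()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # identity link domain warning
                res = sm.GLM(y, X, family=sm.families.Poisson(link=link_obj)).fit(scale=1.0)
            theta = None
        elif family == "negbin":
            res, theta = _nb_profile_glm(y, X, link)
        else:
            raise ValueError(f"unknown family {family!r}")
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        loglik = float(res.llf)
        k = len(params) + (1 if family == "negbin" else 0)
        aic = 2 * k - 2 * loglik
        mu = np.asarray(res.mu)

    poisson_limit = bool(family == "negbin" and theta is not None and theta > 1e4)
    if poisson_limit:
        warning = "NB dispersion diverged; fit is at the Poisson limit"

    var_mu = mu if family == "poisson" or poisson_limit else mu + mu**2 / theta
    df = max(len(y) - len(params), 1)
    pearson = float(np.sum((y - mu) ** 2 / np.maximum(var_mu, 1e-12)) / df)

    r2 = None
    if link == "log":
        lam = float(np.mean(mu))
        var_e = np.log1p(1.0 / lam) if family == "poisson" or poisson_limit else np.log1p(
            1.0 / lam + 1.0 / theta
        )
        var_f = float(np.var(X @ params))
        r2 = _nakagawa(var_f, sigma_u**2, var_e)[1]

    return CountFit(
        family=family, link=link, param_names=names,
        params=np.asarray(params, dtype=float), cov=(cov + cov.T) / 2.0,
        theta=theta, sigma_u=float(sigma_u), loglik=float(loglik),
        aic=float(aic), r2=r2, n_obs=len(y), pearson_dispersion=pearson,
        poisson_limit=poisson_limit, warning=warning, mu=mu,
    )


def fit_co_asynapsis(
    cells: pd.DataFrame,
    response: str = "n_prominent",
    covariate: str = "asy1_length_um",
    log_covariate: bool = False,
) -> CountFit:
    """Poisson GLM of crossover-focus count on the extent of asynapsis.

    Fitted on late-pachytene cells (after the per-genotype accumulation
    cutoffs), pooling genotypes: log E[count] = a + b * asynapsis, with
    log(asynapsis + 1) available as an alternative covariate. Reports the
    Nakagawa pseudo-R² and the Wald p for the slope.
    """
    cells = cells.copy()
    xcol = covariate
    if log_covariate:
        xcol = f"log1p_{covariate}"
        cells[xcol] = np.log1p(cells[covariate].to_numpy(dtype=float))
    fit = fit_count_model(
        cells, response=response, covariate=xcol, family="poisson", link="log",
        random_intercept=None, genotype_col=None,
    )
    if len(cells) < 20:
        fit.warning = (fit.warning + "; " if fit.warning else "") + \
            f"only {len(cells)} cells: estimates may be unstable"
    return fit


def pseudo_r2(fit) -> tuple[float, float]:
    """Nakagawa variance-partition pseudo-R² (marginal, conditional).

    marginal = var_fixed / (var_fixed + var_random + var_residual);
    conditional adds the random-intercept variance to the numerator. For
    fits without random effects the two coincide.
    """
    if isinstance(fit, DecayFit):
        vc = fit.var_components
        return _nakagawa(vc["fixed"], vc["random"], vc["residual"])
    if isinstance(fit, CountFit):
        if fit.link != "log":
            raise ValueError(
                f"residual variance undefined for family {fit.family!r} with "
                f"link {fit.link!r}"
            )
        lam = float(np.mean(fit.mu))
        if fit.family == "poisson" or fit.poisson_limit:
            var_e = np.log1p(1.0 / lam)
        else:
            var_e = np.log1p(1.0 / lam + 1.0 / fit.theta)
        # fixed-effect variance on the linear-predictor scale
        var_f = float(np.var(np.log(np.maximum(fit.mu, 1e-12))))
        return _nakagawa(var_f, fit.sigma_u**2, var_e)
    raise ValueError(f"unsupported fit type {type(fit).__name__}")


def select_family(cells: pd.DataFrame, candidates: list[dict]) -> tuple[CountFit, pd.DataFrame]:
    """Fit candidate count-model specs and pick the best by AIC.

    Candidates are keyword dicts for :func:`fit_count_model` (plus an
    optional 'label'). Within 2 AIC of the best, the simpler family wins
    (Poisson over NB, no random intercept over random intercept), in
    declaration order on exact ties. Overdispersion is flagged when the
    Pearson chi-square / df exceeds 1.5 — a simplified residual diagnostic.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate specifications")
    fits, rows, errors = [], [], []
    for i, spec in enumerate(candidates):
        spec = dict(spec)
        label = spec.pop("label", f"candidate_{i}")
        try:
            f = fit_count_model(cells, **spec)
        except Exception as err:  # noqa: BLE001 - per-candidate failure is data
            errors.append(f"{label}: {err}")
            continue
        complexity = (0 if f.family == "poisson" else 1) + (0 if f.sigma_u == 0 else 1)
        fits.append((label, f, complexity, i))
        rows.append(dict(label=label, family=f.family, sigma_u=f.sigma_u,
                         aic=f.aic, pearson_dispersion=f.pearson_dispersion,
                         overdispersed=f.pearson_dispersion > 1.5))
    if not fits:
        raise RuntimeError("all candidates failed: " + "; ".join(errors))
    table = pd.DataFrame(rows)
    best_aic = min(f.aic for _, f, _, _ in fits)
    eligible = [t for t in fits if t[1].aic <= best_aic + 2.0]
    eligible.sort(key=lambda t: (t[2], t[1].aic, t[3]))
    label, best, _, _ = eligible[0]
    table["selected"] = table["label"] == label
    return best, table
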