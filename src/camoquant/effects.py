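"""Mixed-model effect sizes: GLMM fits, posterior simulation, contrasts, R2.

Per-response generalized linear mixed models mirror the study design:
fixed effects *background* x *species* x *observer* (full interaction),
fish identity as a random intercept, optionally with a random slope over
background.  Families: gaussian (identity) for hue and achromatic contrast,
Gamma (log) for luminance and chromatic contrast, negative binomial (log)
for fluorescent pixel counts.  Effect sizes are reported as the median
difference between predicted cell means on the response scale with a 95%
compatibility interval, obtained from multivariate-normal draws around the
maximum-likelihood estimates ("posterior simulation"); p-values are not
reported.  Model fit is summarized by marginal and conditional R2
(variance-decomposition / Nakagawa style).

Fitting is performed by glmmTMB (R) behind this module's interface; see
:mod:`camoquant._r_glmm`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import polygamma

from ._r_glmm import run_glmm_jobs

__all__ = [
    "FactorDesign",
    "FittedEffects",
    "FAMILIES",
    "validate_trial_table",
    "fit_glmm",
    "fit_glmm_many",
    "posterior_draws",
    "median_difference_ci",
    "r_squared",
    "background_contrast_table",
]

FAMILIES = ("gaussian", "gamma", "negbin")

#: Canonical factor levels, in model order (first level = reference).
DEFAULT_LEVELS = {
    "background": ["dark_grey", "medium_orange", "light_grey"],
    "species": ["S_maderensis", "S_porcus"],
    "observer": ["triplefin", "goby"],
}


class FactorDesign:
    """Treatment-coded full-interaction fixed-effect design.

    Columns: intercept, then main-effect dummies for each factor in order,
    then all interaction products, mirroring a ``f1 * f2 * ...`` formula
    with treatment contrasts.
    """

    def __init__(self, factors: dict[str, list[str]]):
        if not factors:
            raise ValueError("need at least one factor")
        self.factors = {k: list(v) for k, v in factors.items()}
        names = list(self.factors)
        terms: list[tuple[tuple[str, str], ...]] = [()]  # intercept
        for size in range(1, len(names) + 1):
            for combo in itertools.combinations(names, size):
                levels = [self.factors[f][1:] for f in combo]
                for lv in itertools.product(*levels):
                    terms.append(tuple(zip(combo, lv)))
        self.terms = terms

    @property
    def colnames(self) -> list[str]:
        out = []
        for term in self.terms:
            out.append("Intercept" if not term else
                       ":".join(f"{f}[{lv}]" for f, lv in term))
        return out

    @property
    def n_cols(self) -> int:
        return len(self.terms)

    def row(self, cell: dict[str, str]) -> np.ndarray:
        for f in self.factors:
            if cell.get(f) not in self.factors[f]:
                raise ValueError(f"cell must give a valid level for factor {f!r}")
        x = np.empty(self.n_cols)
        for j, term in enumerate(self.terms):
            x[j] = float(all(cell[f] == lv for f, lv in term))
        return x

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        X = np.empty((len(df), self.n_cols))
        for j, term in enumerate(self.terms):
            col = np.ones(len(df))
            for f, lv in term:
                col = col * (df[f].to_numpy() == lv)
            X[:, j] = col
        return X

    def cells(self, partial: dict[str, str] | None = None) -> list[dict[str, str]]:
        """All full cells consistent with a (possibly partial) cell spec."""
        partial = partial or {}
        free = {f: self.factors[f] for f in self.factors if f not in partial}
        out = []
        for combo in itertools.product(*free.values()):
            cell = dict(partial)
            cell.update(dict(zip(free, combo)))
            out.append(cell)
        return out


@dataclass
class FittedEffects:
    """A fitted GLMM: estimates, covariance, variance components, diagnostics."""

    family: str
    design: FactorDesign
    beta: np.ndarray
    cov: np.ndarray
    re_cov: np.ndarray
    re_names: list[str]
    var_random: float
    dispersion: float  # gaussian: residual sd; gamma: CV; negbin: theta
    loglik: float
    converged: bool
    singular: bool
    random_structure: str
    response: str
    mean_response: float
    var_fixed: float
    meta: dict = field(default_factory=dict)

    @property
    def inverse_link(self):
        return (lambda x: x) if self.family == "gaussian" else np.exp

    def predict_cell(self, cell: dict[str, str], beta: np.ndarray | None = None) -> float:
        b = self.beta if beta is None else beta
        return float(self.inverse_link(self.design.row(cell) @ b))


def validate_trial_table(df: pd.DataFrame, response: str,
                         factors: dict[str, list[str]]) -> None:
    required = {"fish_id", response, *factors}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    if not np.all(np.isfinite(df[response].to_numpy(dtype=float))):
        raise ValueError(f"non-finite values in response {response!r}")
    for f, levels in factors.items():
        unknown = set(df[f].unique()) - set(levels)
        if unknown:
            raise ValueError(f"unknown levels {sorted(unknown)} for factor {f!r}")
    if "species" in factors:
        per_fish = df.groupby("fish_id")["species"].nunique()
        if (per_fish > 1).any():
            raise ValueError("each fish must belong to exactly one species")


def _build_job(df, response, family, factors, random, design):
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    validate_trial_table(df, response, factors)
    X = design.matrix(df)
    xcols = [f"x{j}" for j in range(X.shape[1])]
    data = pd.DataFrame(X, columns=xcols)
    data[response] = df[response].to_numpy(dtype=float)
    data["fish_id"] = df["fish_id"].to_numpy()
    job = {
        "response": response,
        "family": family,
        "x_cols": xcols,
        "group": "fish_id",
        "random": random,
    }
    if random == "slope":
        if "background" not in factors:
            raise ValueError("random slope is taken over background")
        data["background"] = df["background"].to_numpy()
        job["slope_factor"] = "background"
        job["slope_levels"] = factors["background"]
    return job, data, X


def _num(v) -> float:
    """Robust scalar conversion for values round-tripped through R/JSON."""
    if v is None or (isinstance(v, str) and v in ("NA", "NaN", "null")):
        return float("nan")
    return float(v)


def _to_fit(res, design, family, response, df, X, random) -> FittedEffects:
    p = design.n_cols
    beta = np.asarray(res["beta"], dtype=float)
    if beta.size != p:
        raise RuntimeError("fixed-effect dimension mismatch between R and design")
    cov = np.asarray(res["vcov"], dtype=float).reshape(p, p)
    k = len(res["re_names"]) if isinstance(res["re_names"], list) else 1
    re_names = res["re_names"] if isinstance(res["re_names"], list) else [res["re_names"]]
    re_cov = np.asarray(res["re_cov"], dtype=float).reshape(k, k)
    eta = X @ beta
    y = df[response].to_numpy(dtype=float)
    structure = res.get("random", random)
    return FittedEffects(
        family=family,
        design=design,
        beta=beta,
        cov=cov,
        re_cov=re_cov,
        re_names=list(re_names),
        var_random=_num(res["var_random"]),
        dispersion=_num(res["sigma"]),
        loglik=_num(res["loglik"]),
        converged=bool(res["converged"]),
        singular=bool(res.get("singular", False)),
        random_structure=structure,
        response=response,
        mean_response=float(np.mean(y)),
        var_fixed=float(np.var(eta)),
        meta={
            "backend": "glmmTMB",
            "random_requested": random,
            "random_fell_back": bool(res.get("fell_back", False)),
            "coef_names": design.colnames,
        },
    )


def fit_glmm(table: pd.DataFrame, response: str, family: str = "gaussian",
             factors: dict[str, list[str]] | None = None,
             random: str = "intercept") -> FittedEffects:
    """Fit one GLMM for a long-format trial table.

    ``factors`` maps factor column names to their ordered levels (first =
    reference); defaults to the study's background/species/observer design
    restricted to columns present in the table.  ``random`` is
    ``"intercept"`` or ``"slope"`` (random background slope per fish, falling
    back to intercept-only if singular).
    """
    return fit_glmm_many([table], response, family, factors, random)[0]


def fit_glmm_many(tables: list[pd.DataFrame], response: str,
                  family: str = "gaussian",
                  factors: dict[str, list[str]] | None = None,
                  random: str = "intercept") -> list[FittedEffects]:
    """Fit the same model on many tables in a single R session (fast path)."""
    if factors is None:
        cols = set(tables[0].columns)
        factors = {f: lv for f, lv in DEFAULT_LEVELS.items() if f in cols}
    design = FactorDesign(factors)
    jobs, datas, Xs = [], [], []
    for df in tables:
        job, data, X = _build_job(df, response, family, factors, random, design)
        jobs.append(job)
        datas.append(data)
        Xs.append(X)
    results = run_glmm_jobs(jobs, datas)
    return [
        _to_fit(res, design, family, response, df, X, random)
        for res, df, X in zip(results, tables, Xs)
    ]


def fit_glmm_multi(specs: list[dict]) -> list["FittedEffects"]:
    """Fit heterogeneous models (different tables/responses/families) in one
    R session.  Each spec dict: table, response, family, random, optionally
    factors."""
    jobs, datas, metas = [], [], []
    for spec in specs:
        df = spec["table"]
        factors = spec.get("factors")
        if factors is None:
            cols = set(df.columns)
            factors = {f: lv for f, lv in DEFAULT_LEVELS.items() if f in cols}
        design = FactorDesign(factors)
        job, data, X = _build_job(df, spec["response"], spec["family"], factors,
                                  spec.get("random", "intercept"), design)
        jobs.append(job)
        datas.append(data)
        metas.append((design, spec, df, X))
    results = run_glmm_jobs(jobs, datas)
    return [
        _to_fit(res, design, spec["family"], spec["response"], df, X,
                spec.get("random", "intercept"))
        for res, (design, spec, df, X) in zip(results, metas)
    ]


def posterior_draws(fit: FittedEffects, n: int = 10000,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Multivariate-normal draws of the fixed-effect vector around the fit.

    This is the parametric "posterior simulation" used for compatibility
    intervals: draws ~ N(beta_hat, V_hat).  A non-PSD covariance (numerical)
    is repaired by clipping negative eigenvalues at zero, with a note in
    the returned array's companion metadata (fit.meta).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = 0.5 * (fit.cov + fit.cov.T)
    w, V = np.linalg.eigh(cov)
    if w.min() < 0:
        if w.min() < -1e-8 * max(w.max(), 1.0):
            fit.meta["cov_repaired"] = float(w.min())
        w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    z = rng.standard_normal((n, len(fit.beta)))
    return fit.beta + z @ A.T


def _cell_predictions(fit: FittedEffects, draws: np.ndarray,
                      partial: dict[str, str]) -> np.ndarray:
    """Per-draw predicted mean for a (possibly partial) cell, response scale.

    Partial cells are averaged over the unspecified factors with equal cell
    weights, on the response scale.
    """
    cells = fit.design.cells(partial)
    rows = np.stack([fit.design.row(c) for c in cells])  # (m, p)
    eta = draws @ rows.T  # (n, m)
    return fit.inverse_link(eta).mean(axis=1)


def median_difference_ci(fit: FittedEffects, draws: np.ndarray,
                         cell_a: dict[str, str], cell_b: dict[str, str]
                         ) -> tuple[float, float, float]:
    """Median difference (a minus b) of predicted means, with 95% CI.

    Differences are computed per draw on the response scale; the reported
    effect is their median with the central 95% compatibility interval.
    """
    diff = _cell_predictions(fit, draws, cell_a) - _cell_predictions(fit, draws, cell_b)
    lo, med, hi = np.percentile(diff, [2.5, 50.0, 97.5])
    return float(med), float(lo), float(hi)


def r_squared(fit: FittedEffects) -> tuple[float, float]:
    """Marginal and conditional R2 by latent-scale variance decomposition.

    marginal = var_f / (var_f + var_r + var_e),
    conditional = (var_f + var_r) / (var_f + var_r + var_e), where var_f is
    the variance of the fixed-effect linear predictor, var_r the mean
    random-effect variance and var_e the family-specific residual variance
    on the link (latent) scale: sigma^2 for gaussian, trigamma(shape) for
    Gamma-log, ln(1 + 1/mu + 1/theta) for negative-binomial-log.
    """
    var_f = fit.var_fixed
    var_r = fit.var_random
    if fit.family == "gaussian":
        var_e = fit.dispersion**2
    elif fit.family == "gamma":
        shape = 1.0 / fit.dispersion**2  # glmmTMB sigma = CV for Gamma
        var_e = float(polygamma(1, shape))
    elif fit.family == "negbin":
        mu = fit.mean_response
        if mu <= 0:
            raise ValueError("negbin R2 undefined for non-positive mean response")
        var_e = float(np.log1p(1.0 / mu + 1.0 / fit.dispersion))
    else:  # pragma: no cover
        raise ValueError(fit.family)
    total = var_f + var_r + var_e
    if total <= 0:
        raise ValueError("degenerate zero-variance model; R2 undefined")
    return var_f / total, (var_f + var_r) / total


def background_contrast_table(fit: FittedEffects, draws: np.ndarray) -> pd.DataFrame:
    """All pairwise background differences per species (x observer), shaped
    like the study's effect-size tables."""
    factors = fit.design.factors
    bgs = factors["background"]
    pairs = [(b, a) for i, a in enumerate(bgs) for b in bgs[i + 1:]]
    other = [f for f in factors if f != "background"]
    rows = []
    for combo in itertools.product(*[factors[f] for f in other]):
        base = dict(zip(other, combo))
        for hi, lo in pairs:
            med, l, h = median_difference_ci(
                fit, draws, {**base, "background": hi}, {**base, "background": lo}
            )
            rows.append({**base, "contrast": f"{hi} - {lo}",
                         "median": med, "ci_lo": l, "ci_hi": h})
    return pd.DataFrame(rows)
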