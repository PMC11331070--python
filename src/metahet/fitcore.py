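"""Fixed-effect binomial logistic regression with Wald inference.

This module is the statistical engine shared by the six extinction/mortality
model structures and by the Monte-Carlo power analysis.  It fits binomial
logit models by iteratively reweighted least squares (IRLS) with step-halving,
so the deviance is non-increasing across iterations, and reports Wald z tests
(two-sided normal p-values) per coefficient.

The six model structures differ only in their fixed-effect design:

1. heterozygosity (He) alone;
2. He plus demographic and habitat covariates, no interactions;
3. model 2 plus He x log nest count and He x log connectivity;
4. covariates plus categorical year and a separate He slope per year;
5. covariates plus 1-generation population-trend category and a separate He
   slope per trend category;
6. as model 5 but with the 2-generation trend category.

Random effects (spatial fields, temporal autocorrelation) are deliberately
out of scope: the engine matches the plain logistic regression used inside
the power analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitResult",
    "ModelSpec",
    "build_model_spec",
    "build_design",
    "fit_logistic",
    "fit_model",
    "wald_pvalue",
]

#: continuous covariates entering models 2-6 (z-standardized columns)
DEMO_ENV_TERMS = (
    "log_nest_count_z",
    "ntrend_z",
    "log_area_z",
    "log_connectivity_z",
    "host_abundance_z",
    "prop_low_veg_z",
    "prop_dry_z",
    "prop_grazed_z",
)

VALID_RESPONSES = ("annual_ext", "overwinter_ext", "nest_mortality")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect design for one of the six model structures."""

    model_id: int
    response: str
    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    categorical: tuple[str, ...] = ()
    #: interactions of He with every level of a categorical column
    slope_by: str | None = None


@dataclass
class FitResult:
    """Coefficients and Wald inference from a binomial logit fit."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    pvalues: np.ndarray
    converged: bool
    n_obs: int
    deviance: float
    n_iter: int = 0

    def coef_for(self, term: str) -> float:
        try:
            return float(self.coef[self.terms.index(term)])
        except ValueError:
            raise KeyError(f"term {term!r} not in fit: {self.terms}") from None

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coef": [float(v) for v in self.coef],
            "se": [float(v) for v in self.se],
            "z": [float(v) for v in self.z],
            "pvalues": [float(v) for v in self.pvalues],
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "deviance": float(self.deviance),
        }


def build_model_spec(model_id: int, response: str) -> ModelSpec:
    """Return the fixed-effect term structure for models 1-6."""
    if response not in VALID_RESPONSES:
        raise ValueError(f"unknown response {response!r}; expected one of {VALID_RESPONSES}")
    if model_id == 1:
        return ModelSpec(1, response, main_effects=("he_z",))
    if model_id == 2:
        return ModelSpec(2, response, main_effects=("he_z",) + DEMO_ENV_TERMS)
    if model_id == 3:
        return ModelSpec(
            3,
            response,
            main_effects=("he_z",) + DEMO_ENV_TERMS,
            interactions=(("he_z", "log_nest_count_z"), ("he_z", "log_connectivity_z")),
        )
    if model_id == 4:
        # year enters as a categorical factor; He gets one slope per year and
        # no global main effect, mirroring the per-year coefficients reported.
        return ModelSpec(
            4,
            response,
            main_effects=DEMO_ENV_TERMS,
            categorical=("year",),
            slope_by="year",
        )
    if model_id == 5:
        return ModelSpec(
            5,
            response,
            main_effects=DEMO_ENV_TERMS,
            categorical=("trend_1gen",),
            slope_by="trend_1gen",
        )
    if model_id == 6:
        return ModelSpec(
            6,
            response,
            main_effects=DEMO_ENV_TERMS,
            categorical=("trend_2gen",),
            slope_by="trend_2gen",
        )
    raise ValueError(f"unknown model_id {model_id}; expected 1..6")


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Construct the design matrix (with intercept) for a model spec.

    Categorical factors are dummy-coded dropping the first (sorted) level;
    ``slope_by`` adds one He-slope column per level of that factor.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for term in spec.main_effects:
        cols.append(df[term].to_numpy(dtype=float))
        names.append(term)
    for cat in spec.categorical:
        levels = sorted(df[cat].astype(str).unique())
        for lev in levels[1:]:
            cols.append((df[cat].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{cat}[{lev}]")
    for a, b in spec.interactions:
        cols.append(df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    if spec.slope_by is not None:
        levels = sorted(df[spec.slope_by].astype(str).unique())
        for lev in levels:
            mask = (df[spec.slope_by].astype(str) == lev).to_numpy(dtype=float)
            cols.append(df["he_z"].to_numpy(dtype=float) * mask)
            names.append(f"he_z:{spec.slope_by}[{lev}]")
    return np.column_stack(cols), names


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # binomial deviance, valid for y in [0,1] (fractional y supported)
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    terms: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood binomial logit fit by IRLS.

    Convergence is declared when the deviance change drops below ``tol``.
    Step-halving enforces a non-increasing deviance.  Perfect separation or
    failure to converge is flagged (``converged=False``) with the last
    iterate's coefficients; the caller decides how to treat such fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if len(terms) != p:
        raise ValueError("terms length must match design columns")

    beta = np.zeros(p)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(y, mu)
    converged = False
    singular = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            singular = True
            break
        # step-halving: never accept an iterate that increases the deviance
        step = beta_new - beta
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * step
            eta_c = np.clip(X @ cand, -500, 500)
            mu_c = 1.0 / (1.0 + np.exp(-eta_c))
            dev_c = _deviance(y, mu_c)
            if dev_c <= dev + 1e-12:
                break
            frac *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        if abs(dev - dev_c) < tol:
            dev = dev_c
            converged = True
            break
        dev = dev_c

    # separation / degeneracy heuristics: a perfect fit on binary data or
    # runaway coefficients mean the MLE does not exist
    if converged and np.max(np.abs(beta)) > 1e2:
        converged = False
    is_binary = np.all((y == 0) | (y == 1))
    if converged and is_binary and dev < 1e-6:
        converged = False
    if y.min() == y.max():
        converged = False

    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    if singular:
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    return FitResult(
        terms=list(terms),
        coef=beta,
        se=se,
        z=zstat,
        pvalues=pvals,
        converged=converged,
        n_obs=n,
        deviance=dev,
        n_iter=it,
    )


def fit_model(df: pd.DataFrame, model_id: int, response: str) -> FitResult:
    """Build the design for one of the six model structures and fit it.

    ``df`` is an analysis table from :func:`metahet.covars.build_analysis_table`
    with a binary column named after the response.
    """
    spec = build_model_spec(model_id, response)
    X, names = build_design(df, spec)
    y = df[response].to_numpy(dtype=float)
    return fit_logistic(X, y, terms=names)


def wald_pvalue(fit: FitResult, term: str) -> float:
    """Two-sided normal p-value for one coefficient."""
    try:
        idx = fit.terms.index(term)
    except ValueError:
        raise KeyError(f"term {term!r} not in fit: {fit.terms}") from None
    return float(fit.pvalues[idx])
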