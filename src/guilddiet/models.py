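"""Geographic and environmental linear models with spatial diagnostics.

Per species, each diet metric (H, J, log10 mean prey size, logit mammal
proportion) is regressed on either the geographic predictor set
(latitude, longitude, elevation, island factor) or the environmental set
(mean annual temperature, cumulated annual precipitation, % tree cover).
Continuous predictors are z-standardized within species; collinear pairs
(|Pearson r| above a threshold, default 0.65) are resolved by a priority
list.  Residual spatial autocorrelation is tested with Moran's I on
inverse great-circle-distance weights; models with a significant I are
refit by GLS with an exponential correlation structure
C_ij = exp(-d_ij / rho), rho estimated by profile maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GuildDietError
from .pooling import distance_matrix_km

log = logging.getLogger("guilddiet")

GEOGRAPHIC_PREDICTORS = ["lat", "lon", "elevation", "island"]
ENVIRONMENTAL_PREDICTORS = ["temperature", "precipitation", "tree_cover"]
#: when two predictors exceed the collinearity threshold, the one earlier
#: in this list is retained (temperature beats precipitation)
COLLINEARITY_PRIORITY = ["temperature", "tree_cover", "precipitation", "lat", "lon", "elevation"]

RESPONSES = {
    "H": "identity",
    "J": "identity",
    "mean_prey_size_g": "log10",
    "prop_mammals": "logit",
}


def standardize_predictors(
    design: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """z-score the named continuous columns (mean 0, sample SD 1) and
    return the (mean, sd) record; constant columns are dropped with a
    warning.  Factor columns are left untouched by not naming them."""
    out = design.copy()
    record: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = out[col].astype(float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            log.warning("standardize_predictors: dropping zero-variance column %r", col)
            out = out.drop(columns=[col])
            continue
        out[col] = (vals - mu) / sd
        record[col] = (mu, sd)
    return out, record


def transform_response(values, kind: str, eps: float = 0.001) -> np.ndarray:
    """identity, log10 (positive values only) or logit with clamping of
    proportions into [eps, 1-eps] before ln(p/(1-p))."""
    x = np.asarray(values, dtype=float)
    if kind == "identity":
        return x
    if kind == "log10":
        if np.any(x[np.isfinite(x)] <= 0):
            raise GuildDietError("log10 transform requires positive values")
        return np.log10(x)
    if kind == "logit":
        p = np.clip(x, eps, 1.0 - eps)
        return np.log(p / (1.0 - p))
    raise GuildDietError(f"unknown transform {kind!r}")


def collinearity_screen(
    design: pd.DataFrame,
    columns: list[str],
    r_threshold: float = 0.65,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise Pearson screen: for each pair with |r| > threshold, drop
    the lower-priority member.  Returns retained columns and the full
    pairwise-r report."""
    priority = priority or COLLINEARITY_PRIORITY
    if len(design) < 3:
        raise GuildDietError("collinearity screen needs at least 3 rows")

    def rank(c: str) -> int:
        return priority.index(c) if c in priority else len(priority)

    report_rows = []
    dropped: set[str] = set()
    cols = list(columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(np.corrcoef(design[a].astype(float), design[b].astype(float))[0, 1])
            report_rows.append({"predictor_a": a, "predictor_b": b, "pearson_r": r})
            if abs(r) > r_threshold:
                loser = b if rank(a) <= rank(b) else a
                if loser not in dropped:
                    log.info(
                        "collinearity: |r(%s, %s)| = %.2f > %.2f; dropping %s",
                        a, b, abs(r), r_threshold, loser,
                    )
                dropped.add(loser)
    retained = [c for c in cols if c not in dropped]
    return retained, pd.DataFrame(report_rows, columns=["predictor_a", "predictor_b", "pearson_r"])


@dataclass
class LinearModelFit:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2: float
    method: str = "OLS"
    response: str = ""
    transform: str = "identity"
    species: str = ""
    model_set: str = ""
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    rho_km: float | None = None

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.t), self.df)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def term_stats(self, term: str) -> tuple[float, float, float, int, float]:
        """(estimate, se, t, df, p) for one term."""
        i = self.terms.index(term)
        return (
            float(self.beta[i]),
            float(self.se[i]),
            float(self.t[i]),
            self.df,
            float(self.p[i]),
        )


def _design_matrix(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    mat = X.astype(float).to_numpy()
    terms = ["intercept"] + list(X.columns)
    return np.column_stack([np.ones(len(X)), mat]), terms


def fit_ols(y, X: pd.DataFrame, **meta) -> LinearModelFit:
    """Ordinary least squares with an intercept.

    SE from sigma^2 (X'X)^-1 with sigma^2 = RSS/(n-p); t = beta/SE;
    df = n - p.  Rank deficiency raises an error naming the dependent
    columns.
    """
    y = np.asarray(y, dtype=float)
    Xm, terms = _design_matrix(X)
    n, p = Xm.shape
    if n <= p:
        raise GuildDietError(f"OLS needs n > p (n={n}, p={p})")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # identify offending columns by incremental rank
        dep = []
        for j in range(1, p):
            if np.linalg.matrix_rank(Xm[:, : j + 1]) == np.linalg.matrix_rank(Xm[:, :j]):
                dep.append(terms[j])
        raise GuildDietError(f"design matrix is rank deficient; dependent columns: {dep}")
    beta, _, _, _ = np.linalg.lstsq(Xm, y, rcond=None)
    fitted = Xm @ beta
    resid = y - fitted
    df = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return LinearModelFit(
        terms=terms, beta=beta, se=se, t=t, df=df, n=n,
        residuals=resid, fitted=fitted, sigma2=sigma2, method="OLS", **meta,
    )


@dataclass
class MoranResult:
    I: float
    expected: float
    var: float
    z: float
    p: float
    n: int
    variance_assumption: str = "normality"


def morans_I(
    residuals, lat, lon, variance: str = "normality", row_normalize: bool = False
) -> MoranResult:
    """Global Moran's I of model residuals on inverse-distance weights.

    w_ij = 1/d_ij (km, great-circle), w_ii = 0, rows unnormalized by
    default (``row_normalize=True`` divides each row by its sum, the
    convention of some spatial packages);
    I = (n / S0) * (sum_ij w_ij e_i e_j) / (sum_i e_i^2) on mean-centred
    residuals.  E[I] = -1/(n-1); the variance comes from the classical
    normality (default) or randomization formula, with a two-sided p via
    the normal approximation.  Coincident points are an error — pool them
    first (the 20-km clustering precludes duplicates).
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if n < 5:
        raise GuildDietError("Moran's I needs at least 5 points")
    d = distance_matrix_km(lat, lon)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        raise GuildDietError(
            "coincident coordinates: inverse-distance weights undefined; pool duplicate sites first"
        )
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    if row_normalize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    e = e - e.mean()
    s0 = w.sum()
    num = float(e @ w @ e)
    den = float(e @ e)
    if den == 0.0:
        raise GuildDietError("Moran's I undefined for constant residuals")
    I = (n / s0) * num / den
    EI = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    if variance == "normality":
        var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - EI**2
    elif variance == "randomization":
        b2 = n * np.sum(e**4) / (den**2)
        var = (
            n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
            - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - EI**2
    else:
        raise GuildDietError(f"unknown variance assumption {variance!r}")
    z = (I - EI) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MoranResult(I=float(I), expected=EI, var=float(var), z=float(z), p=p,
                       n=n, variance_assumption=variance)


def _gls_profile(y: np.ndarray, Xm: np.ndarray, d: np.ndarray, rho: float):
    """GLS solution and profile log-likelihood at fixed rho."""
    n, p = Xm.shape
    C = np.exp(-d / rho)
    L = np.linalg.cholesky(C)
    y_w = _tri_solve(L, y)
    X_w = _tri_solve(L, Xm)
    beta, _, _, _ = np.linalg.lstsq(X_w, y_w, rcond=None)
    resid_w = y_w - X_w @ beta
    rss_w = float(resid_w @ resid_w)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2_ml = rss_w / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
    return beta, rss_w, logdet, ll, X_w, y_w


def _tri_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    return solve_triangular(L, b, lower=True)


def fit_gls_exponential(y, X: pd.DataFrame, lat, lon, **meta) -> LinearModelFit:
    """GLS with exponential spatial correlation C_ij = exp(-d_ij/rho).

    The range rho (km) maximizes the profile log-likelihood, searched by
    bounded scalar minimization on log rho over
    [log(d_min/10), log(10 d_max)].  SE/t/df are reported analogously to
    OLS with sigma^2 = whitened RSS/(n-p) and df = n - p.  A boundary or
    non-converged solution falls back to OLS with a warning and method
    flag ``OLS_fallback``.
    """
    y = np.asarray(y, dtype=float)
    Xm, terms = _design_matrix(X)
    n, p = Xm.shape
    if n <= p + 1:
        raise GuildDietError("GLS needs n > p + 1")
    d = distance_matrix_km(lat, lon)
    off = ~np.eye(n, dtype=bool)
    d_min = float(d[off].min())
    d_max = float(d.max())
    if d_min <= 0:
        raise GuildDietError("coincident coordinates: pool duplicate sites before GLS")
    lo, hi = np.log(d_min / 10.0), np.log(10.0 * d_max)

    def neg_ll(log_rho: float) -> float:
        try:
            return -_gls_profile(y, Xm, d, float(np.exp(log_rho)))[3]
        except np.linalg.LinAlgError:
            return np.inf

    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    at_boundary = (res.x - lo) < 1e-3 * (hi - lo) or (hi - res.x) < 1e-3 * (hi - lo)
    if not res.success or not np.isfinite(res.fun) or at_boundary:
        log.warning("GLS rho search hit boundary or failed to converge; falling back to OLS")
        fit = fit_ols(y, X, **meta)
        fit.method = "OLS_fallback"
        return fit
    rho = float(np.exp(res.x))
    beta, rss_w, _, _, X_w, y_w = _gls_profile(y, Xm, d, rho)
    df = n - p
    sigma2 = rss_w / df
    xtcx_inv = np.linalg.inv(X_w.T @ X_w)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtcx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    fitted = Xm @ beta
    return LinearModelFit(
        terms=terms, beta=beta, se=se, t=t, df=df, n=n,
        residuals=y - fitted, fitted=fitted, sigma2=sigma2,
        method="GLS_exp", rho_km=rho, **meta,
    )


def fit_species_models(
    metrics: pd.DataFrame,
    species: str,
    model_set: str,
    collinearity_r: float = 0.65,
    logit_eps: float = 0.001,
    moran_alpha: float = 0.05,
) -> tuple[list[LinearModelFit], list[MoranResult]]:
    """Fit all four responses for one species against one predictor set.

    Responses: H and J (identity), mean prey size (log10), mammal
    proportion (logit).  Rows with a missing response or predictor are
    dropped per model (counts logged).  The island factor is dropped
    automatically when only one level is present.  Moran's I is run on
    each OLS residual vector; a model with p < ``moran_alpha`` is refit
    by exponential-correlation GLS.
    """
    if model_set == "geographic":
        predictors = list(GEOGRAPHIC_PREDICTORS)
    elif model_set == "environmental":
        predictors = list(ENVIRONMENTAL_PREDICTORS)
    else:
        raise GuildDietError(f"unknown model set {model_set!r}")
    sub = metrics[metrics["predator"] == species].copy()
    if sub.empty:
        raise GuildDietError(f"no sites for species {species!r}")
    if "island" in predictors:
        if sub["island"].astype(bool).nunique() < 2:
            predictors.remove("island")
            log.info("%s: island factor single-level; dropped", species)
        else:
            sub["island"] = sub["island"].astype(bool).astype(float)
    continuous = [c for c in predictors if c != "island"]
    screened, _report = collinearity_screen(sub, continuous, r_threshold=collinearity_r)
    predictors = [c for c in predictors if c == "island" or c in screened]
    fits: list[LinearModelFit] = []
    morans: list[MoranResult] = []
    for response, kind in RESPONSES.items():
        cols = predictors + [response, "lat", "lon"]
        rows = sub.dropna(subset=[c for c in cols if c in sub.columns])
        n_dropped = len(sub) - len(rows)
        if n_dropped:
            log.info("%s %s ~ %s: dropped %d incomplete rows", species, response, model_set, n_dropped)
        if len(rows) <= len(predictors) + 2:
            log.warning("%s %s: too few rows (%d); skipped", species, response, len(rows))
            continue
        design = rows[predictors].copy()
        design, record = standardize_predictors(design, [c for c in predictors if c != "island"])
        y = transform_response(rows[response].to_numpy(), kind, eps=logit_eps)
        meta = dict(response=response, transform=kind, species=species,
                    model_set=model_set, standardization=record)
        fit = fit_ols(y, design, **meta)
        mi = morans_I(fit.residuals, rows["lat"].to_numpy(), rows["lon"].to_numpy())
        morans.append(mi)
        if mi.p < moran_alpha:
            log.info("%s %s (%s): Moran's I p=%.3g; refitting with exponential GLS",
                     species, response, model_set, mi.p)
            fit = fit_gls_exponential(
                y, design, rows["lat"].to_numpy(), rows["lon"].to_numpy(), **meta
            )
        fits.append(fit)
    return fits, morans


def fits_to_frame(fits: list[LinearModelFit]) -> pd.DataFrame:
    """Long-format coefficient table for export (models.csv)."""
    rows = []
    for f in fits:
        for i, term in enumerate(f.terms):
            rows.append(
                {
                    "species": f.species,
                    "model_set": f.model_set,
                    "response": f.response,
                    "transform": f.transform,
                    "term": term,
                    "estimate": float(f.beta[i]),
                    "se": float(f.se[i]),
                    "t": float(f.t[i]),
                    "df": f.df,
                    "p": float(f.p[i]),
                    "n": f.n,
                    "method": f.method,
                    "rho_km": f.rho_km if f.rho_km is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
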