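"""Sympatry-versus-allopatry tests of diet metrics.

A site is *sympatric* (competition factor 1) when its coordinates fall
inside the competitor's distribution range polygon, allopatric (0)
otherwise; boundary points count as inside.  Diet metrics are compared
between the two levels by OLS, optionally adjusting for habitat via
logit-transformed tree cover.  Because allopatric sites concentrate at
range edges, a covariate-controlled randomization test (Freedman-Lane
permutation of latitude/longitude-model residuals) separates the
geographic gradient from the sympatry effect proper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .io import GuildDietError
from .models import LinearModelFit, fit_ols, transform_response
from .pooling import SiteDiet

log = logging.getLogger("guilddiet")


def code_sympatry(diets: list[SiteDiet], competitor_range) -> pd.DataFrame:
    """0/1 competition factor per pooled site from range geometry.

    ``competitor_range`` is a shapely geometry (possibly multi-part) in
    WGS84; the point-in-polygon test uses ``covers`` so boundary points
    are sympatric.
    """
    if competitor_range.is_empty or not competitor_range.is_valid:
        raise GuildDietError("invalid or empty competitor range geometry")
    rows = []
    for d in diets:
        inside = competitor_range.covers(Point(d.lon, d.lat))
        rows.append(
            {
                "cluster_id": d.cluster_id,
                "predator": d.predator,
                "lat": d.lat,
                "lon": d.lon,
                "competition": int(inside),
                "tree_cover": d.covariates.get("tree_cover", np.nan),
            }
        )
    return pd.DataFrame(rows)


def _check_levels(labels: np.ndarray, min_per_level: int = 3) -> None:
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise GuildDietError(
            "competition factor has a single level; species untestable "
            "(as when nearly all sites overlap the competitor's range)"
        )
    if min(n0, n1) < min_per_level:
        raise GuildDietError(
            f"need >= {min_per_level} sites per competition level (have {n0} vs {n1})"
        )


def compare_sympatry(values, labels, **meta) -> LinearModelFit:
    """OLS of a diet metric on the 0/1 competition factor; the factor's
    coefficient is the sympatric-minus-allopatric mean difference."""
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=float)
    keep = np.isfinite(y)
    y, lab = y[keep], lab[keep]
    _check_levels(lab)
    X = pd.DataFrame({"competition": lab})
    return fit_ols(y, X, **meta)


def compare_sympatry_adjusted(values, labels, tree_cover, logit_eps: float = 0.001, **meta) -> LinearModelFit:
    """As :func:`compare_sympatry` with logit-transformed % tree cover as
    an additional predictor; tree cover enters as a proportion in [0,1]
    (percent inputs are rescaled)."""
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=float)
    tc = np.asarray(tree_cover, dtype=float)
    if np.nanmax(tc) > 1.0:
        tc = tc / 100.0
    keep = np.isfinite(y) & np.isfinite(tc)
    y, lab, tc = y[keep], lab[keep], tc[keep]
    _check_levels(lab)
    X = pd.DataFrame({"competition": lab, "logit_tree_cover": transform_response(tc, "logit", eps=logit_eps)})
    return fit_ols(y, X, **meta)


@dataclass
class RandomizationResult:
    observed: float
    null_stats: np.ndarray
    p_emp: float
    B: int
    seed: int
    scheme: str


def _factor_t(Y: np.ndarray, Xm: np.ndarray, col: int) -> np.ndarray:
    """t statistic of one design column for each response column of Y."""
    n, p = Xm.shape
    pinv = np.linalg.pinv(Xm)
    beta = pinv @ Y  # (p, B)
    resid = Y - Xm @ beta
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / (n - p)
    c = np.linalg.inv(Xm.T @ Xm)[col, col]
    se = np.sqrt(np.maximum(sigma2 * c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, beta[col] / se, 0.0)


def randomization_test(
    values,
    labels,
    lat,
    lon,
    B: int = 9999,
    seed: int = 0,
    scheme: str = "freedman_lane",
) -> RandomizationResult:
    """Permutation test of the competition effect controlling geography.

    ``freedman_lane`` (default): fit the nuisance model
    metric ~ lat + lon, permute its residuals, re-add the fitted
    nuisance surface, refit the full model (nuisance + competition) and
    collect the factor's t.  ``labels``: permute the 0/1 factor against
    the raw metric (sensitivity variant; does **not** absorb geographic
    confounding).  p_emp = (1 + #{|t*| >= |t_obs|}) / (B + 1), never
    exactly 0.  A degenerate nuisance fit falls back to label
    permutation with a warning.
    """
    if B < 99:
        raise GuildDietError("randomization test needs B >= 99")
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    keep = np.isfinite(y)
    y, lab, lat, lon = y[keep], lab[keep], lat[keep], lon[keep]
    _check_levels(lab)
    rng = np.random.default_rng(seed)
    n = y.size

    if scheme == "freedman_lane":
        Z = np.column_stack([np.ones(n), lat, lon])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            log.warning("degenerate geographic nuisance design; falling back to label permutation")
            return randomization_test(y, lab, lat, lon, B=B, seed=seed, scheme="labels")
        gamma = np.linalg.lstsq(Z, y, rcond=None)[0]
        nuis_fit = Z @ gamma
        e = y - nuis_fit
        X_full = np.column_stack([Z, lab])
        obs = float(_factor_t(y[:, None], X_full, col=3)[0])
        perms = np.argsort(rng.random((B, n)), axis=1)
        Ystar = nuis_fit[:, None] + e[perms].T  # (n, B)
        null = _factor_t(Ystar, X_full, col=3)
    elif scheme == "labels":
        X_obs = np.column_stack([np.ones(n), lab])
        obs = float(_factor_t(y[:, None], X_obs, col=1)[0])
        perms = np.argsort(rng.random((B, n)), axis=1)
        null = np.empty(B)
        # permuting labels changes the design; loop in blocks for memory
        for b in range(B):
            Xb = np.column_stack([np.ones(n), lab[perms[b]]])
            null[b] = _factor_t(y[:, None], Xb, col=1)[0]
    else:
        raise GuildDietError(f"unknown permutation scheme {scheme!r}")
    p_emp = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (B + 1.0)
    return RandomizationResult(
        observed=obs, null_stats=null, p_emp=float(p_emp), B=B, seed=seed, scheme=scheme
    )
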