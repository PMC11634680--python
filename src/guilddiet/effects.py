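"""Partial-correlation effect sizes and their Fisher transformation.

Each predictor's t statistic in a fitted linear model converts to a
partial correlation r = t / sqrt(t^2 + df), which is then
variance-stabilized as Zr = atanh(r).  Confidence intervals are built on
the Zr scale with SE = 1/sqrt(df - 1): for a model with k predictors and
n points df = n - k - 1, recovering the classical 1/sqrt(n - k - 2) for
a partial correlation controlling k - 1 covariates.  The forest table is
the numeric substrate of a cross-species forest plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GuildDietError
from .models import LinearModelFit

Z975 = 1.959963984540054


def partial_r_from_t(t: float, df: int) -> float:
    """r = t / sqrt(t^2 + df); df must be >= 1."""
    if df < 1:
        raise GuildDietError("partial r needs df >= 1")
    return float(t / np.sqrt(t * t + df))


def fisher_z(r: float) -> float:
    """Zr = 0.5 ln((1+r)/(1-r)) = atanh(r); |r| must be < 1."""
    if abs(r) >= 1.0:
        raise GuildDietError("Fisher z requires |r| < 1")
    return float(np.arctanh(r))


def zr_interval(zr: float, df: int) -> tuple[float, float]:
    """95% CI on the Zr scale: Zr +/- 1.96 / sqrt(df - 1).

    df < 3 yields a missing interval (NaN bounds) with a warning rather
    than an error: the point estimate remains usable.
    """
    if df < 3:
        import logging

        logging.getLogger("guilddiet").warning("zr_interval: df < 3, CI undefined")
        return (float("nan"), float("nan"))
    half = Z975 / np.sqrt(df - 1)
    return (zr - half, zr + half)


@dataclass
class EffectSize:
    species: str
    model_set: str
    response: str
    predictor: str
    t: float
    df: int
    r: float
    zr: float
    ci_lo: float
    ci_hi: float


def forest_table(fits: list[LinearModelFit]) -> pd.DataFrame:
    """One effect-size row per species x set x response x predictor
    (intercepts excluded)."""
    rows = []
    for f in fits:
        for i, term in enumerate(f.terms):
            if term == "intercept":
                continue
            t = float(f.t[i])
            r = partial_r_from_t(t, f.df)
            zr = fisher_z(r)
            lo, hi = zr_interval(zr, f.df)
            rows.append(
                EffectSize(
                    species=f.species,
                    model_set=f.model_set,
                    response=f.response,
                    predictor=term,
                    t=t,
                    df=f.df,
                    r=r,
                    zr=zr,
                    ci_lo=lo,
                    ci_hi=hi,
                ).__dict__
            )
    return pd.DataFrame(
        rows,
        columns=["species", "model_set", "response", "predictor", "t", "df", "r", "zr", "ci_lo", "ci_hi"],
    )


def sign_agreement(effects: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int]:
    """Cross-species direction tally over significant predictor effects.

    For every effect significant at ``alpha`` (two-sided t test), check
    whether the other species' coefficients for the same set x response
    x predictor all share its sign: count (same, different).
    """
    from scipy import stats

    eff = effects.copy()
    eff["p"] = 2.0 * stats.t.sf(np.abs(eff["t"]), eff["df"])
    same = different = 0
    for _, row in eff[eff["p"] < alpha].iterrows():
        others = eff[
            (eff["model_set"] == row["model_set"])
            & (eff["response"] == row["response"])
            & (eff["predictor"] == row["predictor"])
            & (eff["species"] != row["species"])
        ]
        if others.empty:
            continue
        if (np.sign(others["t"]) == np.sign(row["t"])).all():
            same += 1
        else:
            different += 1
    return same, different
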