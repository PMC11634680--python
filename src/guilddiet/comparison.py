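"""Among-species comparison of diet metrics.

One-way ANOVA per metric (species as a three-level factor) followed by
all-pairs t tests on the pooled within-group variance with a Bonferroni
correction.  The pairwise tests use the ANOVA's MS_within and df_within,
which is what a Tukey-style post hoc with Bonferroni-adjusted p-values
amounts to once the studentized range is replaced by the stated
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GuildDietError, TraitTable
from .metrics import genus_proportions
from .pooling import SiteDiet


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    ms_within: float


def oneway_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA from sums of squares.

    Missing values are dropped within each group first (which is why the
    residual df can differ between metrics).  All-identical data give
    F = 0; a zero-variance group with n >= 2 is allowed.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    clean = {k: v[np.isfinite(v)] for k, v in clean.items()}
    clean = {k: v for k, v in clean.items() if v.size > 0}
    if len(clean) < 2:
        raise GuildDietError("ANOVA needs at least 2 non-empty groups")
    if any(v.size < 2 for v in clean.values()):
        raise GuildDietError("ANOVA needs n >= 2 in every group")
    ns = {k: v.size for k, v in clean.items()}
    n = sum(ns.values())
    k = len(clean)
    grand = np.concatenate(list(clean.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in clean.values())
    ss_within = sum(np.sum((v - v.mean()) ** 2) for v in clean.values())
    df_b, df_w = k - 1, n - k
    ms_w = ss_within / df_w
    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else np.inf
    else:
        F = (ss_between / df_b) / ms_w
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={g: float(v.mean()) for g, v in clean.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in clean.items()},
        group_ns=ns,
        ms_within=float(ms_w),
    )


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    estimate: float
    se: float
    t: float
    p_raw: float
    p_adj: float


def pairwise_posthoc(groups: dict[str, np.ndarray]) -> list[PairwiseComparison]:
    """All-pairs t tests on the ANOVA's pooled variance, Bonferroni-adjusted.

    p_adj = min(1, m * p_raw) with m the number of pairs (3 for a
    three-species guild).  The estimate is mean(second) - mean(first) on
    the analysis scale.
    """
    anova = oneway_anova(groups)
    names = sorted(anova.group_means)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        est = anova.group_means[b] - anova.group_means[a]
        se = float(np.sqrt(anova.ms_within * (1.0 / anova.group_ns[a] + 1.0 / anova.group_ns[b])))
        if se == 0.0:
            t = 0.0 if est == 0.0 else np.inf
            p_raw = 1.0 if est == 0.0 else 0.0
        else:
            t = est / se
            p_raw = float(2.0 * stats.t.sf(abs(t), anova.df_within))
        out.append(
            PairwiseComparison(
                pair=(a, b),
                estimate=float(est),
                se=se,
                t=float(t),
                p_raw=p_raw,
                p_adj=min(1.0, m * p_raw),
            )
        )
    return out


def descriptive_summary(
    diets: list[SiteDiet], metrics: pd.DataFrame, traits: TraitTable | None = None
) -> pd.DataFrame:
    """Per-predator summary table: location counts, prey totals, genus
    tallies and mean +/- SD of each diet metric among locations.

    A single-location predator reports SD = 0 with ``single_site=True``.
    """
    rows = []
    for pred in sorted({d.predator for d in diets}):
        sub = [d for d in diets if d.predator == pred]
        msub = metrics[metrics["predator"] == pred]
        n_prey = sum(sum(d.class_totals.values()) for d in sub)
        n_vert = sum(d.n_vertebrate_items for d in sub)
        vert_genera = set()
        mam_genera = set()
        per_site_vert_g = []
        per_site_mam_g = []
        for d in sub:
            site_vg = set()
            for cls, counts in d.genus_counts.items():
                if cls == "invertebrate":
                    continue
                site_vg.update(g for g, c in counts.items() if c > 0)
            vert_genera.update(site_vg)
            mg = {g for g, c in d.mammal_counts.items() if c > 0}
            mam_genera.update(mg)
            per_site_vert_g.append(len(site_vg))
            per_site_mam_g.append(len(mg))

        def mean_sd(vals):
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                return float("nan"), float("nan")
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            return float(vals.mean()), sd

        row = {
            "predator": pred,
            "n_locations": len(sub),
            "n_prey": n_prey,
            "n_vertebrate_prey": n_vert,
            "n_vertebrate_genera": len(vert_genera),
            "n_mammal_genera": len(mam_genera),
            "single_site": len(sub) == 1,
        }
        for label, vals in (
            ("vert_genera_per_site", per_site_vert_g),
            ("mammal_genera_per_site", per_site_mam_g),
            ("H", msub["H"]),
            ("J", msub["J"]),
            ("mean_prey_size_g", msub["mean_prey_size_g"]),
            ("prop_mammals", msub["prop_mammals"]),
        ):
            mu, sd = mean_sd(vals)
            row[f"{label}_mean"] = mu
            row[f"{label}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
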