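"""Diet metrics at the genus level on terrestrial mammals.

For each pooled site the suite computes Shannon diversity
H = -sum p_i ln p_i (nats), Levins' niche breadth B = 1 / sum p_i^2,
Pielou/Shannon evenness J = H / ln G, the count-weighted mean prey body
mass (g), and the proportion of terrestrial-mammal items over all
vertebrate items.  Composition summaries, top-genus unions, per-class
biomass shares and the birds-as-one-genus robustness variant live here
too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GuildDietError, TraitTable, VERTEBRATE_CLASSES
from .pooling import SiteDiet

log = logging.getLogger("guilddiet")


@dataclass
class DietVector:
    genera: list[str]
    n: np.ndarray
    p: np.ndarray

    @property
    def G(self) -> int:
        return len(self.genera)

    @property
    def N(self) -> int:
        return int(self.n.sum())


def genus_proportions(counts: dict[str, int]) -> DietVector:
    """Normalised genus proportions; zero-count genera are dropped before
    G is counted.  An all-zero diet is an error."""
    items = sorted((g, int(c)) for g, c in counts.items() if c > 0)
    if not items:
        raise GuildDietError("empty diet: no genus has a positive count")
    genera = [g for g, _ in items]
    n = np.array([c for _, c in items], dtype=float)
    return DietVector(genera=genera, n=n, p=n / n.sum())


def shannon_H(v: DietVector) -> float:
    """H = -sum p ln p, in nats; 0 for a single genus."""
    return float(-np.sum(v.p * np.log(v.p)))


def levins_B(v: DietVector) -> float:
    """Levins' niche breadth B = 1 / sum p^2 (effective genus number)."""
    return float(1.0 / np.sum(v.p**2))


def evenness_J(v: DietVector) -> float:
    """J = H / ln G in [0, 1]; undefined (NaN, with a warning) at G = 1
    since ln 1 = 0 — such sites are excluded from J models."""
    if v.G < 2:
        log.warning("evenness undefined for single-genus diet; returning NaN")
        return float("nan")
    return shannon_H(v) / float(np.log(v.G))


def genus_mass(traits: TraitTable, genus: str) -> float:
    """Mean body mass of a genus in grams (species masses averaged by the
    trait table at load time)."""
    return traits.mass(genus)


def weighted_mean_prey_size(v: DietVector, traits: TraitTable) -> float:
    """Count-weighted arithmetic mean genus body mass: sum n_i m_i / sum n_i."""
    masses = np.array([traits.mass(g) for g in v.genera])
    return float(np.sum(v.n * masses) / v.n.sum())


def proportion_terrestrial_mammals(site: SiteDiet) -> float:
    """Terrestrial-mammal items over all vertebrate items.

    Bats and unidentified vertebrates count in the denominator only.
    Sites whose sources reported mammals only return NaN (no denominator
    is knowable).  Zero vertebrates is an error.
    """
    if site.mammals_only_reported:
        return float("nan")
    n_vert = site.n_vertebrate_items
    if n_vert == 0:
        raise GuildDietError(f"site {site.cluster_id}: zero vertebrate items")
    return site.n_mammal_items / n_vert


@dataclass
class DietMetrics:
    cluster_id: str
    predator: str
    H: float
    B: float
    J: float
    mean_prey_size_g: float
    prop_mammals: float
    N_mammal_items: int
    G_mammal_genera: int


def site_metrics(site: SiteDiet, traits: TraitTable) -> DietMetrics:
    v = genus_proportions(site.mammal_counts)
    return DietMetrics(
        cluster_id=site.cluster_id,
        predator=site.predator,
        H=shannon_H(v),
        B=levins_B(v),
        J=evenness_J(v),
        mean_prey_size_g=weighted_mean_prey_size(v, traits),
        prop_mammals=proportion_terrestrial_mammals(site),
        N_mammal_items=v.N,
        G_mammal_genera=v.G,
    )


def metrics_table(diets: list[SiteDiet], traits: TraitTable) -> pd.DataFrame:
    """One row per pooled site: diet metrics plus coordinates, island flag
    and covariates — the substrate for all downstream models."""
    rows = []
    for d in diets:
        m = site_metrics(d, traits)
        hb, jb = metrics_with_birds_variant(d)
        row = {
            "cluster_id": d.cluster_id,
            "predator": d.predator,
            "lat": d.lat,
            "lon": d.lon,
            "island": d.island,
            "H": m.H,
            "B": m.B,
            "J": m.J,
            "mean_prey_size_g": m.mean_prey_size_g,
            "prop_mammals": m.prop_mammals,
            "N_mammal_items": m.N_mammal_items,
            "G_mammal_genera": m.G_mammal_genera,
            "H_with_birds": hb,
            "J_with_birds": jb,
        }
        row.update(d.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def composition_summary(prey: pd.DataFrame) -> pd.DataFrame:
    """Per-class item and genus tallies with percentages.

    Item percentages for vertebrate classes are relative to the
    vertebrate total; the ``vertebrate`` summary row is relative to the
    grand total (which may include invertebrate records).  Genus
    percentages count distinct rank=genus taxa per class over all
    vertebrate genera.  Percentages are rounded to 2 decimals for the
    report; computation is full precision.
    """
    items_by_class = prey.groupby("v_class")["count"].sum().to_dict()
    total_items = int(prey["count"].sum())
    vert_items = sum(items_by_class.get(c, 0) for c in VERTEBRATE_CLASSES)
    genus_rows = prey[(prey["rank"] == "genus") & (prey["v_class"].isin(VERTEBRATE_CLASSES))]
    genera_by_class = genus_rows.groupby("v_class")["prey_taxon"].nunique().to_dict()
    total_genera = int(genus_rows["prey_taxon"].nunique())
    rows = [
        {
            "category": "all_items",
            "n_items": total_items,
            "pct_items": 100.0,
            "n_genera": total_genera,
            "pct_genera": 100.0,
        },
        {
            "category": "vertebrate",
            "n_items": vert_items,
            "pct_items": round(100.0 * vert_items / total_items, 2) if total_items else np.nan,
            "n_genera": total_genera,
            "pct_genera": 100.0,
        },
    ]
    for cls in VERTEBRATE_CLASSES:
        n = int(items_by_class.get(cls, 0))
        g = int(genera_by_class.get(cls, 0))
        rows.append(
            {
                "category": cls,
                "n_items": n,
                "pct_items": round(100.0 * n / vert_items, 2) if vert_items else np.nan,
                "n_genera": g,
                "pct_genera": round(100.0 * g / total_genera, 2) if total_genera else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TopGenusUnion:
    union: list[str]
    per_predator_top: dict[str, list[str]]
    coverage_pct: dict[str, float]
    mean_coverage_pct: float


def top_genus_union(diets: list[SiteDiet], k: int = 5) -> TopGenusUnion:
    """Top-k most-preyed mammal genera per predator and their union.

    Coverage is the percentage of a predator's terrestrial-mammal items
    falling in its own top-k set; the mean is unweighted over predators.
    Count ties break alphabetically (logged).
    """
    pooled: dict[str, dict[str, int]] = {}
    for d in diets:
        bucket = pooled.setdefault(d.predator, {})
        for g, c in d.mammal_counts.items():
            bucket[g] = bucket.get(g, 0) + c
    per_top, coverage = {}, {}
    union: set[str] = set()
    for pred in sorted(pooled):
        counts = pooled[pred]
        ordered = sorted(counts.items(), key=lambda gc: (-gc[1], gc[0]))
        if len(ordered) > k and ordered[k - 1][1] == ordered[k][1]:
            log.info("top_genus_union: tie at rank %d for %s broken alphabetically", k, pred)
        top = [g for g, _ in ordered[:k]]
        per_top[pred] = top
        union.update(top)
        total = sum(counts.values())
        coverage[pred] = 100.0 * sum(counts[g] for g in top) / total if total else float("nan")
    mean_cov = float(np.mean(list(coverage.values()))) if coverage else float("nan")
    return TopGenusUnion(
        union=sorted(union),
        per_predator_top=per_top,
        coverage_pct=coverage,
        mean_coverage_pct=mean_cov,
    )


def biomass_share(site: SiteDiet, traits: TraitTable) -> dict[str, float]:
    """Percent of vertebrate prey biomass per class: sum n_i m_i within a
    class over the all-vertebrate total.  Genera without masses are
    skipped (computed over the massed subset, logged)."""
    totals: dict[str, float] = {}
    skipped = []
    for cls, counts in site.genus_counts.items():
        if cls not in VERTEBRATE_CLASSES:
            continue
        s = 0.0
        for g, c in counts.items():
            if g in traits:
                s += c * traits.mass(g)
            else:
                skipped.append(g)
        totals[cls] = s
    if skipped:
        log.info("biomass_share: %d genera lack masses and were skipped", len(set(skipped)))
    grand = sum(totals.values())
    if grand == 0:
        raise GuildDietError(f"site {site.cluster_id}: no massed vertebrate items")
    return {cls: 100.0 * s / grand for cls, s in totals.items()}


def metrics_with_birds_variant(site: SiteDiet) -> tuple[float, float]:
    """H and J recomputed with all bird items pooled as one extra
    pseudo-genus ('Aves') alongside the mammal genera — the robustness
    variant for the diversity/evenness comparisons."""
    counts = dict(site.mammal_counts)
    n_birds = site.class_totals.get("bird", 0)
    if n_birds > 0:
        counts["Aves"] = counts.get("Aves", 0) + n_birds
    v = genus_proportions(counts)
    return shannon_H(v), evenness_J(v)
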