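"""Spatial pooling of diet locations into 20-km clusters.

Locations of the same predator closer than a threshold (default 20 km,
great-circle) are merged by single-linkage transitive closure into
*spatial clusters*: prey counts are summed, coordinates are replaced by
the centroid, covariates by the member mean.  Pooled diets below a
minimum terrestrial-mammal sample size (90 items on the mainland, 50 on
islands) are excluded from metric computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy import stats

from .io import GuildDietError, VERTEBRATE_CLASSES

log = logging.getLogger("guilddiet")

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (vectorised; Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise GuildDietError("latitude out of [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise GuildDietError("longitude out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def distance_matrix_km(lat, lon) -> np.ndarray:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


@dataclass
class ClusterAssignment:
    """Partition of each predator's locations into spatial clusters."""

    #: (predator, location_id) -> cluster_id
    by_location: dict[tuple[str, str], str]
    #: cluster_id -> sorted member location_ids
    members: dict[str, list[str]]
    threshold_km: float = 20.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"predator": pred, "location_id": loc, "cluster_id": cid}
            for (pred, loc), cid in sorted(self.by_location.items())
        ]
        return pd.DataFrame(rows, columns=["predator", "location_id", "cluster_id"])


def build_clusters(
    sites: pd.DataFrame, prey: pd.DataFrame, threshold_km: float = 20.0
) -> ClusterAssignment:
    """Single-linkage clusters of each predator's diet locations.

    An edge joins two locations at great-circle distance strictly below
    ``threshold_km``; clusters are the connected components (so a chain
    of nearby sites may span more than the threshold end-to-end).
    Cluster ids are deterministic: ``predator:lexicographically smallest
    member``.  Clustering is within predator only — diet datapoints are
    per-species.
    """
    by_location: dict[tuple[str, str], str] = {}
    members: dict[str, list[str]] = {}
    site_idx = sites.set_index("location_id")
    for pred, sub in prey.groupby("predator"):
        locs = sorted(set(sub["location_id"]))
        coords = site_idx.loc[locs]
        d = distance_matrix_km(coords["lat"].to_numpy(), coords["lon"].to_numpy())
        adj = csr_matrix(d < threshold_km)
        _, labels = connected_components(adj, directed=False)
        for comp in np.unique(labels):
            comp_locs = [locs[i] for i in np.flatnonzero(labels == comp)]
            cid = f"{pred}:{min(comp_locs)}"
            members[cid] = sorted(comp_locs)
            for loc in comp_locs:
                by_location[(pred, loc)] = cid
    return ClusterAssignment(by_location=by_location, members=members, threshold_km=threshold_km)


@dataclass
class SiteDiet:
    """Pooled per-cluster, per-predator diet with location metadata."""

    cluster_id: str
    predator: str
    lat: float
    lon: float
    island: bool
    mammals_only_reported: bool
    #: rank=genus counts, keyed by vertebrate class then genus
    genus_counts: dict[str, dict[str, int]]
    #: per-class item totals including supra-genus records
    class_totals: dict[str, int]
    covariates: dict[str, float]
    member_ids: list[str] = field(default_factory=list)

    @property
    def mammal_counts(self) -> dict[str, int]:
        return self.genus_counts.get("mammal_terrestrial", {})

    @property
    def n_mammal_items(self) -> int:
        return self.class_totals.get("mammal_terrestrial", 0)

    @property
    def n_vertebrate_items(self) -> int:
        return sum(self.class_totals.get(c, 0) for c in VERTEBRATE_CLASSES)


def pool_clusters(
    validated_prey: pd.DataFrame,
    dropped_prey: pd.DataFrame,
    sites: pd.DataFrame,
    assignment: ClusterAssignment,
) -> list[SiteDiet]:
    """Sum prey counts per cluster and average location metadata.

    ``validated_prey`` holds the rank=genus rows entering metrics (the
    validation report's kept + bat-rerouted rows); ``dropped_prey`` holds
    supra-genus rows, which still count toward class totals.  Centroids
    are unweighted arithmetic means of member coordinates; covariates are
    member means (NaN-aware); the island flag of a mixed cluster is True
    with a warning.
    """
    site_idx = sites.set_index("location_id")
    all_prey = pd.concat(
        [validated_prey.assign(_genus_rank=True), dropped_prey.assign(_genus_rank=False)],
        ignore_index=True,
    )
    out: list[SiteDiet] = []
    for cid in sorted(assignment.members):
        pred = cid.split(":", 1)[0]
        locs = assignment.members[cid]
        rows = all_prey[(all_prey["predator"] == pred) & (all_prey["location_id"].isin(locs))]
        genus_counts: dict[str, dict[str, int]] = {}
        class_totals: dict[str, int] = {}
        for _, r in rows.iterrows():
            cls, n = r["v_class"], int(r["count"])
            class_totals[cls] = class_totals.get(cls, 0) + n
            if r["_genus_rank"]:
                bucket = genus_counts.setdefault(cls, {})
                bucket[r["prey_taxon"]] = bucket.get(r["prey_taxon"], 0) + n
        meta = site_idx.loc[locs]
        island_vals = meta["island"].astype(bool)
        if island_vals.nunique() > 1:
            log.warning("cluster %s mixes island and mainland members; flagged island", cid)
        monly = meta["mammals_only_reported"].astype(bool)
        if monly.nunique() > 1:
            log.warning("cluster %s mixes mammals_only_reported flags; pooled flag True", cid)
        covs = {
            c: float(meta[c].mean()) for c in ("temperature", "precipitation", "tree_cover", "elevation")
        }
        out.append(
            SiteDiet(
                cluster_id=cid,
                predator=pred,
                lat=float(meta["lat"].mean()),
                lon=float(meta["lon"].mean()),
                island=bool(island_vals.any()),
                mammals_only_reported=bool(monly.any()),
                genus_counts=genus_counts,
                class_totals=class_totals,
                covariates=covs,
                member_ids=list(locs),
            )
        )
    return out


def apply_sample_size_filter(
    diets: list[SiteDiet], mainland_min: int = 90, island_min: int = 50
) -> tuple[list[SiteDiet], pd.DataFrame]:
    """Keep pooled diets with enough terrestrial-mammal items.

    Thresholds are inclusive ("at least"): >= ``mainland_min`` items on
    the mainland, >= ``island_min`` on islands.  Returns the kept list
    and an exclusion log with reasons.
    """
    kept, rows = [], []
    for d in diets:
        thr = island_min if d.island else mainland_min
        n = d.n_mammal_items
        if n >= thr:
            kept.append(d)
        else:
            rows.append(
                {
                    "cluster_id": d.cluster_id,
                    "predator": d.predator,
                    "island": d.island,
                    "n_mammal_items": n,
                    "threshold": thr,
                    "reason": "below_min_mammal_items",
                }
            )
    excluded = pd.DataFrame(
        rows, columns=["cluster_id", "predator", "island", "n_mammal_items", "threshold", "reason"]
    )
    return kept, excluded


@dataclass
class HvsNResult:
    predator: str
    slope: float
    t: float
    df: int
    p: float
    n: int


def h_vs_n_check(h, n_items, predator: str = "") -> HvsNResult:
    """Regress the Shannon H index on the mammal item count per site.

    Used as a sanity check that diversity does not track sample size;
    returns the slope's t statistic with df = n - 2 and a two-sided p.
    """
    h = np.asarray(h, dtype=float)
    n_items = np.asarray(n_items, dtype=float)
    if h.size < 3:
        raise GuildDietError("h_vs_n_check needs at least 3 sites")
    x = n_items - n_items.mean()
    sxx = np.sum(x**2)
    if sxx == 0:
        raise GuildDietError("h_vs_n_check: constant item counts")
    slope = float(np.sum(x * h) / sxx)
    resid = h - h.mean() - slope * x
    df = h.size - 2
    rss = float(np.sum(resid**2))
    if rss == 0.0:
        # degenerate exact fit
        return HvsNResult(predator, slope, np.inf if slope != 0 else 0.0, df, 0.0 if slope != 0 else 1.0, h.size)
    se = np.sqrt(rss / df / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return HvsNResult(predator, slope, float(t), df, float(p), h.size)
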