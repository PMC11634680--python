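"""Data model, CSV readers/writers and validation for guild diet tables.

Three input tables drive the pipeline:

* **prey table** — long format, one row per location x predator x prey
  taxon x count, with taxonomic rank (``genus`` / ``supra_genus``) and
  vertebrate class labels;
* **site table** — one row per location with coordinates (decimal
  degrees), an island/mainland flag and pre-extracted environmental
  covariates (the 20-km-radius averaging happens upstream; values arrive
  ready-made);
* **trait table** — genus-level body masses in grams, optionally given as
  species-level masses that are averaged per genus.

All files are UTF-8, comma-separated CSV with a header and decimal
points.  Validation follows the analysis rules: records identified above
the genus level are dropped from diet metrics, bat genera are rerouted to
the other-vertebrates pool (they stay in vertebrate totals but never
enter mammal metrics), and every terrestrial-mammal genus must resolve to
a body mass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape

log = logging.getLogger("guilddiet")

#: default guild; extensible via config (open enum)
DEFAULT_PREDATORS = ("LEO", "TAW", "EEO")

RANKS = ("genus", "supra_genus")

#: exclusive vertebrate class labels; ``invertebrate`` is carried only in
#: grand totals and never enters vertebrate or mammal metrics
V_CLASSES = (
    "mammal_terrestrial",
    "mammal_bat",
    "bird",
    "reptile",
    "amphibian",
    "fish",
    "unidentified_vert",
    "invertebrate",
)

VERTEBRATE_CLASSES = tuple(c for c in V_CLASSES if c != "invertebrate")

PREY_COLUMNS = ["location_id", "predator", "prey_taxon", "rank", "v_class", "count"]
SITE_COLUMNS = [
    "location_id",
    "lat",
    "lon",
    "island",
    "mammals_only_reported",
    "temperature",
    "precipitation",
    "tree_cover",
    "elevation",
]
TRAIT_COLUMNS = ["genus", "mass_g"]

COVARIATE_COLUMNS = ["temperature", "precipitation", "tree_cover", "elevation"]


class GuildDietError(Exception):
    """Base class for pipeline errors."""


class SchemaError(GuildDietError):
    """Malformed input file: names the offending row/column."""


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the pipeline, loadable from YAML."""

    cluster_km: float = 20.0
    mainland_min: int = 90
    island_min: int = 50
    collinearity_r: float = 0.65
    logit_eps: float = 0.001
    permutations: int = 9999
    seed: int = 0
    predators: tuple[str, ...] = DEFAULT_PREDATORS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "predators" in raw:
            raw["predators"] = tuple(raw["predators"])
        return cls(**raw)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def load_prey_table(
    path: str | Path, predators: Iterable[str] = DEFAULT_PREDATORS
) -> pd.DataFrame:
    """Read and validate a long-format prey-count table.

    Returns a typed DataFrame with columns ``location_id, predator,
    prey_taxon, rank, v_class, count``.  Raises :class:`SchemaError`
    naming the first offending row for unknown predators/ranks/classes or
    negative counts; an empty table is an error.
    """
    df = pd.read_csv(path, dtype={"location_id": str, "prey_taxon": str})
    _require_columns(df, PREY_COLUMNS, "prey table")
    df = df[PREY_COLUMNS].copy()
    if df.empty:
        raise SchemaError("prey table: no rows")
    return validate_prey_frame(df, predators=predators)


def validate_prey_frame(
    df: pd.DataFrame, predators: Iterable[str] = DEFAULT_PREDATORS
) -> pd.DataFrame:
    """Schema-level validation of an in-memory prey frame (row numbers are
    1-based data rows, matching the CSV after its header)."""
    predators = set(predators)
    df = df.copy()
    counts = pd.to_numeric(df["count"], errors="coerce")
    for idx, val in counts.items():
        row = int(idx) + 2  # header is line 1
        if not np.isfinite(val):
            raise SchemaError(f"prey table row {row}: non-numeric count")
        if val < 0:
            raise SchemaError(f"prey table row {row}, column 'count': negative count {val}")
        if val != int(val):
            raise SchemaError(f"prey table row {row}: non-integer count {val}")
    df["count"] = counts.astype(int)
    bad = df.loc[~df["predator"].isin(predators)]
    if len(bad):
        row = int(bad.index[0]) + 2
        raise SchemaError(
            f"prey table row {row}, column 'predator': unknown predator {bad['predator'].iloc[0]!r}"
        )
    bad = df.loc[~df["rank"].isin(RANKS)]
    if len(bad):
        row = int(bad.index[0]) + 2
        raise SchemaError(f"prey table row {row}, column 'rank': unknown rank {bad['rank'].iloc[0]!r}")
    bad = df.loc[~df["v_class"].isin(V_CLASSES)]
    if len(bad):
        row = int(bad.index[0]) + 2
        raise SchemaError(
            f"prey table row {row}, column 'v_class': unknown class {bad['v_class'].iloc[0]!r}"
        )
    return df


def write_prey_table(df: pd.DataFrame, path: str | Path) -> None:
    df[PREY_COLUMNS].to_csv(path, index=False)


def load_site_table(path: str | Path) -> pd.DataFrame:
    """Read the site table; coordinates are range-checked, covariates may
    be missing (models later drop incomplete rows per-model)."""
    df = pd.read_csv(path, dtype={"location_id": str})
    _require_columns(df, SITE_COLUMNS, "site table")
    df = df[SITE_COLUMNS].copy()
    if df.empty:
        raise SchemaError("site table: no rows")
    if df["location_id"].duplicated().any():
        dup = df.loc[df["location_id"].duplicated(), "location_id"].iloc[0]
        raise SchemaError(f"site table: duplicate location_id {dup!r}")
    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < lo).any() or (vals > hi).any():
            row = int(df.index[vals.isna() | (vals < lo) | (vals > hi)][0]) + 2
            raise SchemaError(f"site table row {row}: {col} out of [{lo}, {hi}]")
        df[col] = vals.astype(float)
    for col in ("island", "mammals_only_reported"):
        df[col] = df[col].astype(bool)
    for col in COVARIATE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    tc = df["tree_cover"]
    if ((tc < 0) | (tc > 100)).any():
        row = int(df.index[(tc < 0) | (tc > 100)][0]) + 2
        raise SchemaError(f"site table row {row}: tree_cover outside [0, 100]")
    return df


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SITE_COLUMNS].to_csv(path, index=False)


class TraitTable:
    """Genus -> body mass (g).  Accepts either genus-level masses or
    species-level masses that are averaged within genus (arithmetic mean
    over the regional species list)."""

    def __init__(self, masses: Mapping[str, float]):
        bad = {g: m for g, m in masses.items() if not (np.isfinite(m) and m > 0)}
        if bad:
            raise SchemaError(f"trait table: non-positive mass for {sorted(bad)}")
        self._masses = dict(masses)

    @classmethod
    def from_species_masses(cls, species_masses: Mapping[str, Iterable[float]]) -> "TraitTable":
        out = {}
        for genus, vals in species_masses.items():
            vals = list(vals)
            if not vals:
                raise SchemaError(f"trait table: genus {genus!r} has no species masses")
            out[genus] = float(np.mean(vals))
        return cls(out)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        df = pd.read_csv(path)
        _require_columns(df, ["genus"], "trait table")
        if "mass_g" not in df.columns:
            raise SchemaError("trait table: missing columns ['mass_g']")
        if "species" in df.columns:
            grouped = df.groupby("genus")["mass_g"].apply(list).to_dict()
            return cls.from_species_masses(grouped)
        if df["genus"].duplicated().any():
            # duplicated genus rows are treated as species-level masses
            grouped = df.groupby("genus")["mass_g"].apply(list).to_dict()
            return cls.from_species_masses(grouped)
        return cls(dict(zip(df["genus"], df["mass_g"].astype(float))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"genus": list(self._masses), "mass_g": list(self._masses.values())}
        ).to_csv(path, index=False)

    def __contains__(self, genus: str) -> bool:
        return genus in self._masses

    def genera(self) -> list[str]:
        return sorted(self._masses)

    def mass(self, genus: str) -> float:
        try:
            return self._masses[genus]
        except KeyError:
            raise GuildDietError(f"no body mass for genus {genus!r}") from None


@dataclass
class ValidationReport:
    """Accounting of every input prey row: kept, rerouted or dropped.

    ``kept`` rows enter mammal diet metrics; ``rerouted`` rows (bats,
    invertebrates) stay in the relevant totals but not in mammal metrics;
    ``dropped`` rows (supra-genus) leave metric computation entirely while
    still counting toward class totals, mirroring the source analysis.
    """

    kept: pd.DataFrame
    rerouted: pd.DataFrame
    dropped: pd.DataFrame
    missing_trait_genera: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return self.counts.get("input_rows", 0)


def validate_dataset(
    prey: pd.DataFrame, sites: pd.DataFrame, traits: TraitTable
) -> ValidationReport:
    """Cross-table validation and metric-pool routing.

    * every prey ``location_id`` must exist in the site table (hard error);
    * ``rank=supra_genus`` rows are dropped for metrics;
    * bat rows are rerouted to the other-vertebrates pool;
    * invertebrate rows are rerouted out of vertebrate accounting;
    * terrestrial-mammal genera without a trait-table mass are listed.

    Row conservation holds exactly: kept + rerouted + dropped = input rows.
    """
    unknown_sites = set(prey["location_id"]) - set(sites["location_id"])
    if unknown_sites:
        raise GuildDietError(
            f"prey table references unknown location_id(s): {sorted(unknown_sites)[:5]}"
        )
    is_supra = prey["rank"] == "supra_genus"
    is_bat = (~is_supra) & (prey["v_class"] == "mammal_bat")
    is_invert = (~is_supra) & (prey["v_class"] == "invertebrate")
    rerouted = prey.loc[is_bat | is_invert].copy()
    rerouted["reason"] = np.where(
        rerouted["v_class"] == "mammal_bat", "bat_to_other_vertebrates", "invertebrate_excluded"
    )
    dropped = prey.loc[is_supra].copy()
    dropped["reason"] = "supra_genus_excluded_from_metrics"
    kept = prey.loc[~(is_supra | is_bat | is_invert)].copy()

    mammal_genera = set(kept.loc[kept["v_class"] == "mammal_terrestrial", "prey_taxon"])
    missing = sorted(g for g in mammal_genera if g not in traits)
    counts = {
        "input_rows": len(prey),
        "kept": len(kept),
        "rerouted": len(rerouted),
        "dropped": len(dropped),
        "missing_trait_genera": len(missing),
    }
    if missing:
        log.warning("validate_dataset: %d mammal genera lack body masses: %s",
                    len(missing), missing[:10])
    return ValidationReport(kept=kept, rerouted=rerouted, dropped=dropped,
                            missing_trait_genera=missing, counts=counts)


def load_ranges(path: str | Path) -> dict[str, object]:
    """Read competitor range polygons from GeoJSON (WGS84 lon/lat order).

    Returns species -> shapely geometry, keyed by the feature's
    ``species`` property.
    """
    with open(path, "r", encoding="utf-8") as fh:
        gj = json.load(fh)
    out = {}
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    for feat in features:
        species = feat.get("properties", {}).get("species")
        if species is None:
            raise SchemaError("range file: feature without 'species' property")
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            raise GuildDietError(f"range file: invalid geometry for {species!r}")
        out[species] = geom
    return out


def write_ranges(ranges: Mapping[str, object], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"species": sp},
            "geometry": shapely_mapping(geom),
        }
        for sp, geom in sorted(ranges.items())
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
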