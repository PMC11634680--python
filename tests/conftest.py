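import logging

import numpy as np
import pandas as pd
import pytest

import guilddiet as gd

logging.getLogger("guilddiet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_default():
    """One guild dataset under the default (specialist/generalist) conditions."""
    return gd.generate_guild_dataset(gd.scenario_presets("specialist_generalist"), seed=1)


@pytest.fixture(scope="session")
def sim_metrics(sim_default):
    ds = sim_default
    kept, excluded, assignment = gd.pooled_filtered_diets(ds.prey, ds.sites, ds.traits)
    return ds, kept, gd.metrics_table(kept, ds.traits)


@pytest.fixture
def tiny_prey():
    return pd.DataFrame(
        {
            "location_id": ["L1", "L1", "L1", "L2", "L2"],
            "predator": ["LEO", "LEO", "LEO", "TAW", "TAW"],
            "prey_taxon": ["Mus", "Apodemus", "Turdus", "Mus", "Microtus"],
            "rank": ["genus"] * 5,
            "v_class": ["mammal_terrestrial", "mammal_terrestrial", "bird",
                        "mammal_terrestrial", "mammal_terrestrial"],
            "count": [10, 5, 3, 7, 2],
        }
    )


@pytest.fixture
def tiny_sites():
    return pd.DataFrame(
        {
            "location_id": ["L1", "L2"],
            "lat": [40.0, 42.0],
            "lon": [10.0, 12.0],
            "island": [False, False],
            "mammals_only_reported": [False, False],
            "temperature": [15.0, 13.0],
            "precipitation": [600.0, 700.0],
            "tree_cover": [30.0, 40.0],
            "elevation": [200.0, 400.0],
        }
    )


@pytest.fixture
def tiny_traits():
    return gd.TraitTable({"Mus": 20.0, "Apodemus": 27.3, "Microtus": 31.7, "Turdus": 85.0})


def make_site_diet(
    mammal_counts,
    cluster_id="LEO:L1",
    predator="LEO",
    lat=40.0,
    lon=10.0,
    island=False,
    mammals_only=False,
    extra_classes=None,
    extra_genus_counts=None,
    covariates=None,
):
    """Hand-built pooled site for metric tests."""
    class_totals = {"mammal_terrestrial": sum(mammal_counts.values())}
    genus_counts = {"mammal_terrestrial": dict(mammal_counts)}
    if extra_classes:
        for cls, n in extra_classes.items():
            class_totals[cls] = class_totals.get(cls, 0) + n
    if extra_genus_counts:
        for cls, counts in extra_genus_counts.items():
            genus_counts.setdefault(cls, {}).update(counts)
    return gd.SiteDiet(
        cluster_id=cluster_id,
        predator=predator,
        lat=lat,
        lon=lon,
        island=island,
        mammals_only_reported=mammals_only,
        genus_counts=genus_counts,
        class_totals=class_totals,
        covariates=covariates or {"temperature": 15.0, "precipitation": 600.0,
                                  "tree_cover": 30.0, "elevation": 200.0},
        member_ids=[cluster_id.split(":", 1)[1]],
    )


def random_diet_vector(rng, max_g=20):
    g = rng.integers(2, max_g + 1)
    counts = rng.integers(1, 500, g)
    return {f"G{i:02d}": int(c) for i, c in enumerate(counts)}
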