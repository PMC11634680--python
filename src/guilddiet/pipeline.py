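"""End-to-end convenience wrappers over the pipeline stages."""

from __future__ import annotations

import pandas as pd

from .io import AnalysisConfig, TraitTable, validate_dataset
from .metrics import metrics_table
from .pooling import ClusterAssignment, SiteDiet, apply_sample_size_filter, build_clusters, pool_clusters


def pooled_filtered_diets(
    prey: pd.DataFrame,
    sites: pd.DataFrame,
    traits: TraitTable,
    config: AnalysisConfig | None = None,
) -> tuple[list[SiteDiet], pd.DataFrame, ClusterAssignment]:
    """validate -> cluster -> pool -> sample-size filter.

    Returns the kept pooled diets, the exclusion log and the cluster
    assignment.
    """
    config = config or AnalysisConfig()
    report = validate_dataset(prey, sites, traits)
    metric_prey = pd.concat([report.kept, report.rerouted.drop(columns=["reason"])],
                            ignore_index=True)
    metric_prey = metric_prey[metric_prey["v_class"] != "invertebrate"]
    assignment = build_clusters(sites, prey, threshold_km=config.cluster_km)
    diets = pool_clusters(metric_prey, report.dropped.drop(columns=["reason"]), sites, assignment)
    kept, excluded = apply_sample_size_filter(
        diets, mainland_min=config.mainland_min, island_min=config.island_min
    )
    return kept, excluded, assignment


def dataset_metrics(
    prey: pd.DataFrame,
    sites: pd.DataFrame,
    traits: TraitTable,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full metric table (one row per kept pooled site)."""
    kept, _, _ = pooled_filtered_diets(prey, sites, traits, config)
    return metrics_table(kept, traits)
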