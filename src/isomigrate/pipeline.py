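"""End-to-end drivers: world → isoscapes → assignment → clusters → niche.

These functions wire the stage modules together the way a field study
would run them: simulate (or load) the data, filter breeding-grown
outliers, calibrate the feather isoscapes, assign every individual, derive
candidate molt regions by clustering, allocate individuals to regions with
zonal statistics, and score the run against the simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import (
    ODDS_LEVEL,
    AssignmentSurface,
    CovarianceSpec,
    assign_population,
)
from .clustering import (
    DEFAULT_GEO_WEIGHT,
    ClusterMap,
    SimilarityMatrix,
    hclust_cut,
    population_cluster_proportions,
    similarity_matrix,
    spatial_kmeans,
    zonal_max_membership,
)
from .feathers import FeatherRecord, filter_outliers
from .isoscape import Isoscape, apply_range_mask, calibrate_h_isoscape, plant_to_feather_c
from .raster import RasterGrid
from .synthetic import PopulationSpec, WorldScenario, get_preset, make_world, simulate_population

__all__ = ["PipelineResult", "simulate_scenario", "run_pipeline", "region_recovery_rate"]

DEFAULT_COV = CovarianceSpec(sd_h=12.0, sd_c=1.5, rho=0.0)


@dataclass
class PipelineResult:
    """Everything one end-to-end run produces."""

    records: list[FeatherRecord]
    removed: list[FeatherRecord]
    truth: pd.DataFrame
    h_iso: Isoscape
    c_iso: Isoscape
    surfaces: dict[str, AssignmentSurface]
    stacks: dict[str, RasterGrid]
    similarity: SimilarityMatrix
    individual_labels: dict[str, int]
    cluster_map: ClusterMap
    memberships: pd.DataFrame
    proportions: pd.DataFrame


def simulate_scenario(
    scenario: WorldScenario,
    populations: list[PopulationSpec],
    cov: CovarianceSpec = DEFAULT_COV,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[list[FeatherRecord], pd.DataFrame, Isoscape, Isoscape]:
    """Simulate all populations of a scenario on calibrated isoscapes.

    Returns (records, truth, feather δ²H isoscape, feather δ¹³C isoscape),
    with both isoscapes range-masked.  Substreams: one for the world, one
    per population, all spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    world_seed, *pop_seeds = ss.spawn(1 + len(populations))
    precip, plant, range_mask = make_world(scenario, seed=world_seed)
    h_iso = apply_range_mask(calibrate_h_isoscape(precip, sd=cov.sd_h), range_mask)
    c_iso = apply_range_mask(plant_to_feather_c(plant, sd=cov.sd_c), range_mask)
    records: list[FeatherRecord] = []
    truth_frames = []
    for spec, pseed in zip(populations, pop_seeds):
        recs, truth = simulate_population(
            spec, scenario, h_iso.mean, c_iso.mean, cov, seed=pseed
        )
        records.extend(recs)
        truth_frames.append(truth)
    return records, pd.concat(truth_frames, ignore_index=True), h_iso, c_iso


def run_pipeline(
    preset: str | tuple[WorldScenario, list[PopulationSpec]] = "strong",
    cov: CovarianceSpec = DEFAULT_COV,
    level: float = ODDS_LEVEL,
    n_boot: int = 25,
    geo_weight: float = DEFAULT_GEO_WEIGHT,
    k: int | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> PipelineResult:
    """Run the full analysis on a synthetic scenario.

    ``k`` (spatial cluster count) defaults to the number of clusters the
    dendrogram cut finds among individuals.  ``n_boot`` defaults to a
    desk-scale 25 replicates; raise it for publication-grade bootstrap SDs.
    """
    scenario, populations = get_preset(preset) if isinstance(preset, str) else preset
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    sim_seed, boot_seed, km_seed = ss.spawn(3)

    records, truth, h_iso, c_iso = simulate_scenario(scenario, populations, cov, seed=sim_seed)
    kept, removed = filter_outliers(records)
    surfaces, stacks = assign_population(kept, h_iso, c_iso, cov, level)

    surf_list = [surfaces[r.id] for r in kept]
    sim = similarity_matrix(surf_list, n_boot=n_boot, seed=boot_seed)
    labels = hclust_cut(sim)
    if k is None:
        k = max(labels.values())
    cmap = spatial_kmeans(
        surf_list, k=k, geo_weight=geo_weight,
        seed=int(km_seed.generate_state(1)[0] % (2**31)),
    )
    memberships = zonal_max_membership(surf_list, cmap)
    proportions = population_cluster_proportions(
        {r.id: r.population for r in kept}, memberships
    )
    return PipelineResult(
        records=kept, removed=removed, truth=truth, h_iso=h_iso, c_iso=c_iso,
        surfaces=surfaces, stacks=stacks, similarity=sim,
        individual_labels=labels, cluster_map=cmap, memberships=memberships,
        proportions=proportions,
    )


def region_recovery_rate(result: PipelineResult, scenario: WorldScenario) -> float:
    """Fraction of individuals allocated to their true region's cluster.

    Each true molt region is matched to the spatial cluster covering the
    most of its cells; an individual scores a hit when its zonal-maximum
    cluster equals its true region's matched cluster.  Outlier-simulated
    individuals (removed by the filter) are excluded.
    """
    labels_flat = np.nan_to_num(result.cluster_map.labels.values, nan=0.0).astype(int)
    region_to_cluster: dict[str, int] = {}
    for region in scenario.regions:
        inside = region.member_mask(labels_flat.shape) & (labels_flat > 0)
        if not inside.any():
            raise ValueError(f"region {region.id!r} has no clustered cells")
        counts = np.bincount(labels_flat[inside])
        region_to_cluster[region.id] = int(np.argmax(counts))
    truth = result.truth.set_index("id")
    hits = 0
    total = 0
    for _, row in result.memberships.iterrows():
        t = truth.loc[row["id"]]
        if bool(t["outlier"]):
            continue
        total += 1
        if int(row["cluster"]) == region_to_cluster[t["region"]]:
            hits += 1
    if total == 0:
        raise ValueError("no non-outlier individuals to score")
    return hits / total
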