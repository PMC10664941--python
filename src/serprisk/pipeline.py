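"""End-to-end orchestration: simulate -> richness -> access -> indices ->
clustering -> registry statistics."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import epi_stats, healthcare_access, risk_clustering, risk_indices
from . import species_richness
from .risk_clustering import ClusterSolution
from .synthetic_landscape import (
    LandscapeConfig, case_counts_per_ea, generate_landscape)


@dataclass
class PipelineResult:
    bundle: dict
    richness: species_richness.RichnessLayer
    zonal_richness: pd.Series
    travel_surface: healthcare_access.TravelTimeSurface
    travel_minutes: pd.Series
    indices: dict[str, risk_indices.RiskIndex]
    risk_solution: ClusterSolution
    outcome_solution: ClusterSolution
    elevation_fit: epi_stats.RateFitResult


def run_pipeline(config: LandscapeConfig | None = None,
                 n_c: int = 4) -> PipelineResult:
    config = config or LandscapeConfig()
    bundle = generate_landscape(config)
    rasters = bundle["rasters"]
    eas = bundle["eas"]

    thresholds = species_richness.species_thresholds(bundle["occurrences"])
    richness = species_richness.binarize_and_stack(
        bundle["species_layers"], thresholds)
    zonal = species_richness.zonal_mean(richness.layer, eas)

    friction = healthcare_access.build_friction_surface(
        rasters["landcover"], rasters["roads"], rasters["elevation"])
    surface = healthcare_access.travel_time_surface(
        friction, healthcare_access.facility_cells_from_table(
            bundle["facilities"]))
    travel = healthcare_access.zonal_travel_time(surface, eas)

    counts = case_counts_per_ea(bundle["cases"], eas)
    fragmentation = risk_indices.landscape_metrics(rasters["landcover"], eas)
    variables = risk_indices.merge_ea_variables(
        eas, zonal, counts, travel, fragmentation)
    indices = risk_indices.build_all_indices(variables)

    risk_solution = risk_clustering.run_analysis(
        indices, include_scarcity=False, n_c=n_c)
    outcome_solution = risk_clustering.run_analysis(
        indices, include_scarcity=True, n_c=n_c)

    fit = epi_stats.poisson_elevation_fit(
        counts.to_numpy(),
        eas.table["mean_elevation"].to_numpy(),
        eas.table["population"].to_numpy())

    return PipelineResult(
        bundle=bundle, richness=richness, zonal_richness=zonal,
        travel_surface=surface, travel_minutes=travel, indices=indices,
        risk_solution=risk_solution, outcome_solution=outcome_solution,
        elevation_fit=fit)
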