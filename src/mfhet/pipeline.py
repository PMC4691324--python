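"""End-to-end orchestration of the analysis stages.

Ties the per-module operations into the standard cohort analysis:
platform merge → validation status → oncogenicity annotation → presence
matrices → heterogeneity grouping → AF comparison and covariate
associations.  Each stage result is returned so callers (CLI, acceptance
checks, notebooks) can inspect intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort_model import (
    CohortHierarchy,
    GeneRoleTable,
    MutationCall,
    PipelineConfig,
    RecurrenceTable,
    unique_variants,
)
from . import confirmation as conf
from . import heterogeneity as het
from . import oncogenicity as onc

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    status_table: pd.DataFrame
    confirmation_summary: dict
    concordance: dict | None
    onco_calls: dict  # variant-key string -> OncogenicityCall
    oncogenicity_summary: dict
    matrices: dict
    het_results: list
    group_summary: dict
    af_comparison: dict | None = None
    associations: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)


def run_pipeline(
    discovery_calls: Sequence[MutationCall],
    validation_calls: Sequence[MutationCall],
    hierarchy: CohortHierarchy,
    recurrence: RecurrenceTable,
    roles: GeneRoleTable,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    merged = conf.merge_platforms(discovery_calls, validation_calls)
    status_table, summary = conf.confirm_cohort(merged, hierarchy, config)
    try:
        concordance = conf.platform_concordance(status_table)
    except conf.InsufficientDataError:
        concordance = None

    index = unique_variants(merged)
    calls_by_key, onco_summary = onc.classify_cohort(index, recurrence, roles, config)
    onco_by_str = {str(k): v for k, v in calls_by_key.items()}

    matrices = het.build_presence_matrices(status_table, hierarchy, config)
    het_results, group_summary = het.classify_cohort(
        matrices, hierarchy, onco_by_str, config
    )
    try:
        af_comparison = het.private_vs_common_af(het_results)
    except conf.InsufficientDataError:
        af_comparison = None
    associations = het.covariate_association(het_results, hierarchy, config)
    return PipelineResult(
        status_table=status_table,
        confirmation_summary=summary,
        concordance=concordance,
        onco_calls=onco_by_str,
        oncogenicity_summary=onco_summary,
        matrices=matrices,
        het_results=het_results,
        group_summary=group_summary,
        af_comparison=af_comparison,
        associations=associations,
    )
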