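"""Patient-level inter-lesion heterogeneity classification.

From the per-sample presence matrix of validated mutations each patient is
assigned to one of three groups:

* ``HOMOGENEOUS`` — every mutation is present in every sample of every
  lesion (all lesions carry exactly the same mutations);
* ``HETEROGENEOUS`` — no single mutation is common to all lesions;
* ``INTERMEDIATE`` — otherwise (both common and private mutations).

"Common" (truncal) means present in at least one sample of every lesion of
the patient; a stricter every-sample reading is available behind
``PipelineConfig.common_requires_every_sample``.  Mutations detected only by
the deep validation assay (status PRESENT) count as present.  Assay-failed
cells optionally fall back to the discovery-platform detection
(``assay_failed_uses_discovery``, default on), so a variant seen by the
screen is not lost when its validation assay could not be run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_model import (
    CohortHierarchy,
    PatientMeta,
    PipelineConfig,
    VariantKey,
)
from .confirmation import InsufficientDataError, Status
from .oncogenicity import OncogenicityCall
from . import stats_report

__all__ = [
    "PresenceMatrix",
    "PatientHeterogeneityResult",
    "build_presence_matrices",
    "classify_patient",
    "classify_cohort",
    "private_vs_common_af",
    "covariate_association",
    "render_presence_matrix",
    "parse_presence_export",
    "GROUPS",
]

GROUPS = ("HOMOGENEOUS", "INTERMEDIATE", "HETEROGENEOUS")


@dataclass
class PresenceMatrix:
    """Presence/absence of each validated variant in each assayed sample.

    ``presence``: bool DataFrame, rows indexed by variant-key string,
    columns = sample ids ordered by lesion; ``af``: matching float frame of
    observed allele fractions (validation AF, discovery as fallback; NaN
    where absent).  Every row has at least one present cell.
    """

    patient_id: str
    presence: pd.DataFrame
    af: pd.DataFrame
    lesion_of: dict[str, str]
    gene_of: dict[str, str] = field(default_factory=dict)
    validation_only_samples: set[str] = field(default_factory=set)

    @property
    def variants(self) -> list[str]:
        return list(self.presence.index)

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    def lesions(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.lesion_of[s], []).append(s)
        return out


@dataclass
class PatientHeterogeneityResult:
    patient_id: str
    group: str
    common_variants: list[str]
    private_variants: list[str]
    shares_oncogenic: bool
    has_oncogenic: bool
    n_mutations_total: int
    common_af_medians: dict[str, float] = field(default_factory=dict)
    private_af_medians: dict[str, float] = field(default_factory=dict)


def build_presence_matrices(
    status_table: pd.DataFrame,
    hierarchy: CohortHierarchy,
    config: PipelineConfig | None = None,
) -> dict[str, PresenceMatrix]:
    """Build one presence matrix per patient from the validation status
    table.  Variants with no present cell anywhere (nothing validated and
    no fallback) are dropped; patients left with no variants are skipped
    with a warning (they cannot be grouped)."""
    config = config or PipelineConfig()
    matrices: dict[str, PresenceMatrix] = {}
    s2l = hierarchy.sample_to_lesion()
    for patient in hierarchy.patients:
        pt = status_table[status_table["patient_id"] == patient.patient_id]
        if pt.empty:
            continue
        variants = sorted(pt["variant"].unique())
        samples = patient.sample_ids  # ordered by lesion
        presence = pd.DataFrame(False, index=variants, columns=samples)
        af = pd.DataFrame(np.nan, index=variants, columns=samples)
        gene_of: dict[str, str] = {}
        for row in pt.itertuples(index=False):
            if row.sample_id not in presence.columns:
                continue
            gene_of[row.variant] = row.gene_symbol
            present = row.status in (Status.CONFIRMED.value, Status.PRESENT.value)
            if (
                not present
                and row.status == Status.ASSAY_FAILED.value
                and config.assay_failed_uses_discovery
            ):
                present = bool(row.detected_discovery)
            if present:
                presence.loc[row.variant, row.sample_id] = True
                v = row.af_validation
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    v = row.af_discovery
                af.loc[row.variant, row.sample_id] = v
        keep = presence.any(axis=1)
        presence, af = presence[keep], af[keep]
        if presence.empty:
            warnings.warn(
                f"patient {patient.patient_id}: no validated mutations; "
                "excluded from heterogeneity grouping",
                stacklevel=2,
            )
            continue
        discovery_samples = set(
            pt.loc[pt["detected_discovery"].astype(bool), "sample_id"]
        )
        val_only = {s for s in samples if s not in discovery_samples}
        matrices[patient.patient_id] = PresenceMatrix(
            patient_id=patient.patient_id,
            presence=presence,
            af=af,
            lesion_of={s: s2l[s] for s in samples},
            gene_of=gene_of,
            validation_only_samples=val_only,
        )
    return matrices


def _lesion_common_mask(
    matrix: PresenceMatrix, every_sample: bool
) -> pd.Series:
    """For each variant: present in every lesion (>=1 sample per lesion, or
    every sample when ``every_sample``)."""
    lesions = matrix.lesions()
    agg = []
    for _, samples in lesions.items():
        block = matrix.presence[samples]
        agg.append(block.all(axis=1) if every_sample else block.any(axis=1))
    return pd.concat(agg, axis=1).all(axis=1)


def classify_patient(
    matrix: PresenceMatrix,
    patient: PatientMeta,
    onco_calls: Mapping[str, OncogenicityCall] | None = None,
    config: PipelineConfig | None = None,
) -> PatientHeterogeneityResult:
    """Group one patient from their presence matrix.

    ``onco_calls`` maps variant-key strings to oncogenicity calls; when
    given, ``shares_oncogenic`` flags a lesion-common variant with the
    collapsed oncogenic flag.
    """
    config = config or PipelineConfig()
    if matrix.presence.empty:
        raise ValueError(f"patient {matrix.patient_id}: empty presence matrix")
    if len(matrix.lesions()) < 2:
        raise ValueError(f"patient {matrix.patient_id}: needs >=2 lesions")
    common_mask = _lesion_common_mask(
        matrix, every_sample=config.common_requires_every_sample
    )
    all_samples_mask = matrix.presence.all(axis=1)
    if bool(all_samples_mask.all()):
        group = "HOMOGENEOUS"
    elif not bool(common_mask.any()):
        group = "HETEROGENEOUS"
    else:
        group = "INTERMEDIATE"
    common = sorted(common_mask[common_mask].index)
    private = sorted(common_mask[~common_mask].index)

    def _onco(v: str) -> bool:
        return bool(onco_calls and v in onco_calls and onco_calls[v].collapsed_oncogenic)

    def _af_median(v: str) -> float:
        vals = matrix.af.loc[v][matrix.presence.loc[v]]
        vals = vals.dropna()
        return float(vals.median()) if len(vals) else float("nan")

    return PatientHeterogeneityResult(
        patient_id=matrix.patient_id,
        group=group,
        common_variants=common,
        private_variants=private,
        shares_oncogenic=any(_onco(v) for v in common),
        has_oncogenic=any(_onco(v) for v in matrix.variants),
        n_mutations_total=len(matrix.variants),
        common_af_medians={v: _af_median(v) for v in common},
        private_af_medians={v: _af_median(v) for v in private},
    )


def classify_cohort(
    matrices: Mapping[str, PresenceMatrix],
    hierarchy: CohortHierarchy,
    onco_calls: Mapping[str, OncogenicityCall] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[PatientHeterogeneityResult], dict]:
    """Classify every patient with a presence matrix; summarise per group.

    The summary's ``shared_fraction`` is the proportion of grouped patients
    whose lesions share at least one mutation (homogeneous + intermediate).
    """
    results = [
        classify_patient(matrices[p.patient_id], p, onco_calls, config)
        for p in hierarchy.patients
        if p.patient_id in matrices
    ]
    counts = {g: sum(1 for r in results if r.group == g) for g in GROUPS}
    n = len(results)
    per_group = {}
    for g in GROUPS:
        rg = [r for r in results if r.group == g]
        per_group[g] = {
            "n_patients": len(rg),
            "median_mutations_per_patient": (
                float(np.median([r.n_mutations_total for r in rg])) if rg else float("nan")
            ),
            "n_sharing_oncogenic": sum(1 for r in rg if r.shares_oncogenic),
        }
    summary = {
        "n_patients": n,
        "group_counts": counts,
        "shared_fraction": (
            (counts["HOMOGENEOUS"] + counts["INTERMEDIATE"]) / n if n else float("nan")
        ),
        "median_mutations_per_patient": (
            float(np.median([r.n_mutations_total for r in results])) if results else float("nan")
        ),
        "per_group": per_group,
    }
    return results, summary


def private_vs_common_af(
    results: Sequence[PatientHeterogeneityResult],
) -> dict:
    """Compare allele fractions of private vs common mutations.

    Restricted to INTERMEDIATE patients (the only ones with both sets).
    Pooled medians are taken over the per-variant AF medians of all such
    patients; the test is a paired two-tailed Wilcoxon signed-rank over the
    per-patient (median private AF, median common AF) pairs.
    """
    inter = [
        r
        for r in results
        if r.group == "INTERMEDIATE" and r.common_af_medians and r.private_af_medians
    ]
    pairs = []
    pooled_private: list[float] = []
    pooled_common: list[float] = []
    for r in inter:
        pv = [v for v in r.private_af_medians.values() if not np.isnan(v)]
        cv = [v for v in r.common_af_medians.values() if not np.isnan(v)]
        if not pv or not cv:
            continue
        pooled_private.extend(pv)
        pooled_common.extend(cv)
        pairs.append((float(np.median(pv)), float(np.median(cv))))
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"need >=2 intermediate patients with both AF sets, have {len(pairs)}"
        )
    diffs = [p - c for p, c in pairs]
    test = stats_report.wilcoxon_signed_rank(diffs)
    return {
        "median_af_private": float(np.median(pooled_private)),
        "median_af_common": float(np.median(pooled_common)),
        "p_wilcoxon_paired": test.p_value,
        "n_paired_patients": len(pairs),
    }


def covariate_association(
    results: Sequence[PatientHeterogeneityResult],
    hierarchy: CohortHierarchy,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Associate the heterogeneity grouping with clinico-pathological
    covariates.

    Continuous covariates are tested across the three groups
    (Kruskal–Wallis) and across the two-level shared-oncogenic split
    (rank-sum; patients with no oncogenic mutation at all are excluded from
    that split).  Categorical covariates are tested by Fisher's exact test
    on the groups × levels contingency table.  All tests are two-tailed;
    raw (uncorrected) p-values are reported.
    """
    from .cohort_model import CATEGORICAL_COVARIATES, CONTINUOUS_COVARIATES

    config = config or PipelineConfig()
    group_of = {r.patient_id: r.group for r in results}
    shared_onc: dict[str, bool] = {
        r.patient_id: r.shares_oncogenic for r in results if r.has_oncogenic
    }
    rows = []

    def covariate_value(p: PatientMeta, name: str):
        if name == "n_lesions":
            return len(p.lesions)
        return p.covariates.get(name)

    for cov in CONTINUOUS_COVARIATES:
        groups = {g: [] for g in GROUPS}
        two = {True: [], False: []}
        for p in hierarchy.patients:
            v = covariate_value(p, cov)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            if p.patient_id in group_of:
                groups[group_of[p.patient_id]].append(float(v))
            if p.patient_id in shared_onc:
                two[shared_onc[p.patient_id]].append(float(v))
        nonempty = [vals for vals in groups.values() if vals]
        if len(nonempty) >= 2:
            t = stats_report.kruskal_wallis(nonempty)
            rows.append(
                {
                    "covariate": cov,
                    "comparison": "3-group",
                    "test_used": t.test_name,
                    "statistic": t.statistic,
                    "p": t.p_value,
                    "n": t.n,
                }
            )
        if two[True] and two[False]:
            t = stats_report.rank_sum(two[True], two[False])
            rows.append(
                {
                    "covariate": cov,
                    "comparison": "shared-vs-private-oncogenic",
                    "test_used": t.test_name,
                    "statistic": t.statistic,
                    "p": t.p_value,
                    "n": t.n,
                }
            )

    for cov in CATEGORICAL_COVARIATES + ("n_lesions",):
        table: dict = {}
        for p in hierarchy.patients:
            if p.patient_id not in group_of:
                continue
            v = covariate_value(p, cov)
            if v is None:
                continue
            table.setdefault(str(v), {g: 0 for g in GROUPS})
            table[str(v)][group_of[p.patient_id]] += 1
        if len(table) < 2:
            rows.append(
                {
                    "covariate": cov,
                    "comparison": "3-group",
                    "test_used": "skipped (single level)",
                    "statistic": float("nan"),
                    "p": float("nan"),
                    "n": sum(sum(d.values()) for d in table.values()),
                }
            )
            continue
        levels = sorted(table)
        mat = [
            [table[lv][g] for lv in levels]
            for g in GROUPS
            if any(table[lv][g] for lv in levels)
        ]
        t = stats_report.fisher_exact_2xk(mat)
        rows.append(
            {
                "covariate": cov,
                "comparison": "3-group",
                "test_used": t.test_name,
                "statistic": t.statistic,
                "p": t.p_value,
                "n": t.n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# matrix export (heat-map style table)

_CELL_CODES = {"oncogenic-present": "O", "unknown-present": "U", "absent": "."}


def render_presence_matrix(
    matrix: PresenceMatrix,
    onco_calls: Mapping[str, OncogenicityCall] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Export a presence matrix as a heat-map style TSV.

    Cells: ``O`` = oncogenic mutation present, ``U`` = mutation of unknown
    significance present, ``.`` = absent.  Columns are ``lesion|sample``,
    with ``*`` appended for samples assayed only in the validation phase.
    """
    cols = {}
    for s in matrix.samples:
        name = f"{matrix.lesion_of[s]}|{s}"
        if s in matrix.validation_only_samples:
            name += "*"
        cols[s] = name
    out = pd.DataFrame(index=matrix.presence.index, columns=list(cols.values()))
    for v in matrix.variants:
        onc = bool(
            onco_calls and v in onco_calls and onco_calls[v].collapsed_oncogenic
        )
        for s in matrix.samples:
            if matrix.presence.loc[v, s]:
                out.loc[v, cols[s]] = "O" if onc else "U"
            else:
                out.loc[v, cols[s]] = "."
    out.insert(0, "gene", [matrix.gene_of.get(v, "") for v in matrix.variants])
    out.index.name = "variant"
    if path is not None:
        out.to_csv(path, sep="\t")
    return out


def parse_presence_export(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Re-parse an exported matrix: returns the boolean presence frame
    (rows=variants, columns=sample ids) and the sample→lesion mapping."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_cols = [c for c in df.columns if c != "gene"]
    lesion_of = {}
    presence = {}
    for c in sample_cols:
        name = c[:-1] if c.endswith("*") else c
        lesion, sample = name.split("|", 1)
        lesion_of[sample] = lesion
        presence[sample] = df[c].isin(["O", "U"])
    return pd.DataFrame(presence, index=df.index), lesion_of
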