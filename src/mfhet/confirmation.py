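"""Orthogonal-platform validation of somatic calls.

Every variant discovered in at least one sample of a patient is re-assayed
by deep resequencing on a second platform in *all* samples of that patient.
Each (variant, sample) assay receives one status:

* ``CONFIRMED`` — detected on the discovery platform in this sample and
  validated at allele fraction >= 5% (or by the 1–5% rescue rule);
* ``PRESENT`` — not detected at discovery in this sample, but validated
  (the deep assay revealed the variant where the screen missed it);
* ``NOT_DETECTED`` — validation AF below the cut-off with no rescue;
* ``ASSAY_FAILED`` — the assay could not be run or read out (design
  failure, exhausted DNA); no claim is made and the pair is excluded from
  validation denominators.

The rescue rule: a validation AF in [1%, 5%) counts as validated only when
at least one *other* sample of the same patient carries the same variant at
validation AF >= 5% (that sample is recorded as the support).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_model import (
    CohortHierarchy,
    IntegrityError,
    MutationCall,
    PipelineConfig,
    VariantKey,
    unique_variants,
)
from . import stats_report

__all__ = [
    "Status",
    "ValidationStatus",
    "assign_validation_status",
    "merge_platforms",
    "confirm_cohort",
    "platform_concordance",
    "InsufficientDataError",
]


class Status(str, Enum):
    CONFIRMED = "CONFIRMED"
    PRESENT = "PRESENT"
    NOT_DETECTED = "NOT_DETECTED"
    ASSAY_FAILED = "ASSAY_FAILED"


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


@dataclass
class ValidationStatus:
    status: Status
    af_validation: float | None = None
    supporting_sample_id: str | None = None


def assign_validation_status(
    call: MutationCall,
    patient_calls: Sequence[MutationCall],
    config: PipelineConfig,
) -> ValidationStatus:
    """Decide the validation status of one (variant, sample) assay.

    ``patient_calls`` are all calls of the same patient for the same
    variant key (the candidate itself may be among them); they supply the
    sibling-sample support for the rescue rule.  Thresholds are inclusive:
    AF exactly 5% validates, exactly 1% is rescue-eligible.
    """
    key = call.key
    for other in patient_calls:
        if other.key != key:
            raise IntegrityError(
                f"patient_calls contains foreign variant {other.key} != {key}"
            )
    if not call.assay_ok_validation or call.af_validation is None:
        return ValidationStatus(Status.ASSAY_FAILED, call.af_validation)
    af = call.af_validation
    validated = False
    support: str | None = None
    if af >= config.af_confirm_min:
        validated = True
    elif af >= config.af_rescue_min:
        for other in patient_calls:
            if other.sample_id == call.sample_id:
                continue  # a sample never supports itself
            if (
                other.assay_ok_validation
                and other.af_validation is not None
                and other.af_validation >= config.af_confirm_min
            ):
                validated = True
                support = other.sample_id
                break
    if not validated:
        return ValidationStatus(Status.NOT_DETECTED, af)
    status = Status.CONFIRMED if call.detected_discovery else Status.PRESENT
    return ValidationStatus(status, af, support)


def merge_platforms(
    discovery: Iterable[MutationCall],
    validation: Iterable[MutationCall],
) -> list[MutationCall]:
    """Merge per-platform call lists into unified calls keyed by
    (patient, variant, sample).

    A (variant, sample) pair present only in the discovery list keeps
    ``af_validation=None`` (assay never read out → ASSAY_FAILED downstream);
    one present only in the validation list has no discovery detection.
    """
    merged: dict[tuple[str, VariantKey, str], MutationCall] = {}
    for c in discovery:
        k = (c.patient_id, c.key, c.sample_id)
        if k in merged:
            raise IntegrityError(f"duplicate discovery call for {k}")
        merged[k] = MutationCall(**{**c.__dict__})
    for c in validation:
        k = (c.patient_id, c.key, c.sample_id)
        if k in merged:
            base = merged[k]
            base.af_validation = c.af_validation
            base.depth_validation = c.depth_validation
            base.assay_ok_validation = c.assay_ok_validation
            if base.protein_change is None:
                base.protein_change = c.protein_change
        else:
            merged[k] = MutationCall(**{**c.__dict__})
    return list(merged.values())


def confirm_cohort(
    calls: Sequence[MutationCall],
    hierarchy: CohortHierarchy,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign a validation status to every assayed (variant, sample) pair.

    Returns the per-pair status table (one row per assay) and the summary
    counts, which partition the assayed set::

        n_assayed = n_confirmed + n_present_only + n_not_detected + n_assay_failed
    """
    hierarchy.check_samples_resolve(calls)
    index = unique_variants(calls)
    by_patient_variant: dict[tuple[str, VariantKey], list[MutationCall]] = {}
    for patient_id, variants in index.items():
        for key, vcalls in variants.items():
            by_patient_variant[(patient_id, key)] = vcalls

    rows = []
    for (patient_id, key), vcalls in by_patient_variant.items():
        for call in vcalls:
            vs = assign_validation_status(call, vcalls, config)
            rows.append(
                {
                    "patient_id": patient_id,
                    "variant": str(key),
                    "gene_symbol": call.gene_symbol,
                    "protein_change": call.protein_change or "",
                    "variant_class": call.variant_class,
                    "sample_id": call.sample_id,
                    "status": vs.status.value,
                    "af_discovery": call.af_discovery,
                    "af_validation": call.af_validation,
                    "depth_discovery": call.depth_discovery,
                    "depth_validation": call.depth_validation,
                    "detected_discovery": call.detected_discovery,
                    "supporting_sample": vs.supporting_sample_id or "",
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            ["patient_id", "variant", "sample_id"], kind="mergesort"
        ).reset_index(drop=True)
    counts = table["status"].value_counts() if not table.empty else {}
    summary = {
        "n_assayed": int(len(table)),
        "n_confirmed": int(counts.get(Status.CONFIRMED.value, 0)),
        "n_present_only": int(counts.get(Status.PRESENT.value, 0)),
        "n_not_detected": int(counts.get(Status.NOT_DETECTED.value, 0)),
        "n_assay_failed": int(counts.get(Status.ASSAY_FAILED.value, 0)),
    }
    return table, summary


def platform_concordance(
    status_table: pd.DataFrame, confirmed_only: bool = False
) -> dict[str, float]:
    """Cross-platform concordance of allele fractions.

    Spearman's rho over (AF_discovery, AF_validation) pairs where both are
    observed (``confirmed_only=True`` restricts to validated pairs), and a
    ROC analysis in which the validation outcome (CONFIRMED/PRESENT vs
    NOT_DETECTED) is the label and the discovery AF (0 when the variant was
    not called at discovery) is the score; 95% CI for the AUC by the
    Hanley–McNeil asymptotic method.
    """
    t = status_table[status_table["status"] != Status.ASSAY_FAILED.value]
    if confirmed_only:
        t = t[t["status"].isin([Status.CONFIRMED.value, Status.PRESENT.value])]
    paired = t.dropna(subset=["af_discovery", "af_validation"])
    if len(paired) < 3:
        raise InsufficientDataError(
            f"need >=3 AF pairs for concordance, have {len(paired)}"
        )
    sp = stats_report.spearman_rho(
        list(zip(paired["af_discovery"], paired["af_validation"]))
    )
    out = {"spearman_rho": sp.statistic, "rho_pvalue": sp.p_value, "n_pairs": len(paired)}

    roc = status_table[status_table["status"] != Status.ASSAY_FAILED.value].copy()
    label = roc["status"].isin([Status.CONFIRMED.value, Status.PRESENT.value]).to_numpy()
    score = roc["af_discovery"].fillna(0.0).to_numpy(dtype=float)
    n1, n0 = int(label.sum()), int((~label).sum())
    if n1 == 0 or n0 == 0:
        out.update(roc_auc=float("nan"), auc_ci95=(float("nan"), float("nan")))
        return out
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(label, score))
    # Hanley & McNeil (1982) asymptotic standard error
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
        / (n1 * n0)
    )
    out.update(
        roc_auc=auc,
        auc_ci95=(max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)),
        n_pos=n1,
        n_neg=n0,
    )
    return out
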