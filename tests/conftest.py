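import warnings

import pandas as pd
import pytest

from mfhet.cohort_model import (
    CohortHierarchy,
    GeneRoleTable,
    LesionMeta,
    MutationCall,
    PatientMeta,
    PipelineConfig,
    RecurrenceTable,
)


@pytest.fixture
def config():
    return PipelineConfig()


def make_call(
    patient="P1",
    sample="S1",
    gene="TP53",
    chrom="17",
    pos=7578265,
    ref="C",
    alt="T",
    vclass="missense",
    pchange="R196W",
    af_d=None,
    dp_d=None,
    af_v=None,
    dp_v=None,
    assay_ok=True,
):
    return MutationCall(
        patient_id=patient,
        sample_id=sample,
        gene_symbol=gene,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=vclass,
        protein_change=pchange,
        af_discovery=af_d,
        depth_discovery=dp_d,
        af_validation=af_v,
        depth_validation=dp_v,
        assay_ok_validation=assay_ok,
    )


@pytest.fixture
def two_lesion_hierarchy():
    return CohortHierarchy(
        patients=[
            PatientMeta(
                "P1",
                [
                    LesionMeta("P1_L1", ["P1_L1_S1", "P1_L1_S2"]),
                    LesionMeta("P1_L2", ["P1_L2_S1"]),
                ],
                {"grade": "G2", "max_inter_lesion_distance_cm": 2.0},
            )
        ]
    )


@pytest.fixture
def convergent_tp53_cohort():
    """Convergent-evolution patient: lesion 1 (3 samples) clonal for the
    TP53 R196* truncating mutation, lesion 2 (1 sample) carrying the
    catalogue-recurrent TP53 R273H substitution instead."""
    hierarchy = CohortHierarchy(
        patients=[
            PatientMeta(
                "PX01",
                [
                    LesionMeta("L1", ["L1_S1", "L1_S2", "L1_S3"]),
                    LesionMeta("L2", ["L2_S1"]),
                ],
            )
        ]
    )
    r196 = dict(
        gene="TP53", chrom="17", pos=7578265, ref="C", alt="T",
        vclass="nonsense", pchange="R196*",
    )
    r273 = dict(
        gene="TP53", chrom="17", pos=7577120, ref="C", alt="T",
        vclass="missense", pchange="R273H",
    )
    discovery, validation = [], []
    for s in ["L1_S1", "L1_S2", "L1_S3"]:
        discovery.append(
            make_call(patient="PX01", sample=s, af_d=0.40, dp_d=180, **r196)
        )
        validation.append(
            make_call(patient="PX01", sample=s, af_v=0.38, dp_v=1300, **r196)
        )
        validation.append(
            make_call(patient="PX01", sample=s, af_v=0.0, dp_v=1300, **r273)
        )
    discovery.append(
        make_call(patient="PX01", sample="L2_S1", af_d=0.35, dp_d=160, **r273)
    )
    validation.append(
        make_call(patient="PX01", sample="L2_S1", af_v=0.33, dp_v=1400, **r273)
    )
    validation.append(
        make_call(patient="PX01", sample="L2_S1", af_v=0.0, dp_v=1400, **r196)
    )
    recurrence = RecurrenceTable(
        pd.DataFrame(
            [
                {"gene_symbol": "TP53", "protein_change": "R273H",
                 "cosmic_confirmed_samples": 600},
            ]
        )
    )
    roles = GeneRoleTable(
        pd.DataFrame([{"gene_symbol": "TP53", "role": "tumour_suppressor"}])
    )
    return hierarchy, discovery, validation, recurrence, roles


@pytest.fixture
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
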