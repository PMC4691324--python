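"""Patient grouping, shared/private sets, AF comparison, associations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mfhet.cohort_model import (
    CohortHierarchy,
    LesionMeta,
    PatientMeta,
    PipelineConfig,
)
from mfhet.confirmation import InsufficientDataError
from mfhet.heterogeneity import (
    PatientHeterogeneityResult,
    PresenceMatrix,
    classify_cohort,
    classify_patient,
    covariate_association,
    parse_presence_export,
    private_vs_common_af,
    render_presence_matrix,
)
from mfhet.oncogenicity import OncogenicityCall
from mfhet.cohort_model import VariantKey


def make_matrix(cells, lesion_of, patient_id="P1", af=None):
    """cells: {variant: {sample: bool}}"""
    variants = sorted(cells)
    samples = list(lesion_of)
    presence = pd.DataFrame(
        [[bool(cells[v].get(s, False)) for s in samples] for v in variants],
        index=variants,
        columns=samples,
    )
    af_frame = pd.DataFrame(
        [[(af or {}).get(v, {}).get(s, np.nan) for s in samples] for v in variants],
        index=variants,
        columns=samples,
    )
    return PresenceMatrix(
        patient_id=patient_id, presence=presence, af=af_frame, lesion_of=lesion_of
    )


def patient_for(lesion_of, patient_id="P1"):
    lesions = {}
    for s, l in lesion_of.items():
        lesions.setdefault(l, []).append(s)
    return PatientMeta(
        patient_id, [LesionMeta(l, ss) for l, ss in lesions.items()]
    )


def brute_force_group(cells, lesion_of):
    """Independent set-logic oracle for the three-group classification."""
    samples = list(lesion_of)
    lesions = {}
    for s, l in lesion_of.items():
        lesions.setdefault(l, []).append(s)
    in_every_sample = lambda v: all(cells[v].get(s, False) for s in samples)
    lesion_common = lambda v: all(
        any(cells[v].get(s, False) for s in ss) for ss in lesions.values()
    )
    if all(in_every_sample(v) for v in cells):
        return "HOMOGENEOUS"
    if not any(lesion_common(v) for v in cells):
        return "HETEROGENEOUS"
    return "INTERMEDIATE"


TWO_LESIONS = {"a1": "L1", "a2": "L1", "b1": "L2"}


class TestClassifyPatient:
    def test_single_shared_variant_is_homogeneous(self):
        lesion_of = {"a1": "L1", "b1": "L2"}
        m = make_matrix({"v1": {"a1": True, "b1": True}}, lesion_of)
        r = classify_patient(m, patient_for(lesion_of))
        assert r.group == "HOMOGENEOUS"
        assert r.common_variants == ["v1"] and r.private_variants == []

    def test_disjoint_lesion_variants_are_heterogeneous(self):
        m = make_matrix(
            {
                "tp53_a": {"a1": True, "a2": True},
                "tp53_b": {"b1": True},
            },
            TWO_LESIONS,
        )
        r = classify_patient(m, patient_for(TWO_LESIONS))
        assert r.group == "HETEROGENEOUS"
        assert r.common_variants == []

    def test_shared_plus_private_is_intermediate(self):
        m = make_matrix(
            {
                "shared": {"a1": True, "a2": True, "b1": True},
                "private": {"b1": True},
            },
            TWO_LESIONS,
        )
        r = classify_patient(m, patient_for(TWO_LESIONS))
        assert r.group == "INTERMEDIATE"
        assert r.common_variants == ["shared"]
        assert r.private_variants == ["private"]

    def test_lesion_common_but_sample_incomplete_is_intermediate(self):
        # present in >=1 sample of each lesion but missing from a2: the
        # default lesion-level reading keeps it common, but the patient is
        # not homogeneous
        m = make_matrix({"v": {"a1": True, "b1": True}}, TWO_LESIONS)
        r = classify_patient(m, patient_for(TWO_LESIONS))
        assert r.group == "INTERMEDIATE"
        assert r.common_variants == ["v"]

    def test_strict_flag_demotes_sample_incomplete_common(self):
        cfg = PipelineConfig(common_requires_every_sample=True)
        m = make_matrix({"v": {"a1": True, "b1": True}}, TWO_LESIONS)
        r = classify_patient(m, patient_for(TWO_LESIONS), config=cfg)
        assert r.group == "HETEROGENEOUS"

    def test_empty_matrix_rejected(self):
        m = make_matrix({}, TWO_LESIONS)
        with pytest.raises(ValueError, match="empty presence matrix"):
            classify_patient(m, patient_for(TWO_LESIONS))

    def test_shares_oncogenic_uses_common_set_only(self):
        m = make_matrix(
            {
                "shared": {"a1": True, "a2": True, "b1": True},
                "private": {"b1": True},
            },
            TWO_LESIONS,
        )
        key = VariantKey("1", 1, "A", "G")
        onco = {
            "private": OncogenicityCall(key, "G", None, "ONCOGENIC", "R4"),
            "shared": OncogenicityCall(key, "G", None, "UNKNOWN", None),
        }
        r = classify_patient(m, patient_for(TWO_LESIONS), onco)
        assert r.has_oncogenic and not r.shares_oncogenic

    def test_exhaustive_agreement_with_set_logic_oracle(self):
        """All presence matrices with <=3 variants, 2 lesions, <=2
        samples/lesion agree with the brute-force oracle."""
        checked = 0
        for n1, n2 in itertools.product([1, 2], repeat=2):
            samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
            lesion_of = {s: ("L1" if s.startswith("a") else "L2") for s in samples}
            ns = len(samples)
            for nv in (1, 2, 3):
                for bits in itertools.product(range(1, 2**ns), repeat=nv):
                    # each variant present in >=1 sample (row invariant)
                    cells = {
                        f"v{vi}": {
                            s: bool(b >> si & 1) for si, s in enumerate(samples)
                        }
                        for vi, b in enumerate(bits)
                    }
                    m = make_matrix(cells, lesion_of)
                    got = classify_patient(m, patient_for(lesion_of)).group
                    assert got == brute_force_group(cells, lesion_of)
                    checked += 1
        assert checked > 3000

    def test_group_invariant_under_sample_relabeling(self):
        cells = {
            "v1": {"a1": True, "a2": False, "b1": True},
            "v2": {"a1": False, "a2": True, "b1": False},
        }
        base = classify_patient(
            make_matrix(cells, TWO_LESIONS), patient_for(TWO_LESIONS)
        ).group
        # swap lesion labels and sample order
        relabel = {"b1": "L1", "a1": "L2", "a2": "L2"}
        swapped = {
            v: {s: cells[v][s] for s in relabel} for v in cells
        }
        assert (
            classify_patient(
                make_matrix(swapped, relabel), patient_for(relabel)
            ).group
            == base
        )

    def test_adding_common_variant_breaks_heterogeneity(self):
        cells = {"x": {"a1": True, "a2": True}, "y": {"b1": True}}
        m = make_matrix(cells, TWO_LESIONS)
        assert classify_patient(m, patient_for(TWO_LESIONS)).group == "HETEROGENEOUS"
        cells["z"] = {"a1": True, "a2": True, "b1": True}
        m2 = make_matrix(cells, TWO_LESIONS)
        assert classify_patient(m2, patient_for(TWO_LESIONS)).group != "HETEROGENEOUS"


class TestCohortSummary:
    def test_counts_partition_cohort(self):
        lesion_of = {"a1": "L1", "b1": "L2"}
        patterns = {
            "P1": {"v1": {"a1": True, "b1": True}},  # homogeneous
            "P2": {"v1": {"a1": True, "b1": True}, "v2": {"a1": True}},  # intermediate
            "P3": {"v1": {"a1": True}, "v2": {"b1": True}},  # heterogeneous
        }
        matrices, patients = {}, []
        for pid, cells in patterns.items():
            lo = {f"{pid}_{s}": l for s, l in lesion_of.items()}
            cells = {
                v: {f"{pid}_{s}": p for s, p in sm.items()}
                for v, sm in cells.items()
            }
            matrices[pid] = make_matrix(cells, lo, patient_id=pid)
            patients.append(patient_for(lo, pid))
        hierarchy = CohortHierarchy(patients)
        results, summary = classify_cohort(matrices, hierarchy)
        assert summary["group_counts"] == {
            "HOMOGENEOUS": 1, "INTERMEDIATE": 1, "HETEROGENEOUS": 1
        }
        assert summary["shared_fraction"] == pytest.approx(2 / 3)


class TestPrivateVsCommonAF:
    def _result(self, pid, private, common):
        return PatientHeterogeneityResult(
            patient_id=pid,
            group="INTERMEDIATE",
            common_variants=list(common),
            private_variants=list(private),
            shares_oncogenic=False,
            has_oncogenic=False,
            n_mutations_total=len(private) + len(common),
            common_af_medians=dict(common),
            private_af_medians=dict(private),
        )

    def test_equal_afs_give_p_one(self):
        results = [
            self._result(f"P{i}", {"pv": 0.2}, {"cv": 0.2}) for i in range(3)
        ]
        out = private_vs_common_af(results)
        assert out["p_wilcoxon_paired"] == 1.0
        assert out["median_af_private"] == out["median_af_common"]

    def test_signed_rank_matches_exact_enumeration(self):
        pairs = [(0.1, 0.3), (0.2, 0.25), (0.15, 0.3)]
        results = [
            self._result(f"P{i}", {"pv": p}, {"cv": c})
            for i, (p, c) in enumerate(pairs)
        ]
        out = private_vs_common_af(results)
        # oracle: enumerate all sign assignments of |diffs| ranks
        diffs = [p - c for p, c in pairs]
        ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
        w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
        n = len(diffs)
        stats = [
            sum(r for r, keep in zip(ranks, signs) if keep)
            for signs in itertools.product([0, 1], repeat=n)
        ]
        mean = n * (n + 1) / 4
        p_exact = np.mean(
            [abs(s - mean) >= abs(w_obs - mean) - 1e-12 for s in stats]
        )
        assert out["p_wilcoxon_paired"] == pytest.approx(p_exact)

    def test_single_patient_insufficient(self):
        with pytest.raises(InsufficientDataError):
            private_vs_common_af([self._result("P1", {"pv": 0.1}, {"cv": 0.2})])


class TestCovariateAssociation:
    def _cohort(self, n_per_group=5, distance_by_group=None, rng=None):
        rng = rng or np.random.default_rng(0)
        patients, results = [], []
        for g in ("HOMOGENEOUS", "INTERMEDIATE", "HETEROGENEOUS"):
            for i in range(n_per_group):
                pid = f"{g[:3]}{i}"
                lo = {f"{pid}_a": "L1", f"{pid}_b": "L2"}
                pm = patient_for(lo, pid)
                d = (
                    distance_by_group[g](rng)
                    if distance_by_group
                    else float(rng.uniform(1, 3))
                )
                pm.covariates = {
                    "max_inter_lesion_distance_cm": d,
                    "grade": "G2",
                    "subtype": ["ER+/HER2-", "HER2+"][i % 2],
                }
                patients.append(pm)
                results.append(
                    PatientHeterogeneityResult(
                        pid, g, [], [], shares_oncogenic=(g != "HETEROGENEOUS"),
                        has_oncogenic=True, n_mutations_total=1,
                    )
                )
        return results, CohortHierarchy(patients)

    def test_identical_distance_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        results, hierarchy = self._cohort(
            n_per_group=8,
            distance_by_group={g: (lambda r: float(r.uniform(1, 3)))
                               for g in ("HOMOGENEOUS", "INTERMEDIATE", "HETEROGENEOUS")},
            rng=rng,
        )
        table = covariate_association(results, hierarchy)
        row = table[
            (table["covariate"] == "max_inter_lesion_distance_cm")
            & (table["comparison"] == "3-group")
        ].iloc[0]
        assert row["p"] > 0.05

    def test_planted_distance_separation_detected(self):
        """Heterogeneous lesions planted further apart (N(4,1) vs N(1.5,1))
        must yield a significant shared-vs-private oncogenic rank-sum."""
        rng = np.random.default_rng(7)
        results, hierarchy = self._cohort(
            n_per_group=10,
            distance_by_group={
                "HOMOGENEOUS": lambda r: float(r.normal(1.5, 1)),
                "INTERMEDIATE": lambda r: float(r.normal(1.5, 1)),
                "HETEROGENEOUS": lambda r: float(r.normal(4, 1)),
            },
            rng=rng,
        )
        table = covariate_association(results, hierarchy)
        row = table[
            (table["covariate"] == "max_inter_lesion_distance_cm")
            & (table["comparison"] == "shared-vs-private-oncogenic")
        ].iloc[0]
        assert row["p"] < 0.05

    def test_single_level_covariate_skipped(self):
        results, hierarchy = self._cohort()
        table = covariate_association(results, hierarchy)
        row = table[table["covariate"] == "grade"].iloc[0]
        assert "skipped" in row["test_used"]


class TestRenderMatrix:
    def test_all_oncogenic_present_renders_o(self, tmp_path):
        lesion_of = {"a1": "L1", "b1": "L2"}
        m = make_matrix({"v": {"a1": True, "b1": True}}, lesion_of)
        key = VariantKey("1", 1, "A", "G")
        onco = {"v": OncogenicityCall(key, "G", None, "ONCOGENIC", "R4")}
        out = render_presence_matrix(m, onco)
        assert set(out.drop(columns="gene").to_numpy().ravel()) == {"O"}

    def test_two_variants_same_gene_disjoint_rows(self):
        m = make_matrix(
            {
                "17:1:C>T": {"a1": True, "a2": True},
                "17:2:C>T": {"b1": True},
            },
            TWO_LESIONS,
        )
        m.gene_of = {"17:1:C>T": "TP53", "17:2:C>T": "TP53"}
        out = render_presence_matrix(m)
        grid = out.drop(columns="gene")
        present = grid.apply(lambda row: set(row[row != "."].index), axis=1)
        assert present["17:1:C>T"].isdisjoint(present["17:2:C>T"])

    def test_export_round_trips(self, tmp_path):
        rng = np.random.default_rng(3)
        lesion_of = {"s1": "L1", "s2": "L1", "s3": "L2"}
        cells = {
            f"v{i}": {s: bool(rng.integers(2)) or (s == "s1")
                      for s in lesion_of}
            for i in range(4)
        }
        m = make_matrix(cells, lesion_of)
        m.validation_only_samples = {"s3"}
        path = tmp_path / "m.tsv"
        render_presence_matrix(m, None, path)
        presence, lesions = parse_presence_export(path)
        assert lesions == lesion_of
        pd.testing.assert_frame_equal(
            presence.astype(bool), m.presence, check_names=False
        )
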