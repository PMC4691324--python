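"""Synthetic multifocal-cohort generator with recorded ground truth.

Emulates the statistical structure the analysis assumes, at the cohort
scale of the study design it mirrors: ~36 patients with 2–4 lesions each
and 1–3 samples per lesion; a planted heterogeneity group per patient
(homogeneous : intermediate : heterogeneous at 11:13:12); truncal mutations
carried by every sample at cancer-cell fraction 1 and lesion-private
mutations at a configurable subclonal CCF; tumour purity per sample; and
two-platform read sampling (a ~178x discovery screen whose caller misses
low-AF sites, and a ~1344x validation assay re-interrogating every
discovered variant in every sample of the patient, with a configurable
fraction of assays failing).  Observed allele fractions are drawn from a
binomial or beta-binomial read model around ``purity x CCF / 2`` (diploid
heterozygous expectation).  Mutations are planted with known oncogenicity
rules (oncogene hotspots, catalogue-recurrent substitutions, truncating
tumour-suppressor lesions, singleton catalogue entries, passengers), and
each lesion receives a copy-number profile and rearrangement list with
known truncal/private structure.  Every planted fact is recorded in a
:class:`CohortTruth` for downstream recovery checks.

What it does **not** emulate: sequence-level reads, copy-number-aware
allele fractions, germline contamination, or FFPE artefact spectra beyond
simple overdispersion.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_model import (
    CohortHierarchy,
    GeneRoleTable,
    LesionMeta,
    MutationCall,
    PatientMeta,
    RecurrenceTable,
    VariantKey,
    write_hierarchy,
    write_variant_table,
)
from .cn_structural import (
    CopyNumberProfile,
    RearrangementEvent,
    RearrangementSet,
    classify_rearrangement,
)

__all__ = [
    "GeneratorConfig",
    "CohortTruth",
    "PatientTruth",
    "SyntheticCohort",
    "generate_cohort",
    "truth_vs_pipeline_report",
]

GROUPS = ("HOMOGENEOUS", "INTERMEDIATE", "HETEROGENEOUS")


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Cohort-generation parameters.

    Defaults encode the emulated study's conditions: 36 patients, lesion
    counts 2 (22/36), 3 (10/36) or 4 (4/36); group proportions 11:13:12;
    per-patient mutation counts log-normal around a cohort median of ~3
    (range clipped to 1–27, homogeneous patients drawing fewer and
    heterogeneous more); discovery depth 178x, validation depth 1344x;
    subclonal private mutations at half the cancer-cell fraction of truncal
    ones; ~44% of unique variants planted as (tiered) oncogenic; ~7% of
    validation assays failing; inter-lesion distances larger for
    heterogeneous than homogeneous patients.
    """

    n_patients: int = 36
    lesion_count_probs: tuple = ((2, 22 / 36), (3, 10 / 36), (4, 4 / 36))
    samples_per_lesion_probs: tuple = ((1, 0.45), (2, 0.35), (3, 0.20))
    group_proportions: tuple = (11 / 36, 13 / 36, 12 / 36)  # HOM, INT, HET
    mutation_count_median: dict = field(
        default_factory=lambda: {
            "HOMOGENEOUS": 2.5,
            "INTERMEDIATE_TRUNCAL": 1.5,
            "INTERMEDIATE_PRIVATE": 1.5,
            "HETEROGENEOUS_PER_LESION": 2.0,
        }
    )
    mutation_count_sigma: float = 0.6
    mutation_count_max: int = 27
    private_subclone_ccf: float = 0.5
    purity_range: tuple = (0.4, 0.9)
    depth_discovery: float = 178.0
    depth_validation: float = 1344.0
    af_noise: str = "beta-binomial"  # binomial | beta-binomial | none
    overdispersion_rho: float = 0.01
    background_error_rate: float = 0.001
    assay_failure_rate: float = 0.07
    oncogenic_fraction: float = 0.44
    discovery_min_af: float = 0.05
    discovery_min_alt_reads: int = 4
    distance_mean_cm: dict = field(
        default_factory=lambda: {
            "HOMOGENEOUS": 1.5,
            "INTERMEDIATE": 2.5,
            "HETEROGENEOUS": 4.0,
        }
    )
    distance_sd_cm: float = 1.0
    distance_missing_prob: float = 10 / 36
    # structural layer
    n_chromosomes: int = 8
    chrom_length: int = 100_000_000
    segments_per_chrom: int = 5
    truncal_cn_events_mean: float = 3.0
    private_cn_events_mean: dict = field(
        default_factory=lambda: {
            "HOMOGENEOUS": 0.5,
            "INTERMEDIATE": 1.5,
            "HETEROGENEOUS": 3.0,
        }
    )
    truncal_rr_events_mean: float = 4.0
    private_rr_events_mean: dict = field(
        default_factory=lambda: {
            "HOMOGENEOUS": 1.0,
            "INTERMEDIATE": 2.0,
            "HETEROGENEOUS": 5.0,
        }
    )
    rr_jitter_bp: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 3:
            raise ConfigError("need n_patients >= 3 for three groups")
        if not math.isclose(sum(self.group_proportions), 1.0, abs_tol=1e-9):
            raise ConfigError("group_proportions must sum to 1")
        for name, probs in (
            ("lesion_count_probs", self.lesion_count_probs),
            ("samples_per_lesion_probs", self.samples_per_lesion_probs),
        ):
            if not math.isclose(sum(p for _, p in probs), 1.0, abs_tol=1e-9):
                raise ConfigError(f"{name} must sum to 1")
        if not 0 < self.private_subclone_ccf <= 1:
            raise ConfigError("private_subclone_ccf must be in (0,1]")
        if self.af_noise not in ("binomial", "beta-binomial", "none"):
            raise ConfigError(f"unknown af_noise {self.af_noise!r}")
        for r in (
            self.background_error_rate,
            self.assay_failure_rate,
            self.oncogenic_fraction,
            self.distance_missing_prob,
        ):
            if not 0 <= r <= 1:
                raise ConfigError("rates must be within [0,1]")


# --- gene catalogues -------------------------------------------------------

#: oncogene/catalogue hotspots: gene, chrom, pos, ref, alt, class, protein
#: change, catalogue count, planted rule
HOTSPOT_CATALOGUE = (
    ("PIK3CA", "3", 178952085, "A", "G", "missense", "H1047R", 2500, "R1"),
    ("PIK3CA", "3", 178936091, "G", "A", "missense", "E545K", 1800, "R1"),
    ("PIK3CA", "3", 178936082, "G", "A", "missense", "E542K", 900, "R1"),
    ("AKT1", "14", 105246551, "C", "T", "missense", "E17K", 400, "R1"),
    ("ERBB2", "17", 37880220, "T", "C", "missense", "L755S", 120, "R1"),
    ("TP53", "17", 7577120, "C", "T", "missense", "R273H", 600, "R2"),
    ("TP53", "17", 7578406, "C", "T", "missense", "R175H", 700, "R2"),
    ("GATA3", "10", 8111510, "A", "C", "missense", "M294R", 45, "R2"),
)

GENE_ROLES = (
    ("PIK3CA", "oncogene"),
    ("AKT1", "oncogene"),
    ("ERBB2", "oncogene"),
    ("TP53", "tumour_suppressor"),
    ("PTEN", "tumour_suppressor"),
    ("RB1", "tumour_suppressor"),
    ("CDH1", "tumour_suppressor"),
    ("MAP3K1", "tumour_suppressor"),
    ("NF1", "tumour_suppressor"),
    ("GATA3", "other_cancer_gene"),
    ("KMT2C", "other_cancer_gene"),
    ("ARID1A", "other_cancer_gene"),
)

#: tumour suppressors for planted truncating (R4) variants
TSG_POOL = ("TP53", "PTEN", "RB1", "CDH1", "MAP3K1")
#: genes for planted catalogue-singleton (R7) substitutions
SINGLETON_POOL = ("KMT2C", "ARID1A", "NF1", "GATA3")
#: passenger genes (absent from the role table -> not_cancer_gene)
PASSENGER_POOL = (
    "TTN", "MUC16", "USH2A", "DNAH5", "PCLO", "CSMD1", "RYR2", "FLG",
    "OBSCN", "SYNE1", "LRP1B", "FAT3",
)

_CHROM_OF_GENE = {
    "TP53": "17", "PTEN": "10", "RB1": "13", "CDH1": "16", "MAP3K1": "5",
    "NF1": "17", "GATA3": "10", "KMT2C": "7", "ARID1A": "1",
}

_AMINO = "ARNDCQEGHILKMFPSTWYV"
_BASES = "ACGT"


@dataclass
class VariantSpec:
    """One planted unique variant (cohort-level identity + truth labels)."""

    key: VariantKey
    gene_symbol: str
    variant_class: str
    protein_change: str | None
    planted_rule: str | None  # R1/R2/R4/R7 or None (passenger)
    planted_category: str  # ONCOGENIC/POSSIBLE/UNKNOWN
    cosmic_count: int = 0


@dataclass
class PatientTruth:
    patient_id: str
    group: str
    truncal_variants: list[str]
    #: lesion_id -> private variant-key strings
    private_variants: dict[str, list[str]]
    #: (variant_key_str, sample_id) -> planted cancer-cell fraction
    ccf: dict[tuple[str, str], float]
    purity: dict[str, float]
    #: lesion_id -> truncal/private CN event intervals and RR breakpoints
    cn_truncal_events: list[dict] = field(default_factory=list)
    cn_private_events: dict[str, list[dict]] = field(default_factory=dict)
    rr_truncal: list[dict] = field(default_factory=list)
    rr_private: dict[str, list[dict]] = field(default_factory=dict)


@dataclass
class CohortTruth:
    patients: dict[str, PatientTruth]
    #: variant-key string -> VariantSpec
    variants: dict[str, VariantSpec]
    #: variant-key strings never detected by the discovery screen
    undiscovered: set[str] = field(default_factory=set)
    #: (variant_key_str, sample_id) assays flagged as failed
    assay_failed: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    hierarchy: CohortHierarchy
    discovery_calls: list[MutationCall]
    validation_calls: list[MutationCall]
    recurrence: RecurrenceTable
    roles: GeneRoleTable
    cn_profiles: dict[str, dict[str, CopyNumberProfile]]  # patient -> lesion -> profile
    rearrangements: dict[str, dict[str, RearrangementSet]]
    truth: CohortTruth

    def write(self, outdir: str | Path) -> None:
        """Emit the exact file set the analysis readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.discovery_calls, outdir / "discovery.tsv", "discovery")
        write_variant_table(
            self.validation_calls, outdir / "validation.tsv", "validation"
        )
        write_hierarchy(self.hierarchy, outdir / "hierarchy.yaml")
        self.recurrence.df.to_csv(outdir / "recurrence.tsv", sep="\t", index=False)
        self.roles.df.to_csv(outdir / "roles.tsv", sep="\t", index=False)
        cn_dir = outdir / "cn"
        rr_dir = outdir / "rearrangements"
        cn_dir.mkdir(exist_ok=True)
        rr_dir.mkdir(exist_ok=True)
        for pid, by_lesion in self.cn_profiles.items():
            for lid, prof in by_lesion.items():
                prof.segments.to_csv(
                    cn_dir / f"{lid}.bed", sep="\t", index=False, header=False
                )
        for pid, by_lesion in self.rearrangements.items():
            for lid, rrset in by_lesion.items():
                rows = []
                for e in rrset.events:
                    rows.append(
                        [e.chrom1, e.pos1 - 1, e.pos1, e.chrom2, e.pos2 - 1,
                         e.pos2, e.rr_class, 0, e.strand1, e.strand2]
                    )
                pd.DataFrame(rows).to_csv(
                    rr_dir / f"{lid}.bedpe", sep="\t", index=False, header=False
                )
        (outdir / "truth.json").write_text(self._truth_json())

    def _truth_json(self) -> str:
        t = self.truth

        def enc(o):
            if isinstance(o, (set, tuple)):
                return sorted(o) if isinstance(o, set) else list(o)
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        payload = {
            "patients": {
                pid: {
                    "group": pt.group,
                    "truncal_variants": pt.truncal_variants,
                    "private_variants": pt.private_variants,
                    "ccf": {f"{v}|{s}": c for (v, s), c in pt.ccf.items()},
                    "purity": pt.purity,
                }
                for pid, pt in t.patients.items()
            },
            "variants": {
                k: {
                    "gene": v.gene_symbol,
                    "class": v.variant_class,
                    "protein_change": v.protein_change,
                    "rule": v.planted_rule,
                    "category": v.planted_category,
                }
                for k, v in t.variants.items()
            },
            "undiscovered": sorted(t.undiscovered),
            "assay_failed": sorted(f"{v}|{s}" for v, s in t.assay_failed),
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=enc)


# ---------------------------------------------------------------------------


class _VariantFactory:
    """Mints planted variants with globally unique genomic identities for
    non-hotspot classes (hotspots reuse their fixed catalogue coordinates)."""

    def __init__(self, rng: np.random.Generator, oncogenic_fraction: float):
        self.rng = rng
        self.onco_frac = oncogenic_fraction
        self.counter = 0
        self.extra_recurrence_rows: list[dict] = []

    def _unique_site(self, gene: str) -> tuple[str, int, int]:
        self.counter += 1
        chrom = _CHROM_OF_GENE.get(gene, str(1 + (self.counter % 22)))
        pos = 1_000_000 + 137 * self.counter
        residue = 10 + 7 * self.counter  # >=7 aa apart: no accidental clusters
        return chrom, pos, residue

    def _substitution_alleles(self) -> tuple[str, str]:
        ref = _BASES[self.rng.integers(4)]
        alt = _BASES[self.rng.integers(4)]
        while alt == ref:
            alt = _BASES[self.rng.integers(4)]
        return ref, alt

    def make(
        self,
        force_driver: bool = False,
        exclude_hotspots: set | None = None,
        driver_prob: float | None = None,
    ):
        """Draw one planted variant; drivers w.p. ``oncogenic_fraction``
        (``driver_prob`` overrides; always a driver when ``force_driver``)."""
        rng = self.rng
        p = self.onco_frac if driver_prob is None else driver_prob
        driver = force_driver or (rng.random() < p)
        if not driver:
            gene = PASSENGER_POOL[rng.integers(len(PASSENGER_POOL))]
            chrom, pos, residue = self._unique_site(gene)
            ref, alt = self._substitution_alleles()
            aa1, aa2 = (_AMINO[rng.integers(20)] for _ in range(2))
            return VariantSpec(
                VariantKey(chrom, pos, ref, alt), gene, "missense",
                f"{aa1}{residue}{aa2}", None, "UNKNOWN",
            )
        kind = rng.choice(["hotspot", "truncating", "singleton"], p=[0.5, 0.3, 0.2])
        if kind == "hotspot":
            avail = [
                h for h in HOTSPOT_CATALOGUE
                if exclude_hotspots is None or h[6] not in exclude_hotspots
            ] or list(HOTSPOT_CATALOGUE)
            gene, chrom, pos, ref, alt, vc, pc, count, rule = avail[
                rng.integers(len(avail))
            ]
            return VariantSpec(
                VariantKey(chrom, pos, ref, alt), gene, vc, pc, rule,
                "ONCOGENIC", cosmic_count=count,
            )
        if kind == "truncating":
            gene = TSG_POOL[rng.integers(len(TSG_POOL))]
            chrom, pos, residue = self._unique_site(gene)
            vc = ["nonsense", "frameshift_del", "frameshift_ins"][rng.integers(3)]
            if vc == "nonsense":
                ref, alt = self._substitution_alleles()
                pc = f"{_AMINO[rng.integers(20)]}{residue}*"
            elif vc == "frameshift_del":
                ref, alt = "AT", "A"
                pc = f"{_AMINO[rng.integers(20)]}{residue}fs"
            else:
                ref, alt = "A", "AT"
                pc = f"{_AMINO[rng.integers(20)]}{residue}fs"
            return VariantSpec(
                VariantKey(chrom, pos, ref, alt), gene, vc, pc, "R4", "ONCOGENIC"
            )
        # singleton: catalogue count 1 -> POSSIBLE via R7
        gene = SINGLETON_POOL[rng.integers(len(SINGLETON_POOL))]
        chrom, pos, residue = self._unique_site(gene)
        ref, alt = self._substitution_alleles()
        pc = f"{_AMINO[rng.integers(20)]}{residue}{_AMINO[rng.integers(20)]}"
        self.extra_recurrence_rows.append(
            {"gene_symbol": gene, "protein_change": pc, "cosmic_confirmed_samples": 1}
        )
        return VariantSpec(
            VariantKey(chrom, pos, ref, alt), gene, "missense", pc, "R7",
            "POSSIBLE", cosmic_count=1,
        )


def _draw_count(rng: np.random.Generator, median: float, sigma: float, vmax: int) -> int:
    v = int(round(float(np.exp(rng.normal(np.log(median), sigma)))))
    return int(min(max(v, 1), vmax))


def _choice(rng: np.random.Generator, probs: tuple):
    values = [v for v, _ in probs]
    p = np.array([w for _, w in probs], dtype=float)
    return values[rng.choice(len(values), p=p / p.sum())]


def _sample_af(rng, p: float, depth_mean: float, cfg: GeneratorConfig):
    """Observed (af, depth) under the configured read model."""
    if cfg.af_noise == "none":
        return p, int(round(depth_mean))
    depth = max(1, int(rng.poisson(depth_mean)))
    if p <= 0:
        alt = rng.binomial(depth, cfg.background_error_rate)
    elif cfg.af_noise == "binomial":
        alt = rng.binomial(depth, p)
    else:  # beta-binomial with overdispersion rho
        rho = cfg.overdispersion_rho
        scale = (1 - rho) / rho
        alt = rng.binomial(depth, rng.beta(p * scale, (1 - p) * scale))
    return alt / depth, depth


def _covariates(rng: np.random.Generator, group: str, cfg: GeneratorConfig) -> dict:
    age = rng.choice(["<40", "40-49", "50-69", ">70"], p=np.array([2, 11, 17, 6]) / 36)
    grade = rng.choice(["G1", "G2", "G3"], p=np.array([8, 7, 21]) / 36)
    subtype = rng.choice(
        ["ER+/HER2-", "ER-/HER2-", "HER2+"], p=np.array([26, 4, 6]) / 36
    )
    nodes = int(rng.choice([0, 1, 2, 3, 5, 12], p=[16 / 36, 7 / 36, 6 / 36, 3 / 36, 1 / 36, 3 / 36]))
    size = float(np.round(np.exp(rng.normal(np.log(2.2), 0.4)), 1))
    if rng.random() < cfg.distance_missing_prob:
        distance = None
    else:
        distance = float(
            np.round(
                max(0.2, rng.normal(cfg.distance_mean_cm[group], cfg.distance_sd_cm)), 1
            )
        )
    return {
        "age_group": str(age),
        "tumour_size_cm": size,
        "n_positive_nodes": nodes,
        "grade": str(grade),
        "subtype": str(subtype),
        "dcis_present": bool(rng.random() < 30 / 36),
        "lvi_present": bool(rng.random() < 14 / 36),
        "max_inter_lesion_distance_cm": distance,
    }


def _make_cn_profiles(rng, group, lesion_ids, cfg: GeneratorConfig):
    """Per-lesion segmented profiles: diploid baseline, shared truncal
    events plus lesion-private events on segment runs kept one segment
    apart so truncal/private aberration intervals never merge."""
    nseg = cfg.segments_per_chrom
    seglen = cfg.chrom_length // nseg
    chroms = [str(c + 1) for c in range(cfg.n_chromosomes)]
    blocked: set[tuple[str, int]] = set()

    def draw_event():
        for _ in range(60):
            chrom = chroms[rng.integers(len(chroms))]
            i = int(rng.integers(nseg))
            j = int(min(nseg - 1, i + rng.integers(1, 3)))
            touched = {(chrom, k) for k in range(max(0, i - 1), min(nseg, j + 2))}
            if touched & blocked:
                continue
            blocked.update((chrom, k) for k in range(i, j + 1))
            return {
                "chrom": chrom,
                "seg_start": i,
                "seg_end": j,
                "delta": int(rng.choice([-1, 1])),
                "start": i * seglen,
                "end": (j + 1) * seglen,
            }
        return None

    n_truncal = int(rng.poisson(cfg.truncal_cn_events_mean))
    truncal = [e for e in (draw_event() for _ in range(n_truncal)) if e]
    private: dict[str, list[dict]] = {}
    for lid in lesion_ids:
        k = int(rng.poisson(cfg.private_cn_events_mean[group]))
        private[lid] = [e for e in (draw_event() for _ in range(k)) if e]

    profiles: dict[str, CopyNumberProfile] = {}
    for lid in lesion_ids:
        copy = {
            (chrom, k): 2 for chrom in chroms for k in range(nseg)
        }
        for e in truncal + private[lid]:
            for k in range(e["seg_start"], e["seg_end"] + 1):
                copy[(e["chrom"], k)] = max(0, copy[(e["chrom"], k)] + e["delta"])
        rows = [
            {
                "chrom": chrom,
                "start": k * seglen,
                "end": (k + 1) * seglen,
                "copy_number": copy[(chrom, k)],
            }
            for chrom in chroms
            for k in range(nseg)
        ]
        profiles[lid] = CopyNumberProfile(
            lesion_id=lid, segments=pd.DataFrame(rows), ploidy=2.0
        )
    return profiles, truncal, private


def _make_rearrangements(rng, group, lesion_ids, cfg: GeneratorConfig):
    chroms = [str(c + 1) for c in range(cfg.n_chromosomes)]
    used_positions: list[int] = []

    def draw_breakpoints():
        for _ in range(60):
            c1 = chroms[rng.integers(len(chroms))]
            p1 = int(rng.integers(1_000_000, cfg.chrom_length - 1_000_000))
            if rng.random() < 0.25:
                c2 = chroms[rng.integers(len(chroms))]
                while c2 == c1:
                    c2 = chroms[rng.integers(len(chroms))]
                p2 = int(rng.integers(1_000_000, cfg.chrom_length - 1_000_000))
                s1 = "+-"[rng.integers(2)]
                s2 = "+-"[rng.integers(2)]
            else:
                c2 = c1
                p2 = p1 + int(rng.integers(50_000, 5_000_000))
                s1 = "+-"[rng.integers(2)]
                s2 = "+-"[rng.integers(2)]
            if all(abs(p1 - u) > 50_000 and abs(p2 - u) > 50_000 for u in used_positions):
                used_positions.extend([p1, p2])
                return c1, p1, s1, c2, p2, s2
        return None

    n_truncal = int(rng.poisson(cfg.truncal_rr_events_mean))
    truncal = [b for b in (draw_breakpoints() for _ in range(n_truncal)) if b]
    private: dict[str, list] = {}
    for lid in lesion_ids:
        k = int(rng.poisson(cfg.private_rr_events_mean[group]))
        private[lid] = [b for b in (draw_breakpoints() for _ in range(k)) if b]

    sets: dict[str, RearrangementSet] = {}
    for lid in lesion_ids:
        events = []
        for c1, p1, s1, c2, p2, s2 in truncal:
            j1 = int(rng.integers(-cfg.rr_jitter_bp, cfg.rr_jitter_bp + 1))
            j2 = int(rng.integers(-cfg.rr_jitter_bp, cfg.rr_jitter_bp + 1))
            events.append(
                RearrangementEvent(
                    lid, c1, p1 + j1, s1, c2, p2 + j2, s2,
                    classify_rearrangement(c1, s1, c2, s2),
                )
            )
        for c1, p1, s1, c2, p2, s2 in private[lid]:
            events.append(
                RearrangementEvent(
                    lid, c1, p1, s1, c2, p2, s2,
                    classify_rearrangement(c1, s1, c2, s2),
                )
            )
        sets[lid] = RearrangementSet(lesion_id=lid, events=events)
    truncal_dicts = [
        {"chrom1": c1, "pos1": p1, "chrom2": c2, "pos2": p2} for c1, p1, _, c2, p2, _ in truncal
    ]
    private_dicts = {
        lid: [
            {"chrom1": c1, "pos1": p1, "chrom2": c2, "pos2": p2}
            for c1, p1, _, c2, p2, _ in evs
        ]
        for lid, evs in private.items()
    }
    return sets, truncal_dicts, private_dicts


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic under fixed seed)."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    factory = _VariantFactory(rng, cfg.oncogenic_fraction)

    patients: list[PatientMeta] = []
    truth_patients: dict[str, PatientTruth] = {}
    variants: dict[str, VariantSpec] = {}
    discovery_calls: list[MutationCall] = []
    validation_calls: list[MutationCall] = []
    undiscovered: set[str] = set()
    assay_failed: set[tuple[str, str]] = set()
    cn_profiles: dict[str, dict[str, CopyNumberProfile]] = {}
    rearrangements: dict[str, dict[str, RearrangementSet]] = {}

    # fixed cohort composition (largest-remainder apportionment of the
    # group proportions), shuffled: the emulated study design enrols a set
    # number of patients per heterogeneity group rather than sampling iid
    quotas = [p * cfg.n_patients for p in cfg.group_proportions]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(3), key=lambda i: (quotas[i] - counts[i]), reverse=True
    )
    for i in remainders[: cfg.n_patients - sum(counts)]:
        counts[i] += 1
    group_sequence = [GROUPS[i] for i in range(3) for _ in range(counts[i])]
    group_sequence = [group_sequence[i] for i in rng.permutation(cfg.n_patients)]

    med = cfg.mutation_count_median
    for pi in range(cfg.n_patients):
        pid = f"SP{pi + 1:03d}"
        group = group_sequence[pi]
        n_lesions = _choice(rng, cfg.lesion_count_probs)
        lesions = []
        for li in range(n_lesions):
            lid = f"{pid}_L{li + 1}"
            n_samples = _choice(rng, cfg.samples_per_lesion_probs)
            lesions.append(
                LesionMeta(lid, [f"{lid}_S{si + 1}" for si in range(n_samples)])
            )
        meta = PatientMeta(pid, lesions, _covariates(rng, group, cfg))
        patients.append(meta)
        purity = {s: float(rng.uniform(*cfg.purity_range)) for s in meta.sample_ids}

        # ---- plant variants -------------------------------------------
        planted: list[tuple[VariantSpec, dict[str, float]]] = []  # (spec, ccf/sample)
        used_hotspots: set[str] = set()

        def add(spec: VariantSpec, ccf_by_sample: dict[str, float]):
            if spec.protein_change and spec.planted_rule in ("R1", "R2"):
                used_hotspots.add(spec.protein_change)
            planted.append((spec, ccf_by_sample))

        all_samples = meta.sample_ids
        if group == "HOMOGENEOUS":
            n = _draw_count(rng, med["HOMOGENEOUS"], cfg.mutation_count_sigma, cfg.mutation_count_max)
            for _ in range(n):
                spec = factory.make(exclude_hotspots=used_hotspots)
                add(spec, {s: 1.0 for s in all_samples})
        elif group == "INTERMEDIATE":
            n_t = _draw_count(rng, med["INTERMEDIATE_TRUNCAL"], cfg.mutation_count_sigma, cfg.mutation_count_max)
            n_p = _draw_count(rng, med["INTERMEDIATE_PRIVATE"], cfg.mutation_count_sigma, cfg.mutation_count_max)
            for _ in range(n_t):
                spec = factory.make(exclude_hotspots=used_hotspots)
                add(spec, {s: 1.0 for s in all_samples})
            for _ in range(n_p):
                les = lesions[rng.integers(len(lesions))]
                spec = factory.make(exclude_hotspots=used_hotspots)
                add(
                    spec,
                    {
                        s: (cfg.private_subclone_ccf if s in les.samples else 0.0)
                        for s in all_samples
                    },
                )
        else:  # HETEROGENEOUS: disjoint per-lesion sets, clonal within lesion
            for les in lesions:
                n_l = _draw_count(rng, med["HETEROGENEOUS_PER_LESION"], cfg.mutation_count_sigma, cfg.mutation_count_max)
                # first variant of each lesion is a guaranteed driver; the
                # rest compensate so the lesion's expected driver fraction
                # stays at the configured target
                rest_p = (
                    max(0.0, (cfg.oncogenic_fraction * n_l - 1) / (n_l - 1))
                    if n_l > 1
                    else 0.0
                )
                for vi in range(n_l):
                    spec = factory.make(
                        force_driver=(vi == 0),
                        exclude_hotspots=used_hotspots,
                        driver_prob=rest_p,
                    )
                    add(
                        spec,
                        {s: (1.0 if s in les.samples else 0.0) for s in all_samples},
                    )

        # ---- read sampling --------------------------------------------
        truncal_keys: list[str] = []
        private_by_lesion: dict[str, list[str]] = {l.lesion_id: [] for l in lesions}
        ccf_record: dict[tuple[str, str], float] = {}
        for spec, ccf_by_sample in planted:
            kstr = str(spec.key)
            variants.setdefault(kstr, spec)
            detected_any = False
            disc_af: dict[str, tuple[float, int]] = {}
            for s in all_samples:
                ccf = ccf_by_sample[s]
                ccf_record[(kstr, s)] = ccf
                if ccf <= 0:
                    continue
                p = purity[s] * ccf / 2.0
                af, depth = _sample_af(rng, p, cfg.depth_discovery, cfg)
                alt_reads = af * depth
                if af >= cfg.discovery_min_af and alt_reads >= cfg.discovery_min_alt_reads:
                    disc_af[s] = (af, depth)
                    detected_any = True
            if not detected_any:
                undiscovered.add(kstr)
                continue
            if all(c > 0 for c in ccf_by_sample.values()):
                truncal_keys.append(kstr)
            else:
                for les in lesions:
                    if any(ccf_by_sample[s] > 0 for s in les.samples):
                        private_by_lesion[les.lesion_id].append(kstr)
            for s, (af, depth) in disc_af.items():
                discovery_calls.append(
                    MutationCall(
                        pid, s, spec.gene_symbol, spec.key.chrom, spec.key.pos,
                        spec.key.ref_allele, spec.key.alt_allele,
                        spec.variant_class, spec.protein_change,
                        af_discovery=af, depth_discovery=depth,
                    )
                )
            # validation re-assays the variant in every sample of the patient
            for s in all_samples:
                failed = rng.random() < cfg.assay_failure_rate
                if failed:
                    assay_failed.add((kstr, s))
                    validation_calls.append(
                        MutationCall(
                            pid, s, spec.gene_symbol, spec.key.chrom, spec.key.pos,
                            spec.key.ref_allele, spec.key.alt_allele,
                            spec.variant_class, spec.protein_change,
                            af_validation=None, depth_validation=None,
                            assay_ok_validation=False,
                        )
                    )
                    continue
                p = purity[s] * ccf_by_sample[s] / 2.0
                af, depth = _sample_af(rng, p, cfg.depth_validation, cfg)
                validation_calls.append(
                    MutationCall(
                        pid, s, spec.gene_symbol, spec.key.chrom, spec.key.pos,
                        spec.key.ref_allele, spec.key.alt_allele,
                        spec.variant_class, spec.protein_change,
                        af_validation=af, depth_validation=depth,
                    )
                )

        # ---- structural layer -----------------------------------------
        lesion_ids = [l.lesion_id for l in lesions]
        profiles, cn_truncal, cn_private = _make_cn_profiles(rng, group, lesion_ids, cfg)
        rrsets, rr_truncal, rr_private = _make_rearrangements(rng, group, lesion_ids, cfg)
        cn_profiles[pid] = profiles
        rearrangements[pid] = rrsets

        truth_patients[pid] = PatientTruth(
            patient_id=pid,
            group=group,
            truncal_variants=truncal_keys,
            private_variants=private_by_lesion,
            ccf=ccf_record,
            purity=purity,
            cn_truncal_events=cn_truncal,
            cn_private_events=cn_private,
            rr_truncal=rr_truncal,
            rr_private=rr_private,
        )

    hierarchy = CohortHierarchy(patients=patients)
    rec_rows = [
        {"gene_symbol": h[0], "protein_change": h[6], "cosmic_confirmed_samples": h[7]}
        for h in HOTSPOT_CATALOGUE
    ] + factory.extra_recurrence_rows
    recurrence = RecurrenceTable(pd.DataFrame(rec_rows).drop_duplicates(
        ["gene_symbol", "protein_change"]
    ))
    roles = GeneRoleTable(pd.DataFrame(GENE_ROLES, columns=["gene_symbol", "role"]))
    truth = CohortTruth(
        patients=truth_patients,
        variants=variants,
        undiscovered=undiscovered,
        assay_failed=assay_failed,
    )
    return SyntheticCohort(
        config=cfg,
        hierarchy=hierarchy,
        discovery_calls=discovery_calls,
        validation_calls=validation_calls,
        recurrence=recurrence,
        roles=roles,
        cn_profiles=cn_profiles,
        rearrangements=rearrangements,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# truth vs pipeline


def truth_vs_pipeline_report(
    truth: CohortTruth,
    status_table: pd.DataFrame | None = None,
    onco_calls: dict | None = None,
    het_results: list | None = None,
) -> dict:
    """Per-stage recovery metrics of the pipeline against planted truth.

    Returns confusion-style summaries: confirmation sensitivity/specificity
    over assays with a readout (true presence = planted CCF > 0),
    oncogenicity category and rule accuracy over discovered variants, and
    the patient-group confusion matrix and accuracy.
    """
    report: dict = {}
    if status_table is not None and len(status_table):
        bad = set(status_table["patient_id"]) - set(truth.patients)
        if bad:
            raise ValueError(f"status table references unknown patients: {sorted(bad)}")
        tp = fp = tn = fn = 0
        for row in status_table.itertuples(index=False):
            if row.status == "ASSAY_FAILED":
                continue
            pt = truth.patients[row.patient_id]
            actual = pt.ccf.get((row.variant, row.sample_id), 0.0) > 0
            predicted = row.status in ("CONFIRMED", "PRESENT")
            if actual and predicted:
                tp += 1
            elif actual:
                fn += 1
            elif predicted:
                fp += 1
            else:
                tn += 1
        report["confirmation"] = {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "n_true_present": tp + fn,
            "n_true_absent": tn + fp,
        }
    if onco_calls is not None:
        n = cat_ok = rule_ok = 0
        for kstr, call in onco_calls.items():
            spec = truth.variants.get(str(kstr))
            if spec is None:
                continue
            n += 1
            cat_ok += call.category == spec.planted_category
            rule_ok += (call.triggering_rule or None) == spec.planted_rule
        report["oncogenicity"] = {
            "category_accuracy": cat_ok / n if n else float("nan"),
            "rule_accuracy": rule_ok / n if n else float("nan"),
            "n_variants": n,
        }
    if het_results is not None:
        confusion = {g: {h: 0 for h in GROUPS} for g in GROUPS}
        n = ok = 0
        for r in het_results:
            pt = truth.patients.get(r.patient_id)
            if pt is None:
                raise ValueError(f"result for unknown patient {r.patient_id}")
            confusion[pt.group][r.group] += 1
            n += 1
            ok += pt.group == r.group
        report["grouping"] = {
            "accuracy": ok / n if n else float("nan"),
            "confusion": confusion,
            "n_patients": n,
        }
    return report
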