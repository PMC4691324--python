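"""Data model and I/O for multi-lesion somatic variant cohorts.

A multifocal cohort is organised as patients → lesions → samples: each
patient contributes two or more anatomically distinct invasive lesions, and
each lesion one or more geographically distinct sequenced samples.  Somatic
variant calls carry per-sample allele fractions and depths from up to two
sequencing platforms (a discovery screen and a deeper orthogonal validation
assay).  This module defines the domain types, reads/writes the on-disk
formats (variant TSV/VCF, YAML hierarchy, recurrence and gene-role TSVs),
and indexes calls into per-patient unique variants.

Conventions
-----------
* Coordinates are 1-based inclusive (VCF convention).
* Variant identity is the genomic key ``(chrom, pos, ref, alt)`` after
  left-trim normalisation of indel alleles; protein change is annotation
  only, so e.g. two different TP53 substitutions in one patient remain two
  distinct variants.
* Silent (synonymous) variants are parsed and retained on read but excluded
  from all downstream analysis stages, which operate on non-silent coding
  mutations only.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "VariantKey",
    "MutationCall",
    "LesionMeta",
    "PatientMeta",
    "CohortHierarchy",
    "PipelineConfig",
    "RecurrenceTable",
    "GeneRoleTable",
    "FormatError",
    "IntegrityError",
    "VARIANT_CLASSES",
    "NON_SILENT_CLASSES",
    "normalize_alleles",
    "read_variant_table",
    "write_variant_table",
    "read_hierarchy",
    "write_hierarchy",
    "read_recurrence_table",
    "read_gene_role_table",
    "unique_variants",
]

VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_ins",
        "frameshift_del",
        "inframe_ins",
        "inframe_del",
        "splice",
        "silent",
    }
)
#: classes entering downstream analysis ("non-silent coding")
NON_SILENT_CLASSES = VARIANT_CLASSES - {"silent"}

#: variant classes counted as indels (vs substitutions) in cohort tallies
INDEL_CLASSES = frozenset(
    {"frameshift_ins", "frameshift_del", "inframe_ins", "inframe_del"}
)


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


class IntegrityError(ValueError):
    """Inputs violate a structural invariant of the cohort model."""


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalise an allele pair by trimming shared context.

    Trims the common suffix, then the common prefix (always keeping at
    least one base on each allele), advancing ``pos`` for each prefix base
    removed.  This gives a deterministic genomic identity for indels called
    with different amounts of padding context by different pipelines.
    """
    ref, alt = ref.upper(), alt.upper()
    # suffix trim
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # prefix trim
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of a variant: (chrom, pos, ref, alt), left-normalised."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise IntegrityError(
                f"ref and alt alleles identical at {self.chrom}:{self.pos}"
            )

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        pos, ref, alt = normalize_alleles(int(pos), ref, alt)
        return cls(str(chrom), pos, ref, alt)

    def __str__(self) -> str:  # used in report/TSV output
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, alleles = text.split(":")
        ref, alt = alleles.split(">")
        return cls(chrom, int(pos), ref, alt)


@dataclass
class MutationCall:
    """One somatic variant observed (or assayed) in one sample.

    ``af_discovery``/``depth_discovery`` come from the discovery screen,
    ``af_validation``/``depth_validation`` from the deep orthogonal
    resequencing; either pair may be missing (``None``).
    ``assay_ok_validation=False`` marks assays that failed by design or
    through exhausted DNA, for which no validation claim can be made.
    """

    patient_id: str
    sample_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    protein_change: str | None = None
    af_discovery: float | None = None
    depth_discovery: int | None = None
    af_validation: float | None = None
    depth_validation: int | None = None
    assay_ok_validation: bool = True

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise FormatError(
                f"unknown variant_class {self.variant_class!r} "
                f"(expected one of {sorted(VARIANT_CLASSES)})"
            )
        if self.ref_allele == self.alt_allele:
            raise IntegrityError(
                f"ref==alt for {self.gene_symbol} at {self.chrom}:{self.pos}"
            )
        for af, depth, tag in (
            (self.af_discovery, self.depth_discovery, "discovery"),
            (self.af_validation, self.depth_validation, "validation"),
        ):
            if af is not None:
                if not 0.0 <= af <= 1.0:
                    raise ValueError(f"AF {tag} {af} outside [0,1]")
                if depth is None:
                    raise IntegrityError(f"AF {tag} present but depth missing")

    @property
    def key(self) -> VariantKey:
        return VariantKey.normalized(
            self.chrom, self.pos, self.ref_allele, self.alt_allele
        )

    @property
    def is_silent(self) -> bool:
        return self.variant_class == "silent"

    @property
    def is_indel(self) -> bool:
        return self.variant_class in INDEL_CLASSES

    @property
    def detected_discovery(self) -> bool:
        """Detected on the discovery platform: any reported call counts."""
        return self.af_discovery is not None and self.af_discovery > 0


@dataclass
class LesionMeta:
    lesion_id: str
    samples: list[str]


@dataclass
class PatientMeta:
    patient_id: str
    lesions: list[LesionMeta]
    covariates: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [s for les in self.lesions for s in les.samples]

    def lesion_of(self, sample_id: str) -> str:
        for les in self.lesions:
            if sample_id in les.samples:
                return les.lesion_id
        raise KeyError(sample_id)


#: covariates treated as continuous in association tests
CONTINUOUS_COVARIATES = (
    "tumour_size_cm",
    "n_positive_nodes",
    "max_inter_lesion_distance_cm",
)
#: covariates treated as categorical in association tests
CATEGORICAL_COVARIATES = (
    "age_group",
    "grade",
    "subtype",
    "dcis_present",
    "lvi_present",
)


@dataclass
class CohortHierarchy:
    """patients → lesions → samples, with clinico-pathological covariates."""

    patients: list[PatientMeta]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_p: set[str] = set()
        seen_s: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen_p:
                raise IntegrityError(f"duplicate patient_id {p.patient_id!r}")
            seen_p.add(p.patient_id)
            if len(p.lesions) < 2:
                raise IntegrityError(
                    f"patient {p.patient_id!r} has {len(p.lesions)} lesion(s); "
                    "multifocality requires >= 2"
                )
            for les in p.lesions:
                if not les.samples:
                    raise IntegrityError(
                        f"lesion {les.lesion_id!r} of {p.patient_id!r} has no samples"
                    )
                for s in les.samples:
                    if s in seen_s:
                        raise IntegrityError(f"duplicate sample_id {s!r}")
                    seen_s.add(s)

    def patient(self, patient_id: str) -> PatientMeta:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s for p in self.patients for s in p.sample_ids]

    def sample_to_patient(self) -> dict[str, str]:
        return {s: p.patient_id for p in self.patients for s in p.sample_ids}

    def sample_to_lesion(self) -> dict[str, str]:
        return {
            s: les.lesion_id
            for p in self.patients
            for les in p.lesions
            for s in les.samples
        }

    def check_samples_resolve(self, calls: Iterable[MutationCall]) -> None:
        """Every call's sample must exist; hierarchy samples with no calls
        are allowed (assayed-with-no-calls) and reported as a warning."""
        known = set(self.sample_ids)
        called = set()
        for c in calls:
            if c.sample_id not in known:
                raise IntegrityError(
                    f"call references unknown sample {c.sample_id!r}"
                )
            called.add(c.sample_id)
        silent = known - called
        if silent:
            warnings.warn(
                f"{len(silent)} hierarchy sample(s) have no variant calls; "
                "treated as assayed with no somatic calls",
                stacklevel=2,
            )


@dataclass
class PipelineConfig:
    """Thresholds and tolerances shared across analysis stages.

    Defaults encode the published analysis rules: confirmation at allele
    fraction >= 5% with a 1–5% rescue when a sibling sample of the same
    patient carries the variant at >= 5%; COSMIC recurrence at >= 2
    confirmed samples; hotspot proximity within +/- 3 amino acids; clusters
    of more than two substitutions within three residues; two-tailed tests
    at alpha 0.05.
    """

    af_confirm_min: float = 0.05
    af_rescue_min: float = 0.01
    cosmic_recurrent_min: int = 2
    hotspot_window_aa: int = 3
    cluster_min_mutations: int = 3
    alpha: float = 0.05
    rearrangement_bp_tolerance: int = 500
    scna_reciprocal_overlap_min: float = 0.5
    rng_seed: int = 0
    # presence-matrix options (see heterogeneity module)
    common_requires_every_sample: bool = False
    assay_failed_uses_discovery: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.af_rescue_min <= self.af_confirm_min <= 1:
            raise ValueError("require 0 < af_rescue_min <= af_confirm_min <= 1")
        if not 0 < self.scna_reciprocal_overlap_min <= 1:
            raise ValueError("scna_reciprocal_overlap_min must be in (0,1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.rearrangement_bp_tolerance < 0:
            raise ValueError("rearrangement_bp_tolerance must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


class RecurrenceTable:
    """COSMIC-style recurrence snapshot: confirmed-sample counts per
    (gene, protein change).  Optionally carries a per-row cluster flag
    column marking protein positions inside catalogued mutation clusters.
    """

    def __init__(self, rows: Iterable[Mapping] | pd.DataFrame):
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(
                columns=["gene_symbol", "protein_change", "cosmic_confirmed_samples"]
            )
        required = {"gene_symbol", "protein_change", "cosmic_confirmed_samples"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"recurrence table missing column(s): {sorted(missing)}")
        if df.duplicated(["gene_symbol", "protein_change"]).any():
            raise IntegrityError("duplicate (gene_symbol, protein_change) rows")
        df["cosmic_confirmed_samples"] = df["cosmic_confirmed_samples"].astype(int)
        if (df["cosmic_confirmed_samples"] < 0).any():
            raise ValueError("cosmic_confirmed_samples must be non-negative")
        self.df = df.reset_index(drop=True)
        self._count = {
            (g, pc): int(n)
            for g, pc, n in zip(
                df["gene_symbol"], df["protein_change"], df["cosmic_confirmed_samples"]
            )
        }
        self.has_cluster_column = "in_cosmic_cluster" in df.columns

    def count(self, gene_symbol: str, protein_change: str | None) -> int:
        if protein_change is None:
            return 0
        return self._count.get((gene_symbol, protein_change), 0)

    def in_cluster(self, gene_symbol: str, protein_change: str | None) -> bool:
        if not self.has_cluster_column or protein_change is None:
            return False
        sel = self.df[
            (self.df["gene_symbol"] == gene_symbol)
            & (self.df["protein_change"] == protein_change)
        ]
        return bool(len(sel)) and bool(sel["in_cosmic_cluster"].iloc[0])

    def positions_with_min_count(self, gene_symbol: str, min_count: int):
        """Residue positions in a gene whose recurrence count >= min_count."""
        from .oncogenicity import parse_protein_change  # local import, no cycle

        out = []
        sub = self.df[self.df["gene_symbol"] == gene_symbol]
        for pc, n in zip(sub["protein_change"], sub["cosmic_confirmed_samples"]):
            if n >= min_count:
                parsed = parse_protein_change(pc)
                if parsed is not None:
                    out.append(parsed[0])
        return sorted(set(out))


class GeneRoleTable:
    """gene → role (oncogene / tumour_suppressor / other_cancer_gene /
    not_cancer_gene); genes absent from the table default to
    ``not_cancer_gene``."""

    ROLES = ("oncogene", "tumour_suppressor", "other_cancer_gene", "not_cancer_gene")

    def __init__(self, rows: Iterable[Mapping] | pd.DataFrame):
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(columns=["gene_symbol", "role"])
        missing = {"gene_symbol", "role"} - set(df.columns)
        if missing:
            raise FormatError(f"gene-role table missing column(s): {sorted(missing)}")
        if df.duplicated("gene_symbol").any():
            raise IntegrityError("duplicate gene_symbol rows in gene-role table")
        bad = set(df["role"]) - set(self.ROLES)
        if bad:
            raise FormatError(f"unknown role(s): {sorted(bad)}")
        self.df = df.reset_index(drop=True)
        self._role = dict(zip(df["gene_symbol"], df["role"]))

    def role(self, gene_symbol: str) -> str:
        return self._role.get(gene_symbol, "not_cancer_gene")


# ---------------------------------------------------------------------------
# variant table I/O

_TSV_COLUMNS = [
    "patient_id",
    "sample_id",
    "gene_symbol",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "variant_class",
    "protein_change",
    "af",
    "depth",
    "assay_ok",
]

_MANDATORY_TSV = [
    "patient_id",
    "sample_id",
    "gene_symbol",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "variant_class",
    "af",
    "depth",
]


def _parse_optional_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "" or v == ".":
        return None
    return float(v)


def _parse_optional_int(v) -> int | None:
    f = _parse_optional_float(v)
    return None if f is None else int(f)


def read_variant_table(path: str | Path, platform_tag: str) -> list[MutationCall]:
    """Read per-sample somatic calls from a TSV (or VCF) into MutationCalls.

    ``platform_tag`` selects which AF/depth slot the file populates:
    ``"discovery"`` or ``"validation"``.  TSV layout: tab-separated with a
    header naming at least ``patient_id sample_id gene_symbol chrom pos
    ref_allele alt_allele variant_class af depth`` (plus optional
    ``protein_change`` and ``assay_ok``).  Files ending ``.vcf``/``.vcf.gz``
    are parsed as VCF 4.2 with per-sample AD/DP.
    """
    if platform_tag not in ("discovery", "validation"):
        raise ValueError(f"platform_tag must be discovery|validation, got {platform_tag!r}")
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, platform_tag)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file with no header") from exc
    missing = [c for c in _MANDATORY_TSV if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {missing}")
    calls: list[MutationCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = dict(zip(df.columns, row))
        try:
            af = _parse_optional_float(rec["af"])
            depth = _parse_optional_int(rec["depth"])
            kwargs: dict = dict(
                patient_id=rec["patient_id"],
                sample_id=rec["sample_id"],
                gene_symbol=rec["gene_symbol"],
                chrom=str(rec["chrom"]),
                pos=int(rec["pos"]),
                ref_allele=rec["ref_allele"],
                alt_allele=rec["alt_allele"],
                variant_class=rec["variant_class"],
                protein_change=(rec.get("protein_change") or None),
            )
            if platform_tag == "discovery":
                kwargs.update(af_discovery=af, depth_discovery=depth)
            else:
                kwargs.update(
                    af_validation=af,
                    depth_validation=depth,
                    assay_ok_validation=_parse_bool(rec.get("assay_ok", "true")),
                )
            calls.append(MutationCall(**kwargs))
        except (ValueError, KeyError) as exc:
            raise type(exc if isinstance(exc, ValueError) else ValueError(exc))(
                f"{path} line {i}: {exc}"
            ) from exc
    return calls


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "yes", "t")


def _read_vcf(path: Path, platform_tag: str) -> list[MutationCall]:
    """VCF 4.2 reader: per-sample AD/DP (AF computed as alt/DP when no AF
    FORMAT field).  Gene / class / protein annotations are taken from INFO
    keys GENE, VC, PCHANGE; patient from INFO key PATIENT (the hierarchy can
    re-attach patients when absent)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    calls: list[MutationCall] = []
    for var in vcf:
        gene = var.INFO.get("GENE", "")
        vclass = var.INFO.get("VC", "missense")
        pchange = var.INFO.get("PCHANGE")
        patient = var.INFO.get("PATIENT", "")
        alt = var.ALT[0]
        depths = var.format("DP")
        ads = var.format("AD")
        for si, sample in enumerate(samples):
            dp = int(depths[si][0]) if depths is not None else None
            if dp is None or dp < 0:
                continue
            ad_alt = int(ads[si][-1]) if ads is not None else None
            if ad_alt is None or ad_alt < 0:
                continue
            af = ad_alt / dp if dp > 0 else 0.0
            kwargs: dict = dict(
                patient_id=patient,
                sample_id=sample,
                gene_symbol=gene,
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref_allele=var.REF,
                alt_allele=alt,
                variant_class=vclass,
                protein_change=pchange,
            )
            if platform_tag == "discovery":
                kwargs.update(af_discovery=af, depth_discovery=dp)
            else:
                kwargs.update(af_validation=af, depth_validation=dp)
            calls.append(MutationCall(**kwargs))
    return calls


def write_variant_table(
    calls: Iterable[MutationCall], path: str | Path, platform_tag: str
) -> None:
    """Write calls back to the documented TSV layout (lossless round-trip)."""
    rows = []
    for c in calls:
        af = c.af_discovery if platform_tag == "discovery" else c.af_validation
        depth = c.depth_discovery if platform_tag == "discovery" else c.depth_validation
        rows.append(
            {
                "patient_id": c.patient_id,
                "sample_id": c.sample_id,
                "gene_symbol": c.gene_symbol,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref_allele": c.ref_allele,
                "alt_allele": c.alt_allele,
                "variant_class": c.variant_class,
                "protein_change": c.protein_change or "",
                "af": "" if af is None else repr(float(af)),
                "depth": "" if depth is None else depth,
                "assay_ok": str(c.assay_ok_validation).lower(),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hierarchy I/O

def read_hierarchy(path: str | Path) -> CohortHierarchy:
    """Read the YAML hierarchy/covariate file.

    Schema::

        patients:
          - patient_id: P1
            covariates: {grade: G2, subtype: "ER+/HER2-", ...}
            lesions:
              - lesion_id: L1
                samples: [P1_L1_S1, P1_L1_S2]
              - lesion_id: L2
                samples: [P1_L2_S1]
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "patients" not in data:
        raise FormatError(f"{path}: expected a top-level 'patients' list")
    patients = []
    for p in data["patients"]:
        lesions = [
            LesionMeta(lesion_id=str(l["lesion_id"]), samples=[str(s) for s in l["samples"]])
            for l in p.get("lesions", [])
        ]
        patients.append(
            PatientMeta(
                patient_id=str(p["patient_id"]),
                lesions=lesions,
                covariates=dict(p.get("covariates", {})),
            )
        )
    return CohortHierarchy(patients=patients)


def write_hierarchy(hierarchy: CohortHierarchy, path: str | Path) -> None:
    data = {
        "patients": [
            {
                "patient_id": p.patient_id,
                "covariates": dict(p.covariates),
                "lesions": [
                    {"lesion_id": l.lesion_id, "samples": list(l.samples)}
                    for l in p.lesions
                ],
            }
            for p in hierarchy.patients
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_recurrence_table(path: str | Path) -> RecurrenceTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "protein_change": str})
    return RecurrenceTable(df)


def read_gene_role_table(path: str | Path) -> GeneRoleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GeneRoleTable(df)


# ---------------------------------------------------------------------------
# unique-variant index

def unique_variants(
    calls: Iterable[MutationCall],
) -> dict[str, dict[VariantKey, list[MutationCall]]]:
    """Group non-silent calls by genomic variant key within each patient.

    Returns ``{patient_id: {VariantKey: [MutationCall, ...]}}``.  Silent
    variants are excluded.  The same key seen in two patients yields two
    independent per-patient entries (cohort-level recurrence is derived from
    the outer mapping).  A key carrying conflicting gene symbols raises an
    :class:`IntegrityError`.
    """
    index: dict[str, dict[VariantKey, list[MutationCall]]] = {}
    gene_of: dict[VariantKey, str] = {}
    for call in calls:
        if call.is_silent:
            continue
        key = call.key
        known = gene_of.setdefault(key, call.gene_symbol)
        if known != call.gene_symbol:
            raise IntegrityError(
                f"variant {key} annotated with conflicting genes "
                f"{known!r} vs {call.gene_symbol!r}"
            )
        index.setdefault(call.patient_id, {}).setdefault(key, []).append(call)
    return index


def cohort_recurrence_counts(
    index: Mapping[str, Mapping[VariantKey, list]],
) -> dict[VariantKey, int]:
    """Number of distinct patients carrying each variant key."""
    counts: dict[VariantKey, int] = {}
    for _, variants in index.items():
        for key in variants:
            counts[key] = counts.get(key, 0) + 1
    return counts
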