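"""Rule-based oncogenicity classification of somatic variants.

Each unique non-silent variant is assigned one of four tiers by a fixed
cascade of eight rules, evaluated in tier order (first firing tier wins;
within a tier the lowest-numbered rule is recorded):

ONCOGENIC
    R1  non-synonymous substitution or in-frame indel in a canonical
        oncogene at a recurrent hotspot (an exact protein change with
        catalogue recurrence >= 2 in that oncogene);
    R2  non-synonymous substitution recurrent in >= 2 confirmed samples in
        the COSMIC-style catalogue;
    R3  variant recurrent in >= 2 patients of the analysed cohort itself;
    R4  nonsense or frameshifting insertion/deletion in a known tumour
        suppressor.
PUTATIVE
    R5  previously unreported non-synonymous substitution in a known
        cancer gene within +/-3 amino acids of a catalogue mutation
        recurrent in >= 2 samples;
    R6  member of a cohort mutation cluster: more than two non-synonymous
        substitutions within three amino acids of each other.
POSSIBLE
    R7  non-synonymous substitution confirmed somatic in exactly one
        catalogue sample;
    R8  close to a catalogued mutation cluster (requires a cluster flag
        column in the recurrence table; inert without it).
UNKNOWN
    everything else.

In the collapsed binary sense used for cohort summaries, "oncogenic" means
any tier other than UNKNOWN.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cohort_model import (
    GeneRoleTable,
    MutationCall,
    PipelineConfig,
    RecurrenceTable,
    VariantKey,
    cohort_recurrence_counts,
)

__all__ = [
    "Category",
    "OncogenicityCall",
    "parse_protein_change",
    "classify_variant",
    "classify_cohort",
    "cohort_substitution_positions",
]

#: category order, strongest first
CATEGORY_ORDER = ("ONCOGENIC", "PUTATIVE", "POSSIBLE", "UNKNOWN")
Category = str

#: protein-level substitution classes (non-synonymous substitutions)
_SUBSTITUTION_CLASSES = frozenset({"missense", "nonsense"})
#: truncating classes for the tumour-suppressor rule
_TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift_ins", "frameshift_del"})
_INFRAME_CLASSES = frozenset({"inframe_ins", "inframe_del"})

_PCHANGE_RE = re.compile(r"^(?:p\.)?([A-Za-z*]+?)(\d+)(.*)$")


def parse_protein_change(protein_change: str | None):
    """Parse e.g. ``"R196*"`` / ``"p.E545K"`` / ``"T1738fs"`` to
    ``(residue_position, ref_aa, alt_part)``; ``None`` if unparseable."""
    if not protein_change:
        return None
    m = _PCHANGE_RE.match(protein_change.strip())
    if not m:
        return None
    return int(m.group(2)), m.group(1), m.group(3)


@dataclass
class OncogenicityCall:
    variant: VariantKey
    gene_symbol: str
    protein_change: str | None
    category: Category
    triggering_rule: str | None  # "R1".."R8" or None for UNKNOWN
    evidence: dict = field(default_factory=dict)

    @property
    def collapsed_oncogenic(self) -> bool:
        """The collapsed binary flag: any tier above UNKNOWN."""
        return self.category != "UNKNOWN"


def _in_cohort_cluster(
    residue: int, positions: Sequence[int], min_mutations: int, window_aa: int
) -> int:
    """Largest count of distinct cohort substitution positions inside a
    window of span ``window_aa`` residues containing ``residue``; 0 when no
    qualifying window reaches ``min_mutations``."""
    pos_set = sorted(set(positions))
    best = 0
    for start in range(residue - window_aa, residue + 1):
        count = sum(1 for p in pos_set if start <= p <= start + window_aa)
        if count > best:
            best = count
    return best if best >= min_mutations else 0


def classify_variant(
    variant: VariantKey,
    variant_class: str,
    protein_change: str | None,
    gene_symbol: str,
    gene_role: str,
    recurrence: RecurrenceTable,
    dataset_recurrence_count: int,
    cohort_protein_positions: Sequence[int],
    config: PipelineConfig,
) -> OncogenicityCall:
    """Run the rule cascade for one unique variant.

    ``dataset_recurrence_count`` is the number of distinct *patients* in the
    analysed cohort carrying this variant key; ``cohort_protein_positions``
    the distinct residue positions of non-synonymous substitutions observed
    in this gene across the cohort (for the cluster rule).
    """
    parsed = parse_protein_change(protein_change)
    residue = parsed[0] if parsed else None
    is_substitution = variant_class in _SUBSTITUTION_CLASSES
    cosmic_count = recurrence.count(gene_symbol, protein_change)
    hotspots = recurrence.positions_with_min_count(
        gene_symbol, config.cosmic_recurrent_min
    )
    evidence: dict = {
        "cosmic_count": cosmic_count,
        "dataset_recurrence": dataset_recurrence_count,
        "role": gene_role,
        "cluster_size": 0,
        "distance_to_hotspot_aa": None,
    }
    if residue is not None and hotspots:
        evidence["distance_to_hotspot_aa"] = min(abs(residue - h) for h in hotspots)

    def result(category: Category, rule: str | None) -> OncogenicityCall:
        return OncogenicityCall(
            variant, gene_symbol, protein_change, category, rule, evidence
        )

    recurrent_in_cosmic = cosmic_count >= config.cosmic_recurrent_min

    # --- ONCOGENIC tier -------------------------------------------------
    # R1: oncogene hotspot (exact recurrent protein change, substitutions
    # and in-frame indels alike)
    if (
        gene_role == "oncogene"
        and (is_substitution or variant_class in _INFRAME_CLASSES)
        and recurrent_in_cosmic
    ):
        return result("ONCOGENIC", "R1")
    # R2: catalogue-recurrent non-synonymous substitution
    if is_substitution and recurrent_in_cosmic:
        return result("ONCOGENIC", "R2")
    # R3: recurrent in the analysed cohort itself
    if dataset_recurrence_count >= 2:
        return result("ONCOGENIC", "R3")
    # R4: truncating in a tumour suppressor (evaluable without protein pos)
    if gene_role == "tumour_suppressor" and variant_class in _TRUNCATING_CLASSES:
        return result("ONCOGENIC", "R4")

    # --- PUTATIVE tier --------------------------------------------------
    # R5: unreported substitution near a catalogue hotspot, cancer gene
    if (
        is_substitution
        and cosmic_count == 0
        and gene_role != "not_cancer_gene"
        and residue is not None
        and any(abs(residue - h) <= config.hotspot_window_aa for h in hotspots)
    ):
        return result("PUTATIVE", "R5")
    # R6: cohort mutation cluster
    if is_substitution and residue is not None:
        size = _in_cohort_cluster(
            residue,
            cohort_protein_positions,
            config.cluster_min_mutations,
            config.hotspot_window_aa,
        )
        if size:
            evidence["cluster_size"] = size
            return result("PUTATIVE", "R6")

    # --- POSSIBLE tier --------------------------------------------------
    # R7: confirmed somatic in exactly one catalogue sample
    if is_substitution and cosmic_count == 1:
        return result("POSSIBLE", "R7")
    # R8: close to a catalogued mutation cluster (inert without the flag)
    if recurrence.has_cluster_column and residue is not None:
        flagged = [
            parse_protein_change(pc)[0]
            for pc, fl in zip(
                recurrence.df[recurrence.df["gene_symbol"] == gene_symbol][
                    "protein_change"
                ],
                recurrence.df[recurrence.df["gene_symbol"] == gene_symbol][
                    "in_cosmic_cluster"
                ],
            )
            if fl and parse_protein_change(pc) is not None
        ]
        if any(abs(residue - p) <= config.hotspot_window_aa for p in flagged):
            return result("POSSIBLE", "R8")

    return result("UNKNOWN", None)


def cohort_substitution_positions(
    index: Mapping[str, Mapping[VariantKey, Sequence[MutationCall]]],
) -> dict[str, list[int]]:
    """Distinct residue positions of non-synonymous substitutions per gene,
    pooled across the cohort (distinct residues, not distinct variants)."""
    positions: dict[str, set[int]] = {}
    for variants in index.values():
        for calls in variants.values():
            call = calls[0]
            if call.variant_class not in _SUBSTITUTION_CLASSES:
                continue
            parsed = parse_protein_change(call.protein_change)
            if parsed is None:
                continue
            positions.setdefault(call.gene_symbol, set()).add(parsed[0])
    return {g: sorted(s) for g, s in positions.items()}


def classify_cohort(
    index: Mapping[str, Mapping[VariantKey, Sequence[MutationCall]]],
    recurrence: RecurrenceTable,
    roles: GeneRoleTable,
    config: PipelineConfig,
) -> tuple[dict[VariantKey, OncogenicityCall], dict]:
    """Classify every distinct variant of the cohort.

    The same genomic variant observed in several patients receives a single
    cohort-level call (dataset recurrence counts distinct patients, so it
    fires the cohort-recurrence rule for all carriers at once).  Returns the
    per-key calls and a summary with the collapsed oncogenic fraction over
    unique cohort variants.
    """
    dataset_counts = cohort_recurrence_counts(index)
    positions = cohort_substitution_positions(index)
    calls_by_key: dict[VariantKey, OncogenicityCall] = {}
    for variants in index.values():
        for key, calls in variants.items():
            if key in calls_by_key:
                continue
            rep = calls[0]
            calls_by_key[key] = classify_variant(
                key,
                rep.variant_class,
                rep.protein_change,
                rep.gene_symbol,
                roles.role(rep.gene_symbol),
                recurrence,
                dataset_counts[key],
                positions.get(rep.gene_symbol, []),
                config,
            )
    # tallies are over per-patient unique variants (a hotspot recurring in
    # k patients contributes k), matching how such cohorts are counted
    n_unique = sum(len(variants) for variants in index.values())
    n_onco = sum(
        1
        for variants in index.values()
        for key in variants
        if calls_by_key[key].collapsed_oncogenic
    )
    summary = {
        "n_unique_variants": n_unique,
        "n_distinct_keys": len(calls_by_key),
        "n_oncogenic_tiered": n_onco,
        "fraction_oncogenic": (n_onco / n_unique) if n_unique else float("nan"),
    }
    return calls_by_key, summary
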