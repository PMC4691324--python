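"""Private/common comparison of rearrangements and copy-number profiles.

Operates on already-segmented absolute copy-number profiles (BED-like TSV,
integer total copy number per segment) and validated rearrangement
breakpoint lists (BEDPE) for two or more lesions of a patient:

* rearrangements are matched across lesions by class, chromosome pair,
  strand orientations and breakpoint proximity (default tolerance 500 bp);
  an event matched in every lesion of the patient is *common*, otherwise
  *private*;
* copy-number aberrations (copy number differing from the rounded lesion
  ploidy, direction-aware) are common when every lesion carries an
  overlapping same-direction aberration with sufficient reciprocal
  overlap;
* the inter-lesion distance is the minimum-event distance: the smallest
  number of +/-1 copy events on contiguous segment runs transforming one
  profile into the other, with total-copy-number profiles and no
  resurrection of segments at copy 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_model import IntegrityError

__all__ = [
    "RearrangementEvent",
    "RearrangementSet",
    "CopyNumberProfile",
    "read_bedpe",
    "read_cn_bed",
    "classify_rearrangement",
    "match_rearrangements",
    "compare_scna",
    "min_event_distance",
]

RR_CLASSES = (
    "deletion-type",
    "tandem-duplication-type",
    "inversion-type",
    "inter-chromosomal",
)


def classify_rearrangement(
    chrom1: str, strand1: str, chrom2: str, strand2: str
) -> str:
    """Orientation-based class: (+,-) deletion-type, (-,+) tandem
    duplication, (+,+)/(-,-) inversion-type, different chromosomes
    inter-chromosomal."""
    if chrom1 != chrom2:
        return "inter-chromosomal"
    if strand1 == "+" and strand2 == "-":
        return "deletion-type"
    if strand1 == "-" and strand2 == "+":
        return "tandem-duplication-type"
    return "inversion-type"


@dataclass(frozen=True)
class RearrangementEvent:
    lesion_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    rr_class: str

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("breakpoint positions must be non-negative")
        if self.rr_class not in RR_CLASSES:
            raise ValueError(f"unknown rearrangement class {self.rr_class!r}")
        expected = classify_rearrangement(
            self.chrom1, self.strand1, self.chrom2, self.strand2
        )
        if expected != self.rr_class:
            raise IntegrityError(
                f"class {self.rr_class} inconsistent with "
                f"{self.chrom1}{self.strand1}/{self.chrom2}{self.strand2} "
                f"(expected {expected})"
            )

    @property
    def signature(self) -> tuple:
        """Match signature: class, chromosome pair, strands."""
        return (self.rr_class, self.chrom1, self.chrom2, self.strand1, self.strand2)

    @property
    def sort_key(self) -> tuple:
        return (self.chrom1, self.pos1, self.chrom2, self.pos2)


@dataclass
class RearrangementSet:
    lesion_id: str
    events: list[RearrangementEvent] = field(default_factory=list)


def read_bedpe(path: str | Path, lesion_id: str) -> RearrangementSet:
    """Read a BEDPE file (chrom1,start1,end1,chrom2,start2,end2,name,score,
    strand1,strand2).  Breakpoint positions are the 1-based end of each
    half-open interval; class is derived from chromosomes and strands."""
    cols = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "name", "score", "strand1", "strand2",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#", dtype=str)
    events = []
    for r in df.itertuples(index=False):
        events.append(
            RearrangementEvent(
                lesion_id=lesion_id,
                chrom1=str(r.chrom1),
                pos1=int(r.end1),
                strand1=str(r.strand1),
                chrom2=str(r.chrom2),
                pos2=int(r.end2),
                strand2=str(r.strand2),
                rr_class=classify_rearrangement(
                    str(r.chrom1), str(r.strand1), str(r.chrom2), str(r.strand2)
                ),
            )
        )
    return RearrangementSet(lesion_id=lesion_id, events=events)


def _match_two(
    anchor: Sequence[RearrangementEvent],
    other: Sequence[RearrangementEvent],
    tolerance_bp: int,
) -> dict[RearrangementEvent, RearrangementEvent]:
    """Greedy 1-to-1 matching: candidate pairs share a signature and both
    breakpoints lie within the tolerance; pairs accepted in order of
    breakpoint-distance sum, ties broken by genomic order."""
    candidates = []
    for a in anchor:
        for b in other:
            if a.signature != b.signature:
                continue
            d1, d2 = abs(a.pos1 - b.pos1), abs(a.pos2 - b.pos2)
            if d1 <= tolerance_bp and d2 <= tolerance_bp:
                candidates.append((d1 + d2, a.sort_key, b.sort_key, a, b))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    matched: dict[RearrangementEvent, RearrangementEvent] = {}
    used_b: set[RearrangementEvent] = set()
    for _, _, _, a, b in candidates:
        if a in matched or b in used_b:
            continue
        matched[a] = b
        used_b.add(b)
    return matched


def match_rearrangements(
    lesions: Sequence[RearrangementSet], tolerance_bp: int = 500
) -> dict:
    """Partition each lesion's rearrangements into common vs private.

    An event is *common* when a 1-to-1 match with the same signature and
    breakpoints within ``tolerance_bp`` exists in every lesion of the
    patient (anchored on the lexicographically first lesion id, so the
    result is invariant to input order).  Returns common event clusters,
    per-lesion private events, and the fraction of all events that belong
    to a common cluster.
    """
    if len(lesions) < 2:
        raise ValueError("need >=2 lesions to compare rearrangements")
    ordered = sorted(lesions, key=lambda s: s.lesion_id)
    anchor, rest = ordered[0], ordered[1:]
    pair_matches = {
        other.lesion_id: _match_two(anchor.events, other.events, tolerance_bp)
        for other in rest
    }
    clusters = []
    common_members: set[RearrangementEvent] = set()
    for a in sorted(anchor.events, key=lambda e: e.sort_key):
        if all(a in pair_matches[o.lesion_id] for o in rest):
            member_by_lesion = {anchor.lesion_id: a}
            for o in rest:
                member_by_lesion[o.lesion_id] = pair_matches[o.lesion_id][a]
            clusters.append(member_by_lesion)
            common_members.update(member_by_lesion.values())
    private = {
        s.lesion_id: sorted(
            (e for e in s.events if e not in common_members),
            key=lambda e: e.sort_key,
        )
        for s in ordered
    }
    n_total = sum(len(s.events) for s in ordered)
    n_common = sum(len(c) for c in clusters)
    return {
        "common_events": clusters,
        "private_events": private,
        "n_events_total": n_total,
        "fraction_common": (n_common / n_total) if n_total else float("nan"),
    }


# ---------------------------------------------------------------------------
# copy number


@dataclass
class CopyNumberProfile:
    """Segmented absolute (total) copy-number profile of one lesion.

    Segments are half-open ``[start, end)``, sorted and non-overlapping per
    chromosome, with integer copy number >= 0.
    """

    lesion_id: str
    segments: pd.DataFrame  # columns: chrom, start, end, copy_number
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        seg = pd.DataFrame(self.segments)
        required = {"chrom", "start", "end", "copy_number"}
        if set(seg.columns) < required:
            raise IntegrityError(f"segments need columns {sorted(required)}")
        seg = seg.astype(
            {"chrom": str, "start": int, "end": int, "copy_number": int}
        )
        if (seg["copy_number"] < 0).any():
            raise IntegrityError("negative copy number")
        if (seg["end"] <= seg["start"]).any():
            raise IntegrityError("segment with end <= start")
        for chrom, sub in seg.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if not (s["start"].values == sub["start"].values).all():
                raise IntegrityError(f"{chrom}: segments not sorted")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise IntegrityError(f"{chrom}: overlapping segments")
        self.segments = seg.reset_index(drop=True)

    @property
    def baseline(self) -> int:
        """Reference copy number for gain/loss calls: rounded ploidy."""
        return int(round(self.ploidy))

    def aberrations(self) -> pd.DataFrame:
        """Maximal runs of adjacent segments deviating from baseline in the
        same direction, merged into single intervals (so calls are invariant
        to re-segmentation of the same underlying profile)."""
        base = self.baseline
        rows = []
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            cur = None
            for r in sub.itertuples(index=False):
                direction = (
                    "gain" if r.copy_number > base
                    else "loss" if r.copy_number < base
                    else None
                )
                if direction is None:
                    if cur:
                        rows.append(cur)
                        cur = None
                    continue
                if cur and cur["direction"] == direction and cur["end"] == r.start:
                    cur["end"] = r.end
                else:
                    if cur:
                        rows.append(cur)
                    cur = {
                        "chrom": chrom,
                        "start": r.start,
                        "end": r.end,
                        "direction": direction,
                    }
            if cur:
                rows.append(cur)
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])


def read_cn_bed(path: str | Path, lesion_id: str, ploidy: float = 2.0) -> CopyNumberProfile:
    """Read a BED-like TSV: chrom, start, end, absolute copy number
    (header optional, detected)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 1].strip().lower() in ("start", "begin"):
        df = df.iloc[1:]
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "copy_number"]
    return CopyNumberProfile(lesion_id=lesion_id, segments=df, ploidy=ploidy)


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def compare_scna(
    profiles: Sequence[CopyNumberProfile],
    overlap_min: float = 0.5,
    focal_regions: pd.DataFrame | None = None,
) -> dict:
    """Common vs private copy-number aberrations across lesions.

    An aberration of one lesion is *common* when every other lesion has an
    overlapping aberration of the same direction with reciprocal overlap
    >= ``overlap_min``.  ``focal_regions`` (columns chrom, start, end, gene,
    expected_direction) adds per-gene gain/loss/neutral calls per lesion.
    """
    if len(profiles) < 2:
        raise ValueError("need >=2 lesions to compare copy-number profiles")
    ordered = sorted(profiles, key=lambda p: p.lesion_id)
    abs_by_lesion = {p.lesion_id: p.aberrations() for p in ordered}

    def has_match(ab, other: pd.DataFrame) -> bool:
        sub = other[(other["chrom"] == ab.chrom) & (other["direction"] == ab.direction)]
        return any(
            _reciprocal_overlap(ab.start, ab.end, r.start, r.end) >= overlap_min
            for r in sub.itertuples(index=False)
        )

    common, private = [], {p.lesion_id: [] for p in ordered}
    for p in ordered:
        for ab in abs_by_lesion[p.lesion_id].itertuples(index=False):
            if all(
                has_match(ab, abs_by_lesion[q.lesion_id])
                for q in ordered
                if q.lesion_id != p.lesion_id
            ):
                common.append({**ab._asdict(), "lesion_id": p.lesion_id})
            else:
                private[p.lesion_id].append(ab._asdict())
    n_total = sum(len(a) for a in abs_by_lesion.values())
    out = {
        "common_segments": common,
        "private_segments": private,
        "n_aberrations_total": n_total,
        "fraction_common": (len(common) / n_total) if n_total else float("nan"),
    }
    if focal_regions is not None:
        calls = []
        for reg in focal_regions.itertuples(index=False):
            row = {"gene": reg.gene, "chrom": reg.chrom}
            for p in ordered:
                abl = abs_by_lesion[p.lesion_id]
                sub = abl[abl["chrom"] == str(reg.chrom)]
                cover = {"gain": 0, "loss": 0}
                for ab in sub.itertuples(index=False):
                    inter = min(ab.end, reg.end) - max(ab.start, reg.start)
                    if inter > 0:
                        cover[ab.direction] += inter
                if cover["gain"] == cover["loss"] == 0:
                    row[p.lesion_id] = "neutral"
                else:
                    row[p.lesion_id] = max(cover, key=lambda d: (cover[d], d))
            calls.append(row)
        out["focal_gene_calls"] = pd.DataFrame(calls)
    return out


# ---------------------------------------------------------------------------
# minimum-event distance


def _common_grid(a: CopyNumberProfile, b: CopyNumberProfile):
    """Intersect two profiles onto a per-chromosome common segment grid;
    returns {chrom: (copies_a, copies_b)} as integer arrays."""
    chroms_a = set(a.segments["chrom"])
    chroms_b = set(b.segments["chrom"])
    if chroms_a != chroms_b:
        raise IntegrityError(
            f"profiles cover different chromosomes: {sorted(chroms_a ^ chroms_b)}"
        )
    out = {}
    for chrom in sorted(chroms_a):
        sa = a.segments[a.segments["chrom"] == chrom]
        sb = b.segments[b.segments["chrom"] == chrom]
        bounds = sorted(
            set(sa["start"]) | set(sa["end"]) | set(sb["start"]) | set(sb["end"])
        )

        def copies_at(sub: pd.DataFrame, start: int, end: int):
            hit = sub[(sub["start"] <= start) & (sub["end"] >= end)]
            if len(hit) != 1:
                raise IntegrityError(
                    f"{chrom}:{start}-{end}: segment grids not alignable "
                    "(gap or partial overlap)"
                )
            return int(hit["copy_number"].iloc[0])

        ca, cb = [], []
        for s, e in zip(bounds[:-1], bounds[1:]):
            ca.append(copies_at(sa, s, e))
            cb.append(copies_at(sb, s, e))
        out[chrom] = (np.array(ca, dtype=int), np.array(cb, dtype=int))
    return out


def _chrom_distance(ca: np.ndarray, cb: np.ndarray) -> float:
    """Minimum number of +/-1 contiguous-run events turning ``ca`` into
    ``cb`` on one chromosome.

    Decomposes the difference into its positive and negative parts (gain
    and loss events act on disjoint segments and cannot cancel) and counts,
    for each part, the total rise of the step function — the classic
    linear-scan event count.  Segments at copy 0 in the source are absorbing
    (no resurrection): they split the chromosome into independent blocks and
    make any gained target unreachable (``inf``).
    """
    if np.any((ca == 0) & (cb != 0)):
        return math.inf
    d = cb - ca
    pos = np.maximum(d, 0)
    neg = np.maximum(-d, 0)

    def rises(v: np.ndarray) -> int:
        prev = 0
        total = 0
        for x in v:
            if x > prev:
                total += x - prev
            prev = x
        return total

    # segments at 0 in the source carry d == 0, so they contribute a dip to
    # zero in both parts; no event run can span them, which `rises` already
    # accounts for.
    return float(rises(pos) + rises(neg))


def min_event_distance(a: CopyNumberProfile, b: CopyNumberProfile) -> float:
    """Minimum-event distance between two lesions' copy-number profiles.

    Sum over chromosomes of the minimum number of single-step events (one
    event adds +1 or -1 to one contiguous run of segments) transforming
    ``a`` into ``b``.  Returns ``math.inf`` when the target is unreachable
    (a segment at copy 0 in ``a`` would need to gain).
    """
    grid = _common_grid(a, b)
    total = 0.0
    for chrom in sorted(grid):
        ca, cb = grid[chrom]
        dist = _chrom_distance(ca, cb)
        if math.isinf(dist):
            return math.inf
        total += dist
    return total
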