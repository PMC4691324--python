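"""Rearrangement matching, SCNA comparison, minimum-event distance."""

import heapq
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mfhet.cn_structural import (
    CopyNumberProfile,
    RearrangementEvent,
    RearrangementSet,
    classify_rearrangement,
    compare_scna,
    match_rearrangements,
    min_event_distance,
    read_bedpe,
    read_cn_bed,
)
from mfhet.cohort_model import IntegrityError


def profile(copies_by_chrom, lesion_id="L", ploidy=2.0, seglen=10):
    rows = []
    for chrom, copies in copies_by_chrom.items():
        for i, c in enumerate(copies):
            rows.append(
                {"chrom": chrom, "start": i * seglen, "end": (i + 1) * seglen,
                 "copy_number": c}
            )
    return CopyNumberProfile(lesion_id, pd.DataFrame(rows), ploidy)


def event(lesion, c1, p1, s1, c2, p2, s2):
    return RearrangementEvent(
        lesion, c1, p1, s1, c2, p2, s2, classify_rearrangement(c1, s1, c2, s2)
    )


# ---------------------------------------------------------------------------
# independent oracle: A* shortest path over the event graph


def astar_event_distance(a, b):
    """Shortest event path from copy vector a to b.  Moves: +/-1 on any
    contiguous run of strictly positive segments (no negative copies, no
    resurrection of zeros).  Admissible heuristic: max positive deficit +
    max negative deficit (gain and loss events act on disjoint segments)."""
    a, b = tuple(a), tuple(b)
    if any(x == 0 and y != 0 for x, y in zip(a, b)):
        return math.inf
    n = len(a)

    def h(v):
        dp = max((y - x for x, y in zip(v, b)), default=0)
        dn = max((x - y for x, y in zip(v, b)), default=0)
        return max(dp, 0) + max(dn, 0)

    seen = {a: 0}
    queue = [(h(a), 0, a)]
    while queue:
        f, g, v = heapq.heappop(queue)
        if v == b:
            return g
        if g > seen.get(v, math.inf):
            continue
        for i in range(n):
            if v[i] == 0:
                continue
            for j in range(i, n):
                if v[j] == 0:
                    break
                for delta in (1, -1):
                    w = list(v)
                    for k in range(i, j + 1):
                        w[k] += delta
                    if min(w) < 0:
                        continue
                    w = tuple(w)
                    if g + 1 < seen.get(w, math.inf):
                        seen[w] = g + 1
                        heapq.heappush(queue, (g + 1 + h(w), g + 1, w))
    return math.inf


class TestMinEventDistance:
    def test_identical_profiles_zero(self):
        p = profile({"1": [2, 3, 2]})
        assert min_event_distance(p, p) == 0

    def test_single_spanning_gain(self):
        a = profile({"1": [2, 2, 2]})
        b = profile({"1": [3, 3, 2]}, "M")
        assert min_event_distance(a, b) == 1

    def test_two_disjoint_gains(self):
        a = profile({"1": [2, 3, 2]})
        b = profile({"1": [3, 3, 3]}, "M")
        assert min_event_distance(a, b) == 2

    def test_zero_crossing_unreachable(self):
        a = profile({"1": [0, 2]})
        b = profile({"1": [1, 2]}, "M")
        assert math.isinf(min_event_distance(a, b))

    def test_zero_segment_splits_events(self):
        # the zero segment cannot be spanned: two separate gains needed
        a = profile({"1": [2, 0, 2]})
        b = profile({"1": [3, 0, 3]}, "M")
        assert min_event_distance(a, b) == 2

    def test_distance_sums_over_chromosomes(self):
        a = profile({"1": [2, 2], "2": [2, 2]})
        b = profile({"1": [3, 3], "2": [1, 1]}, "M")
        assert min_event_distance(a, b) == 2

    def test_mismatched_grids_rejected(self):
        a = profile({"1": [2, 2]})
        b = profile({"2": [2, 2]}, "M")
        with pytest.raises(IntegrityError, match="different chromosomes"):
            min_event_distance(a, b)

    def test_unaligned_segment_boundaries_intersect(self):
        # b splits a's single segment: intersection grid handles it
        a = CopyNumberProfile(
            "A", pd.DataFrame([{"chrom": "1", "start": 0, "end": 20, "copy_number": 2}])
        )
        b = CopyNumberProfile(
            "B",
            pd.DataFrame(
                [
                    {"chrom": "1", "start": 0, "end": 10, "copy_number": 3},
                    {"chrom": "1", "start": 10, "end": 20, "copy_number": 2},
                ]
            ),
        )
        assert min_event_distance(a, b) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_shortest_path_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            n = int(rng.integers(2, 7))
            ca = rng.integers(0, 5, n)
            cb = rng.integers(0, 5, n)
            a = profile({"1": list(ca)})
            b = profile({"1": list(cb)}, "M")
            assert min_event_distance(a, b) == astar_event_distance(ca, cb), (
                ca, cb,
            )

    def test_lower_bound_max_abs_difference(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            ca = rng.integers(1, 5, 5)
            cb = rng.integers(1, 5, 5)
            d = min_event_distance(profile({"1": list(ca)}), profile({"1": list(cb)}, "M"))
            assert d >= np.max(np.abs(ca - cb))
            assert d >= 0


class TestRearrangementMatching:
    def base_events(self, lesion):
        return [
            event(lesion, "1", 1_000_000, "+", "1", 2_000_000, "-"),
            event(lesion, "2", 5_000_000, "-", "2", 5_400_000, "+"),
            event(lesion, "3", 9_000_000, "+", "8", 1_000_000, "-"),
        ]

    def test_identical_lists_all_common(self):
        out = match_rearrangements(
            [
                RearrangementSet("L1", self.base_events("L1")),
                RearrangementSet("L2", self.base_events("L2")),
            ]
        )
        assert out["fraction_common"] == 1.0

    def test_jitter_within_tolerance_matches(self):
        a = RearrangementSet("L1", [event("L1", "1", 1_000_000, "+", "1", 2_000_000, "-")])
        b = RearrangementSet(
            "L2", [event("L2", "1", 1_000_200, "+", "1", 1_999_800, "-")]
        )
        out = match_rearrangements([a, b], tolerance_bp=500)
        assert out["fraction_common"] == 1.0

    def test_jitter_beyond_tolerance_private(self):
        a = RearrangementSet("L1", [event("L1", "1", 1_000_000, "+", "1", 2_000_000, "-")])
        b = RearrangementSet(
            "L2", [event("L2", "1", 1_010_000, "+", "1", 2_000_000, "-")]
        )
        out = match_rearrangements([a, b], tolerance_bp=500)
        assert out["fraction_common"] == 0.0
        assert len(out["private_events"]["L1"]) == 1

    def test_lesion_private_duplication(self):
        # tandem duplication present only in the second lesion stays private
        common = event("L1", "1", 1_000_000, "+", "1", 2_000_000, "-")
        myc_dup = event("L2", "8", 128_000_000, "-", "8", 128_750_000, "+")
        out = match_rearrangements(
            [
                RearrangementSet("L1", [common]),
                RearrangementSet(
                    "L2",
                    [event("L2", "1", 1_000_100, "+", "1", 2_000_100, "-"), myc_dup],
                ),
            ]
        )
        assert out["private_events"]["L2"] == [myc_dup]
        assert len(out["common_events"]) == 1

    def test_class_must_match(self):
        a = RearrangementSet("L1", [event("L1", "1", 1_000_000, "+", "1", 2_000_000, "-")])
        b = RearrangementSet("L2", [event("L2", "1", 1_000_000, "-", "1", 2_000_000, "+")])
        out = match_rearrangements([a, b])
        assert out["fraction_common"] == 0.0

    def test_fraction_invariant_under_lesion_permutation(self):
        rng = np.random.default_rng(5)
        sets = []
        for lid in ("L1", "L2", "L3"):
            evs = self.base_events(lid)
            if lid != "L1":
                evs = [
                    event(
                        lid, e.chrom1, e.pos1 + int(rng.integers(-300, 300)),
                        e.strand1, e.chrom2, e.pos2 + int(rng.integers(-300, 300)),
                        e.strand2,
                    )
                    for e in evs
                ]
            evs.append(event(lid, "4", int(rng.integers(1, 9)) * 1_000_000, "+", "4", 50_000_000, "+"))
            sets.append(RearrangementSet(lid, evs))
        fractions = {
            match_rearrangements(list(perm))["fraction_common"]
            for perm in itertools.permutations(sets)
        }
        assert len(fractions) == 1

    def test_exhaustive_pairing_oracle_small(self):
        """Greedy nearest matching agrees with exhaustive assignment on
        whether a full match exists for small same-signature sets."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            # well-separated events (spacing > 2x tolerance): the correct
            # 1-to-1 assignment is unambiguous and greedy must find it
            pa = sorted(int(p) * 1500 + int(rng.integers(0, 400)) for p in rng.choice(6, 3, replace=False))
            pb = sorted(int(p) * 1500 + int(rng.integers(0, 400)) for p in rng.choice(6, 3, replace=False))
            a = RearrangementSet(
                "L1", [event("L1", "1", int(p), "+", "1", int(p) + 100_000, "-") for p in pa]
            )
            b = RearrangementSet(
                "L2", [event("L2", "1", int(p), "+", "1", int(p) + 100_000, "-") for p in pb]
            )
            out = match_rearrangements([a, b], tolerance_bp=500)
            # oracle: maximum bipartite matching by brute force permutation
            best = max(
                sum(
                    1
                    for x, y in zip(pa, perm)
                    if abs(x - y) <= 500 and abs((x + 100_000) - (y + 100_000)) <= 500
                )
                for perm in itertools.permutations(pb)
            )
            assert len(out["common_events"]) <= best
            # greedy on sorted 1-d same-signature sets achieves the optimum
            assert len(out["common_events"]) == best


class TestCompareScna:
    def test_identical_profiles_all_common(self):
        a = profile({"1": [2, 3, 3, 2], "2": [1, 2, 2, 2]}, "L1")
        b = profile({"1": [2, 3, 3, 2], "2": [1, 2, 2, 2]}, "L2")
        out = compare_scna([a, b])
        assert out["fraction_common"] == 1.0

    def test_pten_loss_private_to_one_lesion(self):
        a = profile({"10": [2, 1, 2]}, "L1")  # loss over middle segment
        b = profile({"10": [2, 2, 2]}, "L2")
        regions = pd.DataFrame(
            [{"chrom": "10", "start": 12, "end": 18, "gene": "PTEN",
              "expected_direction": "loss"}]
        )
        out = compare_scna([a, b], focal_regions=regions)
        assert out["private_segments"]["L1"]
        calls = out["focal_gene_calls"].iloc[0]
        assert calls["L1"] == "loss" and calls["L2"] == "neutral"

    def test_resegmentation_invariance(self):
        """Splitting segments at extra breakpoints must not change the
        common-aberration calls."""
        rng = np.random.default_rng(2)
        underlying = [2, 2, 3, 3, 3, 2, 1, 1, 2, 2]

        def segmentation(seed):
            r = np.random.default_rng(seed)
            cuts = sorted({0, 10} | set(r.integers(1, 10, 4)))
            rows = []
            for s, e in zip(cuts[:-1], cuts[1:]):
                # only valid segmentations: constant copy within segment
                for k in range(s, e):
                    rows.append(
                        {"chrom": "1", "start": k * 10, "end": (k + 1) * 10,
                         "copy_number": underlying[k]}
                    )
            return rows

        a = CopyNumberProfile("L1", pd.DataFrame(segmentation(1)))
        b = CopyNumberProfile("L2", pd.DataFrame(segmentation(2)))
        out = compare_scna([a, b])
        assert out["fraction_common"] == 1.0

    def test_direction_calls_flip_under_reflection(self):
        a = profile({"1": [3, 2, 1]}, "L1")
        b = profile({"1": [1, 2, 3]}, "L2")  # reflected around baseline 2
        ab_a = a.aberrations()
        ab_b = b.aberrations()
        assert list(ab_a["direction"]) == ["gain", "loss"]
        assert list(ab_b["direction"]) == ["loss", "gain"]

    def test_tetraploid_baseline_not_whole_genome_gain(self):
        p = profile({"1": [4, 4, 5]}, ploidy=4.0)
        ab = p.aberrations()
        assert len(ab) == 1 and ab.iloc[0]["direction"] == "gain"

    def test_overlapping_segments_rejected(self):
        with pytest.raises(IntegrityError, match="overlap"):
            CopyNumberProfile(
                "L",
                pd.DataFrame(
                    [
                        {"chrom": "1", "start": 0, "end": 10, "copy_number": 2},
                        {"chrom": "1", "start": 5, "end": 15, "copy_number": 3},
                    ]
                ),
            )


class TestFileReaders:
    def test_bedpe_round_trip(self, tmp_path):
        p = tmp_path / "x.bedpe"
        p.write_text(
            "1\t999999\t1000000\t1\t1999999\t2000000\tdeletion-type\t0\t+\t-\n"
            "2\t499999\t500000\t7\t999999\t1000000\tinter-chromosomal\t0\t+\t+\n"
        )
        rr = read_bedpe(p, "L1")
        assert [e.rr_class for e in rr.events] == [
            "deletion-type", "inter-chromosomal",
        ]
        assert rr.events[0].pos1 == 1_000_000

    def test_cn_bed_reader(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("1\t0\t10\t2\n1\t10\t20\t3\n")
        prof = read_cn_bed(p, "L1")
        assert list(prof.segments["copy_number"]) == [2, 3]
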