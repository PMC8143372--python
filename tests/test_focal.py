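"""Focal event calling: rule-set examples, properties and a literal oracle."""

import numpy as np
import pandas as pd
import pytest

from plasmacna.focal import (
    AnnotationBundle,
    MissingAnnotationError,
    call_focal_amplifications,
    call_focal_deletions,
    neighbor_weighted_mean,
    overlap_fraction,
)
from plasmacna.profiling import Segment

MB = 1_000_000


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "is_driver", "is_deletion_target"])


@pytest.fixture()
def tiny_annotation():
    genes = _genes([
        ("chr1", 10 * MB, int(10.1 * MB), "EGFR", True, False),
        ("chr1", 40 * MB, int(40.1 * MB), "G0001", False, False),
        ("chr1", 70 * MB, int(70.1 * MB), "CDKN2A", False, True),
    ])
    return AnnotationBundle(genes, _track([]), _track([]), {"chr1": 200 * MB})


def _flat_background(center_start, center_end, mean, chrom="chr1"):
    """Three segments: 30 Mb of zeros either side of the candidate."""
    return [
        Segment(chrom, max(0, center_start - 30 * MB), center_start,
                (center_start - max(0, center_start - 30 * MB)) // 50_000, 0.0),
        Segment(chrom, center_start, center_end, (center_end - center_start) // 50_000, mean),
        Segment(chrom, center_end, center_end + 30 * MB, 600, 0.0),
    ]


class TestAmplificationRules:
    def test_driver_segment_with_modest_gain_is_called(self, tiny_annotation):
        segs = _flat_background(9 * MB, 11 * MB, 0.30)
        events = call_focal_amplifications(segs, tiny_annotation)
        assert len(events) == 1
        assert events[0].genes == ("EGFR",)
        assert events[0].contains_driver
        assert events[0].neighbor_delta == pytest.approx(0.30)

    def test_same_gain_without_driver_needs_058(self, tiny_annotation):
        segs = _flat_background(39 * MB, 41 * MB, 0.30)
        assert call_focal_amplifications(segs, tiny_annotation) == []
        segs = _flat_background(39 * MB, 41 * MB, 0.60)
        events = call_focal_amplifications(segs, tiny_annotation)
        assert [e.genes for e in events] == [("G0001",)]

    def test_large_segment_rejected_despite_high_log2(self, tiny_annotation):
        segs = _flat_background(5 * MB, 30 * MB, 0.9)  # 25 Mb
        assert call_focal_amplifications(segs, tiny_annotation) == []

    def test_geneless_segment_rejected(self, tiny_annotation):
        segs = _flat_background(100 * MB, 102 * MB, 0.9)
        assert call_focal_amplifications(segs, tiny_annotation) == []

    def test_flat_profile_no_events(self, tiny_annotation):
        segs = [Segment("chr1", 0, 200 * MB, 4000, 0.0)]
        assert call_focal_amplifications(segs, tiny_annotation) == []

    def test_segdup_veto_above_half_coverage(self, tiny_annotation):
        segdups = _track([("chr1", 9 * MB, int(10.2 * MB))])  # 60% of 2 Mb segment
        ann = AnnotationBundle(tiny_annotation.genes, segdups, _track([]))
        segs = _flat_background(9 * MB, 11 * MB, 0.30)
        assert call_focal_amplifications(segs, ann) == []

    def test_dgv_reciprocal_overlap_veto(self, tiny_annotation):
        dgv = _track([("chr1", 9 * MB, 11 * MB)])  # matches the segment 1:1
        ann = AnnotationBundle(tiny_annotation.genes, tiny_annotation.segdups, dgv)
        segs = _flat_background(9 * MB, 11 * MB, 0.30)
        assert call_focal_amplifications(segs, ann) == []
        # a small polymorphism inside the segment does not veto reciprocally
        dgv_small = _track([("chr1", 10 * MB, int(10.05 * MB))])
        ann2 = AnnotationBundle(tiny_annotation.genes, tiny_annotation.segdups, dgv_small)
        assert len(call_focal_amplifications(segs, ann2)) == 1

    def test_missing_annotation_rejected(self, tiny_annotation):
        with pytest.raises(MissingAnnotationError):
            AnnotationBundle(tiny_annotation.genes, None, _track([]))


class TestDeletionRules:
    def test_deletion_target_loss_called(self, tiny_annotation):
        segs = _flat_background(69 * MB, int(70.5 * MB), -0.35)
        events = call_focal_deletions(segs, tiny_annotation)
        assert [e.genes for e in events] == [("CDKN2A",)]
        assert events[0].direction == "deletion"

    def test_non_target_gene_rejected(self, tiny_annotation):
        segs = _flat_background(39 * MB, 41 * MB, -0.35)  # only G0001 inside
        assert call_focal_deletions(segs, tiny_annotation) == []

    def test_shallow_loss_rejected(self, tiny_annotation):
        segs = _flat_background(69 * MB, int(70.5 * MB), -0.1)
        assert call_focal_deletions(segs, tiny_annotation) == []


class TestNeighborContext:
    def test_flat_neighbors_mean_zero(self):
        segs = _flat_background(50 * MB, 52 * MB, 0.5)
        ctx = neighbor_weighted_mean(segs, 1)
        assert ctx.combined_weighted_mean == pytest.approx(0.0)

    def test_unequal_flanks_weighted_average(self):
        segs = [
            Segment("chr1", 30 * MB, 50 * MB, 400, 0.1),
            Segment("chr1", 50 * MB, 52 * MB, 40, 0.9),
            Segment("chr1", 52 * MB, 72 * MB, 400, 0.3),
        ]
        ctx = neighbor_weighted_mean(segs, 1)
        assert ctx.left_mean == pytest.approx(0.1)
        assert ctx.right_mean == pytest.approx(0.3)
        assert ctx.combined_weighted_mean == pytest.approx(0.2)

    def test_chromosome_start_uses_right_flank_only(self):
        segs = [
            Segment("chr1", 0, 2 * MB, 40, 0.8),
            Segment("chr1", 2 * MB, 30 * MB, 560, 0.25),
        ]
        ctx = neighbor_weighted_mean(segs, 0)
        assert ctx.left_span == 0
        assert ctx.combined_weighted_mean == pytest.approx(0.25)

    def test_lone_segment_flagged_empty(self):
        segs = [Segment("chr1", 0, 50 * MB, 1000, 0.4)]
        ctx = neighbor_weighted_mean(segs, 0)
        assert ctx.empty


class TestOverlapFraction:
    def test_cases(self):
        seg = Segment("chr1", 100, 200, 2, 0.5)
        assert overlap_fraction(seg, _track([])) == 0.0
        assert overlap_fraction(seg, _track([("chr1", 0, 500)])) == 1.0
        two = _track([("chr1", 100, 130), ("chr1", 150, 175)])
        assert overlap_fraction(seg, two) == pytest.approx(0.55)
        overlapping = _track([("chr1", 100, 150), ("chr1", 120, 160)])
        assert overlap_fraction(seg, overlapping) == pytest.approx(0.60)


# ---------------------------------------------------------------------------
# literal brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_calls(segments, annotation, direction):
    """Re-state every criterion literally and independently."""
    called = []
    for seg in segments:
        if not seg.length_bp < 20 * MB:
            continue
        if direction == "amplification" and not seg.mean_log2 > 0.2:
            continue
        if direction == "deletion" and not seg.mean_log2 < -0.2:
            continue
        genes = [g for g in annotation.genes.itertuples()
                 if g.chrom == seg.chrom and g.start < seg.end and g.end > seg.start]
        if not 1 <= len(genes) <= 100:
            continue
        if direction == "deletion" and not any(g.is_deletion_target for g in genes):
            continue
        # neighbor weighted mean over 20 Mb flanks
        wsum = wtot = 0.0
        for other in segments:
            if other is seg or other.chrom != seg.chrom:
                continue
            for lo, hi in [(seg.start - 20 * MB, seg.start), (seg.end, seg.end + 20 * MB)]:
                ov = min(other.end, hi) - max(other.start, lo)
                if ov > 0:
                    wsum += ov * other.mean_log2
                    wtot += ov
        if wtot == 0:
            num = den = 0.0
            for other in segments:
                if other is seg or other.chrom != seg.chrom:
                    continue
                num += other.length_bp * other.mean_log2
                den += other.length_bp
            background = num / den if den else float("nan")
        else:
            background = wsum / wtot
        delta = seg.mean_log2 - background
        if np.isnan(delta):
            delta = seg.mean_log2
        has_driver = any(g.is_driver for g in genes)
        if direction == "amplification":
            need = 0.2 if has_driver else 0.58
            if not delta >= need:
                continue
        else:
            if not delta <= -0.2:
                continue
        # segmental duplication coverage by union
        pts = []
        for t in annotation.segdups.itertuples():
            if t.chrom == seg.chrom and t.start < seg.end and t.end > seg.start:
                pts.append((max(t.start, seg.start), min(t.end, seg.end)))
        covered, last = 0, None
        for s, e in sorted(pts):
            if last is None or s > last[1]:
                if last:
                    covered += last[1] - last[0]
                last = [s, e]
            else:
                last[1] = max(last[1], e)
        if last:
            covered += last[1] - last[0]
        if covered / seg.length_bp > 0.5:
            continue
        # DGV reciprocal-50% match
        vetoed = False
        for t in annotation.dgv.itertuples():
            if t.chrom != seg.chrom:
                continue
            ov = min(t.end, seg.end) - max(t.start, seg.start)
            if ov > 0 and ov / seg.length_bp >= 0.5 and ov / (t.end - t.start) >= 0.5:
                vetoed = True
        if vetoed:
            continue
        called.append((seg.chrom, seg.start, seg.end))
    return sorted(called)


def random_segment_profile(rng, annotation, chrom="chr1", length=200 * MB):
    cuts = np.sort(rng.choice(np.arange(1, length // MB), int(rng.integers(3, 49)),
                              replace=False)) * MB
    bounds = [0, *map(int, cuts), length]
    segs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        level = rng.choice([0.0, rng.normal(0, 0.1), rng.uniform(0.2, 1.0),
                            -rng.uniform(0.2, 0.8)], p=[0.5, 0.2, 0.2, 0.1])
        segs.append(Segment(chrom, lo, hi, (hi - lo) // 50_000, float(level)))
    return segs


class TestBruteForceAgreement:
    @pytest.mark.parametrize("direction", ["amplification", "deletion"])
    def test_caller_matches_literal_checker_on_random_profiles(self, direction):
        rng = np.random.default_rng(99)
        genes = _genes([
            ("chr1", int(rng.integers(0, 195 * MB)), 0, f"N{i}", i % 4 == 0, i % 5 == 0)
            for i in range(60)
        ])
        genes["end"] = genes.start + 150_000
        segdups = _track([("chr1", int(s), int(s) + int(rng.integers(50_000, 3 * MB)))
                          for s in rng.integers(0, 195 * MB, 40)])
        dgv = _track([("chr1", int(s), int(s) + int(rng.integers(50_000, 2 * MB)))
                      for s in rng.integers(0, 195 * MB, 40)])
        ann = AnnotationBundle(genes, segdups, dgv)
        call = (call_focal_amplifications if direction == "amplification"
                else call_focal_deletions)
        for _ in range(100):
            segs = random_segment_profile(rng, ann)
            got = sorted((e.segment.chrom, e.segment.start, e.segment.end)
                         for e in call(segs, ann))
            assert got == brute_force_calls(segs, ann, direction)


class TestProperties:
    def test_determinism(self, tiny_annotation):
        segs = _flat_background(9 * MB, 11 * MB, 0.30)
        a = call_focal_amplifications(segs, tiny_annotation)
        b = call_focal_amplifications(segs, tiny_annotation)
        assert a == b

    def test_raising_log2_never_uncalls(self, tiny_annotation):
        for extra in (0.1, 0.5, 1.0):
            segs = _flat_background(9 * MB, 11 * MB, 0.30 + extra)
            assert len(call_focal_amplifications(segs, tiny_annotation)) == 1
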