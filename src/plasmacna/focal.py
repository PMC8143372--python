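"""Focal somatic copy-number event calling on segmented log2 profiles.

A focal amplification must satisfy every one of these rules:

1. the segment is shorter than 20 Mb;
2. its mean log2 ratio exceeds 0.2;
3. it contains at least one gene but no more than 100;
4. its log2 ratio stands 0.2 above the length-weighted mean of the
   segments in the 20 Mb flanks on both sides if it contains a known tumor
   driver gene, or 0.58 above it (about one extra copy at full tumor
   content) if it does not;
5. segmental duplications cover at most 50% of it;
6. it does not match a known copy-number-polymorphism (DGV-style) entry.

Focal deletions mirror the rules with log2 below -0.2, a single neighbor
delta of 0.2 (below), and the gene requirement tightened to a gene known to
be recurrently deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .profiling import Segment

MAX_FOCAL_LENGTH = 20_000_000
FLANK = 20_000_000
MIN_ABS_LOG2 = 0.2
DRIVER_DELTA = 0.2
NONDRIVER_DELTA = 0.58
MAX_GENES = 100
SEGDUP_MAX_FRAC = 0.5
DGV_RECIPROCAL = 0.5


class AnnotationError(ValueError):
    pass


class MissingAnnotationError(AnnotationError):
    """A required annotation track was not provided."""


@dataclass
class AnnotationBundle:
    """Gene and repeat tracks the focal criteria are evaluated against."""

    genes: pd.DataFrame       # chrom, start, end, name, is_driver, is_deletion_target
    segdups: pd.DataFrame     # chrom, start, end
    dgv: pd.DataFrame         # chrom, start, end
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for label in ("genes", "segdups", "dgv"):
            track = getattr(self, label)
            if track is None:
                raise MissingAnnotationError(f"annotation track {label!r} is missing")
            if len(track) and not (track.end > track.start).all():
                raise AnnotationError(f"degenerate interval in {label} track")
            setattr(self, label, track.sort_values(["chrom", "start"], ignore_index=True))
        if "is_deletion_target" not in self.genes.columns:
            self.genes = self.genes.assign(is_deletion_target=False)

    @classmethod
    def from_genome(cls, genome: GenomeModel) -> "AnnotationBundle":
        return cls(genome.genes.copy(), genome.segdups.copy(), genome.dgv.copy(),
                   dict(genome.lengths))


@dataclass(frozen=True)
class NeighborContext:
    """Length-weighted log2 background of the 20 Mb flanks of a segment."""

    left_mean: float
    right_mean: float
    combined_weighted_mean: float
    left_span: int
    right_span: int
    empty: bool = False


@dataclass(frozen=True)
class FocalEvent:
    segment: Segment
    direction: str                      # "amplification" | "deletion"
    genes: tuple[str, ...]
    contains_driver: bool
    neighbor_delta: float
    filters_passed: tuple[tuple[str, bool], ...] = field(default=())


def _weighted_window_mean(segments, lo, hi, skip_index):
    """(weighted mean, covered span) of segments overlapping [lo, hi)."""
    total_w = 0.0
    total = 0.0
    for k, seg in enumerate(segments):
        if k == skip_index:
            continue
        ov = min(seg.end, hi) - max(seg.start, lo)
        if ov > 0:
            total += ov * seg.mean_log2
            total_w += ov
    return (total / total_w if total_w > 0 else float("nan")), int(total_w)


def neighbor_weighted_mean(
    segments: list[Segment], index: int, flank: int = FLANK
) -> NeighborContext:
    """Weighted mean log2 of the segments within ``flank`` bp on both sides.

    Weights are the overlap lengths of neighboring segments with the two
    flank windows; the segment itself is excluded and windows are truncated
    at the chromosome's segmented extent.  When neither side has coverage
    (single-segment chromosome) the context is flagged empty and the mean
    falls back to the chromosome-wide weighted mean excluding the segment —
    which is also empty, so callers treat NaN as "no background".
    """
    seg = segments[index]
    same = [s for s in segments if s.chrom == seg.chrom]
    idx = same.index(seg)
    left_mean, left_span = _weighted_window_mean(same, seg.start - flank, seg.start, idx)
    right_mean, right_span = _weighted_window_mean(same, seg.end, seg.end + flank, idx)
    total_span = left_span + right_span
    if total_span > 0:
        parts = []
        if left_span:
            parts.append((left_mean, left_span))
        if right_span:
            parts.append((right_mean, right_span))
        combined = sum(m * w for m, w in parts) / total_span
        return NeighborContext(left_mean, right_mean, combined, left_span, right_span)
    # fall back to the chromosome-wide weighted mean excluding the segment
    combined, span = _weighted_window_mean(same, -np.inf, np.inf, idx)
    return NeighborContext(float("nan"), float("nan"), combined, 0, 0, empty=True)


def _track_overlaps(track: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    t = track[track.chrom == chrom]
    return t[(t.start < end) & (t.end > start)]


def overlap_fraction(segment: Segment, track: pd.DataFrame) -> float:
    """Fraction of the segment covered by the union of track intervals."""
    hits = _track_overlaps(track, segment.chrom, segment.start, segment.end)
    if hits.empty:
        return 0.0
    ivs = sorted(zip(np.maximum(hits.start, segment.start), np.minimum(hits.end, segment.end)))
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / segment.length_bp


def _dgv_hit(segment: Segment, dgv: pd.DataFrame, mode: str, threshold: float) -> bool:
    hits = _track_overlaps(dgv, segment.chrom, segment.start, segment.end)
    if hits.empty:
        return False
    if mode == "any":
        return True
    if mode != "reciprocal":
        raise AnnotationError(f"unknown DGV overlap mode {mode!r}")
    ov = np.minimum(hits.end, segment.end) - np.maximum(hits.start, segment.start)
    frac_seg = ov / segment.length_bp
    frac_entry = ov / (hits.end - hits.start)
    return bool(((frac_seg >= threshold) & (frac_entry >= threshold)).any())


def _genes_in(segment: Segment, genes: pd.DataFrame) -> pd.DataFrame:
    return _track_overlaps(genes, segment.chrom, segment.start, segment.end)


def _call(
    segments: list[Segment],
    annotation: AnnotationBundle,
    direction: str,
    *,
    flank: int = FLANK,
    max_length: int = MAX_FOCAL_LENGTH,
    min_abs_log2: float = MIN_ABS_LOG2,
    driver_delta: float = DRIVER_DELTA,
    nondriver_delta: float = NONDRIVER_DELTA,
    max_genes: int = MAX_GENES,
    segdup_max_frac: float = SEGDUP_MAX_FRAC,
    dgv_mode: str = "reciprocal",
    dgv_threshold: float = DGV_RECIPROCAL,
) -> list[FocalEvent]:
    amp = direction == "amplification"
    events = []
    for i, seg in enumerate(segments):
        checks: list[tuple[str, bool]] = []

        def fails(name: str, ok: bool) -> bool:
            checks.append((name, bool(ok)))
            return not ok

        if fails("size_lt_20mb", seg.length_bp < max_length):
            continue
        log2_ok = seg.mean_log2 > min_abs_log2 if amp else seg.mean_log2 < -min_abs_log2
        if fails("log2_threshold", log2_ok):
            continue
        hit_genes = _genes_in(seg, annotation.genes)
        if fails("contains_gene", len(hit_genes) >= 1):
            continue
        if fails("not_gt_100_genes", len(hit_genes) <= max_genes):
            continue
        contains_driver = bool(hit_genes.is_driver.any())
        if not amp and fails("deletion_target_gene", bool(hit_genes.is_deletion_target.any())):
            continue
        ctx = neighbor_weighted_mean(segments, i, flank)
        delta = seg.mean_log2 - ctx.combined_weighted_mean
        if np.isnan(delta):
            delta = seg.mean_log2  # no background at all: compare against 0
        if amp:
            need = driver_delta if contains_driver else nondriver_delta
            delta_ok = delta >= need
        else:
            delta_ok = delta <= -driver_delta
        if fails("neighbor_delta", delta_ok):
            continue
        if fails("segdup_fraction", overlap_fraction(seg, annotation.segdups) <= segdup_max_frac):
            continue
        if fails("dgv_overlap", not _dgv_hit(seg, annotation.dgv, dgv_mode, dgv_threshold)):
            continue
        events.append(
            FocalEvent(seg, direction, tuple(sorted(hit_genes.name)), contains_driver,
                       float(delta), tuple(checks))
        )
    events.sort(key=lambda e: (e.segment.chrom, e.segment.start))
    return events


def call_focal_amplifications(
    segments: list[Segment], annotation: AnnotationBundle, **kwargs
) -> list[FocalEvent]:
    """Apply the amplification rule set; a segment is emitted iff all pass."""
    return _call(segments, annotation, "amplification", **kwargs)


def call_focal_deletions(
    segments: list[Segment], annotation: AnnotationBundle, **kwargs
) -> list[FocalEvent]:
    """Apply the deletion rule set (deletion-target gene required)."""
    return _call(segments, annotation, "deletion", **kwargs)


def events_to_frame(events: list[FocalEvent]) -> pd.DataFrame:
    """Tidy table of called events (one row per event)."""
    rows = [
        dict(chrom=e.segment.chrom, start=e.segment.start, end=e.segment.end,
             direction=e.direction, mean_log2=e.segment.mean_log2,
             neighbor_delta=e.neighbor_delta, genes=",".join(e.genes),
             contains_driver=e.contains_driver)
        for e in events
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "mean_log2",
                                       "neighbor_delta", "genes", "contains_driver"])
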