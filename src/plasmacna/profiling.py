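"""Read-count copy-number profiling of shallow-WGS plasma samples.

The pipeline is the classic plasma-Seq recipe: reads are counted in
non-overlapping 50 kb windows, normalized by the total read count, corrected
for GC bias with a LOESS fit, normalized against a healthy-control panel to
remove position effects, and the resulting log2 ratios are segmented with an
exact penalized least-squares change-point search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeModel

RATIO_FLOOR_REL = 1e-6  # relative log floor; avoids -inf from dropout bins


class ProfilingError(ValueError):
    pass


class UnknownChromosomeError(ProfilingError):
    pass


class AlreadyNormalizedError(ProfilingError):
    """control_normalize applied twice to the same profile."""


@dataclass
class CopyNumberProfile:
    """One plasma sample's ordered 50 kb bins and their derived ratios.

    ``bins`` starts with ``chrom, start, end, gc, mappable, count`` and gains
    ``ratio`` (total-count normalized), ``corrected`` (GC-corrected) and
    ``log2`` + ``usable`` (control-normalized) as the pipeline stages run.
    """

    sample_id: str
    bins: pd.DataFrame
    total_reads: int
    bin_width: int = 50_000
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "CopyNumberProfile":
        return replace(self, bins=self.bins.copy(), metadata=dict(self.metadata))

    @property
    def has_log2(self) -> bool:
        return "log2" in self.bins.columns

    def usable(self) -> pd.DataFrame:
        if not self.has_log2:
            raise ProfilingError("profile not yet control-normalized")
        return self.bins[self.bins.usable]


@dataclass(frozen=True)
class Segment:
    """Maximal constant-log2 run of usable bins on one chromosome."""

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def profile_from_counts(
    counts: pd.DataFrame, genome: GenomeModel, sample_id: str = "sample", **metadata
) -> CopyNumberProfile:
    """Attach genome bin annotation (gc, mappability) to a 4-column count table."""
    need = {"chrom", "start", "end", "count"}
    if not need.issubset(counts.columns):
        raise ProfilingError(f"count table must have columns {sorted(need)}")
    merged = genome.bins.merge(counts[["chrom", "start", "count"]], on=["chrom", "start"], how="left")
    if merged["count"].isna().any():
        raise ProfilingError("count table does not cover every genome bin")
    merged["count"] = merged["count"].astype(np.int64)
    return CopyNumberProfile(sample_id, merged, int(merged["count"].sum()),
                             genome.bin_width, metadata)


def bin_counts(
    read_starts, genome: GenomeModel, sample_id: str = "sample", **metadata
) -> CopyNumberProfile:
    """Count read start coordinates in the genome's 50 kb windows.

    Each read lands in exactly one bin by its start position (half-open
    intervals).  Reads in PAR-masked / unmappable bins are still counted; the
    bins stay flagged unusable downstream.
    """
    if isinstance(read_starts, pd.DataFrame):
        pairs = read_starts[["chrom", "pos"]].itertuples(index=False)
    else:
        pairs = read_starts
    counts = np.zeros(len(genome.bins), dtype=np.int64)
    offsets: dict[str, tuple[int, int]] = {}
    chrom_arr = genome.bins.chrom.to_numpy()
    for chrom in genome.lengths:
        idx = np.flatnonzero(chrom_arr == chrom)
        offsets[chrom] = (int(idx[0]), int(idx[-1]) + 1)
    for chrom, pos in pairs:
        if chrom not in offsets:
            raise UnknownChromosomeError(f"read on unknown chromosome {chrom!r}")
        if not 0 <= pos < genome.lengths[chrom]:
            raise ProfilingError(f"read position {pos} outside {chrom}")
        lo, _ = offsets[chrom]
        counts[lo + int(pos) // genome.bin_width] += 1
    out = genome.bins.copy()
    out["count"] = counts
    return CopyNumberProfile(sample_id, out, int(counts.sum()), genome.bin_width, metadata)


def normalize_total(profile: CopyNumberProfile) -> CopyNumberProfile:
    """Divide every bin count by the sample's total read count."""
    total = int(profile.bins["count"].sum())
    if total <= 0:
        raise ProfilingError("cannot normalize a profile with zero total reads")
    out = profile.copy()
    out.bins["ratio"] = out.bins["count"] / total
    out.total_reads = total
    return out


def gc_correct(profile: CopyNumberProfile, span: float = 0.3) -> CopyNumberProfile:
    """Remove GC bias by dividing out a LOESS fit of ratio on GC fraction.

    The fit is done in two passes: bins whose first-pass residual is an
    outlier (beyond 2.5 robust SDs in log space — typically bins inside real
    copy-number events) are dropped and the curve refit on the remainder, so
    broad aberrations do not bend the bias estimate.  The fitted curve is
    floored at 1e-6 of its median so extreme-GC bins cannot blow up.  With a
    single distinct GC value the transform is the identity.
    """
    if "ratio" not in profile.bins.columns:
        raise ProfilingError("run normalize_total before gc_correct")
    out = profile.copy()
    b = out.bins
    mask = b.mappable.to_numpy()
    if mask.sum() < 100:
        raise ProfilingError("need at least 100 mappable bins for GC correction")
    gc = b.gc.to_numpy()[mask]
    ratio = b.ratio.to_numpy()[mask]
    corrected = np.full(len(b), np.nan)
    if np.ptp(gc) < 1e-12:
        corrected[mask] = ratio
    else:
        fitted = _robust_gc_fit(ratio, gc, span)
        med_fit = np.median(fitted)
        fitted = np.maximum(fitted, max(med_fit, 1e-300) * 1e-6)
        med_ratio = np.median(ratio)
        corrected[mask] = ratio * (med_ratio / fitted) if med_ratio > 0 else ratio / fitted
    out.bins["corrected"] = corrected
    return out


def _robust_gc_fit(ratio: np.ndarray, gc: np.ndarray, span: float) -> np.ndarray:
    fitted = lowess(ratio, gc, frac=span, return_sorted=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.log2(np.maximum(ratio, 1e-300) / np.maximum(fitted, 1e-300))
    resid = np.where(np.isfinite(resid), resid, 0.0)
    mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    keep = np.abs(resid - np.median(resid)) <= 2.5 * max(mad, 1e-12)
    if keep.sum() >= 30 and keep.sum() < len(ratio):
        pts = lowess(ratio[keep], gc[keep], frac=span)
        fitted = np.interp(gc, pts[:, 0], pts[:, 1])
    return fitted


def control_normalize(
    profile: CopyNumberProfile, panel: list[CopyNumberProfile]
) -> CopyNumberProfile:
    """Log2 ratio of the sample against the median of a healthy-control panel.

    Controls must have been run through the same binning, total-count
    normalization and GC correction.  Bins whose panel baseline is (near)
    zero are flagged unusable and excluded from segmentation.
    """
    if profile.has_log2:
        raise AlreadyNormalizedError("profile already carries control-normalized log2 ratios")
    if not panel:
        raise ProfilingError("control panel is empty")
    if "corrected" not in profile.bins.columns:
        raise ProfilingError("run gc_correct before control_normalize")
    mat = []
    for ctrl in panel:
        if "corrected" not in ctrl.bins.columns:
            raise ProfilingError("control profiles must be GC-corrected")
        if len(ctrl.bins) != len(profile.bins):
            raise ProfilingError("control panel binning does not match the sample")
        mat.append(ctrl.bins.corrected.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN unmappable columns
        baseline = np.nanmedian(np.vstack(mat), axis=0)

    out = profile.copy()
    corrected = out.bins.corrected.to_numpy()
    floor = max(np.nanmedian(baseline), 1e-300) * RATIO_FLOOR_REL
    usable = out.bins.mappable.to_numpy() & np.isfinite(corrected) & (baseline > floor)
    log2 = np.full(len(out.bins), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2[usable] = np.log2(np.maximum(corrected[usable], floor) / baseline[usable])
    out.bins["log2"] = log2
    out.bins["usable"] = usable
    return out


# ---------------------------------------------------------------------------
# segmentation: exact penalized least-squares change-point search
# ---------------------------------------------------------------------------

def _weighted_partition(x, w, penalty, min_bins):
    """Optimal partitioning DP minimizing weighted SSE + penalty per segment.

    Returns list of (i, j) half-open index runs.  O(n^2) with vectorized
    inner loop; exact, so it attains the global optimum of the cost.
    """
    n = len(x)
    if n == 0:
        return []
    if n < 2 * min_bins:
        return [(0, n)]
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * x)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * x * x)])

    def seg_cost(i, j):  # cost of x[i:j] as one segment (vectorized over i)
        sw = cw[j] - cw[i]
        swx = cwx[j] - cwx[i]
        swx2 = cwx2[j] - cwx2[i]
        return swx2 - swx * swx / np.maximum(sw, 1e-300)

    best = np.full(n + 1, np.inf)
    best[0] = -penalty  # first segment's penalty cancels
    prev = np.zeros(n + 1, dtype=int)
    for j in range(min_bins, n + 1):
        i = np.arange(0, j - min_bins + 1)
        cand = best[i] + seg_cost(i, j) + penalty
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = i[k]
    runs = []
    j = n
    while j > 0:
        i = prev[j]
        runs.append((int(i), int(j)))
        j = i
    return runs[::-1]


def segmentation_penalty(x: np.ndarray, alpha: float) -> float:
    """Bonferroni-calibrated penalty for one added change point.

    The noise scale is a robust MAD estimate from successive differences, and
    the per-change-point cost is sigma^2 * chi2_isf(alpha / n, 1): under a
    flat signal, the chance that any of ~n candidate breakpoints improves the
    fit by more than the penalty is about alpha.
    """
    n = len(x)
    diffs = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2) if len(diffs) else 0.0
    sigma = max(sigma, 1e-6)
    return sigma**2 * float(sps.chi2.isf(min(alpha / max(n, 2), 0.5), df=1))


def segment_profile(
    profile: CopyNumberProfile, alpha: float = 0.01, min_bins: int = 3
) -> list[Segment]:
    """Segment the usable log2 bins of each chromosome.

    Bins are length-weighted so short terminal bins contribute less to the
    fit; a chromosome with fewer than ``min_bins`` usable bins becomes a
    single segment.  Segment means are the length-weighted means of their
    member bins.
    """
    if not profile.has_log2:
        raise ProfilingError("segment_profile needs control-normalized log2 ratios")
    if min_bins < 2:
        raise ProfilingError("min_bins must be >= 2")
    segments: list[Segment] = []
    all_x = profile.usable().log2.to_numpy()
    if len(all_x) == 0:
        return segments
    penalty = segmentation_penalty(all_x, alpha)
    for chrom in dict.fromkeys(profile.bins.chrom):
        cb = profile.bins[(profile.bins.chrom == chrom) & profile.bins.usable]
        if len(cb) == 0:
            continue
        x = cb.log2.to_numpy()
        w = ((cb.end - cb.start) / profile.bin_width).to_numpy(dtype=float)
        runs = [(0, len(x))] if len(x) < min_bins else _weighted_partition(x, w, penalty, min_bins)
        starts = cb.start.to_numpy()
        ends = cb.end.to_numpy()
        for i, j in runs:
            mean = float(np.average(x[i:j], weights=w[i:j]))
            segments.append(Segment(chrom, int(starts[i]), int(ends[j - 1]), j - i, mean))
    return segments


def rebin(profile: CopyNumberProfile, width: int) -> CopyNumberProfile:
    """Aggregate 50 kb bins into coarser windows (counts summed, GC averaged).

    A coarse bin is mappable when more than half of its length is.  Total
    counts are conserved exactly.
    """
    if width < profile.bin_width or width % profile.bin_width != 0:
        raise ProfilingError(f"width must be a multiple of {profile.bin_width}")
    b = profile.bins
    key = b.start // width * width
    length = b.end - b.start
    grouped = b.assign(_key=key, _len=length, _maplen=length * b.mappable,
                       _gclen=b.gc * length).groupby(["chrom", "_key"], sort=False)
    agg = grouped.agg(count=("count", "sum"), end=("end", "max"), _len=("_len", "sum"),
                      _maplen=("_maplen", "sum"), _gclen=("_gclen", "sum")).reset_index()
    agg = agg.rename(columns={"_key": "start"})
    agg["gc"] = agg._gclen / agg._len
    agg["mappable"] = agg._maplen > 0.5 * agg._len
    # groupby(sort=False) preserves the (chrom, start)-sorted input order
    out = agg[["chrom", "start", "end", "gc", "mappable", "count"]].reset_index(drop=True)
    return CopyNumberProfile(profile.sample_id, out, int(out["count"].sum()),
                             width, dict(profile.metadata))


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def process_sample(profile: CopyNumberProfile, span: float = 0.3) -> CopyNumberProfile:
    """normalize_total + gc_correct, the per-sample half of the pipeline."""
    return gc_correct(normalize_total(profile), span=span)


def aggregate_log2(profile: CopyNumberProfile, width: int) -> CopyNumberProfile:
    """Average control-normalized log2 ratios into coarser windows.

    Normalization and GC correction happen at the native fine bins where the
    LOESS has the most points; this aggregation is the right way to obtain
    e.g. 1 Mb ratios for tumor-fraction estimation.  A coarse window is
    usable when at least a third of its member bins are.
    """
    if not profile.has_log2:
        raise ProfilingError("aggregate_log2 needs control-normalized log2 ratios")
    if width < profile.bin_width or width % profile.bin_width != 0:
        raise ProfilingError(f"width must be a multiple of {profile.bin_width}")
    b = profile.bins
    key = b.start // width * width
    length = b.end - b.start
    grouped = b.assign(_key=key, _len=length, _gclen=b.gc * length,
                       _l2=np.where(b.usable, b.log2, 0.0),
                       _n_usable=b.usable.astype(int)).groupby(
        ["chrom", "_key"], sort=False)
    agg = grouped.agg(count=("count", "sum"), end=("end", "max"), _len=("_len", "sum"),
                      _gclen=("_gclen", "sum"), _l2=("_l2", "sum"),
                      _n_usable=("_n_usable", "sum"), _n=("start", "size")).reset_index()
    agg = agg.rename(columns={"_key": "start"})
    agg["gc"] = agg._gclen / agg._len
    agg["usable"] = agg._n_usable >= np.maximum(1, agg._n / 3)
    agg["mappable"] = agg["usable"]
    with np.errstate(invalid="ignore"):
        agg["log2"] = np.where(agg._n_usable > 0, agg._l2 / agg._n_usable, np.nan)
    out = agg[["chrom", "start", "end", "gc", "mappable", "count", "log2", "usable"]]
    return CopyNumberProfile(profile.sample_id, out.reset_index(drop=True),
                             int(out["count"].sum()), width, dict(profile.metadata))


def normalize_against_panel(
    counts: pd.DataFrame,
    panel_counts: list[pd.DataFrame],
    genome: GenomeModel,
    sample_id: str = "sample",
    bin_width: int | None = None,
    span: float = 0.3,
) -> CopyNumberProfile:
    """Full normalization of one count table against a panel of count tables.

    The per-sample normalization, GC correction and control normalization run
    at the genome's native 50 kb bins; when a coarser ``bin_width`` is
    requested (e.g. 1 Mb for tumor-fraction estimation) the log2 ratios are
    aggregated afterwards with :func:`aggregate_log2`.
    """
    prof = profile_from_counts(counts, genome, sample_id)
    panel = [profile_from_counts(c, genome, f"control{i}") for i, c in enumerate(panel_counts)]
    prof = process_sample(prof, span)
    panel = [process_sample(p, span) for p in panel]
    normed = control_normalize(prof, panel)
    if bin_width is not None and bin_width != genome.bin_width:
        normed = aggregate_log2(normed, bin_width)
    return normed
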