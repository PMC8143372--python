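"""Plain-text readers and writers: BED tracks, count tables, SEG files."""

from __future__ import annotations

import pandas as pd

from .profiling import CopyNumberProfile, Segment


def write_bed(track: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    track[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    """4-column BED-like count table (chrom, start, end, count)."""
    counts[["chrom", "start", "end", "count"]].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:4]) != ["chrom", "start", "end", "count"]:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "count"])
    return df


def write_log2_bins(profile: CopyNumberProfile, path) -> None:
    cols = ["chrom", "start", "end", "log2", "usable"]
    profile.bins[cols].to_csv(path, sep="\t", index=False)


def write_seg(segments: list[Segment], sample_id: str, path) -> None:
    """SEG-format segment table (1-based closed coordinates, as is customary)."""
    rows = [
        dict(sample=sample_id, chrom=s.chrom, start=s.start + 1, end=s.end,
             n_bins=s.n_bins, mean_log2=s.mean_log2)
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t")
    return [
        Segment(r.chrom, int(r.start) - 1, int(r.end), int(r.n_bins), float(r.mean_log2))
        for r in df.itertuples(index=False)
    ]
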