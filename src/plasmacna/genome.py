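"""Synthetic genome models for read-count copy-number analysis.

A :class:`GenomeModel` carries everything the profiling stages need to know
about the reference: chromosome sizes, the fixed 50 kb binning with per-bin
GC content and mappability, a gene annotation with driver / deletion-target
flags, and the repeat tracks (segmental duplications, copy-number-polymorphic
DGV-style entries, PAR mask) used to veto artifact focal calls.

Coordinates are 0-based half-open throughout, BED-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_WIDTH = 50_000

#: Gene symbols used for simulated driver genes.  The first entries are the
#: osimertinib-resistance genes the focal caller cares about downstream.
DRIVER_GENE_POOL = (
    "EGFR", "ERBB2", "MET", "CDK4", "CDK6", "MDM2", "AKT2", "PIK3CA",
    "CDKN2A", "RB1", "KRAS", "BRAF", "MYC", "CCND1", "TP53", "ALK",
)

#: Tumor-suppressor genes recurrently hit by focal deletions.
DELETION_TARGET_GENES = frozenset({"CDKN2A", "RB1", "PTEN"})


class GenomeError(ValueError):
    """Invalid genome construction parameters."""


@dataclass
class GenomeModel:
    """Chromosomes, 50 kb bins and annotation tracks of a (synthetic) genome.

    Attributes
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bins
        DataFrame ``chrom, start, end, gc, mappable`` exactly tiling every
        chromosome with ``bin_width`` windows (terminal bin may be shorter).
    genes
        DataFrame ``chrom, start, end, name, is_driver, is_deletion_target``.
    segdups, dgv, par_mask
        BED-like interval tracks (``chrom, start, end``).
    """

    chromosomes: list[tuple[str, int]]
    bins: pd.DataFrame
    genes: pd.DataFrame
    segdups: pd.DataFrame
    dgv: pd.DataFrame
    par_mask: pd.DataFrame
    bin_width: int = BIN_WIDTH
    lengths: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = dict(self.chromosomes)
        self._validate()

    def _validate(self) -> None:
        b = self.bins
        for chrom, length in self.chromosomes:
            cb = b[b.chrom == chrom]
            if len(cb) == 0:
                raise GenomeError(f"chromosome {chrom} has no bins")
            starts = cb.start.to_numpy()
            ends = cb.end.to_numpy()
            if starts[0] != 0 or ends[-1] != length:
                raise GenomeError(f"bins do not tile {chrom}")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise GenomeError(f"bins on {chrom} overlap or leave gaps")
            if np.any(ends - starts > self.bin_width):
                raise GenomeError(f"bin wider than {self.bin_width} on {chrom}")
        gc = b.gc.to_numpy()
        if np.any((gc < 0) | (gc > 1)):
            raise GenomeError("gc fractions outside [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def _smooth_gc(n: int, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying GC landscape: low-frequency waves around 0.41."""
    pos = np.arange(n)
    gc = np.full(n, 0.41)
    for _ in range(3):
        period = rng.uniform(30, 300)
        gc += rng.uniform(0.01, 0.05) * np.sin(2 * np.pi * pos / period + rng.uniform(0, 2 * np.pi))
    gc += rng.normal(0, 0.01, n)
    return np.clip(gc, 0.30, 0.65)


def _random_track(
    chromosomes: list[tuple[str, int]],
    rng: np.random.Generator,
    target_frac: float,
    size_range: tuple[int, int],
) -> pd.DataFrame:
    """Sorted non-overlapping random intervals covering ~target_frac per chrom."""
    rows = []
    for chrom, length in chromosomes:
        covered = 0
        starts: list[tuple[int, int]] = []
        budget = int(target_frac * length)
        attempts = 0
        while covered < budget and attempts < 10_000:
            attempts += 1
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            start = int(rng.integers(0, max(1, length - size)))
            if any(start < e and start + size > s for s, e in starts):
                continue
            starts.append((start, start + size))
            covered += size
        for s, e in sorted(starts):
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_genome(
    n_chrom: int = 2,
    chrom_length: int = 100_000_000,
    gene_density: float = 2.0,
    seed: int = 0,
    *,
    bin_width: int = BIN_WIDTH,
    unmappable_frac: float = 0.02,
) -> GenomeModel:
    """Build a deterministic synthetic genome.

    Parameters
    ----------
    n_chrom
        Number of chromosomes (``chr1`` ... ``chrN``), each ``chrom_length`` bp.
    gene_density
        Genes per Mb; roughly 10% of genes are flagged as known drivers and
        the canonical deletion targets (CDKN2A, RB1, PTEN) are always placed.
    seed
        Seeds every random choice; identical seeds give identical genomes.
    """
    if n_chrom < 1:
        raise GenomeError("need at least one chromosome")
    if chrom_length < bin_width:
        raise GenomeError(f"chromosome shorter than one {bin_width} bp bin")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom)]

    bin_rows = []
    for chrom, length in chromosomes:
        starts = np.arange(0, length, bin_width)
        ends = np.minimum(starts + bin_width, length)
        gc = _smooth_gc(len(starts), rng)
        mappable = rng.random(len(starts)) >= unmappable_frac
        for s, e, g, m in zip(starts, ends, gc, mappable):
            bin_rows.append((chrom, int(s), int(e), float(g), bool(m)))
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end", "gc", "mappable"])

    # PAR-style mask at the head of the last chromosome (sex-chromosome analog)
    par_chrom, par_len = chromosomes[-1]
    par_span = min(2_000_000, max(bin_width, int(0.02 * par_len)))
    par_mask = pd.DataFrame([(par_chrom, 0, par_span)], columns=["chrom", "start", "end"])
    in_par = (bins.chrom == par_chrom) & (bins.start < par_span)
    bins.loc[in_par, "mappable"] = False

    # genes: drivers drawn from the canonical pool, filler genes numbered
    gene_rows = []
    driver_names = list(DRIVER_GENE_POOL)
    rng.shuffle(driver_names)
    filler_idx = 0
    for chrom, length in chromosomes:
        n_genes = max(1, int(round(gene_density * length / 1_000_000)))
        starts = np.sort(rng.integers(0, length - 100_000, n_genes))
        for s in starts:
            size = int(rng.integers(10_000, 120_000))
            is_driver = rng.random() < 0.10
            if is_driver and driver_names:
                name = driver_names.pop()
            else:
                is_driver = False
                filler_idx += 1
                name = f"G{filler_idx:04d}"
            gene_rows.append((chrom, int(s), int(min(s + size, length)), name, is_driver))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "is_driver"])
    # guarantee at least one driver and the deletion targets somewhere mappable
    must_place = [n for n in ("EGFR",) if n not in set(genes.name)]
    must_place += [n for n in sorted(DELETION_TARGET_GENES) if n not in set(genes.name)]
    for name in must_place:
        chrom, length = chromosomes[int(rng.integers(0, n_chrom))]
        s = int(rng.integers(par_span if chrom == par_chrom else 0, length - 200_000))
        genes.loc[len(genes)] = (chrom, s, s + int(rng.integers(20_000, 120_000)), name,
                                 name not in DELETION_TARGET_GENES or name in ("CDKN2A", "RB1"))
    genes["is_deletion_target"] = genes.name.isin(DELETION_TARGET_GENES)
    genes = genes.sort_values(["chrom", "start"], ignore_index=True)

    segdups = _random_track(chromosomes, rng, 0.03, (20_000, 200_000))
    dgv = _random_track(chromosomes, rng, 0.05, (5_000, 100_000))

    return GenomeModel(chromosomes, bins, genes, segdups, dgv, par_mask, bin_width)
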