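"""Forward simulation of shallow-WGS plasma profiles and patient cohorts.

The count model is the one the profiling stages invert: the expected read
count of a 50 kb bin is proportional to its length, a smooth GC bias curve,
and the mixture copy number ``tf * c + (1 - tf) * 2`` of tumor fraction
``tf`` and tumor copy number ``c``, with Poisson or negative-binomial
sampling on top.  The cohort generator emulates the summary structure of an
osimertinib resistance study: paired pre/post plasma samples, ddPCR mutant
copies linked to tumor fraction through a Gaussian copula, response rates and
exponential survival with a hazard ratio attached to resistance-related SCNA
status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel

LOG2_FLOOR = -8.0

#: Read-depth range of the healthy-control panel (reads per sample).
CONTROL_READ_RANGE = (6_833_913, 6_981_005)

#: Default amplification / deletion gene pools for simulated rrSCNA carriers.
RR_AMP_POOL = ("EGFR", "ERBB2", "MET", "CDK4", "CDK6", "MDM2", "AKT2", "PIK3CA")
RR_DEL_POOL = ("CDKN2A", "RB1")


class SimulationError(ValueError):
    """Invalid simulation inputs (overlapping events, bad parameters)."""


def expected_log2(tf: float, copies: float, floor: float = LOG2_FLOOR) -> float:
    """Expected log2 ratio of a region at tumor copy number ``copies``.

    ``log2((tf * c + (1 - tf) * 2) / 2)``: the plasma signal is a mixture of
    tumor DNA at ``c`` copies and normal DNA at 2 copies.  A homozygous
    deletion at tf=1 would be -inf; the value is clipped at ``floor``.
    """
    if not 0.0 <= tf <= 1.0:
        raise SimulationError(f"tumor fraction {tf} outside [0, 1]")
    if copies < 0:
        raise SimulationError("copy number must be >= 0")
    mix = (tf * copies + (1.0 - tf) * 2.0) / 2.0
    if mix <= 2.0 ** floor:
        return floor
    return math.log2(mix)


@dataclass(frozen=True)
class SimulatedEvent:
    """One simulated copy-number event (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    total_copies: int
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SimulationError("event end must exceed start")
        if self.total_copies < 0:
            raise SimulationError("total_copies must be >= 0")
        if self.total_copies == 2:
            raise SimulationError("2 copies is the background, not an event")
        if not 0.0 < self.clonal_fraction <= 1.0:
            raise SimulationError("clonal_fraction must be in (0, 1]")

    @property
    def effective_copies(self) -> float:
        """Tumor-cell copy number averaged over clonality."""
        return self.clonal_fraction * self.total_copies + (1 - self.clonal_fraction) * 2.0


#: Quadratic GC bias peaking at gc = 0.45 (ascending polynomial coefficients).
DEFAULT_GC_BIAS = (0.595, 1.8, -2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the count simulator.

    ``gc_bias`` holds ascending polynomial coefficients of the relative
    efficiency curve evaluated at the bin GC fraction; ``None`` disables the
    bias.  ``overdispersion`` is the negative-binomial excess-variance
    coefficient (variance = mu + overdispersion * mu^2); 0 means Poisson.
    """

    tumor_fraction: float = 0.0
    total_reads: int = 6_000_000
    gc_bias: tuple[float, ...] | None = DEFAULT_GC_BIAS
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise SimulationError("tumor_fraction must be in [0, 1]")
        if self.total_reads <= 0:
            raise SimulationError("total_reads must be positive")
        if self.overdispersion < 0:
            raise SimulationError("overdispersion must be >= 0")


def gc_bias_curve(gc: np.ndarray, coeffs: tuple[float, ...] | None) -> np.ndarray:
    """Evaluate the bias polynomial, floored at 0.05 to keep rates positive."""
    gc = np.asarray(gc, dtype=float)
    if coeffs is None:
        return np.ones_like(gc)
    out = np.zeros_like(gc)
    for k, c in enumerate(coeffs):
        out += c * gc**k
    return np.maximum(out, 0.05)


def _bin_copy_numbers(genome: GenomeModel, events: list[SimulatedEvent]) -> np.ndarray:
    """Per-bin tumor copy number, with partial bins interpolated by overlap."""
    by_chrom: dict[str, list[SimulatedEvent]] = {}
    for ev in events:
        if ev.chrom not in genome.lengths:
            raise SimulationError(f"event on unknown chromosome {ev.chrom}")
        if ev.end > genome.lengths[ev.chrom]:
            raise SimulationError(f"event beyond end of {ev.chrom}")
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs.sort(key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                raise SimulationError(f"overlapping events on {chrom}")
    copies = np.full(genome.n_bins, 2.0)
    starts = genome.bins.start.to_numpy()
    ends = genome.bins.end.to_numpy()
    chroms = genome.bins.chrom.to_numpy()
    for chrom, evs in by_chrom.items():
        mask = chroms == chrom
        s, e = starts[mask], ends[mask]
        block = copies[mask]
        for ev in evs:
            ov = np.clip(np.minimum(e, ev.end) - np.maximum(s, ev.start), 0, None)
            frac = ov / (e - s)
            block = block + frac * (ev.effective_copies - 2.0)
        copies[mask] = block
    return copies


def expected_bin_counts(
    genome: GenomeModel, events: list[SimulatedEvent], config: SimulationConfig
) -> np.ndarray:
    """Expected counts per bin; exactly sums to ``total_reads`` over mappable bins."""
    copies = _bin_copy_numbers(genome, events)
    tf = config.tumor_fraction
    mix = (tf * copies + (1.0 - tf) * 2.0) / 2.0
    lengths = (genome.bins.end - genome.bins.start).to_numpy(dtype=float)
    rate = (lengths / genome.bin_width) * gc_bias_curve(genome.bins.gc.to_numpy(), config.gc_bias) * mix
    rate = np.where(genome.bins.mappable.to_numpy(), rate, 0.0)
    total = rate.sum()
    if total <= 0:
        raise SimulationError("no mappable bins with positive rate")
    return rate * (config.total_reads / total)


def simulate_counts(
    genome: GenomeModel, events: list[SimulatedEvent], config: SimulationConfig
) -> pd.DataFrame:
    """Draw raw per-bin read counts; returns ``chrom, start, end, count``.

    Unmappable (incl. PAR-masked) bins receive 0 reads.
    """
    mu = expected_bin_counts(genome, events, config)
    rng = np.random.default_rng(config.seed)
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = rng.gamma(shape, np.where(mu > 0, mu, 1e-12) / shape)
        counts = rng.poisson(np.where(mu > 0, lam, 0.0))
    else:
        counts = rng.poisson(mu)
    out = genome.bins[["chrom", "start", "end"]].copy()
    out["count"] = counts.astype(np.int64)
    return out


def simulate_control_panel(
    genome: GenomeModel, n: int = 10, config: SimulationConfig | None = None
) -> list[pd.DataFrame]:
    """Simulate ``n`` healthy-control profiles (tumor fraction 0).

    Read depths default to the narrow band observed in the reference control
    panel (~6.83-6.98M reads per sample).
    """
    if n < 1:
        raise SimulationError("need at least one control")
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    panel = []
    for _ in range(n):
        reads = int(rng.integers(CONTROL_READ_RANGE[0], CONTROL_READ_RANGE[1] + 1))
        sub = replace(config, tumor_fraction=0.0, total_reads=reads,
                      seed=int(rng.integers(0, 2**31)))
        panel.append(simulate_counts(genome, [], sub))
    return panel


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleSummary:
    """Summary-level plasma sample: tumor fraction and SCNA content."""

    tf: float
    rrscna_genes: tuple[str, ...] = ()
    any_scna: bool = False
    timepoint: str = "pre"


@dataclass
class SimulatedPatient:
    patient_id: str
    pre: SampleSummary
    post: SampleSummary
    ddpcr: dict[str, float]
    responder: bool
    pfs_months: float
    os_months: float
    pfs_event: bool
    os_event: bool
    true_rrscna: bool


@dataclass
class SimulatedCohort:
    patients: list[SimulatedPatient]
    seed: int = 0

    def survival_frame(self) -> pd.DataFrame:
        rows = [
            dict(patient_id=p.patient_id, pfs_months=p.pfs_months, pfs_event=p.pfs_event,
                 os_months=p.os_months, os_event=p.os_event, rrscna=int(p.true_rrscna),
                 tf=p.pre.tf, responder=p.responder)
            for p in self.patients
        ]
        return pd.DataFrame(rows)


def simulate_cohort(
    n_patients: int = 43,
    rr_prevalence: float = 10 / 31,
    hr_rrscna: float = 3.33,
    seed: int = 0,
    *,
    target_rho: float = 0.46,
    median_tf_rr: float = 0.17,
    median_tf_other: float = 0.051,
    tf_sigma: float = 0.45,
    response_rate: tuple[float, float] = (0.81, 0.50),
    pfs_median_months: float = 10.4,
    os_median_months: float = 18.7,
    hr_os: float | None = None,
    follow_up_months: float = 38.4,
    scna_rate_nonrr: float = 0.45,
) -> SimulatedCohort:
    """Simulate a paired pre/post plasma cohort with linked survival outcomes.

    rrSCNA-positive patients (prevalence ``rr_prevalence``) draw their tumor
    fractions from a higher log-normal, carry resistance-gene events, respond
    less often and progress/die at ``hr_rrscna`` (resp. ``hr_os``) times the
    baseline exponential hazard.  ddPCR activating-mutation copies/mL share
    the log-TF latent factor (Gaussian copula) with noise calibrated so their
    Spearman correlation with pre-treatment TF targets ``target_rho``; the
    lowest-signal fifth falls below the assay limit and reads 0 copies/mL.
    """
    if n_patients < 2:
        raise SimulationError("need at least two patients")
    if not 0.0 < rr_prevalence < 1.0:
        raise SimulationError("rr_prevalence must be in (0, 1)")
    if hr_rrscna <= 0:
        raise SimulationError("hr_rrscna must be positive")
    hr_os = hr_rrscna if hr_os is None else hr_os

    rng = np.random.default_rng(seed)
    rr = rng.random(n_patients) < rr_prevalence
    z_tf = rng.normal(size=n_patients)

    med = np.where(rr, median_tf_rr, median_tf_other)
    tf_pre = np.clip(np.exp(np.log(med) + tf_sigma * z_tf), 0.004, 0.55)
    tf_post = np.clip(tf_pre * np.exp(rng.normal(0, 0.35, n_patients)), 0.004, 0.55)

    # ddPCR copies share the full log-TF latent (rr-status shift included);
    # the noise scale is calibrated so the rank correlation targets target_rho
    lat = np.log(tf_pre)
    r_pearson = 2.0 * math.sin(math.pi * min(target_rho, 0.99) / 6.0)
    sd_lat = max(float(np.std(lat)), 1e-9)
    sd_noise = sd_lat * math.sqrt(max(1.0 / r_pearson**2 - 1.0, 1e-9))
    z_dd = lat + rng.normal(0, sd_noise, n_patients)
    z_std = (z_dd - z_dd.mean()) / max(float(np.std(z_dd)), 1e-9)
    act_copies = np.exp(np.log(120.0) + 1.8 * z_std)
    # the lowest-signal fifth falls below the assay's limit and reads 0
    act_copies = np.where(z_dd < np.quantile(z_dd, 0.20), 0.0, act_copies)
    t790m = 1.5 + np.exp(np.log(20.0) + 1.5 * rng.normal(size=n_patients))

    rate_pfs = math.log(2) / pfs_median_months * np.where(rr, hr_rrscna, 1.0)
    rate_os = math.log(2) / os_median_months * np.where(rr, hr_os, 1.0)
    pfs = rng.exponential(1.0 / rate_pfs)
    os_t = rng.exponential(1.0 / rate_os)

    p_resp = np.where(rr, response_rate[1], response_rate[0])
    responder = rng.random(n_patients) < p_resp

    patients = []
    for i in range(n_patients):
        if rr[i]:
            k = int(rng.integers(1, 4))
            genes = tuple(rng.choice(RR_AMP_POOL, size=min(k, len(RR_AMP_POOL)), replace=False))
            if rng.random() < 0.15:
                genes = genes + (str(rng.choice(RR_DEL_POOL)),)
        else:
            genes = ()
        any_scna = bool(rr[i] or rng.random() < scna_rate_nonrr)
        # post-sample rrSCNA content persists in roughly half of carriers
        post_genes = genes if (rr[i] and rng.random() < 0.55) else ()
        patients.append(
            SimulatedPatient(
                patient_id=f"P{i + 1:03d}",
                pre=SampleSummary(float(tf_pre[i]), genes, any_scna, "pre"),
                post=SampleSummary(float(tf_post[i]), post_genes,
                                   bool(post_genes) or any_scna, "post"),
                ddpcr={
                    "activating": float(act_copies[i]),
                    "T790M": float(t790m[i]),
                    "C797S": float(np.exp(rng.normal(0, 1.5)) if rng.random() < 0.19 else 0.0),
                },
                responder=bool(responder[i]),
                pfs_months=float(max(min(pfs[i], follow_up_months), 1e-3)),
                os_months=float(max(min(os_t[i], follow_up_months), 1e-3)),
                pfs_event=bool(pfs[i] <= follow_up_months),
                os_event=bool(os_t[i] <= follow_up_months),
                true_rrscna=bool(rr[i]),
            )
        )
    return SimulatedCohort(patients, seed=seed)
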