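"""Per-patient annotation: ddPCR calls, rrSCNA classification, evaluability.

Assembles paired pre/post plasma samples into patient records and computes
the cohort-level counts used in downstream statistics: mutation detection
rates per ddPCR assay, resistance-related SCNA (rrSCNA) carriers, and the
evaluability gate (a patient whose pre-treatment sample has tumor fraction
below 5% AND no SCNAs at all is excluded from outcome analyses, because the
absence of rrSCNAs cannot be asserted there).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .focal import FocalEvent

ASSAYS = ("del19", "L858R", "L861Q", "T790M", "C797S")
#: pseudo-assay for tables that report one pooled activating-mutation column
POOLED_ACTIVATING = "activating"
ACTIVATING_ASSAYS = ("del19", "L858R", "L861Q")
DDPCR_POSITIVITY_COPIES = 1.0       # strictly more than 1 copy/mL
EVALUABILITY_TF_PERCENT = 5.0
CENSORED_TF_LABEL = "<3.0%"


class AnnotationInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tumor fraction values as printed in cohort tables (possibly censored)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorFractionValue:
    """A tumor fraction in percent, possibly censored as '<3.0%'."""

    percent: float | None
    censored: bool = False

    @classmethod
    def parse(cls, text: str) -> "TumorFractionValue":
        text = text.strip()
        if text == CENSORED_TF_LABEL or text in ("<3.0", "<3%"):
            return cls(None, True)
        m = re.fullmatch(r"([0-9.]+)%?", text)
        if not m:
            raise AnnotationInputError(f"cannot parse tumor fraction {text!r}")
        return cls(float(m.group(1)), False)

    @classmethod
    def from_fraction(cls, tf: float) -> "TumorFractionValue":
        if tf < 0.03:
            return cls(None, True)
        return cls(round(100 * tf, 1), False)

    @property
    def label(self) -> str:
        return CENSORED_TF_LABEL if self.censored else f"{self.percent:.1f}%"

    def numeric(self, censor_value: float = 2.9) -> float:
        """Percent value for rank statistics; censored entries share one value."""
        return censor_value if self.censored else float(self.percent)

    def below(self, threshold_percent: float) -> bool:
        return True if self.censored else self.percent < threshold_percent


# ---------------------------------------------------------------------------
# ddPCR
# ---------------------------------------------------------------------------

def call_ddpcr(copies_per_ml: float) -> bool:
    """Positivity call: strictly more than 1 mutant copy per mL of plasma."""
    if copies_per_ml < 0:
        raise AnnotationInputError("copies/mL cannot be negative")
    return copies_per_ml > DDPCR_POSITIVITY_COPIES


@dataclass(frozen=True)
class DdpcrMeasurement:
    assay: str
    copies_per_ml: float
    positive: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS and self.assay != POOLED_ACTIVATING:
            raise AnnotationInputError(f"unknown ddPCR assay {self.assay!r}")
        object.__setattr__(self, "positive", call_ddpcr(self.copies_per_ml))


# ---------------------------------------------------------------------------
# rrSCNA classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RrscnaGeneList:
    """Resistance-related genes, split by event direction."""

    amplification_genes: frozenset[str]
    deletion_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not (self.amplification_genes or self.deletion_genes):
            raise AnnotationInputError("rrSCNA gene list is empty")


DEFAULT_RRSCNA_GENES = RrscnaGeneList(
    amplification_genes=frozenset(
        {"EGFR", "ERBB2", "MET", "CDK4", "CDK6", "MDM2", "AKT2", "PIK3CA"}
    ),
    deletion_genes=frozenset({"CDKN2A", "RB1"}),
)


def classify_rrscna(
    events: list[FocalEvent], gene_list: RrscnaGeneList = DEFAULT_RRSCNA_GENES
) -> list[str]:
    """Resistance-related genes hit by focal events, direction-aware.

    An amplified gene counts only if it is in the amplification list, a
    deleted gene only if in the deletion list.  Deduplicated and sorted, so
    the result is independent of event order.
    """
    hits: set[str] = set()
    for ev in events:
        pool = (gene_list.amplification_genes if ev.direction == "amplification"
                else gene_list.deletion_genes)
        hits.update(set(ev.genes) & pool)
    return sorted(hits)


# ---------------------------------------------------------------------------
# patient records
# ---------------------------------------------------------------------------

@dataclass
class PatientSample:
    """One plasma sample's molecular annotation."""

    patient_id: str
    timepoint: str                              # "pre" | "post"
    tf: TumorFractionValue
    ddpcr: list[DdpcrMeasurement] = field(default_factory=list)
    mutations: frozenset[str] = frozenset()     # used when raw copies unavailable
    focal_events: list[FocalEvent] = field(default_factory=list)
    rrscna_genes: tuple[str, ...] = ()
    any_scna: bool = False

    def detected_mutations(self) -> frozenset[str]:
        if self.ddpcr:
            return frozenset(m.assay for m in self.ddpcr if m.positive)
        return self.mutations

    def activating_detected(self) -> bool:
        return bool(self.detected_mutations() & ({POOLED_ACTIVATING} | set(ACTIVATING_ASSAYS)))

    @property
    def has_rrscna(self) -> bool:
        return bool(self.rrscna_genes)


@dataclass
class PatientRecord:
    patient_id: str
    pre: PatientSample
    post: PatientSample | None = None
    covariates: dict = field(default_factory=dict)
    response: str | None = None                 # CR | PR | SD | PD
    pfs_months: float | None = None
    os_months: float | None = None
    pfs_event: bool | None = None
    os_event: bool | None = None

    @property
    def evaluable(self) -> bool:
        return assess_evaluability(self)


def assess_evaluability(record: PatientRecord) -> bool:
    """A patient is evaluable unless pre-treatment TF < 5% with no SCNAs.

    Censored ("<3.0%") tumor fractions count as below 5%.  The gate uses the
    presence of ANY focal SCNA, not only resistance-related ones: a low-TF
    sample with some SCNA visible is informative, a low-TF sample with none
    may simply lack tumor signal.
    """
    if record.pre is None:
        raise AnnotationInputError(f"patient {record.patient_id} has no pre sample")
    return not (record.pre.tf.below(EVALUABILITY_TF_PERCENT) and not record.pre.any_scna)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    n_patients: int
    n_evaluable: int
    excluded_ids: tuple[str, ...]
    n_pre_rrscna: int
    detection: dict                 # {(timepoint, assay_or_'activating'): count}
    triple_positive_post: int
    c797s_and_rrscna_post: int
    tf_median_rrscna: float
    tf_median_no_rrscna: float


def summarize_cohort(
    records: list[PatientRecord], censor_value: float = 2.9
) -> CohortSummary:
    """Cohort-level counts and medians.

    Detection counts treat a patient as activating-positive when any of the
    del19/L858R/L861Q assays is positive.  TF medians are over evaluable
    patients grouped by pre-treatment rrSCNA status, with censored tumor
    fractions entering at ``censor_value`` percent (both group medians sit
    well above it, so the policy cannot move them).
    """
    if not records:
        raise AnnotationInputError("empty cohort")
    evaluable = [r for r in records if r.evaluable]
    excluded = tuple(r.patient_id for r in records if not r.evaluable)

    detection: dict = {}
    for tp in ("pre", "post"):
        samples = [getattr(r, tp) for r in records if getattr(r, tp) is not None]
        detection[(tp, "activating")] = sum(s.activating_detected() for s in samples)
        for assay in ("T790M", "C797S"):
            detection[(tp, assay)] = sum(assay in s.detected_mutations() for s in samples)

    post = [r.post for r in records if r.post is not None]
    triple = sum(
        s.activating_detected() and {"T790M", "C797S"} <= s.detected_mutations() for s in post
    )
    c797s_rr = sum("C797S" in s.detected_mutations() and s.has_rrscna for s in post)

    rr = [r.pre.tf.numeric(censor_value) for r in evaluable if r.pre.has_rrscna]
    no_rr = [r.pre.tf.numeric(censor_value) for r in evaluable if not r.pre.has_rrscna]
    return CohortSummary(
        n_patients=len(records),
        n_evaluable=len(evaluable),
        excluded_ids=excluded,
        n_pre_rrscna=sum(r.pre.has_rrscna for r in records),
        detection=detection,
        triple_positive_post=triple,
        c797s_and_rrscna_post=c797s_rr,
        tf_median_rrscna=float(np.median(rr)) if rr else float("nan"),
        tf_median_no_rrscna=float(np.median(no_rr)) if no_rr else float("nan"),
    )


# ---------------------------------------------------------------------------
# cohort table dialects
# ---------------------------------------------------------------------------

_NO_RRSCNA = "No rrSCNAs"


def _parse_mutations(text: str) -> frozenset[str]:
    text = text.strip()
    if text in ("-", ""):
        return frozenset()
    muts = {m.strip() for m in text.split(",")}
    unknown = muts - set(ASSAYS)
    if unknown:
        raise AnnotationInputError(f"unknown mutation label(s) {sorted(unknown)}")
    return frozenset(muts)


def _parse_rrscna(text: str) -> tuple[str, ...]:
    text = text.strip()
    if text in (_NO_RRSCNA, "", "-"):
        return ()
    return tuple(g.strip() for g in text.split(","))


def read_cohort_tsv(path_or_buf, dialect: str = "table2") -> pd.DataFrame:
    """Strict reader for the two cohort table layouts.

    ``table2``: per-patient pre/post mutation strings, rrSCNA gene lists and
    (possibly censored) tumor fractions.  ``table3``: pre-treatment ddPCR
    copies/mL, tumor fraction, SCNA yes/no and the published exclusion flag.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str).fillna("")
    if dialect == "table2":
        need = ["patient", "pre_mutation", "pre_rrscna", "pre_tf",
                "post_mutation", "post_rrscna", "post_tf"]
    elif dialect == "table3":
        need = ["patient", "activating_copies_per_ml", "t790m_copies_per_ml",
                "tf", "scna", "excluded"]
    else:
        raise AnnotationInputError(f"unknown dialect {dialect!r}")
    missing = set(need) - set(df.columns)
    if missing:
        raise AnnotationInputError(f"{dialect} table missing columns {sorted(missing)}")
    # validate parseability up front
    for col in [c for c in need if c.endswith("tf") or c == "tf"]:
        df[col].map(TumorFractionValue.parse)
    return df[need]


def records_from_tables(
    mutations: pd.DataFrame, ddpcr: pd.DataFrame | None = None
) -> list[PatientRecord]:
    """Assemble patient records from the table2 layout (+ optional table3)."""
    dd = ddpcr.set_index("patient") if ddpcr is not None else None
    records = []
    for row in mutations.itertuples(index=False):
        pre_rr = _parse_rrscna(row.pre_rrscna)
        post_rr = _parse_rrscna(row.post_rrscna)
        any_scna_pre = bool(pre_rr)
        covariates: dict = {}
        if dd is not None and row.patient in dd.index:
            t3 = dd.loc[row.patient]
            any_scna_pre = str(t3.scna).strip().lower() == "yes"
            covariates["activating_copies_per_ml"] = float(t3.activating_copies_per_ml)
            covariates["t790m_copies_per_ml"] = float(t3.t790m_copies_per_ml)
        pre = PatientSample(
            row.patient, "pre", TumorFractionValue.parse(row.pre_tf),
            mutations=_parse_mutations(row.pre_mutation),
            rrscna_genes=pre_rr, any_scna=any_scna_pre,
        )
        post = PatientSample(
            row.patient, "post", TumorFractionValue.parse(row.post_tf),
            mutations=_parse_mutations(row.post_mutation),
            rrscna_genes=post_rr, any_scna=bool(post_rr),
        )
        records.append(PatientRecord(row.patient, pre, post, covariates=covariates))
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Write records back out in the table2 layout (round-trip safe)."""
    rows = []
    for r in records:
        rows.append(dict(
            patient=r.patient_id,
            pre_mutation=", ".join(sorted(r.pre.detected_mutations(),
                                          key=ASSAYS.index)) or "-",
            pre_rrscna=", ".join(r.pre.rrscna_genes) or _NO_RRSCNA,
            pre_tf=r.pre.tf.label,
            post_mutation=", ".join(sorted(r.post.detected_mutations(),
                                           key=ASSAYS.index)) or "-",
            post_rrscna=", ".join(r.post.rrscna_genes) or _NO_RRSCNA,
            post_tf=r.post.tf.label,
        ))
    return pd.DataFrame(rows)
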