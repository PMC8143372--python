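"""Bundled example cohort: 43 EGFR-mutant lung adenocarcinoma patients.

The package ships the published per-patient measurements of an osimertinib
resistance cohort as two small TSV tables:

* ``osimertinib_cohort_mutations.tsv`` — per patient, the EGFR mutations,
  resistance-related SCNA genes and tumor fraction of the paired
  pre-osimertinib / at-progression plasma samples;
* ``osimertinib_cohort_ddpcr.tsv`` — pre-treatment ddPCR copies/mL of the
  activating mutation and of T790M, tumor fraction, whether any focal SCNA
  was seen, and the published outcome-analysis exclusion flag.

The aggregated response-by-rrSCNA contingency table of the same cohort is
available as :data:`RESPONSE_2X2`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .patients import PatientRecord, read_cohort_tsv, records_from_tables

#: Response (CR/PR vs SD/PD) by pre-treatment rrSCNA status; rows are
#: (no rrSCNAs, rrSCNAs), columns are (CR/PR, SD/PD).
RESPONSE_2X2 = np.array([[17, 4], [5, 5]])


def _data_path(name: str):
    return resources.files("plasmacna.data").joinpath(name)


def load_mutation_table() -> pd.DataFrame:
    """Paired-sample EGFR mutation / rrSCNA / tumor fraction table."""
    with resources.as_file(_data_path("osimertinib_cohort_mutations.tsv")) as p:
        return read_cohort_tsv(p, dialect="table2")


def load_ddpcr_table() -> pd.DataFrame:
    """Pre-treatment ddPCR copies, tumor fraction and SCNA status table."""
    with resources.as_file(_data_path("osimertinib_cohort_ddpcr.tsv")) as p:
        return read_cohort_tsv(p, dialect="table3")


def load_cohort() -> list[PatientRecord]:
    """The 43 patients as assembled :class:`PatientRecord` objects."""
    return records_from_tables(load_mutation_table(), load_ddpcr_table())
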