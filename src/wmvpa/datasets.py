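"""Packaged study fixtures: per-patient decision values and clinical tables.

These small CSVs transcribe the study's printed supplementary tables so
the full evaluation layer runs offline: 19 male and 30 female patients
with their actual outcome labels (+1 favorable / -1 non-favorable) and
out-of-fold SVM decision values, and the per-patient clinical
characteristics (ages, febrile-seizure history, seizure frequency,
follow-up, ILAE outcome class).

One correction is applied to the female decision table: subject F19 is
printed there with a favorable label, but her ILAE outcome class is 3
(non-favorable) in the clinical table, and only the non-favorable label
is consistent with the cohort's published sensitivity/specificity. The
``label`` column carries the corrected value; ``label_printed`` keeps the
original for provenance. The clinical tables are shipped exactly as
printed (including one subject whose printed surgery age precedes the
MRI age).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_decision_table", "load_clinical_table"]

_FILES = {
    ("decisions", "male"): "male_decisions.csv",
    ("decisions", "female"): "female_decisions.csv",
    ("clinical", "male"): "male_clinical.csv",
    ("clinical", "female"): "female_clinical.csv",
}


def _read(kind: str, cohort: str) -> pd.DataFrame:
    if cohort not in ("male", "female"):
        raise ValueError(f"cohort must be 'male' or 'female', got {cohort!r}")
    ref = resources.files("wmvpa.data") / _FILES[(kind, cohort)]
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_decision_table(cohort: str) -> pd.DataFrame:
    """Per-patient actual labels and SVM decision values for one cohort."""
    return _read("decisions", cohort)


def load_clinical_table(cohort: str) -> pd.DataFrame:
    """Per-patient clinical characteristics for one cohort."""
    return _read("clinical", cohort)
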