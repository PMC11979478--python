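"""TF-IDF baseline vectoriser over pre-index code multisets.

Each patient's document is the multiset of codes recorded strictly before the
index date.  Weighting uses the smoothed inverse document frequency

    idf(code) = ln((1 + N) / (1 + df(code))) + 1

with N the number of patients in the fitting corpus and df the number of
patients carrying the code at least once; vectors are term-count × idf,
unit-L2-normalised by default.  By construction the representation is a
cross-sectional snapshot: it is invariant to the dates and ordering of the
pre-index events, which is exactly the limitation the sequence encoder is
meant to overcome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ehr_data import PatientRecord
from .vectors import PatientVector


@dataclass
class IdfTable:
    """Fitted inverse-document-frequency weights."""

    codes: list[str]
    idf: np.ndarray
    df: np.ndarray
    n_patients: int

    def __post_init__(self) -> None:
        self._index = {c: i for i, c in enumerate(self.codes)}

    @property
    def size(self) -> int:
        return len(self.codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"code": self.codes, "idf": self.idf})

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_tfidf(records: list[PatientRecord]) -> IdfTable:
    """Fit idf weights on a derivation cohort (pre-index events only)."""
    if not records:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    df_counts: Counter[str] = Counter()
    for rec in records:
        df_counts.update(set(rec.pre_index_codes()))
    codes = sorted(df_counts)
    n = len(records)
    df = np.asarray([df_counts[c] for c in codes], dtype=np.float64)
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    return IdfTable(codes=codes, idf=idf, df=df, n_patients=n)


def vectorise_tfidf(
    record: PatientRecord, idf: IdfTable, normalise: bool = True
) -> PatientVector:
    """Weight one patient's pre-index code counts by the fitted idf.

    Codes unseen at fit time are dropped.  A patient whose history is empty or
    entirely out-of-vocabulary yields a zero vector flagged for exclusion
    downstream (a zero vector cannot be unit-normalised).
    """
    counts = Counter(record.pre_index_codes())
    values = np.zeros(idf.size)
    for code, tf in counts.items():
        j = idf._index.get(code)
        if j is not None:
            values[j] = tf * idf.idf[j]
    norm = np.linalg.norm(values)
    if norm == 0.0:
        return PatientVector(values, record.patient_id, "tfidf", flagged=True)
    if normalise:
        values = values / norm
    return PatientVector(values, record.patient_id, "tfidf")


def vectorise_cohort(
    records: list[PatientRecord], idf: IdfTable, normalise: bool = True
) -> list[PatientVector]:
    return [vectorise_tfidf(r, idf, normalise) for r in records]
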