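"""Cohort data model, file I/O, eligibility filters, splitting and tokenisation.

The package works from two flat delimited tables:

* a **patient table** with columns ``patient_id, sex, birth_year, practice_id,
  registration_start, index_date, death_date`` (``death_date`` empty = alive),
* an **event table** with columns ``patient_id, date, code, code_type, source``.

Dates are ISO-8601 (``YYYY-MM-DD``).  The *index date* is the date of the first
recorded heart-failure event; everything the vectorisers see precedes it and
every outcome follows it.
"""

from __future__ import annotations

import datetime as dt
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CODE_TYPES = ("diagnosis", "procedure", "medication")
SOURCES = ("primary_care", "secondary_care")

PATIENT_COLUMNS = (
    "patient_id",
    "sex",
    "birth_year",
    "practice_id",
    "registration_start",
    "index_date",
    "death_date",
)
EVENT_COLUMNS = ("patient_id", "date", "code", "code_type", "source")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class RowError(ValueError):
    """A row of an input table could not be parsed (carries the line number)."""


@dataclass(frozen=True)
class CodedEvent:
    """One dated coded record (diagnosis, procedure or medication)."""

    date: dt.date
    code: str
    code_type: str
    source: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("event code must be non-empty")
        if self.code_type not in CODE_TYPES:
            raise ValueError(f"unknown code_type {self.code_type!r}")


@dataclass
class PatientRecord:
    """One patient's demographics, index date and ordered coded events.

    ``events`` are kept sorted by date.  Events strictly before ``index_date``
    form the modelling history; events on/after it are outcome material.
    """

    patient_id: str
    sex: str
    birth_year: int
    practice_id: str
    registration_start: dt.date
    index_date: dt.date
    death_date: dt.date | None = None
    events: list[CodedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events.sort(key=lambda e: e.date)
        if self.age_at_index < 0:
            raise ValueError(
                f"patient {self.patient_id}: negative age at index "
                f"(birth_year {self.birth_year}, index {self.index_date})"
            )

    @property
    def age_at_index(self) -> int:
        return self.index_date.year - self.birth_year

    def age_at(self, date: dt.date) -> int:
        return max(date.year - self.birth_year, 0)

    def pre_index_events(self) -> list[CodedEvent]:
        return [e for e in self.events if e.date < self.index_date]

    def post_index_events(self) -> list[CodedEvent]:
        return [e for e in self.events if e.date >= self.index_date]

    def pre_index_codes(self) -> list[str]:
        return [e.code for e in self.events if e.date < self.index_date]


@dataclass
class IngestReport:
    n_patients: int
    n_events: int
    orphan_patient_ids: list[str]
    flags: list[str] = field(default_factory=list)


def _parse_date(value, file_label: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowError(
            f"{file_label}, line {line}: unparseable date {value!r}"
        ) from exc


def _check_columns(df: pd.DataFrame, required, label: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{label} table is missing mandatory column {col!r}")


def read_cohort(
    patient_table: str,
    event_table: str,
    delimiter: str = ",",
) -> tuple[list[PatientRecord], IngestReport]:
    """Read the two flat tables and join events onto patients.

    Returns the records plus an :class:`IngestReport`; event rows referencing
    patient ids absent from the patient table are reported as orphans, never
    silently dropped.  Records that violate soft invariants (e.g. a death date
    before the index date) are flagged in the report rather than rejected.
    """
    pat = pd.read_csv(patient_table, sep=delimiter, dtype=str, keep_default_na=False)
    evt = pd.read_csv(event_table, sep=delimiter, dtype=str, keep_default_na=False)
    _check_columns(pat, PATIENT_COLUMNS, "patient")
    _check_columns(evt, EVENT_COLUMNS, "event")

    records: dict[str, PatientRecord] = {}
    flags: list[str] = []
    for i, row in enumerate(pat.itertuples(index=False)):
        line = i + 2  # header is line 1
        pid = str(row.patient_id)
        death = row.death_date.strip() if isinstance(row.death_date, str) else ""
        death_date = _parse_date(death, patient_table, line) if death else None
        try:
            birth_year = int(row.birth_year)
        except ValueError as exc:
            raise RowError(
                f"{patient_table}, line {line}: unparseable birth_year "
                f"{row.birth_year!r}"
            ) from exc
        rec = PatientRecord(
            patient_id=pid,
            sex=str(row.sex),
            birth_year=birth_year,
            practice_id=str(row.practice_id),
            registration_start=_parse_date(row.registration_start, patient_table, line),
            index_date=_parse_date(row.index_date, patient_table, line),
            death_date=death_date,
        )
        if rec.death_date is not None and rec.death_date < rec.index_date:
            flags.append(f"patient {pid}: death_date precedes index_date")
        if rec.index_date < rec.registration_start:
            flags.append(f"patient {pid}: index_date precedes registration_start")
        records[pid] = rec

    orphans: list[str] = []
    for i, row in enumerate(evt.itertuples(index=False)):
        line = i + 2
        pid = str(row.patient_id)
        event = CodedEvent(
            date=_parse_date(row.date, event_table, line),
            code=str(row.code),
            code_type=str(row.code_type),
            source=str(row.source),
        )
        if pid in records:
            records[pid].events.append(event)
        else:
            orphans.append(pid)

    out = list(records.values())
    for rec in out:
        rec.events.sort(key=lambda e: e.date)
    report = IngestReport(
        n_patients=len(out),
        n_events=len(evt) - len(orphans),
        orphan_patient_ids=sorted(set(orphans)),
        flags=flags,
    )
    return out, report


def write_cohort(
    records: list[PatientRecord],
    patient_table: str,
    event_table: str,
    delimiter: str = ",",
) -> None:
    """Write records back to the two flat tables (round-trips ``read_cohort``)."""
    pat_rows = [
        {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "birth_year": r.birth_year,
            "practice_id": r.practice_id,
            "registration_start": r.registration_start.isoformat(),
            "index_date": r.index_date.isoformat(),
            "death_date": r.death_date.isoformat() if r.death_date else "",
        }
        for r in records
    ]
    evt_rows = [
        {
            "patient_id": r.patient_id,
            "date": e.date.isoformat(),
            "code": e.code,
            "code_type": e.code_type,
            "source": e.source,
        }
        for r in records
        for e in r.events
    ]
    pd.DataFrame(pat_rows, columns=list(PATIENT_COLUMNS)).to_csv(
        patient_table, sep=delimiter, index=False
    )
    pd.DataFrame(evt_rows, columns=list(EVENT_COLUMNS)).to_csv(
        event_table, sep=delimiter, index=False
    )


# ---------------------------------------------------------------------------
# Cohort eligibility filters
# ---------------------------------------------------------------------------

@dataclass
class AttritionReport:
    """Per-filter exclusion counts (an attrition ledger)."""

    n_input: int = 0
    excluded_age: int = 0
    excluded_registration: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.excluded_age - self.excluded_registration

    def as_text(self) -> str:
        return (
            f"input patients: {self.n_input}\n"
            f"excluded, age at index below minimum: {self.excluded_age}\n"
            f"excluded, registration shorter than minimum: {self.excluded_registration}\n"
            f"retained: {self.n_retained}\n"
        )


def _add_months(date: dt.date, months: int) -> dt.date:
    month = date.month - 1 + months
    year = date.year + month // 12
    month = month % 12 + 1
    day = min(date.day, [31, 29 if year % 4 == 0 and (year % 100 != 0 or year % 400 == 0) else 28,
                         31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1])
    return dt.date(year, month, day)


def apply_cohort_filters(
    records: list[PatientRecord],
    min_age: int = 35,
    min_registration_months: int = 12,
) -> tuple[list[PatientRecord], AttritionReport]:
    """Apply the eligibility filters: age at index >= ``min_age`` years and at
    least ``min_registration_months`` months of registration before the index
    date.  Exclusions are applied in that order and counted once each."""
    report = AttritionReport(n_input=len(records))
    kept: list[PatientRecord] = []
    for rec in records:
        if rec.age_at_index < min_age:
            report.excluded_age += 1
            continue
        if rec.index_date < _add_months(rec.registration_start, min_registration_months):
            report.excluded_registration += 1
            continue
        kept.append(rec)
    return kept, report


# ---------------------------------------------------------------------------
# Practice-level derivation/validation split
# ---------------------------------------------------------------------------

@dataclass
class CohortSplit:
    """Practice-level partition into derivation and validation cohorts."""

    derivation: list[str]
    validation: list[str]
    practice_assignment: dict[str, str]  # practice_id -> {"derivation","validation"}

    def __post_init__(self) -> None:
        overlap = set(self.derivation) & set(self.validation)
        if overlap:
            raise ValueError(f"patients in both partitions: {sorted(overlap)[:5]}")


def split_by_practice(
    records: list[PatientRecord],
    derivation_fraction: float = 0.8,
    seed: int = 0,
) -> CohortSplit:
    """Randomly assign whole practices (not patients) to derivation/validation.

    Models are fit on the derivation side only and evaluated on validation;
    splitting at practice level keeps the two sides geographically disjoint.
    Deterministic for a given seed.
    """
    if not 0 < derivation_fraction <= 1:
        raise ValueError("derivation_fraction must be in (0, 1]")
    practices = sorted({r.practice_id for r in records})
    if derivation_fraction < 1 and len(practices) < 2:
        raise ValueError(
            "cannot split at practice level: fewer than two practices"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(practices))
    if derivation_fraction == 1:
        n_der = len(practices)
    else:
        n_der = int(round(derivation_fraction * len(practices)))
        n_der = min(max(n_der, 1), len(practices) - 1)
    der_practices = {practices[i] for i in order[:n_der]}
    assignment = {
        p: ("derivation" if p in der_practices else "validation") for p in practices
    }
    derivation = [r.patient_id for r in records if r.practice_id in der_practices]
    validation = [r.patient_id for r in records if r.practice_id not in der_practices]
    return CohortSplit(derivation, validation, assignment)


# ---------------------------------------------------------------------------
# Vocabulary and tokenisation
# ---------------------------------------------------------------------------

PAD, CLS, SEP, UNK = 0, 1, 2, 3
N_RESERVED = 4
SPECIAL_TOKENS = {"[PAD]": PAD, "[CLS]": CLS, "[SEP]": SEP, "[UNK]": UNK}
MAX_AGE = 120


@dataclass
class Vocabulary:
    """Code-to-id mapping plus the value ranges of the age/year/visit channels.

    Ids 0..3 are the reserved ``[PAD] [CLS] [SEP] [UNK]`` tokens; codes occupy
    contiguous ids from 4 ordered by descending corpus frequency then
    lexicographically.
    """

    code_to_id: dict[str, int]
    min_year: int
    max_year: int
    max_visit: int

    @property
    def size(self) -> int:
        return N_RESERVED + len(self.code_to_id)

    @property
    def n_age_buckets(self) -> int:
        return MAX_AGE + 1

    @property
    def n_year_buckets(self) -> int:
        return self.max_year - self.min_year + 1

    @property
    def n_visit_buckets(self) -> int:
        return self.max_visit + 1

    def encode_code(self, code: str) -> int:
        return self.code_to_id.get(code, UNK)

    def encode_age(self, age: int) -> int:
        return int(np.clip(age, 0, MAX_AGE))

    def encode_year(self, year: int) -> int:
        return int(np.clip(year, self.min_year, self.max_year) - self.min_year)

    def encode_visit(self, visit: int) -> int:
        return int(min(visit, self.max_visit))

    @property
    def id_to_code(self) -> dict[int, str]:
        return {v: k for k, v in self.code_to_id.items()}


def build_vocabulary(
    records: list[PatientRecord], min_code_count: int = 5
) -> Vocabulary:
    """Build the code vocabulary from pre-index events.

    Codes occurring fewer than ``min_code_count`` times in the corpus map to
    ``[UNK]``.  Ordering is by descending frequency then lexicographic, so the
    mapping is deterministic for a given corpus.
    """
    if not records:
        raise ValueError("cannot build a vocabulary from an empty cohort")
    counts: Counter[str] = Counter()
    years: list[int] = []
    max_visit = 1
    for rec in records:
        pre = rec.pre_index_events()
        counts.update(e.code for e in pre)
        years.append(rec.index_date.year)
        years.extend(e.date.year for e in pre)
        max_visit = max(max_visit, len({e.date for e in pre}))
    surviving = sorted(
        (c for c, n in counts.items() if n >= min_code_count),
        key=lambda c: (-counts[c], c),
    )
    code_to_id = {c: N_RESERVED + i for i, c in enumerate(surviving)}
    return Vocabulary(
        code_to_id=code_to_id,
        min_year=min(years),
        max_year=max(years),
        max_visit=max_visit,
    )


@dataclass
class TokenSequence:
    """Encoder input: four parallel integer streams of equal length.

    ``token_ids`` carry the codes (with a leading ``[CLS]``), ``age_ids`` the
    patient's age in whole years at each event, ``year_ids`` the calendar-year
    bucket and ``visit_ids`` the visit position (distinct calendar date) the
    event belongs to.  The ``[CLS]`` position carries the age/year at index and
    visit 0.
    """

    token_ids: np.ndarray
    age_ids: np.ndarray
    year_ids: np.ndarray
    visit_ids: np.ndarray
    patient_id: str
    empty_history: bool = False

    def __post_init__(self) -> None:
        lens = {
            len(self.token_ids),
            len(self.age_ids),
            len(self.year_ids),
            len(self.visit_ids),
        }
        if len(lens) != 1:
            raise ValueError("token/age/year/visit streams must share one length")

    def __len__(self) -> int:
        return len(self.token_ids)

    def padded(self, length: int) -> "TokenSequence":
        """Right-pad every stream with PAD/0 to ``length``."""
        if length < len(self):
            raise ValueError("pad length shorter than sequence")
        pad = length - len(self)
        def _p(a):
            return np.concatenate([a, np.zeros(pad, dtype=np.int64)])
        return replace(
            self,
            token_ids=_p(self.token_ids),
            age_ids=_p(self.age_ids),
            year_ids=_p(self.year_ids),
            visit_ids=_p(self.visit_ids),
        )


def tokenise_patient(
    record: PatientRecord,
    vocab: Vocabulary,
    max_len: int = 128,
    include_cls: bool = True,
    sep_between_visits: bool = False,
) -> TokenSequence:
    """Encode one patient's pre-index history as four aligned token streams.

    Only events strictly before the index date are encoded.  Events sharing a
    calendar date share a visit id; visit ids start at 1 and increment by one
    per distinct date.  When the sequence exceeds ``max_len`` the most recent
    tokens are kept (the leading ``[CLS]`` always survives truncation).
    A patient with no pre-index events yields the minimal ``[CLS]``-only
    sequence with ``empty_history=True``.
    """
    pre = record.pre_index_events()
    toks: list[int] = []
    ages: list[int] = []
    yrs: list[int] = []
    visits: list[int] = []
    visit = 0
    last_date: dt.date | None = None
    for e in pre:
        if e.date != last_date:
            if sep_between_visits and last_date is not None:
                toks.append(SEP)
                ages.append(vocab.encode_age(record.age_at(last_date)))
                yrs.append(vocab.encode_year(last_date.year))
                visits.append(vocab.encode_visit(visit))
            visit += 1
            last_date = e.date
        toks.append(vocab.encode_code(e.code))
        ages.append(vocab.encode_age(record.age_at(e.date)))
        yrs.append(vocab.encode_year(e.date.year))
        visits.append(vocab.encode_visit(visit))

    budget = max_len - (1 if include_cls else 0)
    if len(toks) > budget:  # keep the most recent history
        toks, ages, yrs, visits = (
            toks[-budget:],
            ages[-budget:],
            yrs[-budget:],
            visits[-budget:],
        )
    if include_cls:
        toks = [CLS] + toks
        ages = [vocab.encode_age(record.age_at_index)] + ages
        yrs = [vocab.encode_year(record.index_date.year)] + yrs
        visits = [0] + visits

    empty = len(pre) == 0
    if empty:
        warnings.warn(
            f"patient {record.patient_id} has no pre-index events", stacklevel=2
        )
    return TokenSequence(
        token_ids=np.asarray(toks, dtype=np.int64),
        age_ids=np.asarray(ages, dtype=np.int64),
        year_ids=np.asarray(yrs, dtype=np.int64),
        visit_ids=np.asarray(visits, dtype=np.int64),
        patient_id=record.patient_id,
        empty_history=empty,
    )
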