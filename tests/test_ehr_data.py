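import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ehrsubtype.ehr_data import (
    CLS,
    UNK,
    CodedEvent,
    PatientRecord,
    RowError,
    SchemaError,
    apply_cohort_filters,
    build_vocabulary,
    read_cohort,
    split_by_practice,
    tokenise_patient,
    write_cohort,
)
from ehrsubtype.synth_cohort import simulate, strong_signal_config

PATIENT_HEADER = (
    "patient_id,sex,birth_year,practice_id,registration_start,index_date,death_date"
)
EVENT_HEADER = "patient_id,date,code,code_type,source"


def _write(tmp_path, patients_rows, events_rows):
    pfile = tmp_path / "patients.csv"
    efile = tmp_path / "events.csv"
    pfile.write_text("\n".join([PATIENT_HEADER] + patients_rows) + "\n")
    efile.write_text("\n".join([EVENT_HEADER] + events_rows) + "\n")
    return str(pfile), str(efile)


@pytest.fixture()
def three_patient_files(tmp_path):
    patients = [
        "P1,female,1950,G1,2000-01-01,2010-06-01,",
        "P2,male,1940,G1,2001-01-01,2011-01-01,2011-06-15",
        "P3,female,1960,G2,2005-01-01,2012-01-01,",
    ]
    # interleaved across patients and out of date order within P1
    events = [
        "P1,2009-07-20,C,diagnosis,primary_care",
        "P2,2010-03-01,A,medication,primary_care",
        "P1,2008-03-10,A,diagnosis,primary_care",
        "P1,2008-03-10,B,procedure,secondary_care",
    ]
    return _write(tmp_path, patients, events)


class TestReadCohort:
    def test_joins_and_sorts_events(self, three_patient_files):
        records, report = read_cohort(*three_patient_files)
        by_id = {r.patient_id: r for r in records}
        assert report.n_patients == 3
        assert [len(by_id[p].events) for p in ("P1", "P2", "P3")] == [3, 1, 0]
        dates = [e.date for e in by_id["P1"].events]
        assert dates == sorted(dates)
        assert by_id["P2"].death_date == dt.date(2011, 6, 15)
        assert by_id["P1"].death_date is None

    def test_orphan_event_reported(self, tmp_path):
        pfile, efile = _write(
            tmp_path,
            ["P1,female,1950,G1,2000-01-01,2010-06-01,"],
            ["P9,2009-01-01,A,diagnosis,primary_care"],
        )
        records, report = read_cohort(pfile, efile)
        assert report.orphan_patient_ids == ["P9"]
        assert len(records[0].events) == 0

    def test_missing_column_names_it(self, tmp_path):
        pfile = tmp_path / "p.csv"
        pfile.write_text("patient_id,sex\nP1,female\n")
        efile = tmp_path / "e.csv"
        efile.write_text(EVENT_HEADER + "\n")
        with pytest.raises(SchemaError, match="birth_year"):
            read_cohort(str(pfile), str(efile))

    def test_bad_date_carries_line_number(self, tmp_path):
        pfile, efile = _write(
            tmp_path,
            ["P1,female,1950,G1,2000-01-01,2010-06-01,"],
            [
                "P1,2009-01-01,A,diagnosis,primary_care",
                "P1,not-a-date,B,diagnosis,primary_care",
            ],
        )
        with pytest.raises(RowError, match="line 3"):
            read_cohort(pfile, efile)

    def test_roundtrip(self, tmp_path):
        cfg = strong_signal_config(n_patients=25, seed=3)
        records, _ = simulate(cfg)
        p1, e1 = str(tmp_path / "p1.csv"), str(tmp_path / "e1.csv")
        write_cohort(records, p1, e1)
        back, report = read_cohort(p1, e1)
        assert not report.orphan_patient_ids
        p2, e2 = str(tmp_path / "p2.csv"), str(tmp_path / "e2.csv")
        write_cohort(back, p2, e2)
        pd.testing.assert_frame_equal(pd.read_csv(p1), pd.read_csv(p2))
        pd.testing.assert_frame_equal(pd.read_csv(e1), pd.read_csv(e2))


def _mk_patient(pid="P1", birth=1950, index=dt.date(2010, 6, 1),
                reg=dt.date(2000, 1, 1), practice="G1", events=()):
    return PatientRecord(
        patient_id=pid, sex="female", birth_year=birth, practice_id=practice,
        registration_start=reg, index_date=index, events=list(events),
    )


class TestFilters:
    def test_age_minimum_is_35(self):
        young = _mk_patient(birth=1976, index=dt.date(2010, 6, 1))  # age 34
        old = _mk_patient(pid="P2", birth=1975, index=dt.date(2010, 6, 1))  # 35
        kept, report = apply_cohort_filters([young, old])
        assert [r.patient_id for r in kept] == ["P2"]
        assert report.excluded_age == 1

    def test_registration_minimum_is_12_months(self):
        short = _mk_patient(reg=dt.date(2009, 7, 2), index=dt.date(2010, 6, 1))
        exact = _mk_patient(pid="P2", reg=dt.date(2009, 6, 1),
                            index=dt.date(2010, 6, 1))
        kept, report = apply_cohort_filters([short, exact])
        assert [r.patient_id for r in kept] == ["P2"]
        assert report.excluded_registration == 1

    def test_empty_input(self):
        kept, report = apply_cohort_filters([])
        assert kept == [] and report.n_input == 0
        assert report.excluded_age == report.excluded_registration == 0

    def test_idempotent(self, preset_cohort):
        _, records, _ = preset_cohort
        once, _ = apply_cohort_filters(records)
        twice, rep = apply_cohort_filters(once)
        assert [r.patient_id for r in twice] == [r.patient_id for r in once]
        assert rep.excluded_age == 0 and rep.excluded_registration == 0


class TestSplit:
    @pytest.fixture()
    def ten_practice_records(self):
        return [
            _mk_patient(pid=f"P{i}", practice=f"G{i % 10}") for i in range(50)
        ]

    def test_eight_two_split_and_determinism(self, ten_practice_records):
        s1 = split_by_practice(ten_practice_records, 0.8, seed=5)
        s2 = split_by_practice(ten_practice_records, 0.8, seed=5)
        der_practices = {
            p for p, c in s1.practice_assignment.items() if c == "derivation"
        }
        assert len(der_practices) == 8
        assert s1.derivation == s2.derivation and s1.validation == s2.validation

    @pytest.mark.parametrize("seed", range(5))
    def test_practices_never_straddle(self, ten_practice_records, seed):
        split = split_by_practice(ten_practice_records, 0.8, seed=seed)
        by_id = {r.patient_id: r.practice_id for r in ten_practice_records}
        der = {by_id[p] for p in split.derivation}
        val = {by_id[p] for p in split.validation}
        assert not der & val

    def test_fraction_one_puts_everyone_in_derivation(self, ten_practice_records):
        split = split_by_practice(ten_practice_records, 1.0, seed=0)
        assert len(split.derivation) == 50 and split.validation == []

    def test_single_practice_errors(self):
        recs = [_mk_patient(pid=f"P{i}", practice="G0") for i in range(5)]
        with pytest.raises(ValueError, match="practice"):
            split_by_practice(recs, 0.8, seed=0)


def _ev(date, code):
    return CodedEvent(date, code, "diagnosis", "primary_care")


class TestVocabulary:
    def test_min_count_threshold(self):
        events = [_ev(dt.date(2009, 1, 1 + i), "A") for i in range(5)]
        events += [_ev(dt.date(2009, 2, 1), "B")]
        rec = _mk_patient(events=events)
        vocab = build_vocabulary([rec], min_code_count=2)
        assert "A" in vocab.code_to_id and "B" not in vocab.code_to_id
        assert vocab.encode_code("B") == UNK

    def test_deterministic_and_reserved(self, preset_cohort):
        _, records, _ = preset_cohort
        v1 = build_vocabulary(records, 5)
        v2 = build_vocabulary(records, 5)
        assert v1.code_to_id == v2.code_to_id
        assert min(v1.code_to_id.values()) == 4  # reserved ids 0..3
        ids = sorted(v1.code_to_id.values())
        assert ids == list(range(4, 4 + len(ids)))  # contiguous bijection

    def test_hand_counted_size(self):
        r1 = _mk_patient(pid="P1", events=[_ev(dt.date(2009, 1, 1), "A"),
                                           _ev(dt.date(2009, 1, 2), "B")])
        r2 = _mk_patient(pid="P2", events=[_ev(dt.date(2009, 1, 1), "A"),
                                           _ev(dt.date(2009, 1, 3), "C")])
        r3 = _mk_patient(pid="P3", events=[_ev(dt.date(2009, 2, 1), "A")])
        vocab = build_vocabulary([r1, r2, r3], min_code_count=1)
        # 4 reserved + 3 distinct surviving codes
        assert vocab.size == 7


class TestTokenise:
    def test_same_day_events_share_visit(self):
        d1, d2 = dt.date(2009, 3, 10), dt.date(2009, 7, 20)
        rec = _mk_patient(events=[_ev(d1, "A"), _ev(d1, "B"), _ev(d2, "C")])
        vocab = build_vocabulary([rec], 1)
        seq = tokenise_patient(rec, vocab, max_len=16)
        assert seq.visit_ids.tolist() == [0, 1, 1, 2]  # CLS then visits

    def test_post_index_events_excluded(self):
        rec = _mk_patient(
            index=dt.date(2010, 6, 1),
            events=[_ev(dt.date(2009, 1, 1), "A"), _ev(dt.date(2010, 6, 1), "B"),
                    _ev(dt.date(2011, 1, 1), "C")],
        )
        vocab = build_vocabulary([rec], 1)
        seq = tokenise_patient(rec, vocab, max_len=16)
        assert len(seq) == 2  # CLS + the single pre-index event
        assert vocab.encode_code("A") in seq.token_ids

    def test_hand_written_four_streams(self):
        # birth 1950; index 2010-06-01; visits 2008-03-10 (A,B), 2009-07-20 (C)
        d1, d2 = dt.date(2008, 3, 10), dt.date(2009, 7, 20)
        rec = _mk_patient(events=[_ev(d1, "A"), _ev(d1, "B"), _ev(d2, "C")])
        vocab = build_vocabulary([rec], 1)
        seq = tokenise_patient(rec, vocab, max_len=16)
        assert seq.token_ids.tolist() == [CLS, 4, 5, 6]  # A,B,C lexicographic
        assert seq.age_ids.tolist() == [60, 58, 58, 59]
        assert seq.year_ids.tolist() == [2, 0, 0, 1]  # years 2008..2010
        assert seq.visit_ids.tolist() == [0, 1, 1, 2]

    def test_truncation_keeps_most_recent(self):
        events = [_ev(dt.date(2009, 1, 1) + dt.timedelta(days=i), f"C{i}")
                  for i in range(10)]
        rec = _mk_patient(events=events)
        vocab = build_vocabulary([rec], 1)
        seq = tokenise_patient(rec, vocab, max_len=4)
        assert len(seq) == 4
        kept = [vocab.id_to_code[t] for t in seq.token_ids[1:]]
        assert kept == ["C7", "C8", "C9"]
        assert seq.token_ids[0] == CLS

    def test_empty_history_flagged(self):
        rec = _mk_patient(events=[])
        other = _mk_patient(pid="P2", events=[_ev(dt.date(2009, 1, 1), "A")])
        vocab = build_vocabulary([rec, other], 1)
        with pytest.warns(UserWarning, match="no pre-index"):
            seq = tokenise_patient(rec, vocab, max_len=8)
        assert seq.empty_history and len(seq) == 1

    def test_streams_on_random_cohort(self, preset_cohort):
        cfg, records, _ = preset_cohort
        vocab = build_vocabulary(records, 5)
        for rec in records[:100]:
            seq = tokenise_patient(rec, vocab, max_len=64)
            assert len(seq) <= 64
            assert np.all(np.diff(seq.visit_ids) >= 0)
            assert (
                len(seq.age_ids) == len(seq.year_ids) == len(seq.visit_ids)
                == len(seq.token_ids)
            )
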