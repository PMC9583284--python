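"""Shared fixtures and record-building helpers."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

_COUNTER = itertools.count()

_DEFAULTS = {
    "source": "ED",
    "provider_code": "TRUST00",
    "provider_patient_id": None,
    "nhs_number": None,
    "dob": None,
    "age_at_activity": None,
    "first_name": None,
    "last_name": None,
    "sex": None,
    "postcode": None,
    "start_datetime": "2016-06-01 12:00",
    "end_datetime": None,
    "site": "SITE00",
    "conveyed": pd.NA,
    "admission_method": None,
    "clinical_key": "GENMED|D00",
    "disposition": None,
}


def rec(**kwargs) -> dict:
    """One record row with sensible defaults; override any field."""
    row = dict(_DEFAULTS)
    row["record_id"] = f"{kwargs.get('source', row['source'])}-{next(_COUNTER):07d}"
    row.update(kwargs)
    return row


def records_frame(rows) -> pd.DataFrame:
    """Build a pipeline-shaped DataFrame from ``rec()`` rows."""
    df = pd.DataFrame(rows)
    for col in ("dob", "start_datetime", "end_datetime"):
        df[col] = pd.to_datetime(df[col])
    df["conveyed"] = df["conveyed"].astype("boolean")
    df["age_at_activity"] = df["age_at_activity"].astype("Int64")
    return df


@pytest.fixture
def make_records():
    return records_frame


# a handful of valid NHS numbers (mod-11) reused across tests
VALID_NHS = [
    "0000000000",
    "0000000019",
    "0000000027",
    "0000000035",
    "0000000043",
    "0000000108",
    "0000000116",
    "0000000205",
]


def deterministic_fixture():
    """Hand-crafted 20-record case with a fully specified expected outcome.

    Exercises every resolution step at least once: NHS-number seeding (S1),
    approximate-birth-year rescue (S2), provider-ID match (S3), full
    demographic match (S4), partial demographic match (S5), clustering of
    the leftovers (S6) and singletons (S7) — including the ambiguity and
    source-exclusion edge cases (twins sharing sex/dob/postcode, a shared
    provider patient ID pointing at two entities, an ambulance record
    barred from demographic matching).

    Returns (records, expected_entities, expected_steps) where
    expected_entities is a set of frozensets of record_ids.
    """
    N1, N2, N3, N4, N5 = (
        "0000000019",
        "0000000027",
        "0000000035",
        "0000000043",
        "0000000108",
    )
    D1, D3, D4, D5, D9 = "1980-05-10", "2000-01-01", "1970-07-07", "1960-06-06", "1955-03-03"
    PC1, PC2, PC3, PC4 = "AA1 1AA", "BB2 2BB", "CC3 3CC", "EE5 5EE"

    rows = [
        # E1: seeded by r01; grown by every step S2-S5 plus an ambulance S1
        dict(record_id="r01", source="ED", nhs_number=N1, dob=D1, provider_code="TRUST00",
             provider_patient_id="0001", first_name="ALICE", last_name="SMITH",
             sex="female", postcode=PC1, age_at_activity=36),
        dict(record_id="r02", source="IP", nhs_number=N1, dob=D1, provider_code="TRUST05",
             provider_patient_id="0005", admission_method="emergency"),
        dict(record_id="r03", source="NHS111", nhs_number=N1, dob=None, age_at_activity=35,
             start_datetime="2015-06-01 10:00", site=None, provider_code="NHS111PROV"),
        dict(record_id="r04", source="ED", nhs_number=None, dob=D1, provider_code="TRUST00",
             provider_patient_id="0001"),
        dict(record_id="r05", source="ED", nhs_number=None, dob=D1, first_name="ALICE",
             last_name="SMITH", sex="female", postcode=PC1),
        dict(record_id="r06", source="NHS111", nhs_number=None, dob=D1, sex="female",
             postcode=PC1, site=None, provider_code="NHS111PROV"),
        # E2: shares dob D1 with E1 (distinct NHS number) and shares a
        # provider patient id with r02 -> makes r20's S3 lookup ambiguous
        dict(record_id="r07", source="ED", nhs_number=N2, dob=D1, sex="male", postcode=PC2,
             first_name="BOB", last_name="JONES"),
        dict(record_id="r08", source="IP", nhs_number=N2, dob=D1, provider_code="TRUST05",
             provider_patient_id="0005", admission_method="emergency"),
        # twins E3/E4 share (sex, dob, postcode); r09 matches both -> stays out
        dict(record_id="r09", source="NHS111", sex="female", dob=D3, postcode=PC3,
             site=None, provider_code="NHS111PROV"),
        dict(record_id="r10", source="ED", nhs_number=N3, dob=D3, sex="female", postcode=PC3,
             first_name="CARA", last_name="KELLY"),
        dict(record_id="r11", source="ED", nhs_number=N4, dob=D3, sex="female", postcode=PC3,
             first_name="DANA", last_name="KELLY"),
        # S6 chain: r12-r13 share (sex, dob, postcode); r13-r14 share provider id
        dict(record_id="r12", source="ED", sex="male", dob=D4, postcode=PC4),
        dict(record_id="r13", source="IP", sex="male", dob=D4, postcode=PC4,
             provider_code="TRUST07", provider_patient_id="0007",
             admission_method="emergency"),
        dict(record_id="r14", source="NHS111", dob=D4, provider_code="TRUST07",
             provider_patient_id="0007", site=None),
        # ambulance records: S1 works; demographic matching is barred
        dict(record_id="r15", source="AMB", nhs_number=N1, dob=D1, conveyed=True,
             site="SITE00", provider_code="AMBPROV", provider_patient_id=None,
             end_datetime="2016-06-01 12:30"),
        dict(record_id="r16", source="AMB", nhs_number=None, dob=D1, first_name="ALICE",
             last_name="SMITH", sex="female", postcode=PC1, conveyed=False,
             provider_code="AMBPROV", provider_patient_id=None, site=None),
        # shares nothing with anyone
        dict(record_id="r17", source="ED", dob=D9, first_name="EVE", last_name="FOX",
             sex="female", postcode=PC4),
        # E5: a plain two-record NHS-number entity
        dict(record_id="r18", source="NHS111", nhs_number=N5, dob=D5, site=None,
             provider_code="NHS111PROV"),
        dict(record_id="r19", source="IP", nhs_number=N5, dob=D5,
             admission_method="emergency"),
        # provider-id key points at both E1 (r02) and E2 (r08): not unique
        dict(record_id="r20", source="ED", nhs_number=None, dob=D1, provider_code="TRUST05",
             provider_patient_id="0005"),
    ]
    records = records_frame([{**_DEFAULTS, **r} for r in rows])

    expected_entities = {
        frozenset({"r01", "r02", "r03", "r04", "r05", "r06", "r15"}),
        frozenset({"r07", "r08"}),
        frozenset({"r10"}),
        frozenset({"r11"}),
        frozenset({"r12", "r13", "r14"}),
        frozenset({"r18", "r19"}),
        frozenset({"r09"}),
        frozenset({"r16"}),
        frozenset({"r17"}),
        frozenset({"r20"}),
    }
    expected_steps = {
        "r01": "S1", "r02": "S1", "r03": "S2", "r04": "S3", "r05": "S4",
        "r06": "S5", "r07": "S1", "r08": "S1", "r09": "S7", "r10": "S1",
        "r11": "S1", "r12": "S6", "r13": "S6", "r14": "S6", "r15": "S1",
        "r16": "S7", "r17": "S7", "r18": "S1", "r19": "S1", "r20": "S7",
    }
    return records, expected_entities, expected_steps
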