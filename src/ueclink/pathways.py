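"""Patient journeys across the linked platform and their analyses.

A journey starts from a telephone-helpline call (or from an ED attendance
with no preceding call), attaches the earliest same-person ED attendance
arriving within 48 hours of the call, and attaches the earliest same-person
emergency admission episode starting on the ED arrival date or the next
calendar day ("up to one night after").

Three analysis surfaces are provided:

* compliance with helpline recommendations — what fraction of low-acuity
  calls (self-care / primary-care advice) are nonetheless followed by an ED
  attendance within 48 h, how often those attendances are urgent, and how
  often high-acuity recommendations end in a nonurgent attendance
  (mis-triage);
* attendance frequency — ED attendances per person per NHS reporting year
  (April-March), their rank-frequency distribution, and how persistent the
  top-k frequent attenders are between consecutive years.

Urgency classification of an attendance is a pluggable interface because
the published classification algorithm is external to this package;
``admission_based_urgency`` is a deliberately simple stand-in that labels
an attendance urgent iff it led to an admission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd

from .deterministic import EntityMap

__all__ = [
    "Journey",
    "build_journeys",
    "compliance_stats",
    "attendance_frequency",
    "admission_based_urgency",
    "LOW_ACUITY",
    "HIGH_ACUITY",
]

URGENCY_LABELS = ("urgent", "nonurgent", "unknown")
LOW_ACUITY = ("self_care", "primary_care")
HIGH_ACUITY = ("ed_advised", "ambulance_dispatched")

ED_WINDOW = pd.Timedelta(hours=48)


@dataclass
class Journey:
    entity_id: object
    index_call_id: str | None
    call_start: pd.Timestamp | None
    call_disposition: str | None
    call_age: int | None
    ed_record_id: str | None
    ed_arrival: pd.Timestamp | None
    admission_record_id: str | None
    admission_start: pd.Timestamp | None
    urgency_label: str = "unknown"

    @property
    def has_ed(self) -> bool:
        return self.ed_record_id is not None

    @property
    def admitted(self) -> bool:
        return self.admission_record_id is not None


def _earliest(rows: pd.DataFrame) -> pd.Series:
    """Earliest by start time, ties broken by smallest record_id."""
    return rows.sort_values(["start_datetime", "record_id"]).iloc[0]


def build_journeys(platform: pd.DataFrame, entity_map: EntityMap) -> list:
    """Construct journeys for every helpline call and every unattached ED
    attendance on the final platform.

    ED attachment window is half-open: arrival strictly after the call
    start and at most 48 h later.  Admission attachment: emergency episode
    starting on the ED arrival date or the following day; each call
    attaches at most one attendance and each attendance at most one
    admission (earliest, then smallest record_id).
    """
    df = platform.copy()
    df["_entity"] = df["record_id"].map(entity_map.assignments)
    calls = df[df["source"] == "NHS111"]
    eds = df[(df["source"] == "ED") & df["start_datetime"].notna()]
    ips = df[
        (df["source"] == "IP")
        & (df["admission_method"] == "emergency")
        & df["start_datetime"].notna()
    ]
    eds_by_entity = dict(tuple(eds.groupby("_entity"))) if len(eds) else {}
    ips_by_entity = dict(tuple(ips.groupby("_entity"))) if len(ips) else {}

    def attach_admission(entity, ed_row):
        cand = ips_by_entity.get(entity)
        if cand is None:
            return None
        day = ed_row["start_datetime"].normalize()
        ok = cand[
            (cand["start_datetime"].dt.normalize() >= day)
            & (cand["start_datetime"].dt.normalize() <= day + pd.Timedelta(days=1))
        ]
        return None if ok.empty else _earliest(ok)

    journeys = []
    attached_ed_ids = set()
    for _, call in calls.iterrows():
        entity = call["_entity"]
        ed_row = None
        cand = eds_by_entity.get(entity)
        if cand is not None and pd.notna(call["start_datetime"]):
            ok = cand[
                (cand["start_datetime"] > call["start_datetime"])
                & (cand["start_datetime"] <= call["start_datetime"] + ED_WINDOW)
            ]
            if not ok.empty:
                ed_row = _earliest(ok)
        admission = attach_admission(entity, ed_row) if ed_row is not None else None
        if ed_row is not None:
            attached_ed_ids.add(ed_row["record_id"])
        journeys.append(
            Journey(
                entity_id=entity,
                index_call_id=call["record_id"],
                call_start=call["start_datetime"],
                call_disposition=call["disposition"],
                call_age=None if pd.isna(call["age_at_activity"]) else int(call["age_at_activity"]),
                ed_record_id=None if ed_row is None else ed_row["record_id"],
                ed_arrival=None if ed_row is None else ed_row["start_datetime"],
                admission_record_id=None if admission is None else admission["record_id"],
                admission_start=None if admission is None else admission["start_datetime"],
            )
        )

    # ED attendances with no preceding call are index events themselves
    for _, ed_row in eds.iterrows():
        if ed_row["record_id"] in attached_ed_ids:
            continue
        admission = attach_admission(ed_row["_entity"], ed_row)
        journeys.append(
            Journey(
                entity_id=ed_row["_entity"],
                index_call_id=None,
                call_start=None,
                call_disposition=None,
                call_age=None,
                ed_record_id=ed_row["record_id"],
                ed_arrival=ed_row["start_datetime"],
                admission_record_id=None if admission is None else admission["record_id"],
                admission_start=None if admission is None else admission["start_datetime"],
            )
        )
    return journeys


def admission_based_urgency(journey: Journey) -> str:
    """Toy stand-in urgency rule: urgent iff the attendance led to an
    admission.  A placeholder for an externally defined classification."""
    return "urgent" if journey.admitted else "nonurgent"


def classify_journeys(journeys: Iterable[Journey], classifier: Callable) -> None:
    """Apply an urgency classifier to every journey with an attendance."""
    for j in journeys:
        if j.has_ed:
            label = classifier(j)
            if label not in URGENCY_LABELS:
                raise ValueError(f"classifier returned unknown label {label!r}")
            j.urgency_label = label


@dataclass
class ComplianceStats:
    """Helpline compliance / mis-triage rates, with their denominators.

    Rates are None (not 0) when the denominator is empty.
    """

    noncompliance_rate: float | None
    n_low_acuity_calls: int
    urgent_among_noncompliant_rate: float | None
    n_noncompliant_attendances: int
    mistriage_rate: float | None
    n_high_acuity_attended: int


def compliance_stats(
    journeys: Iterable[Journey],
    urgency_classifier: Callable = admission_based_urgency,
    min_age: int | None = 16,
) -> ComplianceStats:
    """Compliance and mis-triage summary over adult call journeys.

    * noncompliance: low-acuity calls (advised self-care or primary care)
      followed by an ED attendance within 48 h;
    * of those noncompliant attendances, the fraction classified urgent
      (suggesting the original advice was insufficient);
    * mis-triage: high-acuity calls (ED advised or ambulance dispatched)
      whose attached attendance is classified nonurgent.

    ``min_age`` restricts the analysis to callers at least that old
    (default 16; the adult cut-off is a convention, so it is a parameter);
    calls with unknown age are retained.  Pass None to disable.
    """
    journeys = [j for j in journeys if j.index_call_id is not None]
    if min_age is not None:
        journeys = [j for j in journeys if j.call_age is None or j.call_age >= min_age]
    classify_journeys(journeys, urgency_classifier)

    low = [j for j in journeys if j.call_disposition in LOW_ACUITY]
    noncomp = [j for j in low if j.has_ed]
    high_attended = [
        j for j in journeys if j.call_disposition in HIGH_ACUITY and j.has_ed
    ]

    def rate(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return ComplianceStats(
        noncompliance_rate=rate(len(noncomp), len(low)),
        n_low_acuity_calls=len(low),
        urgent_among_noncompliant_rate=rate(
            sum(1 for j in noncomp if j.urgency_label == "urgent"), len(noncomp)
        ),
        n_noncompliant_attendances=len(noncomp),
        mistriage_rate=rate(
            sum(1 for j in high_attended if j.urgency_label == "nonurgent"),
            len(high_attended),
        ),
        n_high_acuity_attended=len(high_attended),
    )


def reporting_year(ts: pd.Series) -> pd.Series:
    """NHS reporting year (April-March), labelled by its starting year."""
    return ts.dt.year - (ts.dt.month < 4).astype(int)


@dataclass
class AttendanceFrequency:
    counts: pd.DataFrame  # entity, year, n_attendances
    rank_frequency: pd.DataFrame  # year, n_attendances, n_persons
    persistence: pd.DataFrame  # year, next_year, k, overlap, persistence


def attendance_frequency(
    platform: pd.DataFrame, entity_map: EntityMap, k: int = 100
) -> AttendanceFrequency:
    """ED attendances per person per reporting year, the rank-frequency
    table, and top-k attender persistence between consecutive years.

    ``k`` is clamped to the number of attending persons in either year;
    top-k membership is decided by attendance count (ties by entity id).
    """
    eds = platform[(platform["source"] == "ED") & platform["start_datetime"].notna()].copy()
    eds["entity"] = eds["record_id"].map(entity_map.assignments)
    eds["year"] = reporting_year(eds["start_datetime"])

    counts = (
        eds.groupby(["entity", "year"]).size().rename("n_attendances").reset_index()
    )
    rank_freq = (
        counts.groupby(["year", "n_attendances"])
        .size()
        .rename("n_persons")
        .reset_index()
        .sort_values(["year", "n_attendances"])
        .reset_index(drop=True)
    )

    years = sorted(counts["year"].unique())
    rows = []
    for y0, y1 in zip(years[:-1], years[1:]):
        if y1 != y0 + 1:
            continue
        top = {}
        for y in (y0, y1):
            sub = counts[counts["year"] == y].sort_values(
                ["n_attendances", "entity"], ascending=[False, True]
            )
            top[y] = list(sub["entity"])
        kk = min(k, len(top[y0]), len(top[y1]))
        if kk == 0:
            continue
        overlap = len(set(top[y0][:kk]) & set(top[y1][:kk]))
        rows.append(
            {"year": y0, "next_year": y1, "k": kk, "overlap": overlap, "persistence": overlap / kk}
        )
    persistence = pd.DataFrame(rows, columns=["year", "next_year", "k", "overlap", "persistence"])
    return AttendanceFrequency(counts=counts, rank_frequency=rank_freq, persistence=persistence)
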