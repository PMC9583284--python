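"""Final platform assembly: deduplication, exclusions, evaluation.

Some providers re-supply records around the April start of the NHS
reporting year, so records belonging to the same resolved patient with
identical start/end times and identical key clinical information are
collapsed to a single representative.  Records dated outside the platform
period (or undated) are then excluded, as are inpatient episodes whose
admission method is not an emergency admission.  Unlinked records are
genuine activity and keep their own entity ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import SOURCES
from .deterministic import EntityMap

__all__ = [
    "deduplicate",
    "apply_exclusions",
    "finalize",
    "assemble",
    "evaluate_against_truth",
    "AssemblyReport",
    "LinkageEvaluation",
]


def deduplicate(records: pd.DataFrame, entity_map: EntityMap):
    """Collapse duplicate records; returns (records, removed_per_source).

    Records are duplicates when they belong to the same resolved patient,
    come from the same source with the same start and finish date-times,
    and carry identical key clinical information; the one with the smallest
    record_id is retained.
    """
    df = records.copy()
    df["_entity"] = df["record_id"].map(entity_map.assignments)
    if df["_entity"].isna().any():
        raise ValueError("entity map does not cover all records")
    keep = (
        df.sort_values("record_id")
        .groupby(
            ["_entity", "source", "start_datetime", "end_datetime", "clinical_key"],
            dropna=False,
            sort=False,
        )
        .head(1)
    )
    removed = df.loc[~df["record_id"].isin(keep["record_id"])]
    removed_per_source = (
        removed["source"].value_counts().reindex(SOURCES, fill_value=0).astype(int)
    )
    out = df.loc[df["record_id"].isin(keep["record_id"])].drop(columns="_entity")
    return out.reset_index(drop=True), removed_per_source


def apply_exclusions(records: pd.DataFrame, period_start, period_end):
    """Drop out-of-period/undated records and non-emergency admissions.

    The governing date is the start of call for helpline and ambulance
    records, the arrival for ED and the episode start for inpatient
    records (all held in ``start_datetime``).  Returns
    (records, per-source counts by reason).
    """
    start = pd.Timestamp(period_start)
    end = pd.Timestamp(period_end) + pd.Timedelta(days=1)
    if not start < end:
        raise ValueError("period_start must be before period_end")
    df = records.copy()

    governing = df["start_datetime"]
    date_bad = governing.isna() | (governing < start) | (governing >= end)
    nonemergency = (
        ~date_bad & (df["source"] == "IP") & (df["admission_method"] != "emergency")
    )

    counts = pd.DataFrame(
        {
            "date_missing_or_outside": df.loc[date_bad, "source"]
            .value_counts()
            .reindex(SOURCES, fill_value=0),
            "nonemergency_admission": df.loc[nonemergency, "source"]
            .value_counts()
            .reindex(SOURCES, fill_value=0),
        }
    ).astype(int)
    out = df.loc[~(date_bad | nonemergency)].reset_index(drop=True)
    return out, counts


def finalize(entity_map: EntityMap, records: pd.DataFrame) -> EntityMap:
    """Restrict the entity map to surviving records (a partition of them)."""
    missing = [r for r in records["record_id"] if r not in entity_map.assignments]
    if missing:
        raise ValueError(f"surviving records without an entity id: {missing[:5]} ...")
    return entity_map.restrict(records["record_id"])


@dataclass
class AssemblyReport:
    """Per-source accounting of the final platform build.

    Satisfies ``total == duplicates + exclusions + final`` per source.
    """

    counts: pd.DataFrame  # rows: sources; columns: total, duplicates, ... final

    def to_text(self) -> str:
        lines = ["Final platform: records in and exclusions from the database", ""]
        lines.append(self.counts.to_string())
        return "\n".join(lines)


def assemble(records: pd.DataFrame, entity_map: EntityMap, period_start, period_end):
    """Deduplicate, apply exclusions, finalize; returns
    (platform_records, final_entity_map, AssemblyReport)."""
    totals = records["source"].value_counts().reindex(SOURCES, fill_value=0).astype(int)
    deduped, n_dup = deduplicate(records, entity_map)
    kept, excl = apply_exclusions(deduped, period_start, period_end)
    final_map = finalize(entity_map, kept)
    counts = pd.DataFrame(
        {
            "total": totals,
            "duplicates": n_dup,
            "excluded_date": excl["date_missing_or_outside"],
            "excluded_nonemergency": excl["nonemergency_admission"],
            "final": kept["source"].value_counts().reindex(SOURCES, fill_value=0).astype(int),
        }
    )
    counts.index.name = "source"
    return kept, final_map, AssemblyReport(counts)


def _pair_count(sizes: pd.Series) -> int:
    return int((sizes * (sizes - 1) // 2).sum())


@dataclass
class LinkageEvaluation:
    """Pairwise and cluster-level agreement between an entity map and truth."""

    pair_precision: float
    pair_recall: float
    pair_f: float
    cluster_exact_match_rate: float
    n_predicted_pairs: int
    n_truth_pairs: int
    n_common_pairs: int
    empty_prediction: bool  # no predicted pairs: precision 1.0 by convention


def evaluate_against_truth(entity_map: EntityMap, truth: dict) -> LinkageEvaluation:
    """Pairwise precision/recall/F of the resolved entities against ground
    truth, plus the fraction of true persons recovered exactly.

    Counts same-entity record pairs via cluster-size arithmetic, which is
    equivalent to enumerating all record pairs.
    """
    df = pd.DataFrame(
        {"record_id": list(entity_map.assignments), "entity": list(entity_map.assignments.values())}
    )
    not_covered = [r for r in df["record_id"] if r not in truth]
    if not_covered:
        raise ValueError(f"truth does not cover records: {not_covered[:5]} ...")
    df["person"] = df["record_id"].map(truth)

    predicted = _pair_count(df.groupby("entity").size())
    actual = _pair_count(df.groupby("person").size())
    common = _pair_count(df.groupby(["entity", "person"]).size())

    empty = predicted == 0
    precision = 1.0 if empty else common / predicted
    recall = 1.0 if actual == 0 else common / actual
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)

    cluster_sets = df.groupby("entity")["record_id"].apply(frozenset)
    person_sets = df.groupby("person")["record_id"].apply(frozenset)
    predicted_sets = set(cluster_sets)
    exact = sum(1 for s in person_sets if s in predicted_sets)
    exact_rate = exact / len(person_sets) if len(person_sets) else 1.0

    return LinkageEvaluation(
        pair_precision=precision,
        pair_recall=recall,
        pair_f=f,
        cluster_exact_match_rate=exact_rate,
        n_predicted_pairs=predicted,
        n_truth_pairs=actual,
        n_common_pairs=common,
        empty_prediction=empty,
    )
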