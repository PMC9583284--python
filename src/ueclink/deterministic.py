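"""Seven-step deterministic entity resolution.

Records from all four sources are resolved to shared entity IDs by a strict
sequence of identifier-based steps; a record assigned at one step is never
reconsidered by a later one.

S1  Each distinct (valid NHS number, valid date of birth) pair seeds an
    entity.
S2  Records with a valid NHS number but no valid dob join an S1 entity with
    the same NHS number whose birth year matches the approximate birth year
    (activity year minus age at activity) within +-1.
S3  (provider code, provider patient ID, dob) uniquely matching one
    existing entity.  Ambulance records excluded (no provider patient ID).
S4  (first name, last name, sex, dob, postcode) uniquely matching one
    entity.  Helpline (no names) and ambulance (incident postcode)
    excluded; high-occupancy "communal" postcodes barred.
S5  (sex, dob, postcode) uniquely matching one entity; ambulance excluded,
    communal postcodes barred.
S6  Remaining records clustered by the union of the three patterns above
    (same per-pattern exclusions); each connected component of two or more
    records becomes a new entity.
S7  Every record still unassigned gets its own entity.

"Uniquely matching one entity" is evaluated against the entities existing
when the step begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .ingest import _NORMALIZED_POSTCODE_RE

__all__ = ["EntityMap", "excluded_postcodes", "resolve", "STEPS"]

STEPS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "P")


@dataclass
class EntityMap:
    """Assignment of every record to an entity, with step provenance."""

    assignments: dict = field(default_factory=dict)  # record_id -> entity_id
    provenance: dict = field(default_factory=dict)  # record_id -> step label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": list(self.assignments),
                "entity_id": list(self.assignments.values()),
                "step": [self.provenance[r] for r in self.assignments],
            }
        )

    def clusters(self) -> dict:
        """entity_id -> sorted list of member record_ids."""
        out: dict = {}
        for rid, eid in self.assignments.items():
            out.setdefault(eid, []).append(rid)
        for members in out.values():
            members.sort()
        return out

    def restrict(self, record_ids) -> "EntityMap":
        keep = set(record_ids)
        return EntityMap(
            {r: e for r, e in self.assignments.items() if r in keep},
            {r: s for r, s in self.provenance.items() if r in keep},
        )


def excluded_postcodes(records: pd.DataFrame, top_fraction: float = 0.01) -> set:
    """Postcodes barred from identifier matching: the ``top_fraction`` of
    postcodes with the greatest number of distinct patients (communal
    establishments such as prisons or care homes).

    Distinct patients are counted by NHS number where present, otherwise by
    (first name, last name, dob).  Ties at the cut rank are broken by
    lexicographic postcode order.
    """
    if not 0.0 <= top_fraction <= 1.0:
        raise ValueError("top_fraction must be in [0, 1]")
    df = records[records["postcode"].notna()].copy()
    if df.empty:
        return set()

    name_key = df["first_name"].astype(str) + "|" + df["last_name"].astype(str) + "|" + df[
        "dob"
    ].astype(str)
    has_name_key = df["first_name"].notna() & df["last_name"].notna() & df["dob"].notna()
    patient = df["nhs_number"].astype(object).where(
        df["nhs_number"].notna(), ("NM:" + name_key).where(has_name_key, None)
    )
    df["patient_key"] = patient
    df = df[df["patient_key"].notna()]
    if df.empty:
        return set()

    counts = (
        df.groupby("postcode")["patient_key"].nunique().rename("n_patients").reset_index()
    )
    k = math.ceil(top_fraction * len(counts))
    if k == 0:
        return set()
    counts = counts.sort_values(["n_patients", "postcode"], ascending=[False, True])
    return set(counts["postcode"].head(k))


def _check_normalized(records: pd.DataFrame) -> None:
    pc = records["postcode"].dropna()
    if len(pc) and not pc.map(lambda s: bool(_NORMALIZED_POSTCODE_RE.match(s))).all():
        raise ValueError(
            "records do not look validated: non-normalized postcodes present; "
            "run ueclink.ingest.validate_records first"
        )


def _iter_keys(sub: pd.DataFrame, key_cols):
    """Yield (row index, key tuple) efficiently."""
    cols = [sub[c].to_numpy() for c in key_cols]
    for pos, idx in enumerate(sub.index):
        yield idx, tuple(col[pos] for col in cols)


def _build_index(df, assigned_rows, cand_mask, key_cols, entity_of):
    """key tuple -> set of entity ids, over already-assigned eligible rows."""
    index: dict = {}
    for idx, key in _iter_keys(df.loc[assigned_rows & cand_mask, key_cols], key_cols):
        index.setdefault(key, set()).add(entity_of[idx])
    return index


def resolve(
    records: pd.DataFrame,
    *,
    excluded: set | None = None,
    top_fraction: float = 0.01,
):
    """Run the seven deterministic steps; returns (EntityMap, step_counts).

    ``records`` must already be validated/normalized (non-null identifier
    values are taken as valid).  ``step_counts`` is a per-source, per-step
    DataFrame whose rows sum to the per-source record totals.  Entity IDs
    are opaque sequential integers issued in input order.
    """
    df = records.reset_index(drop=True)
    _check_normalized(df)
    if excluded is None:
        excluded = excluded_postcodes(df, top_fraction)

    n = len(df)
    entity_of: dict = {}  # row index -> entity id
    step_of: dict = {}
    next_entity = 0

    src = df["source"]
    has = {
        col: df[col].notna()
        for col in (
            "nhs_number",
            "dob",
            "age_at_activity",
            "start_datetime",
            "provider_code",
            "provider_patient_id",
            "first_name",
            "last_name",
            "sex",
            "postcode",
        )
    }
    pc_ok = has["postcode"] & ~df["postcode"].isin(list(excluded))

    def assigned_mask():
        m = pd.Series(False, index=df.index)
        if entity_of:
            m.loc[list(entity_of)] = True
        return m

    # --- S1: distinct (NHS number, dob) pairs seed entities -----------
    s1_mask = has["nhs_number"] & has["dob"]
    s1_entities: dict = {}  # (nhs, dob) -> entity id
    for idx, key in _iter_keys(df.loc[s1_mask, ["nhs_number", "dob"]], ["nhs_number", "dob"]):
        eid = s1_entities.get(key)
        if eid is None:
            eid = next_entity
            next_entity += 1
            s1_entities[key] = eid
        entity_of[idx] = eid
        step_of[idx] = "S1"

    # --- S2: NHS number, no valid dob, approximate birth year ---------
    by_nhs: dict = {}
    for (nhs, dob), eid in s1_entities.items():
        by_nhs.setdefault(nhs, []).append((eid, pd.Timestamp(dob).year))
    s2_mask = has["nhs_number"] & ~has["dob"] & has["age_at_activity"] & has["start_datetime"]
    for idx in df.index[s2_mask & ~assigned_mask()]:
        approx_year = df.at[idx, "start_datetime"].year - int(df.at[idx, "age_at_activity"])
        cands = {
            eid
            for eid, year in by_nhs.get(df.at[idx, "nhs_number"], ())
            if abs(year - approx_year) <= 1
        }
        if len(cands) == 1:
            entity_of[idx] = next(iter(cands))
            step_of[idx] = "S2"

    # --- S3/S4/S5: unique match to an existing entity ------------------
    # the same eligibility applies on both sides of a pattern: an ambulance
    # record's incident-location postcode must not seed a key either
    step_specs = [
        (
            "S3",
            ["provider_code", "provider_patient_id", "dob"],
            has["provider_code"] & has["provider_patient_id"] & has["dob"] & (src != "AMB"),
        ),
        (
            "S4",
            ["first_name", "last_name", "sex", "dob", "postcode"],
            has["first_name"] & has["last_name"] & has["sex"] & has["dob"] & pc_ok
            & ~src.isin(["NHS111", "AMB"]),
        ),
        (
            "S5",
            ["sex", "dob", "postcode"],
            has["sex"] & has["dob"] & pc_ok & (src != "AMB"),
        ),
    ]
    for step, key_cols, cand_mask in step_specs:
        assigned = assigned_mask()
        index = _build_index(df, assigned, cand_mask, key_cols, entity_of)
        for idx, key in _iter_keys(df.loc[~assigned & cand_mask, key_cols], key_cols):
            ents = index.get(key)
            if ents is not None and len(ents) == 1:
                entity_of[idx] = next(iter(ents))
                step_of[idx] = step

    # --- S6: cluster remaining records by the union of the patterns ----
    assigned = assigned_mask()
    remaining = df.index[~assigned]
    graph = nx.Graph()
    graph.add_nodes_from(remaining)
    for _, key_cols, cand_mask in step_specs:
        sub = df.loc[~assigned & cand_mask, key_cols]
        if sub.empty:
            continue
        for _, group in sub.groupby(key_cols, sort=False, dropna=True):
            idxs = list(group.index)
            graph.add_edges_from(zip(idxs[:-1], idxs[1:]))
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        eid = next_entity
        next_entity += 1
        for idx in sorted(component):
            entity_of[idx] = eid
            step_of[idx] = "S6"

    # --- S7: everything else gets its own entity -----------------------
    for idx in df.index[~assigned_mask()]:
        entity_of[idx] = next_entity
        next_entity += 1
        step_of[idx] = "S7"

    rid = df["record_id"]
    emap = EntityMap(
        {rid.iat[i]: entity_of[i] for i in range(n)},
        {rid.iat[i]: step_of[i] for i in range(n)},
    )
    counts = (
        pd.crosstab(df["source"], pd.Series([step_of[i] for i in range(n)], index=df.index))
        .reindex(columns=[s for s in STEPS if s != "P"], fill_value=0)
        .rename_axis(index="source", columns="step")
    )
    return emap, counts
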