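"""Ground-truthed synthetic generator for multi-source urgent-care records.

Emits event records for four sources — telephone-helpline calls (NHS111),
ambulance incidents (AMB), emergency-department attendances (ED) and
inpatient episodes (IP) — drawn from a synthetic population with known
identity, then degrades them with the corruption modes the linkage has to
survive: per-source identifier missingness, name typos, day/month
transposition in dates of birth, loss of meaningful leading zeros in
provider patient IDs, and duplicate records injected near the April
reporting-year boundary.

Structure the linkage relies on is built in: a conveyed ambulance incident
spawns an ED attendance at the same hospital site within a -60/+180 minute
window of the ambulance's arrival at the destination, and attendances may
spawn an emergency admission episode starting the same or the following
day.  Twins (shared date of birth, postcode, sex and surname) and communal
postcodes provide the hard cases for identifier-based resolution.

All outputs are pandas DataFrames with the column schema documented in
``docs/data_dictionary.md``; ``truth_person_id`` carries the ground truth
and must be stripped before records enter the pipeline.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pandas as pd

from .config import SOURCES, DISPOSITIONS, GeneratorConfig
from .ingest import nhs_check_digit

__all__ = [
    "generate_population",
    "generate_activity",
    "degrade_records",
    "ground_truth",
    "strip_truth",
    "write_records",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "record_id",
    "source",
    "provider_code",
    "provider_patient_id",
    "nhs_number",
    "dob",
    "age_at_activity",
    "first_name",
    "last_name",
    "sex",
    "postcode",
    "start_datetime",
    "end_datetime",
    "site",
    "conveyed",
    "admission_method",
    "clinical_key",
    "disposition",
    "truth_person_id",
]

_FIRST_NAMES_F = [
    "MARY", "PATRICIA", "LINDA", "BARBARA", "ELIZABETH", "JENNIFER", "MARIA",
    "SUSAN", "MARGARET", "DOROTHY", "LISA", "NANCY", "KAREN", "BETTY",
    "HELEN", "SANDRA", "DONNA", "CAROL", "RUTH", "SHARON", "MICHELLE",
    "LAURA", "SARAH", "KIMBERLY", "DEBORAH", "JESSICA", "SHIRLEY",
    "CYNTHIA", "ANGELA", "MELISSA", "BRENDA", "AMY", "ANNA", "REBECCA",
    "VIRGINIA", "KATHLEEN", "PAMELA", "MARTHA", "DEBRA", "AMANDA",
]
_FIRST_NAMES_M = [
    "JAMES", "JOHN", "ROBERT", "MICHAEL", "WILLIAM", "DAVID", "RICHARD",
    "CHARLES", "JOSEPH", "THOMAS", "CHRISTOPHER", "DANIEL", "PAUL", "MARK",
    "DONALD", "GEORGE", "KENNETH", "STEVEN", "EDWARD", "BRIAN", "RONALD",
    "ANTHONY", "KEVIN", "JASON", "MATTHEW", "GARY", "TIMOTHY", "JOSE",
    "LARRY", "JEFFREY", "FRANK", "SCOTT", "ERIC", "STEPHEN", "ANDREW",
    "RAYMOND", "GREGORY", "JOSHUA", "JERRY", "DENNIS",
]
_LAST_NAMES = [
    "SMITH", "JONES", "TAYLOR", "BROWN", "WILLIAMS", "WILSON", "JOHNSON",
    "DAVIES", "ROBINSON", "WRIGHT", "THOMPSON", "EVANS", "WALKER", "WHITE",
    "ROBERTS", "GREEN", "HALL", "WOOD", "JACKSON", "CLARKE", "PATEL",
    "KHAN", "LEWIS", "JAMES", "PHILLIPS", "MASON", "MITCHELL", "ROSE",
    "DAVIS", "RODGERS", "PARKER", "COOPER", "TURNER", "HILL", "WARD",
    "MORRIS", "MOORE", "CLARK", "LEE", "KING", "BAKER", "HARRISON",
    "MORGAN", "ALLEN", "HUGHES", "EDWARDS", "SHAW", "BENNETT", "CARTER",
    "GRAY", "OBRIEN", "MURPHY", "STONE", "KELLY", "BELL", "COX", "RICHARDS",
    "FOX", "HOLMES", "MARSHALL",
]

_SPECIALTIES = ["GENMED", "PAEDS", "ORTHO", "CARDIO", "SURG", "GERI", "RESP", "NEURO"]

# letters used in postcodes (no I, mirrors real outward codes avoiding confusables)
_PC_LETTERS = np.array(list("ABCDEFGHJKLMNPQRSTUVWXYZ"))


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Independent substream for a pipeline stage, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _make_nhs_numbers(n: int, rng: np.random.Generator) -> list:
    """n unique valid 10-digit NHS numbers (mod-11 check digit)."""
    out: list = []
    seen: set = set()
    while len(out) < n:
        for c in rng.integers(0, 10**9, size=max(2 * (n - len(out)), 64)):
            s = f"{int(c):09d}"
            if s in seen:
                continue
            cd = nhs_check_digit(s)
            if cd is None:  # computed check digit 10: no valid number exists
                continue
            seen.add(s)
            out.append(s + str(cd))
            if len(out) == n:
                break
    return out


def _make_postcode_pool(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pool of n distinct postcode-shaped strings like 'L9 3AA'."""
    pool: list = []
    seen: set = set()
    while len(pool) < n:
        m = max(2 * (n - len(pool)), 64)
        l1 = rng.choice(_PC_LETTERS, m)
        d1 = rng.integers(1, 100, m)
        d2 = rng.integers(0, 10, m)
        l2 = rng.choice(_PC_LETTERS, m)
        l3 = rng.choice(_PC_LETTERS, m)
        for a, b, c, d, e in zip(l1, d1, d2, l2, l3):
            pc = f"{a}{b} {c}{d}{e}"
            if pc not in seen:
                seen.add(pc)
                pool.append(pc)
                if len(pool) == n:
                    break
    return np.asarray(pool, dtype=object)


def _postcode_pool(config: GeneratorConfig) -> np.ndarray:
    """The shared postcode universe for a config (own substream: reproducible
    independently of how many draws other stages have consumed)."""
    return _make_postcode_pool(config.n_postcodes, _rng(config.seed, 10))


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the ground-truth population.

    Returns a DataFrame with one row per person: person_id, nhs_number,
    first_name, last_name, sex, dob, postcode, is_twin.  Twin pairs share
    dob, postcode, sex and last name; a configurable fraction of persons
    live at a small set of communal (high-occupancy) postcodes.
    """
    config.validate()
    n = config.n_persons
    rng = _rng(config.seed, 0)
    if n == 0:
        return pd.DataFrame(
            columns=[
                "person_id", "nhs_number", "first_name", "last_name",
                "sex", "dob", "postcode", "is_twin",
            ]
        )

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    first = np.where(
        sex == "female",
        rng.choice(np.asarray(_FIRST_NAMES_F, dtype=object), n),
        rng.choice(np.asarray(_FIRST_NAMES_M, dtype=object), n),
    )
    last = rng.choice(np.asarray(_LAST_NAMES, dtype=object), n)

    ref = pd.Timestamp(config.period_start)
    age_days = rng.integers(0, int(100 * 365.25), n)
    dob = ref - pd.to_timedelta(age_days, unit="D")
    dob = dob.normalize()

    pool = _postcode_pool(config)
    communal = pool[: config.n_communal_postcodes]
    residential = pool[config.n_communal_postcodes :]
    postcode = rng.choice(residential, n)
    if config.n_communal_postcodes > 0:
        communal_mask = rng.random(n) < config.communal_postcode_fraction
        postcode[communal_mask] = rng.choice(communal, int(communal_mask.sum()))

    is_twin = np.zeros(n, dtype=bool)
    n_twin = int(round(config.twin_fraction * n))
    n_twin -= n_twin % 2
    if n_twin:
        idx = rng.permutation(n)[:n_twin]
        a, b = idx[0::2], idx[1::2]
        dob = dob.to_numpy()
        dob[b] = dob[a]
        dob = pd.DatetimeIndex(dob)
        postcode[b] = postcode[a]
        sex[b] = sex[a]
        last[b] = last[a]
        first[b] = np.where(
            sex[b] == "female",
            rng.choice(np.asarray(_FIRST_NAMES_F, dtype=object), len(b)),
            rng.choice(np.asarray(_FIRST_NAMES_M, dtype=object), len(b)),
        )
        is_twin[idx] = True

    return pd.DataFrame(
        {
            "person_id": [f"P{i:06d}" for i in range(n)],
            "nhs_number": _make_nhs_numbers(n, rng),
            "first_name": first,
            "last_name": last,
            "sex": sex,
            "dob": pd.DatetimeIndex(dob),
            "postcode": postcode,
            "is_twin": is_twin,
        }
    )


def _completed_years(start: pd.Series, dob: pd.Series) -> pd.Series:
    """Age in completed years at the activity date."""
    before = (start.dt.month * 100 + start.dt.day) < (dob.dt.month * 100 + dob.dt.day)
    return (start.dt.year - dob.dt.year - before.astype(int)).astype("Int64")


def generate_activity(persons: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Draw per-person event records for all four sources.

    Records at this stage carry complete, uncorrupted identifiers (apart
    from structural absences: helpline calls have no names, ambulance
    incidents no provider patient ID and an incident-location postcode).
    Conveyed ambulance incidents spawn ED attendances at the same site, and
    ED attendances spawn emergency admission episodes with probability
    ``admission_prob_given_ed``.
    """
    config.validate()
    if len(persons) == 0:
        raise ValueError("persons must be nonempty")
    rng = _rng(config.seed, 1)

    t0 = pd.Timestamp(config.period_start)
    t1 = pd.Timestamp(config.period_end) + timedelta(days=1)
    span = int((t1 - t0).total_seconds())
    sites = np.asarray([f"SITE{j:02d}" for j in range(config.n_sites)], dtype=object)
    trusts = np.asarray([f"TRUST{j:02d}" for j in range(config.n_sites)], dtype=object)
    site_to_trust = dict(zip(sites, trusts))
    n_persons = len(persons)

    def base_frame(pidx: np.ndarray, source: str, start: pd.Series) -> pd.DataFrame:
        p = persons.iloc[pidx].reset_index(drop=True)
        start = pd.Series(start).reset_index(drop=True)
        df = pd.DataFrame(
            {
                "source": source,
                "provider_patient_id": [f"{i:07d}" for i in pidx],
                "nhs_number": p["nhs_number"].to_numpy(),
                "dob": p["dob"].to_numpy(),
                "first_name": p["first_name"].to_numpy(),
                "last_name": p["last_name"].to_numpy(),
                "sex": p["sex"].to_numpy(),
                "postcode": p["postcode"].to_numpy(),
                "start_datetime": start,
                "truth_person_id": p["person_id"].to_numpy(),
            }
        )
        df["age_at_activity"] = _completed_years(df["start_datetime"], p["dob"])
        df["clinical_key"] = [
            f"{s}|D{d:02d}"
            for s, d in zip(
                rng.choice(np.asarray(_SPECIALTIES, dtype=object), len(df)),
                rng.integers(0, 20, len(df)),
            )
        ]
        return df

    def uniform_times(k: int) -> pd.Series:
        return t0 + pd.to_timedelta(rng.integers(0, span, k), unit="s")

    frames = []

    # --- NHS 111 calls ------------------------------------------------
    counts = rng.poisson(config.event_rates["NHS111"], n_persons)
    pidx = np.repeat(np.arange(n_persons), counts)
    k = len(pidx)
    df = base_frame(pidx, "NHS111", uniform_times(k))
    df["provider_code"] = "NHS111PROV"
    df["first_name"] = pd.Series([None] * k, dtype=object)  # never captured by the helpline
    df["last_name"] = pd.Series([None] * k, dtype=object)
    df["end_datetime"] = df["start_datetime"] + pd.to_timedelta(
        rng.integers(2, 21, k), unit="m"
    )
    df["site"] = pd.Series([None] * k, dtype=object)
    df["conveyed"] = pd.array([pd.NA] * k, dtype="boolean")
    df["admission_method"] = pd.Series([None] * k, dtype=object)
    df["disposition"] = rng.choice(
        np.asarray(DISPOSITIONS, dtype=object),
        k,
        p=[config.disposition_probs[d] for d in DISPOSITIONS],
    )
    frames.append(df)

    # --- Ambulance incidents ------------------------------------------
    counts = rng.poisson(config.event_rates["AMB"], n_persons)
    pidx = np.repeat(np.arange(n_persons), counts)
    k = len(pidx)
    amb = base_frame(pidx, "AMB", uniform_times(k))
    amb["provider_code"] = "AMBPROV"
    amb["provider_patient_id"] = pd.Series([None] * k, dtype=object)  # never available for ambulance records
    # destination arrival (end_datetime) = call start + travel time
    amb["end_datetime"] = amb["start_datetime"] + pd.to_timedelta(
        rng.integers(20, 91, k), unit="m"
    )
    conveyed = rng.random(k) < config.conveyance_prob
    amb["conveyed"] = pd.array(conveyed, dtype="boolean")
    amb_site = rng.choice(sites, k)
    amb["site"] = np.where(conveyed, amb_site, None)
    # incident-location postcode, not residence
    at_home = rng.random(k) < config.incident_at_home_prob
    pool = _postcode_pool(config)
    amb["postcode"] = np.where(
        at_home, amb["postcode"].to_numpy(), rng.choice(pool, k)
    )
    amb["admission_method"] = pd.Series([None] * k, dtype=object)
    amb["disposition"] = pd.Series([None] * k, dtype=object)
    frames.append(amb)

    # --- ED attendances: ambient walk-ins + spawned from conveyance ---
    counts = rng.poisson(config.event_rates["ED"], n_persons)
    pidx = np.repeat(np.arange(n_persons), counts)
    k = len(pidx)
    ed_amb_part = base_frame(pidx, "ED", uniform_times(k))
    ed_amb_part["site"] = rng.choice(sites, k)

    conv = amb[amb["conveyed"] == True]  # noqa: E712  (nullable boolean)
    kc = len(conv)
    lo, hi = config.ed_offset_minutes
    offset = rng.uniform(lo, hi, kc)
    if config.ed_offset_out_of_window_prob > 0:
        tail = rng.random(kc) < config.ed_offset_out_of_window_prob
        offset[tail] = rng.uniform(181.0, 480.0, int(tail.sum()))
    # map truth ids back to positional person indices
    pid_to_pos = {pid: i for i, pid in enumerate(persons["person_id"])}
    conv_pidx = np.asarray([pid_to_pos[t] for t in conv["truth_person_id"]], dtype=int)
    spawned = base_frame(
        conv_pidx,
        "ED",
        (conv["end_datetime"] + pd.to_timedelta(offset, unit="m"))
        .dt.floor("s")
        .reset_index(drop=True),
    )
    spawned["site"] = conv["site"].to_numpy()

    ed = pd.concat([ed_amb_part, spawned], ignore_index=True)
    ke = len(ed)
    ed["provider_code"] = ed["site"].map(site_to_trust)
    ed["end_datetime"] = ed["start_datetime"] + pd.to_timedelta(
        rng.integers(60, 481, ke), unit="m"
    )
    ed["conveyed"] = pd.array([pd.NA] * ke, dtype="boolean")
    ed["admission_method"] = pd.Series([None] * ke, dtype=object)
    ed["disposition"] = pd.Series([None] * ke, dtype=object)
    frames.append(ed)

    # --- Inpatient episodes: ambient + emergency admissions from ED ---
    counts = rng.poisson(config.event_rates["IP"], n_persons)
    pidx = np.repeat(np.arange(n_persons), counts)
    k = len(pidx)
    ip_ambient = base_frame(pidx, "IP", uniform_times(k))
    ip_ambient["site"] = rng.choice(sites, k)
    ip_ambient["admission_method"] = np.where(
        rng.random(k) < config.nonemergency_admission_rate, "other", "emergency"
    )

    admitted = ed[rng.random(ke) < config.admission_prob_given_ed]
    ka = len(admitted)
    adm_pidx = np.asarray(
        [pid_to_pos[t] for t in admitted["truth_person_id"]], dtype=int
    )
    ip_spawned = base_frame(
        adm_pidx,
        "IP",
        (admitted["start_datetime"] + pd.to_timedelta(rng.uniform(60, 360, ka), unit="m"))
        .dt.floor("s")
        .reset_index(drop=True),
    )
    ip_spawned["site"] = admitted["site"].to_numpy()
    ip_spawned["admission_method"] = "emergency"

    ip = pd.concat([ip_ambient, ip_spawned], ignore_index=True)
    ki = len(ip)
    ip["provider_code"] = ip["site"].map(site_to_trust)
    ip["end_datetime"] = ip["start_datetime"] + pd.to_timedelta(
        rng.integers(1, 11, ki), unit="D"
    )
    ip["conveyed"] = pd.array([pd.NA] * ki, dtype="boolean")
    ip["disposition"] = pd.Series([None] * ki, dtype=object)
    frames.append(ip)

    # --- assemble with per-source sequential record ids ----------------
    out = []
    for frame in frames:
        frame = frame.reset_index(drop=True)
        src = frame["source"].iloc[0] if len(frame) else None
        frame["record_id"] = [f"{src}-{i:07d}" for i in range(len(frame))]
        out.append(frame)
    records = pd.concat(out, ignore_index=True)
    records["conveyed"] = records["conveyed"].astype("boolean")
    return records[RECORD_COLUMNS]


def degrade_records(records: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Apply identifier missingness and corruption; inject boundary duplicates.

    Identifier presence is thinned per source to the configured
    probabilities; names receive single-character typos; dates of birth have
    day and month transposed (only possible when day <= 12); provider
    patient IDs lose leading zeros; ED/IP records starting within two weeks
    after a reporting-year boundary (April 1) are duplicated.  Ground truth
    is preserved.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    df = records.copy().reset_index(drop=True)
    n = len(df)
    if n == 0:
        return df

    src = df["source"].to_numpy()

    def presence_keep(presence_map) -> np.ndarray:
        p = np.asarray([presence_map[s] for s in src])
        return rng.random(n) < p

    for col, pmap in [
        ("nhs_number", config.nhs_number_presence),
        ("dob", config.dob_presence),
        ("postcode", config.postcode_presence),
        ("sex", config.sex_presence),
    ]:
        keep = presence_keep(pmap)
        df.loc[~keep, col] = pd.NaT if col == "dob" else None

    keep_names = presence_keep(config.name_presence)
    df.loc[~keep_names, ["first_name", "last_name"]] = None

    # single-character typos in names
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for col in ("first_name", "last_name"):
        present = df[col].notna().to_numpy()
        hit = present & (rng.random(n) < config.typo_rate)
        for i in np.flatnonzero(hit):
            s = df.at[i, col]
            if not s:
                continue
            pos = int(rng.integers(0, len(s)))
            df.at[i, col] = s[:pos] + letters[int(rng.integers(0, 26))] + s[pos + 1 :]

    # day/month transposition (only well defined when day <= 12)
    dob = df["dob"]
    transposable = dob.notna() & (dob.dt.day <= 12)
    hit = transposable.to_numpy() & (rng.random(n) < config.dob_transposition_rate)
    for i in np.flatnonzero(hit):
        d = df.at[i, "dob"]
        df.at[i, "dob"] = pd.Timestamp(year=d.year, month=d.day, day=d.month)

    # loss of meaningful leading zeros in provider patient IDs
    ppid = df["provider_patient_id"]
    zeroed = ppid.notna() & ppid.astype(str).str.startswith("0")
    hit = zeroed.to_numpy() & (rng.random(n) < config.leading_zero_loss_rate)
    for i in np.flatnonzero(hit):
        df.at[i, "provider_patient_id"] = df.at[i, "provider_patient_id"].lstrip("0") or "0"

    # duplicate ED/IP records near the April reporting-year boundary
    start = df["start_datetime"]
    boundary = (
        df["source"].isin(["ED", "IP"])
        & start.notna()
        & (start.dt.month == 4)
        & (start.dt.day <= 14)
    )
    hit = boundary.to_numpy() & (rng.random(n) < config.duplicate_rate_at_year_boundary)
    if hit.any():
        dups = df.loc[hit].copy()
        dups["record_id"] = [
            f"{s}-D{i:06d}" for i, s in enumerate(dups["source"])
        ]
        df = pd.concat([df, dups], ignore_index=True)

    return df


def ground_truth(records: pd.DataFrame) -> dict:
    """Total map record_id -> true person_id; for evaluation only."""
    if "truth_person_id" not in records.columns:
        raise ValueError("records lack truth_person_id")
    if records["truth_person_id"].isna().any():
        raise ValueError("records lack truth_person_id for some rows")
    return dict(zip(records["record_id"], records["truth_person_id"]))


def strip_truth(records: pd.DataFrame) -> pd.DataFrame:
    """Drop the ground-truth column: the view the pipeline is allowed to see."""
    return records.drop(columns=["truth_person_id"], errors="ignore")


def write_records(records: pd.DataFrame, outdir, config: GeneratorConfig | None = None) -> None:
    """Write one CSV per source, a truth CSV and (optionally) the config JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = {"NHS111": "nhs111.csv", "AMB": "ambulance.csv", "ED": "ed.csv", "IP": "inpatient.csv"}
    for source in SOURCES:
        sub = records[records["source"] == source].drop(columns=["truth_person_id"], errors="ignore")
        sub.to_csv(outdir / names[source], index=False, date_format="%Y-%m-%dT%H:%M:%S")
    if "truth_person_id" in records.columns:
        records[["record_id", "truth_person_id"]].rename(
            columns={"truth_person_id": "person_id"}
        ).to_csv(outdir / "truth.csv", index=False)
    if config is not None:
        (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
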