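"""Reading, validation and normalization of per-source record files.

Every identifier field is checked against a pattern rule or a code set
before linkage: NHS numbers must pass the national mod-11 checksum,
postcodes are re-spaced and upper-cased, names are folded to a canonical
alphabet, coded fields must belong to their code set, and dates of birth
must lie within 110 years of the activity date.  Invalid values are
blanked, never dropped: a record with a corrupt identifier still represents
genuine care activity and is retained for the later resolution steps.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "nhs_check_digit",
    "validate_nhs_number",
    "normalize_postcode",
    "normalize_name",
    "validate_records",
    "default_code_sets",
    "read_records",
    "ValidationReport",
]

_POSTCODE_RE = re.compile(r"^[A-Z]{1,2}[0-9][A-Z0-9]? ?[0-9][A-Z]{2}$")
_NORMALIZED_POSTCODE_RE = re.compile(r"^[A-Z]{1,2}[0-9][A-Z0-9]? [0-9][A-Z]{2}$")
_NAME_KEEP_RE = re.compile(r"[^A-Z' \-]")


def nhs_check_digit(first_nine: str) -> int | None:
    """Mod-11 check digit for a 9-digit prefix; None if no valid digit exists.

    Weights 10..2 on the first nine digits; check = 11 - (sum mod 11), with
    11 mapped to 0 and 10 meaning the prefix admits no valid number.
    """
    if len(first_nine) != 9 or not first_nine.isdigit():
        raise ValueError("expected exactly 9 digits")
    total = sum(int(d) * w for d, w in zip(first_nine, range(10, 1, -1)))
    check = 11 - (total % 11)
    if check == 11:
        return 0
    if check == 10:
        return None
    return check


def validate_nhs_number(candidate) -> bool:
    """True iff candidate is a 10-digit string with a correct check digit."""
    if not isinstance(candidate, str) or len(candidate) != 10 or not candidate.isdigit():
        return False
    return nhs_check_digit(candidate[:9]) == int(candidate[9])


def normalize_postcode(candidate):
    """Canonical postcode form: upper case, one space before the final three
    characters.  Returns None for anything that does not look like a postcode."""
    if not isinstance(candidate, str):
        return None
    s = re.sub(r"\s+", "", candidate.strip().upper())
    if not 5 <= len(s) <= 7:
        return None
    s = s[:-3] + " " + s[-3:]
    if not _NORMALIZED_POSTCODE_RE.match(s):
        return None
    return s


def normalize_name(candidate):
    """Upper-case, fold diacritics, strip everything but letters, hyphen and
    apostrophe, collapse whitespace.  Returns None if nothing is left."""
    if not isinstance(candidate, str):
        return None
    s = unicodedata.normalize("NFKD", candidate).encode("ascii", "ignore").decode()
    s = _NAME_KEEP_RE.sub("", s.upper())
    s = re.sub(r"\s+", " ", s).strip()
    return s or None


def default_code_sets(sites=None) -> dict:
    """Allowed values for the coded fields the linkage touches."""
    return {
        "sex": {"male", "female"},
        "admission_method": {"emergency", "other"},
        "source": {"NHS111", "AMB", "ED", "IP"},
        "site": None if sites is None else set(sites),
    }


@dataclass
class ValidationReport:
    """Per-field accounting of what validation found and changed.

    For every checked field, ``missing + invalid + valid == n_records``;
    ``corrected`` counts values that were altered by normalization but kept
    (a subset of valid).
    """

    n_records: int
    field_counts: pd.DataFrame
    issues: list = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"ValidationReport(n={self.n_records})\n{self.field_counts}"


def _count(report_rows, issues, record_ids, name, missing, invalid, corrected, n):
    report_rows[name] = {
        "missing": int(missing.sum()),
        "invalid": int(invalid.sum()),
        "corrected": int(corrected.sum()),
        "valid": int(n - missing.sum() - invalid.sum()),
    }
    for i in np.flatnonzero(invalid.to_numpy()):
        issues.append((record_ids.iloc[i], name, "invalid"))


def validate_records(records: pd.DataFrame, code_sets: dict | None = None):
    """Validate and normalize a record frame; returns (clean, report).

    Pattern rules: NHS-number checksum, postcode shape, name alphabet; code
    sets for sex, admission_method, source, site; range rule for dob
    (within 110 years before the activity date, never after it).  Failing
    values are set missing and counted; records are never dropped here.
    Idempotent: validating the output again changes nothing.
    """
    if code_sets is None:
        code_sets = default_code_sets()
    df = records.copy().reset_index(drop=True)
    n = len(df)
    rows: dict = {}
    issues: list = []
    rid = df["record_id"]

    # NHS number: checksum pattern rule
    raw = df["nhs_number"]
    missing = raw.isna()
    ok = raw.map(lambda v: validate_nhs_number(v) if isinstance(v, str) else False)
    invalid = ~missing & ~ok
    df.loc[invalid, "nhs_number"] = None
    _count(rows, issues, rid, "nhs_number", missing, invalid, pd.Series(False, index=df.index), n)

    # postcode: normalize, blank non-conforming
    raw = df["postcode"]
    missing = raw.isna()
    norm = raw.map(normalize_postcode)
    invalid = ~missing & norm.isna()
    corrected = ~missing & norm.notna() & (norm != raw)
    df["postcode"] = norm
    _count(rows, issues, rid, "postcode", missing, invalid, corrected, n)

    # names
    for col in ("first_name", "last_name"):
        raw = df[col]
        missing = raw.isna()
        norm = raw.map(normalize_name)
        invalid = ~missing & norm.isna()
        corrected = ~missing & norm.notna() & (norm != raw)
        df[col] = norm
        _count(rows, issues, rid, col, missing, invalid, corrected, n)

    # coded fields
    for col in ("sex", "admission_method", "source", "site"):
        allowed = code_sets.get(col)
        raw = df[col]
        missing = raw.isna()
        if allowed is None:
            invalid = pd.Series(False, index=df.index)
        else:
            invalid = ~missing & ~raw.isin(list(allowed))
        df.loc[invalid, col] = None
        _count(rows, issues, rid, col, missing, invalid, pd.Series(False, index=df.index), n)

    # dob range rule: within 110 years before activity, never after
    dob = pd.to_datetime(df["dob"], errors="coerce")
    start = pd.to_datetime(df["start_datetime"], errors="coerce")
    missing = df["dob"].isna()
    unparseable = ~missing & dob.isna()
    age_days = (start - dob).dt.days
    out_of_range = (
        ~missing & dob.notna() & start.notna()
        & ((age_days < 0) | (age_days > 110 * 365.25))
    )
    invalid = unparseable | out_of_range
    dob[invalid] = pd.NaT
    df["dob"] = dob
    _count(rows, issues, rid, "dob", missing, invalid, pd.Series(False, index=df.index), n)

    # age: plausibility range
    age = pd.to_numeric(df["age_at_activity"], errors="coerce")
    missing = df["age_at_activity"].isna()
    invalid = ~missing & (age.isna() | (age < 0) | (age > 110))
    age[invalid] = np.nan
    df["age_at_activity"] = age.astype("Int64")
    _count(rows, issues, rid, "age_at_activity", missing, invalid, pd.Series(False, index=df.index), n)

    report = ValidationReport(
        n_records=n,
        field_counts=pd.DataFrame(rows).T[["missing", "invalid", "corrected", "valid"]],
        issues=issues,
    )
    return df, report


_SOURCE_FILES = {
    "NHS111": "nhs111.csv",
    "AMB": "ambulance.csv",
    "ED": "ed.csv",
    "IP": "inpatient.csv",
}


def read_records(indir) -> pd.DataFrame:
    """Read the per-source CSVs written by the generator into one frame."""
    from pathlib import Path

    indir = Path(indir)
    frames = []
    for source, fname in _SOURCE_FILES.items():
        path = indir / fname
        if not path.exists():
            continue
        try:
            df = pd.read_csv(
                path,
                dtype={
                    "nhs_number": "string",
                    "provider_patient_id": "string",
                    "age_at_activity": "Int64",
                },
                parse_dates=["dob", "start_datetime", "end_datetime"],
            )
        except (OSError, pd.errors.ParserError) as exc:
            raise IOError(f"unreadable source file {path}: {exc}") from exc
        frames.append(df)
    if not frames:
        raise IOError(f"no source files found under {indir}")
    out = pd.concat(frames, ignore_index=True)
    if "conveyed" in out.columns:
        out["conveyed"] = out["conveyed"].astype("boolean")
    # pandas reads string columns as object with NaN; keep plain python str/None
    for col in ("nhs_number", "provider_patient_id"):
        out[col] = out[col].astype(object).where(out[col].notna(), None)
    return out
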