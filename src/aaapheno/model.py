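"""Coded-EHR domain model: event types, code normalization, wildcard
matching, and delimited-file ingestion.

The phenotyping algorithm consumes three flat streams — the minimal extract
any EMR back end can produce:

1. subject identifiers (the cohort),
2. dated ICD-9 diagnosis events (subject, date, code, clinic, age at event),
3. dated CPT procedure events (same fields, CPT code).

Real extracts mix code dialects ("4414" vs "441.4"), so every code is
normalized on ingestion to the canonical dotted form used throughout the
package; all rule logic then operates on exact strings plus explicit
wildcard patterns (e.g. ``441.*``), never on substring heuristics.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import logging
import re
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSystem",
    "SchemaError",
    "RowParseError",
    "Subject",
    "DiagnosisEvent",
    "ProcedureEvent",
    "CodePattern",
    "normalize_icd9",
    "normalize_cpt",
    "code_matches",
    "load_streams",
    "write_streams",
    "events_from_frame",
    "DEFAULT_COLUMNS",
]


class CodingSystem(str, enum.Enum):
    """Coding system of a pattern or code set."""

    ICD9 = "ICD9"
    CPT = "CPT"


class SchemaError(ValueError):
    """An input table is missing a required column or is structurally invalid."""


class RowParseError(ValueError):
    """One or more rows of an input table could not be parsed.

    Carries the offending 0-based row indices (relative to the data rows of
    the file, header excluded) in :attr:`rows`.
    """

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


@dataclasses.dataclass(frozen=True)
class Subject:
    """One cohort member, identified by an opaque string."""

    subject_id: str

    def __post_init__(self) -> None:
        if not self.subject_id or not str(self.subject_id).strip():
            raise ValueError("subject_id must be non-empty")


@dataclasses.dataclass(frozen=True)
class DiagnosisEvent:
    """One dated, clinic-attributed ICD-9 diagnosis assignment."""

    subject_id: str
    event_date: dt.date
    icd9_code: str
    clinic: str
    age_at_event: int

    def __post_init__(self) -> None:
        if not 0 <= self.age_at_event <= 150:
            raise ValueError(f"age_at_event out of range: {self.age_at_event}")

    @property
    def code(self) -> str:
        return self.icd9_code


@dataclasses.dataclass(frozen=True)
class ProcedureEvent:
    """One dated, clinic-attributed CPT procedure assignment."""

    subject_id: str
    event_date: dt.date
    cpt_code: str
    clinic: str
    age_at_event: int

    def __post_init__(self) -> None:
        if not 0 <= self.age_at_event <= 150:
            raise ValueError(f"age_at_event out of range: {self.age_at_event}")

    @property
    def code(self) -> str:
        return self.cpt_code


# --------------------------------------------------------------------------
# code normalization
# --------------------------------------------------------------------------

_SUBCODE_RE = re.compile(r"^\d{1,2}$")


def _split_undotted_icd9(code: str) -> tuple[str, str]:
    """Split an undotted ICD-9 string into (category, subcode)."""
    if code.startswith("V"):
        width = 3  # V + 2 digits
    elif code.startswith("E"):
        width = 4  # E + 3 digits
    else:
        width = 3  # 3-digit numeric category
    return code[:width], code[width:]


def _pad_category(cat: str) -> str:
    """Left-pad short numeric parts with zeros ('38' -> '038', 'V1' -> 'V01')."""
    if cat.startswith(("V", "E")):
        width = 2 if cat.startswith("V") else 3
        return cat[0] + cat[1:].zfill(width)
    return cat.zfill(3)


def normalize_icd9(raw: str) -> str:
    """Return the canonical dotted form of an ICD-9 code.

    Canonical form: a 3-character category (``441``, ``038``, ``V45``; E codes
    carry a 4-character ``E###`` category), followed by ``.`` and 1–2 digits
    when a subcode is present.  Accepts dotted and undotted input, pads short
    numeric categories with leading zeros, preserves V/E prefixes upper-case,
    and is idempotent.

    Raises
    ------
    ValueError
        For empty input, a category longer than its allowed width before the
        dot, a subcode longer than 2 digits, or non-alphanumeric characters.
    """
    if raw is None:
        raise ValueError("ICD-9 code is missing")
    code = str(raw).strip().upper()
    if not code:
        raise ValueError("ICD-9 code is empty")
    if not re.fullmatch(r"[0-9VE.]+", code):
        raise ValueError(f"malformed ICD-9 code: {raw!r}")

    if "." in code:
        cat, dot, sub = code.partition(".")
        if "." in sub:
            raise ValueError(f"malformed ICD-9 code (multiple dots): {raw!r}")
    else:
        cat, sub = _split_undotted_icd9(code)

    if cat.startswith("V"):
        body, width = cat[1:], 2
    elif cat.startswith("E"):
        body, width = cat[1:], 3
    else:
        body, width = cat, 3
    if not body or not body.isdigit() or len(body) > width:
        raise ValueError(f"malformed ICD-9 category in {raw!r}: {cat!r}")
    cat = _pad_category(cat)

    if sub == "":
        return cat
    if not _SUBCODE_RE.fullmatch(sub):
        raise ValueError(f"malformed ICD-9 subcode in {raw!r}: {sub!r}")
    return f"{cat}.{sub}"


def normalize_cpt(raw: str) -> str:
    """Return the canonical form of a CPT/HCPCS code: trimmed, upper-case.

    Standard CPT codes are 5 characters (digits, or 4 digits + letter for
    category-II/III codes; HCPCS level II is letter + 4 digits).
    """
    if raw is None:
        raise ValueError("CPT code is missing")
    code = str(raw).strip().upper()
    if not code:
        raise ValueError("CPT code is empty")
    if not re.fullmatch(r"[0-9A-Z]{4,5}", code):
        raise ValueError(f"malformed CPT code: {raw!r}")
    return code


# --------------------------------------------------------------------------
# code patterns
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CodePattern:
    """A literal code or a trailing-wildcard pattern in one coding system.

    A wildcard pattern is a category prefix followed by exactly one trailing
    ``.*`` (e.g. ``441.*``) and matches the bare category plus any 1–2 digit
    subcode of that category.
    """

    system: CodingSystem
    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern
        if not pat:
            raise ValueError("empty code pattern")
        if "*" in pat:
            if not pat.endswith(".*") or "*" in pat[:-1]:
                raise ValueError(
                    f"wildcard pattern must have exactly one trailing '.*': {pat!r}"
                )
            prefix = pat[:-2]
            if not prefix or "." in prefix:
                raise ValueError(f"wildcard prefix must be a bare category: {pat!r}")

    @property
    def is_wildcard(self) -> bool:
        return self.pattern.endswith(".*")

    @property
    def prefix(self) -> str:
        """Category prefix of a wildcard pattern (the pattern itself if literal)."""
        return self.pattern[:-2] if self.is_wildcard else self.pattern


def code_matches(pattern: CodePattern, code: str) -> bool:
    """True if a normalized code matches a pattern.

    Literal patterns match by string equality.  A wildcard ``P.*`` matches the
    bare category ``P`` and ``P.d`` / ``P.dd`` for any 1–2 digits — never a
    different category.
    """
    if not pattern.is_wildcard:
        return code == pattern.pattern
    prefix = pattern.prefix
    if code == prefix:
        return True
    if code.startswith(prefix + "."):
        sub = code[len(prefix) + 1 :]
        return bool(_SUBCODE_RE.fullmatch(sub))
    return False


# --------------------------------------------------------------------------
# delimited-file I/O
# --------------------------------------------------------------------------

#: Default column names; override any of them via the ``columns`` mapping.
DEFAULT_COLUMNS: dict[str, str] = {
    "subject_id": "subject_id",
    "event_date": "event_date",
    "icd9_code": "icd9_code",
    "cpt_code": "cpt_code",
    "clinic": "clinic",
    "age_at_event": "age_at_event",
}

_EVENT_FIELDS = ("subject_id", "event_date", "clinic", "age_at_event")


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        # sniff from the header; fall back to comma for single-column files
        import csv

        with open(path, newline="") as fh:
            header = fh.readline()
        try:
            delimiter = csv.Sniffer().sniff(header, delimiters=",;\t|").delimiter
        except csv.Error:
            delimiter = ","
    return pd.read_csv(path, sep=delimiter, dtype=str)


def _require_columns(df: pd.DataFrame, names: Iterable[str], path) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def _parse_events(
    df: pd.DataFrame,
    colmap: Mapping[str, str],
    code_field: str,
    normalizer,
    path,
) -> pd.DataFrame:
    required = [colmap[f] for f in _EVENT_FIELDS] + [colmap[code_field]]
    _require_columns(df, required, path)

    out = pd.DataFrame(index=df.index)
    out["subject_id"] = df[colmap["subject_id"]].astype(str).str.strip()

    dates = pd.to_datetime(df[colmap["event_date"]], errors="coerce", format="mixed")
    bad = list(df.index[dates.isna()])
    if bad:
        raise RowParseError(
            f"{path}: unparseable {colmap['event_date']!r} in rows {bad[:10]}"
            + (" ..." if len(bad) > 10 else ""),
            bad,
        )
    out["event_date"] = dates.dt.normalize()

    ages = pd.to_numeric(df[colmap["age_at_event"]], errors="coerce")
    bad = list(df.index[ages.isna() | (ages < 0) | (ages > 150) | (ages % 1 != 0)])
    if bad:
        raise RowParseError(
            f"{path}: invalid {colmap['age_at_event']!r} in rows {bad[:10]}"
            + (" ..." if len(bad) > 10 else ""),
            bad,
        )
    out["age_at_event"] = ages.astype(int)

    codes, bad = [], []
    for i, v in df[colmap[code_field]].items():
        try:
            codes.append(normalizer(v))
        except ValueError:
            codes.append(None)
            bad.append(i)
    if bad:
        raise RowParseError(
            f"{path}: malformed {colmap[code_field]!r} in rows {bad[:10]}"
            + (" ..." if len(bad) > 10 else ""),
            bad,
        )
    out[code_field] = codes

    # Blank clinic means "not attributed to any clinic" -> non-specialty.
    out["clinic"] = df[colmap["clinic"]].fillna("").astype(str).str.strip()
    return out[["subject_id", "event_date", code_field, "clinic", "age_at_event"]]


def load_streams(
    subjects_path,
    dx_path,
    px_path,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and validate the three input streams.

    Events whose ``subject_id`` does not appear in the subject table are
    dropped with a logged count (the identifier stream acts as the cohort
    filter).  All codes are normalized and all dates day-truncated.

    Parameters
    ----------
    columns
        Optional mapping from logical field name (keys of
        :data:`DEFAULT_COLUMNS`) to the column name used in the files.
    delimiter
        Field delimiter; auto-detected when ``None``.

    Returns
    -------
    (subjects, diagnoses, procedures)
        DataFrames with canonical column names.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}

    subjects = _read_table(subjects_path, delimiter)
    _require_columns(subjects, [colmap["subject_id"]], subjects_path)
    subjects = pd.DataFrame(
        {"subject_id": subjects[colmap["subject_id"]].astype(str).str.strip()}
    )
    if subjects.empty:
        raise SchemaError(f"{subjects_path}: subject table is empty")
    dupes = subjects["subject_id"][subjects["subject_id"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(
            f"{subjects_path}: duplicate subject ids: {list(dupes[:5])}"
        )

    dx = _parse_events(_read_table(dx_path, delimiter), colmap, "icd9_code",
                       normalize_icd9, dx_path)
    px = _parse_events(_read_table(px_path, delimiter), colmap, "cpt_code",
                       normalize_cpt, px_path)

    known = set(subjects["subject_id"])
    for name, frame in (("diagnosis", dx), ("procedure", px)):
        unknown = ~frame["subject_id"].isin(known)
        if unknown.any():
            logger.warning(
                "dropped %d %s event(s) with subject ids outside the cohort",
                int(unknown.sum()), name,
            )
    dx = dx[dx["subject_id"].isin(known)].reset_index(drop=True)
    px = px[px["subject_id"].isin(known)].reset_index(drop=True)
    return subjects, dx, px


def write_streams(out_dir, subjects: pd.DataFrame, dx: pd.DataFrame,
                  px: pd.DataFrame) -> dict[str, str]:
    """Serialize the three streams as CSV under ``out_dir``; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, frame in (("subjects", subjects), ("diagnoses", dx),
                        ("procedures", px)):
        path = os.path.join(out_dir, f"{name}.csv")
        frame = frame.copy()
        if "event_date" in frame.columns:
            frame["event_date"] = pd.to_datetime(frame["event_date"]).dt.strftime(
                "%Y-%m-%d"
            )
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def events_from_frame(frame: pd.DataFrame, system: CodingSystem):
    """Convert a loaded event DataFrame to a list of event objects."""
    cls = DiagnosisEvent if system is CodingSystem.ICD9 else ProcedureEvent
    code_col = "icd9_code" if system is CodingSystem.ICD9 else "cpt_code"
    out = []
    for row in frame.itertuples(index=False):
        date = getattr(row, "event_date")
        if isinstance(date, pd.Timestamp):
            date = date.date()
        out.append(
            cls(
                subject_id=str(getattr(row, "subject_id")),
                event_date=date,
                **{code_col: getattr(row, code_col)},
                clinic=str(getattr(row, "clinic")) if getattr(row, "clinic") == getattr(row, "clinic") else "",
                age_at_event=int(getattr(row, "age_at_event")),
            )
        )
    return out
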