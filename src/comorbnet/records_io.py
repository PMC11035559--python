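"""Reading and normalising raw diagnosis records.

The pipeline's input atom is one diagnosis event: an opaque patient
identifier, a gender (``M``/``W``), an ICD-10 code and the patient's age
at the event (given directly, or derived from birth and event dates).
Codes are kept at the three-or-four character level ``XX.X`` — one letter,
two digits, optionally a dot and a single further digit — and every valid
code maps to exactly one ICD-10 chapter block.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Gender",
    "DiagnosisEvent",
    "ChapterCategory",
    "ICDCodeError",
    "RecordSchema",
    "ParseReport",
    "normalize_icd",
    "chapter_of",
    "table_block",
    "parse_records",
    "MAX_AGE",
]

MAX_AGE = 130

#: days per year used when deriving completed years from two dates
_DAYS_PER_YEAR = 365.25


class Gender(str, enum.Enum):
    """Patient gender as stratified in the registry: men (M) / women (W)."""

    M = "M"
    W = "W"


class ICDCodeError(ValueError):
    """Raised for a string that cannot be reduced to a valid ICD-10 code."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"not a valid ICD-10 code: {raw!r}")


@dataclass(frozen=True, order=True)
class DiagnosisEvent:
    patient_id: str
    gender: Gender
    icd_code: str
    age_at_event: int

    def __post_init__(self) -> None:
        if not 0 <= self.age_at_event <= MAX_AGE:
            raise ValueError(f"age_at_event out of [0, {MAX_AGE}]: {self.age_at_event}")
        if not _CODE_RE.fullmatch(self.icd_code):
            raise ICDCodeError(self.icd_code)


# normalized form: letter + two digits + optional ".d"
_CODE_RE = re.compile(r"[A-Z][0-9]{2}(\.[0-9])?")
# accepted raw forms before truncation / re-punctuation
_RAW_RE = re.compile(r"([A-Z])([0-9]{2})(?:\.?([0-9]+))?")


def normalize_icd(raw: str) -> str:
    """Normalise a raw ICD-10 string to the ``XX.X`` code level.

    Upper-cases, re-punctuates dotless subcodes (``"I671"`` -> ``"I67.1"``)
    and truncates anything beyond one post-decimal digit (``"I67.12"`` ->
    ``"I67.1"``); three-character codes pass through unchanged.  Idempotent
    on its own output.

    Raises
    ------
    ICDCodeError
        If *raw* cannot be reduced to the letter + two digits (+ one
        optional decimal digit) pattern.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ICDCodeError(str(raw))
    s = raw.strip().upper()
    m = _RAW_RE.fullmatch(s)
    if m is None:
        raise ICDCodeError(raw)
    letter, digits, sub = m.groups()
    if sub is None:
        return f"{letter}{digits}"
    return f"{letter}{digits}.{sub[0]}"


@dataclass(frozen=True)
class ChapterCategory:
    """One ICD-10 chapter block: an inclusive code range plus display tags."""

    start: str  # e.g. "H00"
    end: str  # e.g. "H59"
    label: str
    display_color: str | None = None

    def contains(self, code: str) -> bool:
        stem = code[:3]
        return self.start <= stem <= self.end

    @property
    def block_label(self) -> str:
        return f"{self.start}-{self.end}"


# Full ICD-10 chapter table.  Ranges are widened to letter boundaries where
# the official chapters leave gaps (e.g. E90->E99) so that every syntactically
# valid code maps to exactly one category.  Colors follow the conventional
# chapter palette used for ego-network rendering.
CHAPTERS: tuple[ChapterCategory, ...] = (
    ChapterCategory("A00", "B99", "Certain infectious and parasitic diseases"),
    ChapterCategory("C00", "D49", "Neoplasms"),
    ChapterCategory("D50", "D99", "Diseases of the blood and blood-forming organs"),
    ChapterCategory("E00", "E99", "Endocrine, nutritional and metabolic diseases", "lightblue"),
    ChapterCategory("F00", "F99", "Mental and behavioural disorders", "cyan"),
    ChapterCategory("G00", "G99", "Diseases of the nervous system", "yellow"),
    ChapterCategory("H00", "H59", "Diseases of the eye and adnexa", "coral"),
    ChapterCategory("H60", "H99", "Diseases of the ear and mastoid process", "coral"),
    ChapterCategory("I00", "I99", "Diseases of the circulatory system", "green"),
    ChapterCategory("J00", "J99", "Diseases of the respiratory system"),
    ChapterCategory("K00", "K99", "Diseases of the digestive system"),
    ChapterCategory("L00", "L99", "Diseases of the skin and subcutaneous tissue"),
    ChapterCategory("M00", "M99", "Diseases of the musculoskeletal system and connective tissue"),
    ChapterCategory("N00", "N99", "Diseases of the genitourinary system"),
    ChapterCategory("O00", "O99", "Pregnancy, childbirth and the puerperium"),
    ChapterCategory("P00", "P99", "Certain conditions originating in the perinatal period"),
    ChapterCategory("Q00", "Q99", "Congenital malformations, deformations and chromosomal abnormalities", "pink"),
    ChapterCategory("R00", "R99", "Symptoms, signs and abnormal clinical and laboratory findings", "orange"),
    ChapterCategory("S00", "T99", "Injury, poisoning and certain other consequences of external causes"),
    ChapterCategory("U00", "U99", "Codes for special purposes"),
    ChapterCategory("V00", "Y99", "External causes of morbidity and mortality"),
    ChapterCategory("Z00", "Z99", "Factors influencing health status and contact with health services", "violet"),
)

_MERGED_H = ChapterCategory("H00", "H99", "Diseases of the eye and adnexa / ear and mastoid process", "coral")

#: single-letter blocks used for tabular ego-network summaries; anything
#: outside them is pooled under ``"other"``.
TABLE_BLOCKS: tuple[str, ...] = (
    "E00-E99", "F00-F99", "G00-G99", "H00-H99", "I00-I99",
    "J00-J99", "M00-M99", "Q00-Q99", "R00-R99", "Z00-Z99",
)


def chapter_of(code: str, merged_h: bool = False) -> ChapterCategory:
    """Map a normalised code to its (unique) ICD-10 chapter block.

    With ``merged_h=True`` the eye (H00-H59) and ear (H60-H95) blocks are
    reported as a single H00-H99 block, the convention used in tabular
    summaries.
    """
    if not _CODE_RE.fullmatch(code):
        raise ICDCodeError(code)
    if merged_h and code[0] == "H":
        return _MERGED_H
    for cat in CHAPTERS:
        if cat.contains(code):
            return cat
    raise AssertionError("chapter table is total; unreachable")  # pragma: no cover


def table_block(code: str) -> str:
    """Single-letter block label for summary tables, or ``"other"``."""
    block = f"{code[0]}00-{code[0]}99"
    return block if block in TABLE_BLOCKS else "other"


@dataclass
class RecordSchema:
    """Column-name mapping from an input delimited file to event fields.

    Either ``age_at_event`` or both ``birth_date`` and ``diagnosis_date``
    must be mapped; when only dates are given the age is derived as
    completed years, ``floor((diagnosis - birth) / 365.25 days)``.
    """

    patient_id: str = "patient_id"
    gender: str = "gender"
    icd_code: str = "icd_code"
    diagnosis_date: str | None = None
    birth_date: str | None = None
    age_at_event: str | None = "age_at_event"
    delimiter: str = ","

    def required_columns(self) -> list[str]:
        cols = [self.patient_id, self.gender, self.icd_code]
        if self.age_at_event is not None:
            cols.append(self.age_at_event)
            if self.diagnosis_date is not None:
                cols.append(self.diagnosis_date)
        elif self.diagnosis_date is not None and self.birth_date is not None:
            cols += [self.diagnosis_date, self.birth_date]
        else:
            raise ValueError(
                "schema must map age_at_event, or both diagnosis_date and birth_date"
            )
        return cols


@dataclass
class ParseReport:
    """Row accounting for one parse: read = kept + dropped, with reasons."""

    rows_read: int = 0
    rows_kept: int = 0
    rows_dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def duplicates_collapsed(self) -> int:
        return self.drop_reasons.get("duplicate", 0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["duplicates_collapsed"] = self.duplicates_collapsed
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def parse_records(
    source: str | Path,
    schema: RecordSchema | Mapping[str, str] | None = None,
) -> tuple[list[DiagnosisEvent], ParseReport]:
    """Parse a delimited registry file into normalised diagnosis events.

    Malformed rows (bad code, unknown gender, unparseable date/age, missing
    fields) are dropped and tallied per reason, never silently; duplicate
    (patient, code, date-or-age) rows collapse to one event.

    Returns the events in input order (first occurrence wins) plus a
    :class:`ParseReport` satisfying ``rows_read == rows_kept + rows_dropped``
    (duplicates count as dropped, under the ``"duplicate"`` reason).
    """
    if schema is None:
        schema = RecordSchema()
    elif isinstance(schema, Mapping):
        schema = RecordSchema(**schema)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")

    df = pd.read_csv(path, sep=schema.delimiter, dtype=str, keep_default_na=False)
    for col in schema.required_columns():
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")

    report = ParseReport(rows_read=len(df))
    events: list[DiagnosisEvent] = []
    seen: set[tuple] = set()

    def drop(reason: str) -> None:
        report.rows_dropped += 1
        report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + 1

    use_age = schema.age_at_event is not None and schema.age_at_event in df.columns
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pid = str(row[schema.patient_id]).strip()
        if not pid:
            drop("missing_patient_id")
            continue
        g = str(row[schema.gender]).strip().upper()
        if g not in ("M", "W"):
            drop("unknown_gender")
            continue
        try:
            code = normalize_icd(row[schema.icd_code])
        except ICDCodeError:
            drop("invalid_icd_code")
            continue
        if use_age:
            try:
                age = int(str(row[schema.age_at_event]).strip())
            except ValueError:
                drop("invalid_age")
                continue
            dedup_time = age if schema.diagnosis_date is None else row.get(schema.diagnosis_date)
        else:
            try:
                dx = pd.Timestamp(str(row[schema.diagnosis_date]))
                born = pd.Timestamp(str(row[schema.birth_date]))
                if pd.isna(dx) or pd.isna(born):
                    raise ValueError
            except ValueError:
                drop("invalid_date")
                continue
            age = int((dx - born).days // _DAYS_PER_YEAR)
            dedup_time = str(row[schema.diagnosis_date]).strip()
        if not 0 <= age <= MAX_AGE:
            drop("age_out_of_range")
            continue
        key = (pid, code, dedup_time)
        if key in seen:
            drop("duplicate")
            continue
        seen.add(key)
        events.append(DiagnosisEvent(pid, Gender(g), code, age))
        report.rows_kept += 1
    return events, report


def write_registry(events: Iterable[DiagnosisEvent], path: str | Path) -> None:
    """Write events as a CSV in the same schema :func:`parse_records` reads."""
    df = pd.DataFrame(
        [(e.patient_id, e.gender.value, e.icd_code, e.age_at_event) for e in events],
        columns=["patient_id", "gender", "icd_code", "age_at_event"],
    )
    df.to_csv(path, index=False)
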