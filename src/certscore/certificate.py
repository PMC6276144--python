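"""Domain model for medical certificates of cause of death (MCCOD).

A certificate follows the WHO international form: Part 1 holds the chain of
events leading to death on up to four lines (line *a* = immediate cause; the
lowest used line is the underlying cause of death, UCOD), each with a time
interval from onset to death; Part 2 holds contributing conditions. This
module defines the record types, batch CSV input/output and structural
validation. Structural findings (e.g. an interval unit without a value) are
distinct from the certification *errors* detected in :mod:`certscore.rules`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd


class IntervalUnit(enum.StrEnum):
    MINUTES = "minutes"
    HOURS = "hours"
    DAYS = "days"
    WEEKS = "weeks"
    MONTHS = "months"
    YEARS = "years"


class AgeUnit(enum.StrEnum):
    DAYS = "days"
    MONTHS = "months"
    YEARS = "years"


class Sex(enum.StrEnum):
    MALE = "male"
    FEMALE = "female"


class GBDGroup(enum.StrEnum):
    """Broad Global Burden of Disease cause groups."""

    COMMUNICABLE = "communicable"
    NON_COMMUNICABLE = "non_communicable"
    EXTERNAL = "external"
    ILL_DEFINED = "ill_defined"


class Arm(enum.StrEnum):
    """Study arm: paper pre-intervention, online system, online + training."""

    PRE_INTERVENTION = "pre_intervention"
    ONLINE = "online"
    ONLINE_TRAINING = "online_training"


SENIORITY_BANDS = ("0-5", "6-10", "11-15", "16-20", "21-25", "26-30", ">30")

SPECIALITIES = (
    "general_medicine",
    "internal_medicine",
    "pediatrics_neonatology",
    "intensive_care",
    "pneumology",
    "oncology",
    "emergency",
    "general_surgery",
    "other",
)

FACILITY_LEVELS = ("I", "II", "III")


@dataclass(frozen=True)
class CauseLine:
    """One Part 1 line: a condition and its onset-to-death interval.

    ``position`` 1 corresponds to line "a" (immediate cause); the highest
    used position holds the underlying cause of death.
    """

    position: int
    cause_text: str = ""
    interval_value: float | None = None
    interval_unit: IntervalUnit | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 4:
            raise ValueError(f"position must be 1..4, got {self.position}")

    @property
    def is_empty(self) -> bool:
        return not self.cause_text.strip()

    @property
    def has_interval(self) -> bool:
        return self.interval_value is not None and self.interval_unit is not None


@dataclass(frozen=True)
class CertificateRecord:
    certificate_id: str
    part1: tuple[CauseLine, CauseLine, CauseLine, CauseLine]
    part2: str
    age_value: float
    age_unit: AgeUnit | None
    sex: Sex
    gbd_group: GBDGroup
    arm: Arm
    seniority_years: str
    speciality: str
    facility_level: str
    months_since_training: float | None = None

    def used_lines(self) -> list[CauseLine]:
        """Part 1 lines with non-empty cause text, in position order."""
        return [ln for ln in self.part1 if not ln.is_empty]

    @property
    def ucod_line(self) -> CauseLine | None:
        """The lowest-positioned non-empty Part 1 line (the UCOD)."""
        used = self.used_lines()
        return used[-1] if used else None

    @property
    def age_years(self) -> float:
        """Age expressed in years (value taken as years when unit absent)."""
        if self.age_unit == AgeUnit.DAYS:
            return self.age_value / 365.25
        if self.age_unit == AgeUnit.MONTHS:
            return self.age_value / 12.0
        return self.age_value


@dataclass(frozen=True)
class ValidationFinding:
    """A structural problem with a record (not a certification error)."""

    code: str
    message: str
    line: int | None = None


def validate_record(record: CertificateRecord) -> list[ValidationFinding]:
    """Structural validation; an empty list means structurally valid."""
    findings: list[ValidationFinding] = []
    positions = [ln.position for ln in record.part1]
    if sorted(positions) != [1, 2, 3, 4]:
        findings.append(
            ValidationFinding("bad_positions", f"part1 positions {positions} are not 1..4")
        )
    for ln in record.part1:
        if (ln.interval_value is None) != (ln.interval_unit is None):
            findings.append(
                ValidationFinding(
                    "partial_interval",
                    "interval value and unit must be present together",
                    line=ln.position,
                )
            )
        if ln.interval_value is not None and ln.interval_value < 0:
            findings.append(
                ValidationFinding("negative_interval", "interval value < 0", line=ln.position)
            )
        if ln.is_empty and ln.has_interval:
            findings.append(
                ValidationFinding(
                    "interval_without_cause", "interval given on an empty line", line=ln.position
                )
            )
    used = record.used_lines()
    if not used:
        findings.append(ValidationFinding("no_cause", "no cause reported in part 1"))
    elif record.part1[0].is_empty:
        # Leading blank before the chain is structural, not the blank-lines error.
        findings.append(ValidationFinding("leading_blank", "line 1a is empty", line=1))
    if record.age_value < 0:
        findings.append(ValidationFinding("negative_age", "age_value < 0"))
    if record.arm == Arm.PRE_INTERVENTION and record.months_since_training is not None:
        findings.append(
            ValidationFinding(
                "months_in_pre_arm",
                "months_since_training present for a pre-intervention certificate",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

#: Mandatory columns of the certificate batch CSV. Intervals are encoded as
#: "value;unit" in a single column per line to keep the schema flat.
CERTIFICATE_COLUMNS = (
    "certificate_id",
    "cause_1a",
    "interval_1a",
    "cause_1b",
    "interval_1b",
    "cause_1c",
    "interval_1c",
    "cause_1d",
    "interval_1d",
    "part2",
    "age_value",
    "age_unit",
    "sex",
    "gbd_group",
    "arm",
    "seniority_years",
    "speciality",
    "facility_level",
    "months_since_training",
)


class SchemaError(ValueError):
    """The CSV lacks a mandatory column or has an unusable layout."""


class RowError(ValueError):
    """A data row could not be parsed; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class ColumnMapping:
    """Optional renames and per-column value maps applied before parsing.

    ``columns`` maps schema name -> actual CSV header; ``values`` maps column
    name -> {csv value -> canonical value} (keys matched case-insensitively).
    """

    columns: dict[str, str] = field(default_factory=dict)
    values: dict[str, dict[str, str]] = field(default_factory=dict)

    def source_column(self, name: str) -> str:
        return self.columns.get(name, name)

    def map_value(self, column: str, value: str) -> str:
        vmap = self.values.get(column)
        if vmap:
            for key, out in vmap.items():
                if key.lower() == value.lower():
                    return out
        return value


def _parse_enum(enum_cls, value: str, column: str, row: int):
    try:
        return enum_cls(value.strip().lower())
    except ValueError:
        raise RowError(row, f"unparseable {column} value {value!r}") from None


def _parse_interval(cell: str, row: int, position: int) -> tuple[float | None, IntervalUnit | None]:
    cell = cell.strip()
    if not cell:
        return None, None
    try:
        value_s, unit_s = cell.split(";")
        value = float(value_s)
        unit = IntervalUnit(unit_s.strip().lower())
    except (ValueError, TypeError):
        raise RowError(row, f"unparseable interval_{'abcd'[position - 1]} value {cell!r}") from None
    return value, unit


def _parse_band(value: str, allowed: Sequence[str], column: str, row: int) -> str:
    v = value.strip()
    for cand in allowed:
        if cand.lower() == v.lower():
            return cand
    raise RowError(row, f"unparseable {column} value {value!r}")


def read_certificates(source, mapping: ColumnMapping | None = None) -> list[CertificateRecord]:
    """Read a certificate batch CSV into records, preserving row order.

    ``source`` is a path or open text stream. Empty cells become absent/empty
    fields; enumerations parse case-insensitively. Raises :class:`SchemaError`
    for a missing mandatory column and :class:`RowError` (with the 1-based
    data-row number) for an unparseable value. An empty file yields ``[]``.
    """
    mapping = mapping or ColumnMapping()
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in CERTIFICATE_COLUMNS if mapping.source_column(c) not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[CertificateRecord] = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, raw))
        get = lambda c: mapping.map_value(c, str(row[mapping.source_column(c)]))  # noqa: E731
        lines = []
        for pos, letter in enumerate("abcd", start=1):
            value, unit = _parse_interval(get(f"interval_1{letter}"), i, pos)
            lines.append(
                CauseLine(pos, get(f"cause_1{letter}").strip(), value, unit)
            )
        age_unit_s = get("age_unit").strip()
        months_s = get("months_since_training").strip()
        try:
            age_value = float(get("age_value"))
        except ValueError:
            raise RowError(i, f"unparseable age_value {get('age_value')!r}") from None
        try:
            months = float(months_s) if months_s else None
        except ValueError:
            raise RowError(i, f"unparseable months_since_training {months_s!r}") from None
        records.append(
            CertificateRecord(
                certificate_id=get("certificate_id"),
                part1=tuple(lines),
                part2=get("part2").strip(),
                age_value=age_value,
                age_unit=_parse_enum(AgeUnit, age_unit_s, "age_unit", i) if age_unit_s else None,
                sex=_parse_enum(Sex, get("sex"), "sex", i),
                gbd_group=_parse_enum(GBDGroup, get("gbd_group"), "gbd_group", i),
                arm=_parse_enum(Arm, get("arm"), "arm", i),
                seniority_years=_parse_band(get("seniority_years"), SENIORITY_BANDS, "seniority_years", i),
                speciality=_parse_band(get("speciality"), SPECIALITIES, "speciality", i),
                facility_level=_parse_band(get("facility_level"), FACILITY_LEVELS, "facility_level", i),
                months_since_training=months,
            )
        )
    return records


def certificates_to_frame(records: Iterable[CertificateRecord]) -> pd.DataFrame:
    """Render records to a DataFrame on the batch CSV schema."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"certificate_id": rec.certificate_id}
        for ln, letter in zip(rec.part1, "abcd"):
            row[f"cause_1{letter}"] = ln.cause_text
            row[f"interval_1{letter}"] = (
                f"{ln.interval_value:g};{ln.interval_unit}" if ln.has_interval else ""
            )
        row.update(
            part2=rec.part2,
            age_value=rec.age_value,
            age_unit=str(rec.age_unit) if rec.age_unit else "",
            sex=str(rec.sex),
            gbd_group=str(rec.gbd_group),
            arm=str(rec.arm),
            seniority_years=rec.seniority_years,
            speciality=rec.speciality,
            facility_level=rec.facility_level,
            months_since_training="" if rec.months_since_training is None else rec.months_since_training,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CERTIFICATE_COLUMNS))


def write_certificates(records: Iterable[CertificateRecord], sink) -> None:
    """Write a certificate batch CSV (inverse of :func:`read_certificates`)."""
    certificates_to_frame(records).to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# Assessment CSV (records + error profiles + scores)
# ---------------------------------------------------------------------------

ASSESSMENT_FLAG_COLUMNS = (
    "multiple_causes_per_line",
    "missing_time_interval",
    "incorrect_sequence",
    "ill_defined_ucod",
    "blank_lines",
    "abbreviations",
    "additional_errors",
    "external_missing_details",
    "neoplasm_missing_details",
    "age_no_units",
    "other_additional",
)

ASSESSMENT_COLUMNS = (
    "certificate_id",
    "arm",
    *ASSESSMENT_FLAG_COLUMNS,
    "n_major",
    "n_minor",
    "n_errors",
    "score",
    "correct",
)


def write_assessment(records, profiles, scores, sink) -> None:
    """Write the per-certificate assessment CSV (flags as 0/1).

    Raises ``ValueError`` on a length mismatch. Round-trips through
    :func:`read_assessment`.
    """
    records, profiles, scores = list(records), list(profiles), list(scores)
    if not (len(records) == len(profiles) == len(scores)):
        raise ValueError(
            f"length mismatch: {len(records)} records, {len(profiles)} profiles, "
            f"{len(scores)} scores"
        )
    rows = []
    for rec, prof, sc in zip(records, profiles, scores):
        row = {"certificate_id": rec.certificate_id, "arm": str(rec.arm)}
        flags = prof.as_dict()
        for col in ASSESSMENT_FLAG_COLUMNS:
            row[col] = int(flags[col])
        row.update(
            n_major=sc.n_major,
            n_minor=sc.n_minor,
            n_errors=sc.n_errors,
            score=sc.score,
            correct=int(sc.correct),
        )
        rows.append(row)
    pd.DataFrame(rows, columns=list(ASSESSMENT_COLUMNS)).to_csv(sink, index=False)


def read_assessment(source) -> pd.DataFrame:
    """Read an assessment CSV; flag and score columns come back as integers."""
    df = pd.read_csv(source, dtype={"certificate_id": str})
    missing = [c for c in ASSESSMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing assessment column(s): {', '.join(missing)}")
    for col in (*ASSESSMENT_FLAG_COLUMNS, "n_major", "n_minor", "n_errors", "score", "correct"):
        df[col] = df[col].astype(int)
    return df


__all__ = [
    "AgeUnit",
    "Arm",
    "ASSESSMENT_COLUMNS",
    "ASSESSMENT_FLAG_COLUMNS",
    "CERTIFICATE_COLUMNS",
    "CauseLine",
    "CertificateRecord",
    "ColumnMapping",
    "FACILITY_LEVELS",
    "GBDGroup",
    "IntervalUnit",
    "RowError",
    "SchemaError",
    "SENIORITY_BANDS",
    "Sex",
    "SPECIALITIES",
    "ValidationFinding",
    "certificates_to_frame",
    "read_assessment",
    "read_certificates",
    "validate_record",
    "write_assessment",
    "write_certificates",
]
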