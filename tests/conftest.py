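"""Shared fixtures and builders for the certscore test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from certscore.certificate import (
    AgeUnit,
    Arm,
    CauseLine,
    CertificateRecord,
    GBDGroup,
    IntervalUnit,
    Sex,
)
from certscore.rules import ERROR_TYPES, SUBTYPES, ErrorProfile, SubtypeFlags, default_rules
from certscore.simulate import Attributes


@pytest.fixture(scope="session")
def rules():
    return default_rules()


def make_record(
    lines,
    part2: str = "",
    *,
    age_value: float = 60.0,
    age_unit: AgeUnit | None = AgeUnit.YEARS,
    sex: Sex = Sex.MALE,
    gbd_group: GBDGroup = GBDGroup.NON_COMMUNICABLE,
    arm: Arm = Arm.ONLINE,
    seniority: str = "11-15",
    speciality: str = "general_medicine",
    facility: str = "II",
    months: float | None = None,
    intervals: bool = True,
) -> CertificateRecord:
    """Build a record from up to four Part 1 cause texts.

    ``lines`` items are either a cause string, None/"" for an empty line, or
    a (text, value, unit) triple. Plain strings get a default interval when
    ``intervals`` is true.
    """
    part1 = []
    for pos in range(1, 5):
        item = lines[pos - 1] if pos - 1 < len(lines) else None
        if item is None or item == "":
            part1.append(CauseLine(pos))
        elif isinstance(item, tuple):
            text, value, unit = item
            part1.append(CauseLine(pos, text, value, unit))
        elif intervals:
            part1.append(CauseLine(pos, item, float(pos), IntervalUnit.DAYS))
        else:
            part1.append(CauseLine(pos, item))
    return CertificateRecord(
        certificate_id="test-0",
        part1=tuple(part1),
        part2=part2,
        age_value=age_value,
        age_unit=age_unit,
        sex=sex,
        gbd_group=gbd_group,
        arm=arm,
        seniority_years=seniority,
        speciality=speciality,
        facility_level=facility,
        months_since_training=months,
    )


def all_plantable_profiles():
    """Every ErrorProfile the generator can plant: 2^7 flag combinations,
    additional-error certificates expanded over their subtypes (the
    external subtype is impossible together with an ill-defined UCOD)."""
    out = []
    for flags in itertools.product([False, True], repeat=len(ERROR_TYPES)):
        named = dict(zip(ERROR_TYPES, flags))
        if not named["additional_errors"]:
            out.append(ErrorProfile(**named))
            continue
        for subtype in SUBTYPES:
            if subtype == "external_missing_details" and named["ill_defined_ucod"]:
                continue
            out.append(ErrorProfile(**named, subtypes=SubtypeFlags(**{subtype: True})))
    return out


def attributes_for(profile: ErrorProfile, arm: Arm, rng: np.random.Generator) -> Attributes:
    """A random attribute draw consistent with the profile's constraints."""
    gbd = (
        GBDGroup.ILL_DEFINED
        if profile.ill_defined_ucod
        else GBDGroup(["communicable", "non_communicable", "external"][int(rng.integers(3))])
    )
    return Attributes(
        certificate_id="t-0",
        arm=arm,
        age_value=float(rng.integers(0, 100)),
        sex=Sex(["male", "female"][int(rng.integers(2))]),
        gbd_group=gbd,
        seniority_years="6-10",
        speciality="internal_medicine",
        facility_level="III",
        months_since_training=4.0 if arm == Arm.ONLINE_TRAINING else None,
    )
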