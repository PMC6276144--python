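"""Group-level summary tables: correctness, error prevalence, attributes.

All percentages are computed on unrounded counts; 1-decimal rounding is
applied only when rendering. Improvement columns are percentage-point
differences, pre-intervention minus each intervention arm, computed on the
unrounded percentages and rounded at presentation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .certificate import Arm, CertificateRecord
from .rules import ERROR_TYPES, SUBTYPES, ErrorProfile
from .scoring import COUNT_BANDS, ScoreResult, error_count_band

ARM_ORDER = (Arm.PRE_INTERVENTION, Arm.ONLINE, Arm.ONLINE_TRAINING)
IMPROVEMENT_COLUMNS = ("improvement_online", "improvement_online_training")

AGE_BANDS = ("0-4", "5-44", "45-64", "65-74", "75-84", ">=85")
MONTHS_BANDS = ("<3", "3-6", ">6")


def improvement(p_pre: float, p_post: float) -> float:
    """Percentage-point improvement, pre minus post (positive = improvement)."""
    for p in (p_pre, p_post):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"percentage out of [0, 100]: {p}")
    return p_pre - p_post


def age_band(age_years: float) -> str:
    edges = (5, 45, 65, 75, 85)
    for band, hi in zip(AGE_BANDS, edges):
        if age_years < hi:
            return band
    return AGE_BANDS[-1]


def months_band(months: float) -> str:
    """Months-since-training band; the 3-month boundary falls in 3-6."""
    if months < 3:
        return "<3"
    if months <= 6:
        return "3-6"
    return ">6"


def _check_arms(arms: Iterable[str]) -> list[str]:
    present: list[str] = []
    valid = {str(a) for a in Arm}
    for a in pd.unique(pd.Series(list(arms))):
        if a not in valid:
            raise ValueError(f"unknown arm label {a!r}")
        present.append(a)
    return [str(a) for a in ARM_ORDER if str(a) in present]


def _add_improvements(table: pd.DataFrame) -> pd.DataFrame:
    pre = str(Arm.PRE_INTERVENTION)
    if pre in table.columns:
        for arm, col in zip((Arm.ONLINE, Arm.ONLINE_TRAINING), IMPROVEMENT_COLUMNS):
            if str(arm) in table.columns:
                table[col] = table[pre] - table[str(arm)]
    return table


def correctness_table(scores_by_arm: pd.DataFrame) -> pd.DataFrame:
    """Distribution of error-count bands per arm, with improvements.

    ``scores_by_arm`` needs columns ``arm`` and ``n_errors``. Rows are the
    bands 0 (correctly certified), 1, 2, 3, 4+; cells are column percentages
    (summing to 100 per arm before rounding); improvement columns give
    pre-intervention minus intervention percentages per band.
    """
    df = scores_by_arm
    if df.empty:
        raise ValueError("at least one certificate per arm is required")
    arms = _check_arms(df["arm"])
    bands = df["n_errors"].map(error_count_band)
    out = pd.DataFrame(index=list(COUNT_BANDS))
    for arm in arms:
        sub = bands[df["arm"] == arm]
        counts = sub.value_counts().reindex(COUNT_BANDS, fill_value=0)
        out[arm] = 100.0 * counts / counts.sum()
    out.index.name = "n_errors_band"
    # Improvement is the *rise* in the correctly-certified share, reported on
    # the band-0 row only (the error-count bands carry no improvement column).
    pre = str(Arm.PRE_INTERVENTION)
    if pre in out.columns:
        for arm, col in zip((Arm.ONLINE, Arm.ONLINE_TRAINING), IMPROVEMENT_COLUMNS):
            if str(arm) in out.columns:
                out[col] = float("nan")
                out.loc["0", col] = out.loc["0", str(arm)] - out.loc["0", pre]
    return out


def prevalence_table(profiles_by_arm: pd.DataFrame) -> pd.DataFrame:
    """Per-arm prevalence (%) of each error type and subtype.

    ``profiles_by_arm`` needs an ``arm`` column plus the 0/1 flag columns
    (the assessment-CSV layout). Subtype rows appear below the error types.
    """
    df = profiles_by_arm
    if df.empty:
        raise ValueError("at least one certificate per arm is required")
    arms = _check_arms(df["arm"])
    rows = list(ERROR_TYPES) + list(SUBTYPES)
    out = pd.DataFrame(index=rows)
    for arm in arms:
        sub = df[df["arm"] == arm]
        out[arm] = [100.0 * sub[r].astype(float).mean() for r in rows]
    out.index.name = "error_type"
    return _add_improvements(out)


def profiles_to_frame(
    records: Sequence[CertificateRecord], profiles: Sequence[ErrorProfile]
) -> pd.DataFrame:
    """Flag matrix (0/1) with an ``arm`` column, one row per certificate."""
    rows = []
    for rec, prof in zip(records, profiles):
        row = {"arm": str(rec.arm)}
        row.update({k: int(v) for k, v in prof.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


def attribute_summary(
    records: Sequence[CertificateRecord], scores: Sequence[ScoreResult]
) -> pd.DataFrame:
    """Any-error % and mean error score by deceased/certifier attributes.

    One row per (attribute, category) actually present in the data;
    months-since-training rows cover only certificates carrying that field
    (the trained arm), mirroring the study's tabulation.
    """
    if len(records) != len(scores):
        raise ValueError("records and scores differ in length")
    base = pd.DataFrame(
        {
            "any_error": [0 if s.correct else 1 for s in scores],
            "score": [s.score for s in scores],
            "age_band": [age_band(r.age_years) for r in records],
            "sex": [str(r.sex) for r in records],
            "gbd_group": [str(r.gbd_group) for r in records],
            "seniority_years": [r.seniority_years for r in records],
            "speciality": [r.speciality for r in records],
            "facility_level": [r.facility_level for r in records],
            "months_band": [
                months_band(r.months_since_training)
                if r.months_since_training is not None
                else None
                for r in records
            ],
        }
    )
    order = {
        "age_band": AGE_BANDS,
        "sex": ("male", "female"),
        "gbd_group": ("communicable", "non_communicable", "external", "ill_defined"),
        "seniority_years": None,
        "speciality": None,
        "facility_level": ("I", "II", "III"),
        "months_band": MONTHS_BANDS,
    }
    rows = []
    for attr, cats in order.items():
        sub = base.dropna(subset=[attr])
        grouped = sub.groupby(attr, sort=False)
        stats = {
            cat: (100.0 * g["any_error"].mean(), g["score"].mean(), len(g))
            for cat, g in grouped
        }
        cat_order = cats if cats is not None else sorted(stats)
        for cat in cat_order:
            if cat not in stats:  # categories with zero certificates are omitted
                continue
            pct, mean_score, n = stats[cat]
            rows.append(
                {
                    "attribute": attr,
                    "category": cat,
                    "any_error_pct": pct,
                    "mean_score": mean_score,
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["attribute", "category", "any_error_pct", "mean_score", "n"])


def render_table(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation copy with percentages rounded to ``decimals`` places."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out


def format_table(table: pd.DataFrame, decimals: int = 1) -> str:
    """Aligned plain-text rendering."""
    return render_table(table, decimals).to_string()


__all__ = [
    "AGE_BANDS",
    "ARM_ORDER",
    "IMPROVEMENT_COLUMNS",
    "MONTHS_BANDS",
    "age_band",
    "attribute_summary",
    "correctness_table",
    "format_table",
    "improvement",
    "months_band",
    "prevalence_table",
    "profiles_to_frame",
    "render_table",
]
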