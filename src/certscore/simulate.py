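"""Seeded generator of certificate cohorts with planted error profiles.

Emulates the statistical structure of a three-arm certification-quality
study: a paper-based pre-intervention arm, an online-certification arm and
an online + training arm. Error flags are drawn independently per
certificate with arm-specific base probabilities (defaults calibrated to the
published per-arm prevalences) plus a per-year age effect on the log-odds
scale; attributes are drawn from the published marginal distributions. Each
certificate's text is then *rendered* from the planted profile so that the
rule-based detectors recover exactly that profile (the module's central
round-trip contract). The online system's hard constraints (no blank lines,
fewer abbreviations, ill-defined-cause warning) are emulated purely as lower
planted probabilities in the online arms, not as a mechanistic form model.

The rendering vocabulary is co-designed with the shipped default rule
configuration; a custom :class:`~certscore.rules.RuleConfig` does not change
what the renderer emits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .certificate import (
    Arm,
    AgeUnit,
    CauseLine,
    CertificateRecord,
    GBDGroup,
    IntervalUnit,
    Sex,
)
from .rules import ERROR_TYPES, SUBTYPES, ErrorProfile, SubtypeFlags

# ---------------------------------------------------------------------------
# Default calibration (study conditions)
# ---------------------------------------------------------------------------

_ARMS = ("pre_intervention", "online", "online_training")

#: Per-arm base probability of each error type.
DEFAULT_ERROR_PROBS = {
    "multiple_causes_per_line": (0.020, 0.013, 0.006),
    "missing_time_interval": (0.960, 0.471, 0.300),
    "incorrect_sequence": (0.403, 0.259, 0.179),
    "ill_defined_ucod": (0.520, 0.454, 0.389),
    "blank_lines": (0.113, 0.002, 0.003),
    "abbreviations": (0.117, 0.046, 0.041),
    "additional_errors": (0.323, 0.266, 0.210),
}

#: Per-arm additional-error subtype rates (normalised into mixture weights).
DEFAULT_SUBTYPE_RATES = {
    "external_missing_details": (0.047, 0.046, 0.021),
    "neoplasm_missing_details": (0.150, 0.081, 0.063),
    "age_no_units": (0.000, 0.002, 0.006),
    "other_additional": (0.127, 0.137, 0.120),
}

DEFAULT_AGE_BAND_WEIGHTS = {
    (0, 4): 194,
    (5, 44): 248,
    (45, 64): 373,
    (65, 74): 368,
    (75, 84): 516,
    (85, 99): 394,
}
DEFAULT_SEX_WEIGHTS = {"male": 1087, "female": 1007}
#: Distribution of the broad cause group among non-ill-defined certificates
#: (the ill-defined group is forced by the planted ill-defined-UCOD flag).
DEFAULT_GBD_WEIGHTS = {"communicable": 730, "non_communicable": 1175, "external": 71}
DEFAULT_SENIORITY_WEIGHTS = {
    "0-5": 141, "6-10": 405, "11-15": 412, "16-20": 370,
    "21-25": 245, "26-30": 239, ">30": 288,
}
DEFAULT_SPECIALITY_WEIGHTS = {
    "general_medicine": 468, "internal_medicine": 746, "pediatrics_neonatology": 165,
    "intensive_care": 178, "pneumology": 57, "oncology": 36, "emergency": 170,
    "general_surgery": 63, "other": 217,
}
DEFAULT_FACILITY_WEIGHTS = {"I": 35, "II": 982, "III": 1083}
DEFAULT_MONTHS_BAND_WEIGHTS = {"<3": 234, "3-6": 455, ">6": 211}


class ConfigError(ValueError):
    """The synthetic-cohort configuration is invalid."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort sizes, planted error prevalences and attribute distributions.

    Defaults reproduce the study conditions: arm sizes 300/900/900, per-arm
    error prevalences and additional-error subtype mix from the published
    error tables, attribute margins proportional to the published counts,
    and a per-year age effect of log(1.009) on each error's log-odds,
    centred at the cohort mean age so arm-level prevalences stay on target.
    """

    n_per_arm: dict[str, int] = field(
        default_factory=lambda: {"pre_intervention": 300, "online": 900, "online_training": 900}
    )
    error_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_PROBS)
    )
    subtype_rates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_RATES)
    )
    age_band_weights: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BAND_WEIGHTS)
    )
    sex_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_WEIGHTS))
    gbd_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GBD_WEIGHTS))
    seniority_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENIORITY_WEIGHTS)
    )
    speciality_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIALITY_WEIGHTS)
    )
    facility_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACILITY_WEIGHTS)
    )
    months_band_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MONTHS_BAND_WEIGHTS)
    )
    age_effect: float = math.log(1.009)
    age_reference: float | None = None  # None -> mean age of the default draw
    category_increments: dict[str, float] = field(default_factory=dict)
    doctor_intercept_sd: float = 0.0
    certificates_per_doctor: float = 1.67
    seed: int = 0

    def validate(self) -> None:
        for arm, n in self.n_per_arm.items():
            if arm not in _ARMS:
                raise ConfigError(f"unknown arm {arm!r}")
            if n < 1:
                raise ConfigError(f"n_per_arm[{arm!r}] must be positive")
        for name, probs in {**self.error_probs, **self.subtype_rates}.items():
            if len(probs) != 3:
                raise ConfigError(f"{name!r} needs one probability per arm")
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigError(f"{name!r} probabilities must lie in [0, 1]")
        for wname in (
            "age_band_weights", "sex_weights", "gbd_weights", "seniority_weights",
            "speciality_weights", "facility_weights", "months_band_weights",
        ):
            weights = getattr(self, wname)
            if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ConfigError(f"{wname} must be non-negative with positive sum")
        if self.doctor_intercept_sd < 0:
            raise ConfigError("doctor_intercept_sd must be non-negative")

    @property
    def mean_age(self) -> float:
        """Expected age (years) under the configured age-band distribution."""
        total = sum(self.age_band_weights.values())
        return sum(w * (lo + hi) / 2.0 for (lo, hi), w in self.age_band_weights.items()) / total

    def field_notes(self) -> dict[str, str]:
        """Provenance of each calibrated default."""
        return {
            "n_per_arm": "study arm sizes: 300 pre-intervention, 900 online, 900 online+training",
            "error_probs": "per-arm prevalence of each error type in the assessed certificates",
            "subtype_rates": "per-arm prevalence of each additional-error subtype",
            "age_band_weights": "deceased age-band counts in the assessed sample",
            "sex_weights": "deceased sex counts",
            "gbd_weights": "broad cause-group counts among non-ill-defined certificates",
            "seniority_weights": "certifier seniority-band counts",
            "speciality_weights": "certifier speciality counts",
            "facility_weights": "health-facility level counts",
            "months_band_weights": "months-from-training counts (trained arm only)",
            "age_effect": "per-year odds ratio 1.009 for a higher error score, on the log scale",
        }


def paper_calibrated_config(seed: int = 0) -> SyntheticConfig:
    """The shipped default configuration (see :meth:`SyntheticConfig.field_notes`)."""
    return SyntheticConfig(seed=seed)


# ---------------------------------------------------------------------------
# Rendering vocabulary (co-designed with data/default_rules.yaml)
# ---------------------------------------------------------------------------

#: Valid two-line chains (immediate cause, underlying cause) per cause group.
VALID_CHAINS = {
    "communicable": (
        ("sepsis", "neumonia"),
        ("neumonia", "tuberculosis pulmonar"),
        ("sepsis", "meningitis bacteriana"),
        ("tuberculosis pulmonar", "infeccion por virus de inmunodeficiencia humana"),
        ("sepsis", "infeccion por virus de inmunodeficiencia humana"),
    ),
    "non_communicable": (
        ("infarto agudo de miocardio", "hipertension arterial esencial"),
        ("infarto agudo de miocardio", "diabetes mellitus tipo 2"),
        ("enfermedad renal cronica", "diabetes mellitus tipo 2"),
        ("accidente cerebrovascular isquemico", "hipertension arterial esencial"),
        ("neumonia", "enfermedad pulmonar obstructiva cronica"),
        ("cirrosis hepatica", "hepatitis cronica"),
        ("sepsis", "neoplasia maligna de estomago"),
        ("neumonia", "neoplasia maligna de pulmon"),
        ("peritonitis", "apendicitis aguda"),
    ),
    "external": (
        ("sepsis", "traumatismo encefalocraneano por caida accidental de altura"),
        ("sepsis", "envenenamiento accidental por inhalacion de gas"),
        ("sepsis", "quemadura extensa accidental por fuego directo"),
        ("sepsis", "ahogamiento accidental por inmersion en rio"),
    ),
}

#: (immediate, underlying) pairs outside the causal closure; both mapped.
INVALID_PAIRS = (
    ("diabetes mellitus tipo 2", "fractura de femur"),
    ("fractura de femur", "neumonia"),
    ("tuberculosis pulmonar", "diabetes mellitus tipo 2"),
    ("neumonia", "enfermedad renal cronica"),
)

#: Ill-defined UCOD terms that are unmapped in the category map (do not by
#: themselves imply an improbable sequence).
ILL_DEFINED_PLAIN = (
    "paro cardiaco",
    "insuficiencia cardiaca",
    "insuficiencia hepatica",
    "insuficiencia respiratoria",
    "falla organica multiple",
    "choque",
    "senilidad",
)
#: The mapped mode-of-dying term; non-initiating, so planting it as the UCOD
#: also renders an incorrect sequence.
ILL_DEFINED_NON_INITIATING = "paro cardiorrespiratorio"

BARE_EXTERNAL = ("traumatismo", "envenenamiento", "quemadura", "ahogamiento")
#: Specific single conditions safe above any unmapped UCOD.
NEUTRAL_BASES = ("sepsis", "neumonia", "infarto agudo de miocardio", "cirrosis hepatica")
#: Unmapped, error-free filler conditions.
FILLERS = (
    "anemia cronica",
    "desnutricion proteica",
    "artritis reumatoide",
    "hipotiroidismo",
    "epilepsia",
    "ulcera gastrica",
)
PART2_BENIGN = ("obesidad", "tabaquismo cronico", "alcoholismo cronico")
ABBREVIATIONS_UPPER = ("HTA", "EPOC", "IAM", "VIH", "TBC")
BARE_NEOPLASM = ("tumor", "neoplasia", "cancer")

_INTERVALS = (
    ((1, 48), IntervalUnit.HOURS),   # immediate cause
    ((2, 30), IntervalUnit.DAYS),
    ((1, 11), IntervalUnit.MONTHS),
    ((1, 20), IntervalUnit.YEARS),   # underlying cause
)


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


@dataclass(frozen=True)
class Attributes:
    """Attribute draw for one certificate (inputs to the renderer)."""

    certificate_id: str
    arm: Arm
    age_value: float
    sex: Sex
    gbd_group: GBDGroup
    seniority_years: str
    speciality: str
    facility_level: str
    months_since_training: float | None


class RenderError(RuntimeError):
    """A planted profile combination could not be rendered (none known)."""


def render_certificate(
    profile: ErrorProfile, attributes: Attributes, rng: np.random.Generator
) -> CertificateRecord:
    """Build certificate content manifesting exactly the planted profile.

    Every true flag is made to manifest (e.g. an ill-defined UCOD term on the
    lowest used line, an adjacent cause pair outside the causal closure, an
    empty line strictly inside the chain) and every false flag is guaranteed
    absent, so assessing the rendered certificate with the default rules
    recovers the planted profile.
    """
    sub = profile.subtypes
    seq, illd = profile.incorrect_sequence, profile.ill_defined_ucod
    if illd and sub.external_missing_details:
        raise RenderError("ill-defined UCOD and bare external UCOD cannot co-occur")
    if illd != (attributes.gbd_group == GBDGroup.ILL_DEFINED):
        raise RenderError("gbd_group must be ill_defined iff the ill-defined flag is planted")

    # Underlying-cause override and the two content lines above/below it.
    if illd:
        ucod = ILL_DEFINED_NON_INITIATING if seq else _pick(rng, ILL_DEFINED_PLAIN)
        rest = [_pick(rng, NEUTRAL_BASES), ucod]
    elif sub.external_missing_details:
        if seq:
            rest = ["hipertension arterial esencial", "traumatismo"]
        else:
            ucod = _pick(rng, BARE_EXTERNAL)
            rest = ["sepsis" if ucod == "traumatismo" else _pick(rng, NEUTRAL_BASES), ucod]
    elif seq:
        rest = list(_pick(rng, INVALID_PAIRS))
    else:
        rest = list(_pick(rng, VALID_CHAINS[str(attributes.gbd_group)]))

    combo = f"{_pick(rng, FILLERS)} y {_pick(rng, FILLERS)}"
    if profile.blank_lines:
        top = combo if profile.multiple_causes_per_line else _pick(rng, FILLERS)
        texts: list[str | None] = [top, None, rest[0], rest[1]]
    else:
        texts = ([combo] if profile.multiple_causes_per_line else []) + rest

    # Part 1 lines with plausible, monotone time intervals.
    used_idx = [i for i, t in enumerate(texts) if t is not None]
    drop = _pick(rng, used_idx) if profile.missing_time_interval else None
    lines: list[CauseLine] = []
    for pos in range(1, 5):
        text = texts[pos - 1] if pos - 1 < len(texts) else None
        if text is None:
            lines.append(CauseLine(pos))
            continue
        rank = min(used_idx.index(pos - 1), len(used_idx) - 1)
        slot = round(rank * (len(_INTERVALS) - 1) / max(len(used_idx) - 1, 1))
        (lo, hi), unit = _INTERVALS[slot]
        if pos - 1 == drop:
            lines.append(CauseLine(pos, text.capitalize()))
        else:
            lines.append(
                CauseLine(pos, text.capitalize(), float(rng.integers(lo, hi + 1)), unit)
            )

    # Part 2 pieces.
    pieces: list[str] = []
    if sub.neoplasm_missing_details:
        pieces.append(_pick(rng, BARE_NEOPLASM))
    if sub.other_additional:
        routes = ["hipertension", "diabetes mellitus"]
        if illd:
            routes.append("tuberculosis pulmonar")  # UCOD-capable cause left in Part 2
        pieces.append(_pick(rng, routes))
    if profile.abbreviations:
        pieces.append(_pick(rng, ABBREVIATIONS_UPPER))
    if rng.random() < 0.3:
        pieces.append(_pick(rng, PART2_BENIGN))

    return CertificateRecord(
        certificate_id=attributes.certificate_id,
        part1=tuple(lines),
        part2="; ".join(pieces),
        age_value=attributes.age_value,
        age_unit=None if sub.age_no_units else AgeUnit.YEARS,
        sex=attributes.sex,
        gbd_group=attributes.gbd_group,
        arm=attributes.arm,
        seniority_years=attributes.seniority_years,
        speciality=attributes.speciality,
        facility_level=attributes.facility_level,
        months_since_training=attributes.months_since_training,
    )


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, weights: dict, n: int) -> list:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return [keys[i] for i in rng.choice(len(keys), size=n, p=w / w.sum())]


def _planted_probability(base: float, shift: np.ndarray) -> np.ndarray:
    """Per-certificate probabilities with marginal mean exactly ``base``.

    The covariate shift (age effect, category increments, doctor intercepts)
    redistributes risk on the logit scale *within* the arm; a scalar offset,
    solved by bisection, keeps the arm-level marginal prevalence at the
    configured value — the configured prevalences are arm margins, which is
    what published error-prevalence tables report. 0 and 1 are absorbing.
    """
    if base <= 0.0:
        return np.zeros_like(shift)
    if base >= 1.0:
        return np.ones_like(shift)
    l0 = logit(base)
    if not shift.any():
        return np.full_like(shift, base)
    lo, hi = -20.0, 20.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expit(l0 + mid + shift).mean() < base:
            lo = mid
        else:
            hi = mid
    return expit(l0 + 0.5 * (lo + hi) + shift)


def sample_cohort(
    config: SyntheticConfig | None = None,
) -> list[tuple[CertificateRecord, ErrorProfile]]:
    """Draw a full three-arm cohort of (certificate, planted profile) pairs.

    Fully reproducible from ``config.seed``; assessing each rendered
    certificate with the default rules recovers its planted profile.
    """
    config = config or paper_calibrated_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    age_ref = config.age_reference if config.age_reference is not None else config.mean_age

    out: list[tuple[CertificateRecord, ErrorProfile]] = []
    for arm_idx, arm_name in enumerate(_ARMS):
        n = config.n_per_arm.get(arm_name, 0)
        if n == 0:
            continue
        arm = Arm(arm_name)
        bands = _draw(rng, config.age_band_weights, n)
        ages = np.array([rng.integers(lo, hi + 1) for lo, hi in bands], dtype=float)
        sexes = _draw(rng, config.sex_weights, n)
        gbd_draws = _draw(rng, config.gbd_weights, n)
        seniorities = _draw(rng, config.seniority_weights, n)
        specialities = _draw(rng, config.speciality_weights, n)
        facilities = _draw(rng, config.facility_weights, n)
        if arm == Arm.ONLINE_TRAINING:
            month_bands = _draw(rng, config.months_band_weights, n)
            months = [
                round(float(rng.uniform(*{"<3": (0.25, 3.0), "3-6": (3.0, 6.0), ">6": (6.0, 12.0)}[b])), 1)
                for b in month_bands
            ]
        else:
            months = [None] * n

        shift = config.age_effect * (ages - age_ref)
        if config.category_increments:
            attrs_by_cov = {
                "sex": sexes, "gbd_group": gbd_draws, "seniority_years": seniorities,
                "speciality": specialities, "facility_level": facilities,
            }
            for key, delta in config.category_increments.items():
                cov, _, value = key.partition("=")
                if cov in attrs_by_cov:
                    shift = shift + delta * np.array(
                        [v == value for v in attrs_by_cov[cov]], dtype=float
                    )
        if config.doctor_intercept_sd > 0:
            n_doctors = max(1, round(n / config.certificates_per_doctor))
            intercepts = rng.normal(0.0, config.doctor_intercept_sd, n_doctors)
            shift = shift + intercepts[rng.integers(0, n_doctors, n)]

        flags = {}
        planted_p = {}
        for err in ERROR_TYPES:
            p = _planted_probability(config.error_probs[err][arm_idx], shift)
            planted_p[err] = p
            flags[err] = rng.random(n) < p

        # Subtype mixture targets; the external subtype is impossible on
        # ill-defined certificates, so weights are conditioned on that flag
        # to keep the *marginal* subtype rates on target.
        sub_w = np.array(
            [config.subtype_rates[s][arm_idx] for s in SUBTYPES], dtype=float
        )
        t = sub_w / sub_w.sum() if sub_w.sum() > 0 else np.array([0.0, 0.0, 0.0, 1.0])
        t_ext, t_rest = t[0], max(1.0 - t[0], 1e-12)
        for i in range(n):
            subtype_flags = SubtypeFlags()
            if flags["additional_errors"][i]:
                if flags["ill_defined_ucod"][i]:
                    w = np.array([0.0, *(t[1:] / t_rest)])
                else:
                    q = planted_p["ill_defined_ucod"][i]
                    w_ext = min(t_ext / max(1.0 - q, 1e-12), 1.0)
                    w = np.array([w_ext, *(t[1:] * (1.0 - w_ext) / t_rest)])
                if w.sum() <= 0:
                    chosen = "other_additional"
                else:
                    chosen = SUBTYPES[int(rng.choice(len(SUBTYPES), p=w / w.sum()))]
                subtype_flags = SubtypeFlags(**{chosen: True})
            profile = ErrorProfile(
                multiple_causes_per_line=bool(flags["multiple_causes_per_line"][i]),
                missing_time_interval=bool(flags["missing_time_interval"][i]),
                incorrect_sequence=bool(flags["incorrect_sequence"][i]),
                ill_defined_ucod=bool(flags["ill_defined_ucod"][i]),
                blank_lines=bool(flags["blank_lines"][i]),
                abbreviations=bool(flags["abbreviations"][i]),
                additional_errors=bool(flags["additional_errors"][i]),
                subtypes=subtype_flags,
            )
            attrs = Attributes(
                certificate_id=f"{arm_name}-{i:05d}",
                arm=arm,
                age_value=float(ages[i]),
                sex=Sex(sexes[i]),
                gbd_group=GBDGroup.ILL_DEFINED
                if profile.ill_defined_ucod
                else GBDGroup(gbd_draws[i]),
                seniority_years=seniorities[i],
                speciality=specialities[i],
                facility_level=facilities[i],
                months_since_training=months[i],
            )
            out.append((render_certificate(profile, attrs, rng), profile))
    return out


def split_cohort(cohort):
    """(records, profiles) lists from a sampled cohort."""
    records = [rec for rec, _ in cohort]
    profiles = [prof for _, prof in cohort]
    return records, profiles


__all__ = [
    "Attributes",
    "ConfigError",
    "DEFAULT_ERROR_PROBS",
    "DEFAULT_SUBTYPE_RATES",
    "RenderError",
    "SyntheticConfig",
    "paper_calibrated_config",
    "render_certificate",
    "sample_cohort",
    "split_cohort",
]
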