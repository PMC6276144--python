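"""Deterministic detectors for the seven certification error types.

Four *major* errors (weight 2 in the composite score) — multiple causes per
line, missing time interval, incorrect sequence of events, ill-defined
underlying cause — and three *minor* errors (weight 1) — blank lines within
the chain, abbreviations, and "additional errors" with four reported
subtypes. Each detector is a pure function of the record and a
:class:`RuleConfig` holding the lexical knowledge (ill-defined cause lexicon,
abbreviation list, condition-category causal relation, ...). The shipped
default configuration is a deliberately explicit stand-in for the clinical
judgment a human certificate reviewer applies; every lexicon is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from ._text import contains_term, normalize, raw_tokens, tokens
from .certificate import CauseLine, CertificateRecord, ValidationFinding, validate_record

MAJOR_ERRORS = (
    "multiple_causes_per_line",
    "missing_time_interval",
    "incorrect_sequence",
    "ill_defined_ucod",
)
MINOR_ERRORS = ("blank_lines", "abbreviations", "additional_errors")
ERROR_TYPES = MAJOR_ERRORS + MINOR_ERRORS
SUBTYPES = (
    "external_missing_details",
    "neoplasm_missing_details",
    "age_no_units",
    "other_additional",
)


@dataclass(frozen=True)
class SubtypeFlags:
    external_missing_details: bool = False
    neoplasm_missing_details: bool = False
    age_no_units: bool = False
    other_additional: bool = False

    def __bool__(self) -> bool:
        return any(self.as_dict().values())

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in SUBTYPES}


@dataclass(frozen=True)
class ErrorProfile:
    """Seven error flags plus additional-error subtype flags.

    Invariant: ``additional_errors`` is true iff at least one subtype flag is.
    """

    multiple_causes_per_line: bool = False
    missing_time_interval: bool = False
    incorrect_sequence: bool = False
    ill_defined_ucod: bool = False
    blank_lines: bool = False
    abbreviations: bool = False
    additional_errors: bool = False
    subtypes: SubtypeFlags = field(default_factory=SubtypeFlags)

    def __post_init__(self) -> None:
        if self.additional_errors != bool(self.subtypes):
            raise ValueError("additional_errors must equal OR of subtype flags")

    def as_dict(self) -> dict[str, bool]:
        d = {name: getattr(self, name) for name in ERROR_TYPES}
        d.update(self.subtypes.as_dict())
        return d

    @property
    def any_error(self) -> bool:
        return any(getattr(self, name) for name in ERROR_TYPES)


class RuleConfigError(ValueError):
    """The rule configuration violates its invariants."""


@dataclass(frozen=True)
class RuleConfig:
    """Lexical knowledge driving the detectors (all text pre-normalized)."""

    ill_defined: frozenset[str]
    abbreviations: frozenset[str]
    abbreviation_whitelist: frozenset[str]
    conjunctions: tuple[str, ...]
    category_map: dict[str, str]
    causal_pairs: frozenset[tuple[str, str]]
    non_initiating: frozenset[str]
    neoplasm_terms: frozenset[str]
    neoplasm_qualifiers: frozenset[str]
    external_terms: frozenset[str]
    external_intent_terms: frozenset[str]
    external_mechanism_terms: frozenset[str]
    hypertension_terms: frozenset[str]
    hypertension_qualifiers: frozenset[str]
    diabetes_terms: frozenset[str]
    diabetes_qualifiers: frozenset[str]
    ucod_capable_terms: frozenset[str]

    def __post_init__(self) -> None:
        for name in (
            "ill_defined",
            "abbreviations",
            "conjunctions",
            "neoplasm_terms",
            "external_terms",
            "hypertension_terms",
            "diabetes_terms",
        ):
            if not getattr(self, name):
                raise RuleConfigError(f"lexicon {name!r} must be non-empty")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph: dict[str, set[str]] = {}
        for cause, cons in self.causal_pairs:
            graph.setdefault(cause, set()).add(cons)
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(node: str, path: tuple[str, ...]) -> None:
            if state.get(node) == 2:
                return
            if state.get(node) == 1:
                raise RuleConfigError(f"causal_relation has a cycle through {node!r}")
            state[node] = 1
            for nxt in graph.get(node, ()):
                visit(nxt, path + (node,))
            state[node] = 2

        for node in list(graph):
            visit(node, ())

    @property
    def closure(self) -> dict[str, frozenset[str]]:
        """Transitive closure of the causal relation: category -> reachable."""
        try:
            return self._closure_cache  # type: ignore[attr-defined]
        except AttributeError:
            pass
        graph: dict[str, set[str]] = {}
        for cause, cons in self.causal_pairs:
            graph.setdefault(cause, set()).add(cons)
        closure: dict[str, frozenset[str]] = {}
        for start in graph:
            seen: set[str] = set()
            stack = list(graph[start])
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                stack.extend(graph.get(node, ()))
            closure[start] = frozenset(seen)
        object.__setattr__(self, "_closure_cache", closure)
        return closure

    def category_of(self, cause_text: str) -> str | None:
        return self.category_map.get(normalize(cause_text))

    @classmethod
    def from_dict(cls, data: dict) -> "RuleConfig":
        def norm_set(key: str) -> frozenset[str]:
            return frozenset(normalize(t) for t in data.get(key, []))

        return cls(
            ill_defined=norm_set("ill_defined"),
            abbreviations=norm_set("abbreviations"),
            abbreviation_whitelist=frozenset(str(t) for t in data.get("abbreviation_whitelist", [])),
            conjunctions=tuple(str(t) for t in data.get("conjunctions", [])),
            category_map={normalize(k): str(v) for k, v in data.get("category_map", {}).items()},
            causal_pairs=frozenset((str(a), str(b)) for a, b in data.get("causal_pairs", [])),
            non_initiating=frozenset(str(t) for t in data.get("non_initiating", [])),
            neoplasm_terms=norm_set("neoplasm_terms"),
            neoplasm_qualifiers=norm_set("neoplasm_qualifiers"),
            external_terms=norm_set("external_terms"),
            external_intent_terms=norm_set("external_intent_terms"),
            external_mechanism_terms=norm_set("external_mechanism_terms"),
            hypertension_terms=norm_set("hypertension_terms"),
            hypertension_qualifiers=norm_set("hypertension_qualifiers"),
            diabetes_terms=norm_set("diabetes_terms"),
            diabetes_qualifiers=norm_set("diabetes_qualifiers"),
            ucod_capable_terms=norm_set("ucod_capable_terms"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RuleConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_rules() -> RuleConfig:
    """The rule configuration shipped with the package."""
    text = resources.files("certscore.data").joinpath("default_rules.yaml").read_text("utf-8")
    return RuleConfig.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------


def detect_multiple_causes_per_line(line: CauseLine, config: RuleConfig) -> bool:
    """More than one condition phrase on a single Part 1 line."""
    if line.is_empty:
        return False
    text = normalize(line.cause_text)
    for token in config.conjunctions:
        text = text.replace(token, "\x00")
    phrases = [p for p in text.split("\x00") if any(c.isalnum() for c in p)]
    return len(phrases) >= 2


def detect_missing_time_interval(record: CertificateRecord) -> bool:
    """Any used Part 1 line without an onset-to-death interval."""
    return any(not ln.has_interval for ln in record.used_lines())


def detect_incorrect_sequence(record: CertificateRecord, config: RuleConfig) -> bool:
    """Clinically improbable chain of events in Part 1.

    Each used line's condition is mapped to a category; the flag fires when
    an adjacent used pair (position p+1 causing position p) is outside the
    transitive closure of the causal relation, or when the UCOD's category is
    marked non-initiating. Unmapped conditions are treated as compatible.
    """
    by_pos = {ln.position: ln for ln in record.part1}
    for pos in (1, 2, 3):
        upper, lower = by_pos.get(pos), by_pos.get(pos + 1)
        if upper is None or lower is None or upper.is_empty or lower.is_empty:
            continue
        cat_up = config.category_of(upper.cause_text)
        cat_low = config.category_of(lower.cause_text)
        if cat_up is None or cat_low is None or cat_up == cat_low:
            continue
        if cat_up not in config.closure.get(cat_low, frozenset()):
            return True
    ucod = record.ucod_line
    if ucod is not None:
        cat = config.category_of(ucod.cause_text)
        if cat is not None and cat in config.non_initiating:
            return True
    return False


def detect_ill_defined_ucod(record: CertificateRecord, config: RuleConfig) -> bool:
    """Ill-defined or poorly specified condition as the underlying cause."""
    ucod = record.ucod_line
    if ucod is None:
        return False
    return normalize(ucod.cause_text) in config.ill_defined


def detect_blank_lines(record: CertificateRecord) -> bool:
    """An empty Part 1 line strictly between two used lines.

    Leading blanks (empty 1a above the chain) are a structural validation
    finding, not this error; trailing blanks are allowed.
    """
    used = [ln.position for ln in record.part1 if not ln.is_empty]
    if len(used) < 2:
        return False
    lo, hi = min(used), max(used)
    empty = {ln.position for ln in record.part1 if ln.is_empty}
    return any(lo < pos < hi for pos in empty)


def detect_abbreviations(record: CertificateRecord, config: RuleConfig) -> bool:
    """Abbreviation used anywhere in the cause text (Parts 1 and 2)."""
    texts = [ln.cause_text for ln in record.used_lines()]
    if record.part2.strip():
        texts.append(record.part2)
    for text in texts:
        if any(tok in config.abbreviations for tok in tokens(text)):
            return True
        for tok in raw_tokens(text):
            if tok.isupper() and 2 <= len(tok) <= 6 and tok not in config.abbreviation_whitelist:
                return True
    return False


def detect_additional_errors(record: CertificateRecord, config: RuleConfig) -> SubtypeFlags:
    """The reported subtypes of the "additional errors" minor type."""
    cause_texts = [normalize(ln.cause_text) for ln in record.used_lines()]
    part2 = normalize(record.part2)
    all_texts = cause_texts + ([part2] if part2 else [])

    def has_any(text: str, terms: frozenset[str]) -> bool:
        return any(contains_term(text, t) for t in terms)

    ucod = record.ucod_line
    ucod_text = normalize(ucod.cause_text) if ucod is not None else ""
    external = (
        bool(ucod_text)
        and has_any(ucod_text, config.external_terms)
        and not has_any(ucod_text, config.external_intent_terms)
        and not has_any(ucod_text, config.external_mechanism_terms)
    )
    neoplasm = any(
        has_any(t, config.neoplasm_terms) and not has_any(t, config.neoplasm_qualifiers)
        for t in all_texts
    )
    age_no_units = record.age_unit is None
    ucod_ill_defined = ucod_text in config.ill_defined
    other = (
        any(
            (has_any(t, config.hypertension_terms) and not has_any(t, config.hypertension_qualifiers))
            or (has_any(t, config.diabetes_terms) and not has_any(t, config.diabetes_qualifiers))
            for t in all_texts
        )
        or (bool(part2) and ucod_ill_defined and has_any(part2, config.ucod_capable_terms))
    )
    return SubtypeFlags(
        external_missing_details=external,
        neoplasm_missing_details=neoplasm,
        age_no_units=age_no_units,
        other_additional=other,
    )


class AssessmentError(ValueError):
    """The record is structurally invalid and cannot be assessed."""

    def __init__(self, findings: list[ValidationFinding]):
        super().__init__("; ".join(f.message for f in findings))
        self.findings = findings


def assess(
    record: CertificateRecord, config: RuleConfig | None = None, *, strict: bool = True
) -> ErrorProfile:
    """Run all detectors on one certificate.

    With ``strict`` (default) a structurally invalid record raises
    :class:`AssessmentError` listing the validation findings.
    """
    config = config or default_rules()
    if strict:
        findings = validate_record(record)
        if findings:
            raise AssessmentError(findings)
    subtypes = detect_additional_errors(record, config)
    return ErrorProfile(
        multiple_causes_per_line=any(
            detect_multiple_causes_per_line(ln, config) for ln in record.part1
        ),
        missing_time_interval=detect_missing_time_interval(record),
        incorrect_sequence=detect_incorrect_sequence(record, config),
        ill_defined_ucod=detect_ill_defined_ucod(record, config),
        blank_lines=detect_blank_lines(record),
        abbreviations=detect_abbreviations(record, config),
        additional_errors=bool(subtypes),
        subtypes=subtypes,
    )


def assess_batch(records, config: RuleConfig | None = None, *, strict: bool = True):
    """Assess an iterable of records; returns a list of profiles."""
    config = config or default_rules()
    return [assess(rec, config, strict=strict) for rec in records]


__all__ = [
    "AssessmentError",
    "ERROR_TYPES",
    "ErrorProfile",
    "MAJOR_ERRORS",
    "MINOR_ERRORS",
    "RuleConfig",
    "RuleConfigError",
    "SUBTYPES",
    "SubtypeFlags",
    "assess",
    "assess_batch",
    "default_rules",
    "detect_abbreviations",
    "detect_additional_errors",
    "detect_blank_lines",
    "detect_ill_defined_ucod",
    "detect_incorrect_sequence",
    "detect_missing_time_interval",
    "detect_multiple_causes_per_line",
]
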