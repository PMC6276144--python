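"""Error-type detectors: one test class per rule plus whole-profile checks."""

import dataclasses

import numpy as np
import pytest

from certscore.certificate import Arm, CauseLine, GBDGroup
from certscore.rules import (
    ErrorProfile,
    RuleConfig,
    RuleConfigError,
    SubtypeFlags,
    assess,
    detect_abbreviations,
    detect_additional_errors,
    detect_blank_lines,
    detect_ill_defined_ucod,
    detect_incorrect_sequence,
    detect_missing_time_interval,
    detect_multiple_causes_per_line,
)

from conftest import make_record


class TestMultipleCausesPerLine:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("neumonia; sepsis", True),
            ("neumonia, sepsis", True),
            ("neumonia y sepsis", True),
            ("neumonia", False),
            ("insuficiencia renal cronica", False),  # multiword single condition
            ("", False),
        ],
    )
    def test_conjunction_splitting(self, rules, text, expected):
        assert detect_multiple_causes_per_line(CauseLine(1, text), rules) is expected


class TestMissingTimeInterval:
    def test_one_missing_interval_among_used_lines_suffices(self):
        rec = make_record(["Sepsis", "Neumonia", ("Tuberculosis pulmonar", None, None)])
        assert detect_missing_time_interval(rec) is True

    def test_all_used_lines_with_intervals(self):
        rec = make_record(["Sepsis", "Neumonia"])
        assert detect_missing_time_interval(rec) is False


class TestIncorrectSequence:
    def test_permitted_pair_passes(self, rules):
        rec = make_record(["sepsis", "diabetes mellitus tipo 2"])
        assert detect_incorrect_sequence(rec, rules) is False

    def test_pair_outside_closure_fires(self, rules):
        rec = make_record(["diabetes mellitus tipo 2", "fractura de femur"])
        assert detect_incorrect_sequence(rec, rules) is True

    def test_transitive_reachability_is_honoured(self, rules):
        # tuberculosis -> pneumonia -> sepsis: a two-step path is compatible
        rec = make_record(["sepsis", "tuberculosis pulmonar"])
        assert detect_incorrect_sequence(rec, rules) is False

    def test_single_used_line_cannot_violate(self, rules):
        rec = make_record(["neumonia"])
        assert detect_incorrect_sequence(rec, rules) is False

    def test_unmapped_conditions_are_compatible(self, rules):
        rec = make_record(["anemia cronica", "hipotiroidismo"])
        assert detect_incorrect_sequence(rec, rules) is False

    def test_non_initiating_ucod_fires(self, rules):
        rec = make_record(["sepsis", "paro cardiorrespiratorio"])
        assert detect_incorrect_sequence(rec, rules) is True

    def test_cyclic_relation_rejected(self, rules):
        with pytest.raises(RuleConfigError, match="cycle"):
            dataclasses.replace(
                rules, causal_pairs=frozenset({("a", "b"), ("b", "c"), ("c", "a")})
            )


class TestIllDefinedUcod:
    @pytest.mark.parametrize(
        "ucod,expected",
        [
            ("paro cardiaco", True),  # mode of dying
            ("insuficiencia hepatica", True),  # organ failure
            ("Paro Cardíaco", True),  # accent/case insensitive
            ("tuberculosis pulmonar", False),
            ("neoplasia maligna de estomago", False),
        ],
    )
    def test_lowest_used_line_matched_against_lexicon(self, rules, ucod, expected):
        rec = make_record(["Sepsis", ucod])
        assert detect_ill_defined_ucod(rec, rules) is expected

    def test_ucod_is_lowest_used_line_not_line_a(self, rules):
        rec = make_record(["paro cardiaco", "tuberculosis pulmonar"])
        assert detect_ill_defined_ucod(rec, rules) is False


class TestBlankLines:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            (["Sepsis", None, "Neumonia", None], True),  # gap inside the chain
            (["Sepsis", "Neumonia", None, None], False),  # trailing blanks allowed
            ([None, "Sepsis", "Neumonia", None], False),  # leading blank is structural
            (["Sepsis", None, None, "Neumonia"], True),
        ],
    )
    def test_strictly_between_used_lines(self, pattern, expected):
        assert detect_blank_lines(make_record(pattern)) is expected


class TestAbbreviations:
    def test_lexicon_token_in_part1(self, rules):
        assert detect_abbreviations(make_record(["IAM"]), rules) is True

    def test_spelled_out_causes_pass(self, rules):
        rec = make_record(["Infarto agudo de miocardio", "Diabetes mellitus tipo 2"])
        assert detect_abbreviations(rec, rules) is False

    def test_part2_is_included(self, rules):
        rec = make_record(["Sepsis", "Neumonia"], part2="VIH")
        assert detect_abbreviations(rec, rules) is True

    def test_unknown_all_caps_token_fires(self, rules):
        # the heuristic covers 2-6 letter capitals absent from the whitelist
        rec = make_record(["Sepsis por BGN", "Neumonia"])
        assert detect_abbreviations(rec, rules) is True

    def test_long_capitalised_word_is_not_an_abbreviation(self, rules):
        rec = make_record(["Sepsis por PSEUDOMONAS", "Neumonia"])
        assert detect_abbreviations(rec, rules) is False

    def test_whitelisted_roman_numerals_pass(self, rules):
        rec = make_record(["Insuficiencia cardiaca clase III", "Neumonia"])
        assert detect_abbreviations(rec, rules) is False


class TestAdditionalErrors:
    def test_bare_external_ucod_missing_details(self, rules):
        rec = make_record(["Sepsis", "Traumatismo"], gbd_group=GBDGroup.EXTERNAL)
        assert detect_additional_errors(rec, rules).external_missing_details is True

    def test_external_with_intent_and_mechanism_passes(self, rules):
        rec = make_record(
            ["Sepsis", "Traumatismo encefalocraneano por caida accidental de altura"],
            gbd_group=GBDGroup.EXTERNAL,
        )
        assert detect_additional_errors(rec, rules).external_missing_details is False

    def test_qualified_neoplasm_passes(self, rules):
        rec = make_record(["Sepsis", "Neoplasia maligna de estomago"])
        assert detect_additional_errors(rec, rules).neoplasm_missing_details is False

    def test_bare_neoplasm_fires(self, rules):
        rec = make_record(["Sepsis", "Neumonia"], part2="tumor")
        assert detect_additional_errors(rec, rules).neoplasm_missing_details is True

    def test_age_without_units(self, rules):
        rec = make_record(["Sepsis", "Neumonia"], age_unit=None)
        assert detect_additional_errors(rec, rules).age_no_units is True

    def test_unqualified_hypertension_is_other(self, rules):
        rec = make_record(["Sepsis", "Neumonia"], part2="hipertension")
        assert detect_additional_errors(rec, rules).other_additional is True

    def test_qualified_hypertension_passes(self, rules):
        rec = make_record(["Infarto agudo de miocardio", "Hipertension arterial esencial"])
        assert detect_additional_errors(rec, rules).other_additional is False

    def test_ucod_capable_cause_in_part2_with_ill_defined_ucod(self, rules):
        rec = make_record(
            ["Sepsis", "paro cardiaco"],
            part2="tuberculosis pulmonar",
            gbd_group=GBDGroup.ILL_DEFINED,
        )
        assert detect_additional_errors(rec, rules).other_additional is True

    def test_ucod_capable_cause_in_part2_with_specific_ucod_passes(self, rules):
        rec = make_record(["Sepsis", "Neumonia"], part2="tuberculosis pulmonar")
        assert detect_additional_errors(rec, rules).other_additional is False


class TestAssess:
    def test_error_free_certificate_all_false(self, rules):
        prof = assess(make_record(["Sepsis", "Neumonia"]), rules)
        assert prof == ErrorProfile()

    def test_single_planted_error_yields_exactly_that_flag(self, rules):
        rec = make_record(["Sepsis", "Neumonia"], intervals=False)
        prof = assess(rec, rules)
        assert prof == ErrorProfile(missing_time_interval=True)

    def test_determinism(self, rules):
        rec = make_record(["Sepsis", "paro cardiaco"], gbd_group=GBDGroup.ILL_DEFINED)
        assert assess(rec, rules) == assess(rec, rules)

    def test_ill_defined_ucod_implies_at_least_one_error(self, rules):
        rec = make_record(["Sepsis", "insuficiencia cardiaca"], gbd_group=GBDGroup.ILL_DEFINED)
        assert assess(rec, rules).any_error

    def test_structurally_invalid_record_raises_with_findings(self, rules):
        from certscore.rules import AssessmentError

        with pytest.raises(AssessmentError, match="no cause"):
            assess(make_record([None, None, None, None]), rules)

    def test_adding_ill_defined_lowest_line_never_decreases_flags(self, rules):
        # monotonicity: appending an ill-defined UCOD can only add errors
        rng = np.random.default_rng(0)
        bases = [
            ["Sepsis", "Neumonia"],
            ["Infarto agudo de miocardio", "Diabetes mellitus tipo 2"],
            ["Sepsis", "Neumonia", None],
            ["anemia cronica"],
        ]
        for base in bases:
            rec = make_record([x for x in base if x], gbd_group=GBDGroup.NON_COMMUNICABLE)
            before = sum(assess(rec, rules).as_dict()[k] for k in ErrorProfile().as_dict())
            used = [x for x in base if x]
            term = ["paro cardiaco", "choque", "insuficiencia renal"][int(rng.integers(3))]
            extended = make_record(used + [term], gbd_group=GBDGroup.ILL_DEFINED)
            after = sum(assess(extended, rules).as_dict()[k] for k in ErrorProfile().as_dict())
            assert after >= before

    def test_profile_invariant_enforced(self):
        with pytest.raises(ValueError, match="additional_errors"):
            ErrorProfile(additional_errors=True)
        with pytest.raises(ValueError, match="additional_errors"):
            ErrorProfile(subtypes=SubtypeFlags(age_no_units=True))
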