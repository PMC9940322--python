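"""Code normalization, pattern matching and case ascertainment."""

import datetime as dt
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoconcord.phenotyping import (
    CaseFlag,
    ClaimRecord,
    CodeError,
    CodePattern,
    CodeSystem,
    Condition,
    ConditionDefinition,
    EnrollmentSpan,
    FlagStatus,
    RecordType,
    Source,
    apply_cohort_filters,
    ascertain_bc_case,
    ascertain_max_case,
    code_matches,
    normalize_code,
)
from neoconcord.linkage import MotherInfantPair

BIRTH = dt.date(2005, 3, 14)


def claim(code, system=CodeSystem.ICD9_DX, day=5, person="I1",
          record_type=RecordType.INPATIENT, dx_position=1):
    return ClaimRecord(
        person_id=person,
        record_type=record_type,
        service_date=BIRTH + dt.timedelta(days=day),
        code_system=system,
        code=code,
        dx_position=dx_position,
    )


class TestNormalizeCode:
    @pytest.mark.parametrize("raw,system,expected", [
        ("99,468", CodeSystem.CPT, "99468"),
        ("769.12", CodeSystem.ICD9_DX, "76912"),
        ("96.71", CodeSystem.ICD9_PC, "9671"),
        (" 779.0 ", CodeSystem.ICD9_DX, "7790"),
        ("v30.00", CodeSystem.ICD9_DX, "V3000"),
    ])
    def test_strips_punctuation_and_uppercases(self, raw, system, expected):
        assert normalize_code(raw, system) == expected

    @pytest.mark.parametrize("raw,system", [
        ("", CodeSystem.ICD9_DX),
        ("...", CodeSystem.ICD9_DX),
        ("9946", CodeSystem.CPT),      # four digits
        ("99468X", CodeSystem.CPT),    # CPT admits no wildcards
        ("76x9", CodeSystem.ICD9_DX),  # interior wildcard
    ])
    def test_rejects_malformed_codes_naming_the_value(self, raw, system):
        with pytest.raises(CodeError):
            normalize_code(raw, system)

    def test_wildcards_only_in_patterns(self):
        with pytest.raises(CodeError):
            normalize_code("769.xx", CodeSystem.ICD9_DX)
        assert normalize_code("769.xx", CodeSystem.ICD9_DX, allow_wildcards=True) == "769xx"


class TestCodeMatches:
    @pytest.mark.parametrize("code,pattern,system,expected", [
        ("76912", "769.xx", CodeSystem.ICD9_DX, True),
        ("769", "769.xx", CodeSystem.ICD9_DX, True),
        ("76801", "769.xx", CodeSystem.ICD9_DX, False),
        ("9670", "96.7", CodeSystem.ICD9_PC, True),    # stem matches more specific code
        ("9672", "96.7", CodeSystem.ICD9_PC, True),
        ("9390", "96.7", CodeSystem.ICD9_PC, False),
        ("99468", "99,468", CodeSystem.CPT, True),
        ("99469", "99,468", CodeSystem.CPT, False),
    ])
    def test_prefix_for_icd9_exact_for_cpt(self, code, pattern, system, expected):
        assert code_matches(code, CodePattern(system, pattern), system) is expected

    def test_system_mismatch_is_false_not_an_error(self):
        pattern = CodePattern(CodeSystem.ICD9_DX, "769.xx")
        assert code_matches("76912", pattern, CodeSystem.ICD9_PC) is False


class TestAscertainMax:
    def test_infant_claim_in_window_is_case(self, conditions):
        flag = ascertain_max_case(
            [claim("769.0", day=5)], conditions[Condition.RDS], "I1", "M1", BIRTH
        )
        assert flag.status is FlagStatus.CASE
        assert flag.source is Source.MAX

    def test_same_claim_outside_window_is_noncase(self, conditions):
        flag = ascertain_max_case(
            [claim("769.0", day=45)], conditions[Condition.RDS], "I1", "M1", BIRTH
        )
        assert flag.status is FlagStatus.NONCASE

    @pytest.mark.parametrize("day,expected", [
        (0, FlagStatus.CASE), (30, FlagStatus.CASE), (31, FlagStatus.NONCASE),
        (-1, FlagStatus.NONCASE),
    ])
    def test_window_is_closed_day0_to_day30(self, conditions, day, expected):
        flag = ascertain_max_case(
            [claim("769.0", day=day)], conditions[Condition.RDS], "I1", "M1", BIRTH
        )
        assert flag.status is expected

    def test_mother_record_claim_counts(self, conditions):
        flag = ascertain_max_case(
            [claim("779.00", day=2, person="M1")],
            conditions[Condition.SEIZURE], "I1", "M1", BIRTH,
        )
        assert flag.status is FlagStatus.CASE

    def test_unrelated_person_claim_does_not_count(self, conditions):
        flag = ascertain_max_case(
            [claim("769.0", person="I999")], conditions[Condition.RDS], "I1", "M1", BIRTH
        )
        assert flag.status is FlagStatus.NONCASE

    def test_delivery_claims_are_not_eligible_encounters(self, conditions):
        flag = ascertain_max_case(
            [claim("769.0", record_type=RecordType.DELIVERY)],
            conditions[Condition.RDS], "I1", "M1", BIRTH,
        )
        assert flag.status is FlagStatus.NONCASE

    def test_any_dx_position_counts(self, conditions):
        flag = ascertain_max_case(
            [claim("769.0", dx_position=9)], conditions[Condition.RDS], "I1", "M1", BIRTH
        )
        assert flag.status is FlagStatus.CASE

    def test_empty_claims_is_noncase(self, conditions):
        flag = ascertain_max_case([], conditions[Condition.RDS], "I1", "M1", BIRTH)
        assert flag.status is FlagStatus.NONCASE

    def test_nicu_outside_year_range_is_excluded(self, conditions):
        flag = ascertain_max_case(
            [claim("99,468", system=CodeSystem.CPT)],
            conditions[Condition.NICU], "I1", "M1", dt.date(2002, 6, 1),
        )
        assert flag.status is FlagStatus.EXCLUDED_YEAR


@st.composite
def claim_lists(draw):
    codes = ["769.0", "769.12", "486", "V30.00", "779.0"]
    n = draw(st.integers(0, 12))
    return [
        claim(
            draw(st.sampled_from(codes)),
            day=draw(st.integers(-10, 60)),
            person=draw(st.sampled_from(["I1", "M1", "I2"])),
            record_type=draw(st.sampled_from(list(RecordType))),
        )
        for _ in range(n)
    ]


class TestAscertainmentProperties:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(claims=claim_lists(), seed=st.integers(0, 1000))
    def test_invariant_under_claim_permutation(self, conditions, claims, seed):
        definition = conditions[Condition.RDS]
        base = ascertain_max_case(claims, definition, "I1", "M1", BIRTH)
        shuffled = list(claims)
        random.Random(seed).shuffle(shuffled)
        assert ascertain_max_case(shuffled, definition, "I1", "M1", BIRTH) == base

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(claims=claim_lists(), extra=claim_lists())
    def test_adding_claims_never_revokes_a_case(self, conditions, claims, extra):
        definition = conditions[Condition.RDS]
        before = ascertain_max_case(claims, definition, "I1", "M1", BIRTH)
        after = ascertain_max_case(claims + extra, definition, "I1", "M1", BIRTH)
        if before.status is FlagStatus.CASE:
            assert after.status is FlagStatus.CASE
        if after.status is FlagStatus.NONCASE:
            assert before.status is FlagStatus.NONCASE

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(claims=claim_lists(), days=st.lists(st.integers(31, 400) | st.integers(-400, -1), max_size=5))
    def test_out_of_window_claims_never_affect_the_flag(self, conditions, claims, days):
        definition = conditions[Condition.RDS]
        base = ascertain_max_case(claims, definition, "I1", "M1", BIRTH)
        injected = claims + [claim("769.0", day=d) for d in days]
        assert ascertain_max_case(injected, definition, "I1", "M1", BIRTH) == base


class TestAscertainBC:
    def make_record(self, value):
        from neoconcord.phenotyping import BirthCertRecord

        flags = {c: False for c in Condition}
        flags[Condition.RDS] = value
        return BirthCertRecord("B1", BIRTH, flags)

    @pytest.mark.parametrize("value,expected", [
        (True, FlagStatus.CASE),
        (False, FlagStatus.NONCASE),
        (None, FlagStatus.EXCLUDED_MISSING),
    ])
    def test_checkbox_states(self, conditions, value, expected):
        flag = ascertain_bc_case(self.make_record(value), conditions[Condition.RDS])
        assert flag.status is expected
        assert flag.source is Source.BC

    def test_absent_condition_key_is_rejected_by_name(self, conditions):
        from neoconcord.phenotyping import BirthCertRecord

        record = BirthCertRecord("B1", BIRTH, {Condition.RDS: True})
        with pytest.raises(KeyError, match="NICU"):
            ascertain_bc_case(record, conditions[Condition.NICU])

    def test_excluded_missing_only_on_bc_side(self):
        with pytest.raises(ValueError):
            CaseFlag(Condition.RDS, Source.MAX, FlagStatus.EXCLUDED_MISSING)


class TestCohortFilters:
    def pair(self, birth=BIRTH):
        return MotherInfantPair("M1", "I1", birth, )

    def spans(self, infant_end_day, mother_end_day=60):
        return {
            "I1": [EnrollmentSpan("I1", BIRTH, BIRTH + dt.timedelta(days=infant_end_day))],
            "M1": [EnrollmentSpan("M1", BIRTH - dt.timedelta(days=200),
                                  BIRTH + dt.timedelta(days=mother_end_day))],
        }

    def test_coverage_through_day30_required(self, conditions):
        kept, excl = apply_cohort_filters(
            [self.pair()], self.spans(infant_end_day=29), conditions[Condition.RDS]
        )
        assert not kept and excl[0].reason == "coverage_gap_infant"
        kept, excl = apply_cohort_filters(
            [self.pair()], self.spans(infant_end_day=30), conditions[Condition.RDS]
        )
        assert len(kept) == 1 and not excl

    def test_mother_coverage_also_required(self, conditions):
        kept, excl = apply_cohort_filters(
            [self.pair()], self.spans(60, mother_end_day=10), conditions[Condition.RDS]
        )
        assert not kept and excl[0].reason == "coverage_gap_mother"

    def test_nicu_year_restriction(self, conditions):
        nicu = conditions[Condition.NICU]
        kept, excl = apply_cohort_filters(
            [MotherInfantPair("M1", "I1", dt.date(2002, 5, 1))], self.spans(60), nicu
        )
        assert not kept and excl[0].reason == "excluded_year"
        kept, _ = apply_cohort_filters([self.pair()], self.spans(60), nicu)
        assert len(kept) == 1  # birth year 2005 with full enrollment

    def test_missing_enrollment_is_logged(self, conditions):
        kept, excl = apply_cohort_filters([self.pair()], {}, conditions[Condition.RDS])
        assert not kept and excl[0].reason.startswith("no_enrollment")


def test_default_conditions_cover_all_five(conditions):
    assert set(conditions) == set(Condition)
    assert conditions[Condition.NICU].year_restriction == (2004, 2010)
    assert all(c.window_days == 30 for c in conditions.values())
    assert all(len(conditions[c].codes) > 0 for c in conditions)
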