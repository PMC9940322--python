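"""Condition definitions and case ascertainment.

A *condition* is defined by a set of billing-code patterns (ICD-9-CM
diagnosis, ICD-9-CM procedure, or CPT) together with a postnatal time
window. On the claims side a neonate is a case when at least one
inpatient or outpatient encounter — on the infant's record or, by
default, the mother's — carries a matching code, in any diagnosis
position, with a service date inside the window. On the
birth-certificate side case status is read off an explicit yes/no
checkbox; a blank checkbox is an exclusion, not a negative, because the
certificate form forces a determination whereas an absent claim code is
interpreted as absence of disease.

Wildcard semantics follow ICD-9 family conventions: a pattern such as
``769.xx`` (or the bare stem ``96.7``) matches every more specific code
sharing its root after normalization, while CPT patterns are exact
five-digit matches.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence


class CodeSystem(str, Enum):
    """Coding vocabulary a pattern or claim code belongs to."""

    ICD9_DX = "ICD9_DX"   # ICD-9-CM diagnosis
    ICD9_PC = "ICD9_PC"   # ICD-9-CM procedure
    CPT = "CPT"           # Current Procedural Terminology


class Condition(str, Enum):
    """The five neonatal critical conditions under study."""

    NICU = "NICU"                  # neonatal intensive-care admission
    RDS = "RDS"                    # respiratory distress syndrome
    SEIZURE = "SEIZURE"            # convulsions in newborn
    AV = "AV"                      # assisted (mechanical) ventilation
    BIRTH_INJURY = "BIRTH_INJURY"  # birth trauma


class RecordType(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    DELIVERY = "delivery"


class Source(str, Enum):
    MAX = "MAX"  # Medicaid Analytic eXtract claims
    BC = "BC"    # birth certificate


class FlagStatus(str, Enum):
    CASE = "case"
    NONCASE = "noncase"
    EXCLUDED_MISSING = "excluded_missing"  # blank BC checkbox
    EXCLUDED_YEAR = "excluded_year"        # outside a condition's year range


#: Record types eligible to ascertain a case. Delivery claims identify
#: deliveries for linkage but are not themselves qualifying encounters.
ELIGIBLE_RECORD_TYPES = frozenset({RecordType.INPATIENT, RecordType.OUTPATIENT})

_WILDCARD_RE = re.compile(r"X*$")


class CodeError(ValueError):
    """A raw code or pattern that cannot be normalized for its system."""


def normalize_code(raw: str, system: CodeSystem, *, allow_wildcards: bool = False) -> str:
    """Normalize a raw billing code for matching.

    Dots, commas and whitespace are stripped and letters upper-cased, so
    the printed forms ``99,468`` (CPT) and ``769.12`` (ICD-9 dx) become
    ``99468`` and ``76912``. Wildcard characters (``x``) are only legal
    in patterns (``allow_wildcards=True``) and only as a trailing run;
    they are kept lower-case in the normalized form. CPT codes must be
    exactly five digits and admit no wildcards.

    Raises :class:`CodeError` naming the offending value.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CodeError(f"empty or non-string code: {raw!r}")
    code = re.sub(r"[.,\s]", "", raw).upper()
    if not code:
        raise CodeError(f"code is empty after normalization: {raw!r}")
    n_wild = len(_WILDCARD_RE.search(code).group(0))
    stem = code[: len(code) - n_wild] if n_wild else code
    if "X" in stem:
        raise CodeError(f"wildcards must be a trailing run: {raw!r}")
    if n_wild and not allow_wildcards:
        raise CodeError(f"wildcards not allowed in a claim code: {raw!r}")
    if system is CodeSystem.CPT:
        if n_wild or not re.fullmatch(r"\d{5}", stem):
            raise CodeError(f"CPT code must be exactly 5 digits: {raw!r}")
    return stem + "x" * n_wild


@dataclass(frozen=True)
class CodePattern:
    """One entry of a condition's code set.

    ``pattern`` is stored normalized (no dots/commas/whitespace, upper
    case, wildcards as a trailing run of ``x``).
    """

    system: CodeSystem
    pattern: str

    def __post_init__(self) -> None:
        norm = normalize_code(self.pattern, self.system, allow_wildcards=True)
        object.__setattr__(self, "pattern", norm)

    @property
    def stem(self) -> str:
        return self.pattern.rstrip("x")

    def matches(self, code: str, system: CodeSystem) -> bool:
        """Whether a normalized claim ``code`` in ``system`` satisfies this pattern.

        A system mismatch is ``False``, never an error. Wildcard and bare
        ICD-9 stem patterns match by prefix; CPT matches exactly.
        """
        if system is not self.system:
            return False
        if self.system is CodeSystem.CPT:
            return code == self.pattern
        return code.startswith(self.stem)


def code_matches(code: str, pattern: CodePattern, system: CodeSystem) -> bool:
    """Functional alias for :meth:`CodePattern.matches`."""
    return pattern.matches(code, system)


@dataclass(frozen=True)
class ConditionDefinition:
    """A condition's code set plus its ascertainment rules.

    Parameters
    ----------
    window_days
        Length of the postnatal ascertainment window. A claim qualifies
        when its service date lies in the closed interval
        ``[birth_date, birth_date + window_days]`` (day of birth = day 0).
    year_restriction
        Inclusive birth-year range outside of which pairs are excluded
        rather than classified. NICU carries (2004, 2010) because the
        certificate checkbox only exists on the post-2003 form revision.
    use_mother_records
        Whether claims on the linked mother's record also ascertain the
        infant's case status (the default, applied to all conditions).
    """

    name: Condition
    codes: tuple[CodePattern, ...]
    window_days: int = 30
    year_restriction: Optional[tuple[int, int]] = None
    use_mother_records: bool = True

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        object.__setattr__(self, "codes", tuple(self.codes))

    def code_is_case(self, code: str, system: CodeSystem) -> bool:
        return any(p.matches(code, system) for p in self.codes)

    def window_contains(self, birth_date: dt.date, service_date: dt.date) -> bool:
        offset = (service_date - birth_date).days
        return 0 <= offset <= self.window_days

    def year_ok(self, birth_date: dt.date) -> bool:
        if self.year_restriction is None:
            return True
        lo, hi = self.year_restriction
        return lo <= birth_date.year <= hi


@dataclass(frozen=True)
class ClaimRecord:
    """One billed encounter line from the claims extract."""

    person_id: str
    record_type: RecordType
    service_date: dt.date
    code_system: CodeSystem
    code: str
    dx_position: int = 1
    linked_mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dx_position < 1:
            raise ValueError(f"dx_position must be >= 1, got {self.dx_position}")
        object.__setattr__(
            self, "code", normalize_code(self.code, self.code_system)
        )


@dataclass(frozen=True)
class BirthCertRecord:
    """One birth certificate with identifiers and condition checkboxes.

    ``condition_flags`` maps every condition to ``True`` (checked),
    ``False`` (explicitly unchecked) or ``None`` (no determination).
    """

    cert_id: str
    birth_date: dt.date
    condition_flags: Mapping[Condition, Optional[bool]]
    infant_ssn: Optional[str] = None
    mother_ssn: Optional[str] = None


@dataclass(frozen=True)
class CaseFlag:
    condition: Condition
    source: Source
    status: FlagStatus

    def __post_init__(self) -> None:
        if self.status is FlagStatus.EXCLUDED_MISSING and self.source is not Source.BC:
            raise ValueError("excluded_missing only arises on the BC side")


def ascertain_max_case(
    claims: Iterable[ClaimRecord],
    condition: ConditionDefinition,
    infant_id: str,
    mother_id: Optional[str],
    birth_date: dt.date,
    *,
    eligible_record_types: frozenset = ELIGIBLE_RECORD_TYPES,
) -> CaseFlag:
    """Classify one infant from claims.

    Case iff at least one eligible claim on the infant's (or, when the
    condition says so, the linked mother's) record matches the code set
    inside the postnatal window. Any diagnosis position counts. The
    result is independent of claim ordering; an empty stream is a
    non-case. Year restrictions yield ``excluded_year`` before any claim
    is inspected.
    """
    if not condition.year_ok(birth_date):
        return CaseFlag(condition.name, Source.MAX, FlagStatus.EXCLUDED_YEAR)
    eligible_people = {infant_id}
    if condition.use_mother_records and mother_id is not None:
        eligible_people.add(mother_id)
    for claim in claims:
        if claim.person_id not in eligible_people:
            continue
        if claim.record_type not in eligible_record_types:
            continue
        if not condition.window_contains(birth_date, claim.service_date):
            continue
        if condition.code_is_case(claim.code, claim.code_system):
            return CaseFlag(condition.name, Source.MAX, FlagStatus.CASE)
    return CaseFlag(condition.name, Source.MAX, FlagStatus.NONCASE)


def ascertain_bc_case(
    record: BirthCertRecord, condition: ConditionDefinition
) -> CaseFlag:
    """Classify one infant from the certificate checkbox.

    Checked → case, unchecked → non-case, no determination →
    ``excluded_missing``. Year restrictions yield ``excluded_year``.
    """
    if condition.name not in record.condition_flags:
        raise KeyError(
            f"certificate {record.cert_id} carries no flag for {condition.name.value}"
        )
    if not condition.year_ok(record.birth_date):
        return CaseFlag(condition.name, Source.BC, FlagStatus.EXCLUDED_YEAR)
    flag = record.condition_flags[condition.name]
    if flag is None:
        return CaseFlag(condition.name, Source.BC, FlagStatus.EXCLUDED_MISSING)
    status = FlagStatus.CASE if flag else FlagStatus.NONCASE
    return CaseFlag(condition.name, Source.BC, status)


@dataclass(frozen=True)
class EnrollmentSpan:
    person_id: str
    start: dt.date
    end: dt.date  # inclusive


def _covered(
    spans: Sequence[EnrollmentSpan], start: dt.date, end: dt.date
) -> bool:
    """Continuous coverage: a single span must contain [start, end]."""
    return any(s.start <= start and s.end >= end for s in spans)


@dataclass
class CohortExclusion:
    infant_id: str
    reason: str


def apply_cohort_filters(
    pairs: Sequence,
    enrollment_spans: Mapping[str, Sequence[EnrollmentSpan]],
    condition: ConditionDefinition,
) -> tuple[list, list[CohortExclusion]]:
    """Retain pairs meeting the enrollment and year criteria.

    Both mother and infant must have a single enrollment span covering
    the full postnatal window ``[birth, birth + window_days]`` (so
    coverage ending on day 29 fails a 30-day window). For conditions
    with a year restriction, births outside the range are excluded as
    ``excluded_year``. Pairs with no enrollment information at all are
    excluded and logged.

    ``pairs`` may be any objects exposing ``mother_id``, ``infant_id``
    and ``birth_date``.
    """
    kept: list = []
    exclusions: list[CohortExclusion] = []
    for pair in pairs:
        if not condition.year_ok(pair.birth_date):
            exclusions.append(CohortExclusion(pair.infant_id, "excluded_year"))
            continue
        window_end = pair.birth_date + dt.timedelta(days=condition.window_days)
        ok = True
        for person, label in ((pair.infant_id, "infant"), (pair.mother_id, "mother")):
            spans = enrollment_spans.get(person)
            if not spans:
                exclusions.append(
                    CohortExclusion(pair.infant_id, f"no_enrollment_{label}")
                )
                ok = False
                break
            if not _covered(spans, pair.birth_date, window_end):
                exclusions.append(
                    CohortExclusion(pair.infant_id, f"coverage_gap_{label}")
                )
                ok = False
                break
        if ok:
            kept.append(pair)
    return kept, exclusions
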