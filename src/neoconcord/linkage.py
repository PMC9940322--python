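"""Two-step deterministic mother–infant linkage.

Step 1: certificates carrying both the mother's and the infant's Social
Security Number are linked directly to the claims enrollees by exact
SSN match on both identifiers. Step 2 handles the remainder: infants
and mothers are first paired *within* the claims data through the
shared Medicaid family identifier (case ID) with the infant's birth
date matched against the mother's delivery-claim dates, and each
resulting pair is then attached to a certificate through whichever SSN
is available. Every ambiguity — an SSN shared by several people, a
certificate claimed by several pairs, an infant matching several
mothers — is dropped and logged, never resolved by guessing, so linked
identifiers are one-to-one by construction and the procedure's output
does not depend on input row order.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .phenotyping import BirthCertRecord

logger = logging.getLogger(__name__)


class Role(str, Enum):
    MOTHER = "mother"
    INFANT = "infant"


class LinkagePath(str, Enum):
    BOTH_SSN_EXACT = "both_ssn_exact"
    CASE_ID_THEN_SSN = "case_id_then_ssn"
    UNLINKED = "unlinked"


def normalize_ssn(value: Optional[str]) -> Optional[str]:
    """Strip non-digits; anything not exactly 9 digits is treated as absent."""
    if value is None:
        return None
    digits = re.sub(r"\D", "", str(value))
    return digits if len(digits) == 9 else None


@dataclass(frozen=True)
class MaxPerson:
    """One Medicaid enrollee (mother or infant)."""

    person_id: str
    role: Role
    ssn: Optional[str] = None
    case_id: Optional[str] = None
    birth_date: Optional[dt.date] = None          # infants
    delivery_dates: tuple[dt.date, ...] = ()      # mothers

    def __post_init__(self) -> None:
        object.__setattr__(self, "ssn", normalize_ssn(self.ssn))
        object.__setattr__(self, "delivery_dates", tuple(self.delivery_dates))


@dataclass(frozen=True)
class MotherInfantPair:
    mother_id: str
    infant_id: str
    birth_date: dt.date
    linkage_path: LinkagePath = LinkagePath.UNLINKED
    bc_cert_id: Optional[str] = None

    def __post_init__(self) -> None:
        has_cert = self.bc_cert_id is not None
        if has_cert != (self.linkage_path is not LinkagePath.UNLINKED):
            raise ValueError("bc_cert_id must be set exactly when a path links")


@dataclass
class LinkageReport:
    n_candidates: int = 0
    n_linked_by_path: dict = field(default_factory=dict)
    n_ambiguous_dropped: int = 0
    ppv_vs_truth: Optional[float] = None


def _unique_index(people: Iterable[MaxPerson], role: Role) -> dict[str, MaxPerson]:
    """SSN → person for one role; SSNs shared within the role are unusable."""
    counts: Counter[str] = Counter(
        p.ssn for p in people if p.role is role and p.ssn
    )
    return {
        p.ssn: p
        for p in people
        if p.role is role and p.ssn and counts[p.ssn] == 1
    }


def link_exact_ssn(
    max_people: Sequence[MaxPerson],
    bc_records: Sequence[BirthCertRecord],
) -> tuple[list[MotherInfantPair], list[MaxPerson], list[BirthCertRecord], int]:
    """Direct linkage of certificates with both SSNs present.

    A pair is emitted only when the certificate's mother and infant SSNs
    each match exactly one claims enrollee of the right role, and no
    other certificate shares either SSN. Returns the pairs, the claims
    people and certificates left for step 2, and the number of
    candidates dropped as ambiguous.
    """
    mothers = _unique_index(max_people, Role.MOTHER)
    infants = _unique_index(max_people, Role.INFANT)

    complete = [
        r
        for r in bc_records
        if normalize_ssn(r.mother_ssn) and normalize_ssn(r.infant_ssn)
    ]
    m_counts = Counter(normalize_ssn(r.mother_ssn) for r in complete)
    i_counts = Counter(normalize_ssn(r.infant_ssn) for r in complete)

    pairs: list[MotherInfantPair] = []
    linked_people: set[str] = set()
    linked_certs: set[str] = set()
    n_ambiguous = 0
    for rec in complete:
        mssn = normalize_ssn(rec.mother_ssn)
        issn = normalize_ssn(rec.infant_ssn)
        if m_counts[mssn] > 1 or i_counts[issn] > 1:
            n_ambiguous += 1
            logger.info("cert %s dropped: duplicate SSN across certificates", rec.cert_id)
            continue
        mother = mothers.get(mssn)
        infant = infants.get(issn)
        if mother is None or infant is None:
            continue  # not linkable in this step; remains for step 2
        pairs.append(
            MotherInfantPair(
                mother_id=mother.person_id,
                infant_id=infant.person_id,
                birth_date=infant.birth_date or rec.birth_date,
                linkage_path=LinkagePath.BOTH_SSN_EXACT,
                bc_cert_id=rec.cert_id,
            )
        )
        linked_people.update((mother.person_id, infant.person_id))
        linked_certs.add(rec.cert_id)

    remaining_people = [p for p in max_people if p.person_id not in linked_people]
    remaining_certs = [r for r in bc_records if r.cert_id not in linked_certs]
    return pairs, remaining_people, remaining_certs, n_ambiguous


def pair_within_max(
    max_people: Sequence[MaxPerson], date_tolerance_days: int = 0
) -> tuple[list[MotherInfantPair], int]:
    """Pair infants to mothers inside the claims data.

    An infant pairs with a mother sharing its case ID when the infant's
    birth date lies within ``date_tolerance_days`` of one of the
    mother's delivery-claim dates. An infant matching several mothers is
    dropped as ambiguous; several infants matching one mother (twins)
    are all kept as separate pairs.
    """
    if date_tolerance_days < 0:
        raise ValueError("date_tolerance_days must be >= 0")
    mothers_by_case: dict[str, list[MaxPerson]] = defaultdict(list)
    for p in max_people:
        if p.role is Role.MOTHER and p.case_id:
            mothers_by_case[p.case_id].append(p)

    pairs: list[MotherInfantPair] = []
    n_ambiguous = 0
    infants = sorted(
        (p for p in max_people if p.role is Role.INFANT),
        key=lambda p: p.person_id,
    )
    for infant in infants:
        if not infant.case_id or infant.birth_date is None:
            continue
        candidates = [
            m
            for m in mothers_by_case.get(infant.case_id, [])
            if any(
                abs((infant.birth_date - d).days) <= date_tolerance_days
                for d in m.delivery_dates
            )
        ]
        if len(candidates) == 1:
            pairs.append(
                MotherInfantPair(
                    mother_id=candidates[0].person_id,
                    infant_id=infant.person_id,
                    birth_date=infant.birth_date,
                )
            )
        elif len(candidates) > 1:
            n_ambiguous += 1
            logger.info(
                "infant %s dropped: %d mothers match within tolerance",
                infant.person_id, len(candidates),
            )
    return pairs, n_ambiguous


def link_pairs_to_bc(
    pairs: Sequence[MotherInfantPair],
    bc_records: Sequence[BirthCertRecord],
    max_people: Sequence[MaxPerson],
) -> tuple[list[MotherInfantPair], int]:
    """Attach claims-internal pairs to certificates via the available SSN.

    Each pair is matched on whichever of the mother's or infant's SSN is
    known (both, when both are). A unique certificate match links the
    pair with path ``case_id_then_ssn``; zero matches leave it unlinked;
    several matches — or one certificate claimed by several pairs — drop
    every pair involved. Returns the full pair list (linked and
    unlinked) and the ambiguous-drop count.
    """
    ssn_of = {p.person_id: p.ssn for p in max_people}
    by_mother_ssn: dict[str, list[BirthCertRecord]] = defaultdict(list)
    by_infant_ssn: dict[str, list[BirthCertRecord]] = defaultdict(list)
    for rec in bc_records:
        mssn = normalize_ssn(rec.mother_ssn)
        issn = normalize_ssn(rec.infant_ssn)
        if mssn:
            by_mother_ssn[mssn].append(rec)
        if issn:
            by_infant_ssn[issn].append(rec)

    candidate: dict[int, BirthCertRecord] = {}
    ambiguous: set[int] = set()
    cert_claims: dict[str, list[int]] = defaultdict(list)
    for idx, pair in enumerate(pairs):
        mssn = ssn_of.get(pair.mother_id)
        issn = ssn_of.get(pair.infant_id)
        if issn:
            matches = list(by_infant_ssn.get(issn, []))
            if mssn:  # both known: both must agree
                matches = [
                    r for r in matches if normalize_ssn(r.mother_ssn) in (None, mssn)
                ]
        elif mssn:
            matches = list(by_mother_ssn.get(mssn, []))
        else:
            matches = []
        if len(matches) == 1:
            candidate[idx] = matches[0]
            cert_claims[matches[0].cert_id].append(idx)
        elif len(matches) > 1:
            ambiguous.add(idx)
            logger.info(
                "pair (%s, %s) dropped: SSN matches %d certificates",
                pair.mother_id, pair.infant_id, len(matches),
            )
    for cert_id, idxs in cert_claims.items():
        if len(idxs) > 1:
            ambiguous.update(idxs)
            logger.info("cert %s dropped: claimed by %d pairs", cert_id, len(idxs))

    out: list[MotherInfantPair] = []
    for idx, pair in enumerate(pairs):
        if idx in ambiguous:
            continue
        rec = candidate.get(idx)
        if rec is None:
            out.append(pair)
        else:
            out.append(
                MotherInfantPair(
                    mother_id=pair.mother_id,
                    infant_id=pair.infant_id,
                    birth_date=pair.birth_date,
                    linkage_path=LinkagePath.CASE_ID_THEN_SSN,
                    bc_cert_id=rec.cert_id,
                )
            )
    return out, len(ambiguous)


def two_step_link(
    max_people: Sequence[MaxPerson],
    bc_records: Sequence[BirthCertRecord],
    date_tolerance_days: int = 0,
) -> tuple[list[MotherInfantPair], LinkageReport]:
    """Run the full procedure: exact-SSN linkage first, the case-ID path
    on the remainder. A pair linked in step 1 is never revisited."""
    step1, rest_people, rest_certs, amb1 = link_exact_ssn(max_people, bc_records)
    internal, amb2 = pair_within_max(rest_people, date_tolerance_days)
    step2, amb3 = link_pairs_to_bc(internal, rest_certs, rest_people)
    pairs = step1 + step2
    report = LinkageReport(
        n_candidates=len(pairs),
        n_linked_by_path={
            LinkagePath.BOTH_SSN_EXACT.value: len(step1),
            LinkagePath.CASE_ID_THEN_SSN.value: sum(
                1 for p in step2 if p.linkage_path is LinkagePath.CASE_ID_THEN_SSN
            ),
            LinkagePath.UNLINKED.value: sum(
                1 for p in step2 if p.linkage_path is LinkagePath.UNLINKED
            ),
        },
        n_ambiguous_dropped=amb1 + amb2 + amb3,
    )
    return pairs, report


def evaluate_linkage(
    pairs: Sequence[MotherInfantPair],
    truth: Mapping[str, tuple[str, str]],
) -> LinkageReport:
    """Score linked pairs against known truth (synthetic runs only).

    ``truth`` maps infant_id → (mother_id, cert_id). The positive
    predictive value is the fraction of emitted links whose mother and
    certificate are both correct; with no links it is undefined.
    """
    by_path: Counter[str] = Counter(p.linkage_path.value for p in pairs)
    linked = [p for p in pairs if p.linkage_path is not LinkagePath.UNLINKED]
    correct = sum(
        1
        for p in linked
        if truth.get(p.infant_id) == (p.mother_id, p.bc_cert_id)
    )
    return LinkageReport(
        n_candidates=len(pairs),
        n_linked_by_path=dict(by_path),
        ppv_vs_truth=(correct / len(linked)) if linked else None,
    )
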