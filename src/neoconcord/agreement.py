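"""Two-by-two concordance tables and agreement statistics.

For one condition, every analyzable mother–infant pair is
cross-classified by its case status in the two sources into

====  =========  =========
            BC +       BC −
MAX +        a          b
MAX −        c          d
====  =========  =========

from which the module computes observed agreement ``po = (a+d)/N``,
chance-expected agreement ``pe`` from the margins, Cohen's kappa
``(po − pe)/(1 − pe)``, the two cross-source sensitivities (each source
scored against the other as if it were a gold standard), prevalence per
100 pairs, and the decomposition of the case union into both-source and
single-source captures. Pairs whose certificate carries no determination
for the condition (a blank checkbox) are removed from all four cells and
counted separately, as are pairs outside a condition's year range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Optional

from .phenotyping import CaseFlag, Condition, FlagStatus, Source


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero on the final displayed digit.

    Report formatting uses this convention (rather than banker's
    rounding) because it reproduces the robust printed rows.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class KappaCategory(str, Enum):
    POOR = "poor"              # <= 20%
    FAIR = "fair"              # (20, 40]
    MODERATE = "moderate"      # (40, 60]
    SUBSTANTIAL = "substantial"  # (60, 80]
    HIGH = "high"              # > 80%


@dataclass(frozen=True)
class TwoByTwoTable:
    """Concordance cell counts for one condition and stratum.

    ``a`` both-positive, ``b`` MAX-only, ``c`` BC-only, ``d``
    both-negative; ``n_excluded_missing`` and ``n_excluded_year`` count
    pairs removed before cross-classification.
    """

    condition: Condition
    stratum: str
    a: int
    b: int
    c: int
    d: int
    n_excluded_missing: int = 0
    n_excluded_year: int = 0

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells) or self.n_excluded_missing < 0:
            raise ValueError(f"negative cell count in {cells}")
        if self.n == 0:
            raise ValueError("empty table: a+b+c+d must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def max_total(self) -> int:
        return self.a + self.b

    @property
    def bc_total(self) -> int:
        return self.a + self.c

    @classmethod
    def from_margins(
        cls,
        condition: Condition,
        stratum: str,
        max_total: int,
        bc_total: int,
        both: int,
        denominator: int,
        **kwargs,
    ) -> "TwoByTwoTable":
        """Build the table from marginal case counts and a denominator,
        the form in which published results print it."""
        if both > min(max_total, bc_total):
            raise ValueError(
                f"both-count {both} exceeds a marginal total "
                f"({max_total}, {bc_total})"
            )
        a = both
        b = max_total - both
        c = bc_total - both
        d = denominator - (a + b + c)
        return cls(condition, stratum, a, b, c, d, **kwargs)

    def swapped(self) -> "TwoByTwoTable":
        """The table with the two sources exchanged (b and c swapped)."""
        return TwoByTwoTable(
            self.condition, self.stratum, self.a, self.c, self.b, self.d,
            self.n_excluded_missing, self.n_excluded_year,
        )


def build_two_by_two(
    max_flags: Mapping[str, CaseFlag],
    bc_flags: Mapping[str, CaseFlag],
    condition: Condition,
    stratum: str = "",
) -> TwoByTwoTable:
    """Cross-classify per-pair case flags from the two sources.

    Both mappings must be keyed by the same pair identifiers; a pair
    present on one side only is an error naming the pair. Pairs excluded
    on either side (missing BC determination, out-of-range birth year)
    drop out of all four cells into the exclusion counters.
    """
    if max_flags.keys() != bc_flags.keys():
        odd = set(max_flags) ^ set(bc_flags)
        raise ValueError(f"flag streams disagree on pairs: {sorted(odd)[:5]}")
    a = b = c = d = n_missing = n_year = 0
    for pair_id, mf in max_flags.items():
        bf = bc_flags[pair_id]
        if FlagStatus.EXCLUDED_YEAR in (mf.status, bf.status):
            n_year += 1
            continue
        if bf.status is FlagStatus.EXCLUDED_MISSING:
            n_missing += 1
            continue
        mcase = mf.status is FlagStatus.CASE
        bcase = bf.status is FlagStatus.CASE
        if mcase and bcase:
            a += 1
        elif mcase:
            b += 1
        elif bcase:
            c += 1
        else:
            d += 1
    return TwoByTwoTable(
        condition, stratum, a, b, c, d,
        n_excluded_missing=n_missing, n_excluded_year=n_year,
    )


def cohen_kappa(table: TwoByTwoTable) -> tuple[float, float, Optional[float]]:
    """Observed agreement, chance-expected agreement and crude kappa.

    ``po = (a+d)/N``; ``pe`` is the sum over the two categories of the
    products of the marginal proportions; ``kappa = (po − pe)/(1 − pe)``.
    When ``pe`` is 1 (all mass in a single margin on both sides) kappa is
    undefined and returned as ``None``, never coerced to a number.
    """
    n = table.n
    po = (table.a + table.d) / n
    p_max_pos = (table.a + table.b) / n
    p_bc_pos = (table.a + table.c) / n
    pe = p_max_pos * p_bc_pos + (1 - p_max_pos) * (1 - p_bc_pos)
    if math.isclose(pe, 1.0, rel_tol=0.0, abs_tol=1e-15):
        return po, pe, None
    return po, pe, (po - pe) / (1 - pe)


def cross_sensitivity(table: TwoByTwoTable, reference: Source) -> Optional[float]:
    """One source's capture of the other's cases.

    With the birth certificate as reference, ``a/(a+c)`` is the claims
    data's sensitivity; with claims as reference, ``a/(a+b)`` is the
    certificate's. A zero reference total makes the ratio undefined
    (``None``).
    """
    denom = table.bc_total if reference is Source.BC else table.max_total
    if denom == 0:
        return None
    return table.a / denom


def prevalence_per_100(case_count: int, denominator: int) -> float:
    """Identified cases per 100 mother–infant pairs."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    return 100.0 * case_count / denominator


def kappa_category(kappa: float) -> KappaCategory:
    """Band a kappa on the percent scale.

    Bands are contiguous half-open intervals on the value rounded to one
    decimal percent: poor ≤ 20.0 < fair ≤ 40.0 < moderate ≤ 60.0 <
    substantial ≤ 80.0 < high.
    """
    pct = round_half_up(100.0 * kappa, 1)
    if pct <= 20.0:
        return KappaCategory.POOR
    if pct <= 40.0:
        return KappaCategory.FAIR
    if pct <= 60.0:
        return KappaCategory.MODERATE
    if pct <= 80.0:
        return KappaCategory.SUBSTANTIAL
    return KappaCategory.HIGH


def discordance_decomposition(
    table: TwoByTwoTable,
) -> tuple[int, int, int, Optional[float]]:
    """Split the case union into single-source and both-source captures.

    Returns ``(only_max, only_bc, both, pct_discordant_of_union)`` where
    the percentage is ``100·(b+c)/(a+b+c)``, undefined for an empty
    union.
    """
    union = table.a + table.b + table.c
    if union == 0:
        return table.b, table.c, table.a, None
    return table.b, table.c, table.a, 100.0 * (table.b + table.c) / union


def reconstruct_denominator(
    case_count: int, printed_prevalence_per100: float, *, decimals: int = 2
) -> tuple[int, tuple[int, int]]:
    """Invert the prevalence formula to recover an analysis denominator.

    Given a case count and a prevalence printed to ``decimals`` places,
    returns the point estimate ``round(100·count/prevalence)`` and the
    closed interval of integers N whose exact prevalence rounds
    (half-up) back to the printed value.
    """
    if printed_prevalence_per100 <= 0:
        raise ValueError("printed prevalence must be positive")
    p = printed_prevalence_per100
    half = 0.5 * 10 ** (-decimals)
    point = round(100.0 * case_count / p)
    # 100c/N rounds to p iff p - half <= 100c/N < p + half; decreasing in N
    lo = math.floor(100.0 * case_count / (p + half)) + 1
    hi = math.floor(100.0 * case_count / (p - half)) if p > half else point
    # guard against float edge effects at the interval ends
    def _ok(n: int) -> bool:
        return n > 0 and round_half_up(100.0 * case_count / n, decimals) == p
    while lo <= hi and not _ok(lo):
        lo += 1
    while hi >= lo and not _ok(hi):
        hi -= 1
    return point, (lo, hi)


@dataclass(frozen=True)
class AgreementResult:
    """Full agreement summary for one table."""

    condition: Condition
    stratum: str
    n: int
    po: float
    pe: float
    kappa: Optional[float]
    kappa_category: Optional[KappaCategory]
    sens_max: Optional[float]
    sens_bc: Optional[float]
    prev_max_per100: float
    prev_bc_per100: float
    pct_discordant_of_union: Optional[float]
    n_excluded_missing: int
    n_excluded_year: int


def summarize(table: TwoByTwoTable) -> AgreementResult:
    po, pe, kappa = cohen_kappa(table)
    _, _, _, pct_disc = discordance_decomposition(table)
    return AgreementResult(
        condition=table.condition,
        stratum=table.stratum,
        n=table.n,
        po=po,
        pe=pe,
        kappa=kappa,
        kappa_category=None if kappa is None else kappa_category(kappa),
        sens_max=cross_sensitivity(table, Source.BC),
        sens_bc=cross_sensitivity(table, Source.MAX),
        prev_max_per100=prevalence_per_100(table.max_total, table.n),
        prev_bc_per100=prevalence_per_100(table.bc_total, table.n),
        pct_discordant_of_union=pct_disc,
        n_excluded_missing=table.n_excluded_missing,
        n_excluded_year=table.n_excluded_year,
    )
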