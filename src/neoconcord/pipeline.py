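"""Stage orchestration over whole tables.

The record-level operations in :mod:`neoconcord.phenotyping` define the
semantics one infant at a time; this module applies the same rules to
entire cohorts with vectorized table operations (the two paths are
equivalence-tested), and chains simulate → link → phenotype → agree.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as ncio
from .agreement import AgreementResult, TwoByTwoTable, build_two_by_two, summarize
from .linkage import LinkageReport, two_step_link
from .phenotyping import (
    CaseFlag,
    CodeSystem,
    Condition,
    ConditionDefinition,
    FlagStatus,
    RecordType,
    Source,
)
from .simulate import CohortTables, SimulationConfig, simulate_cohort

ELIGIBLE_TYPES = (RecordType.INPATIENT.value, RecordType.OUTPATIENT.value)


def truth_pairs_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """Pairs table taken from simulation truth (oracle linkage)."""
    return pd.DataFrame({
        "pair_id": truth["pair_id"],
        "mother_id": truth["mother_id"],
        "infant_id": truth["infant_id"],
        "cert_id": truth["cert_id"],
        "linkage_path": "both_ssn_exact",
        "birth_date": truth["birth_date"],
    })


def filter_enrolled(
    pairs: pd.DataFrame, enrollment: pd.DataFrame, window_days: int = 30
) -> pd.DataFrame:
    """Keep pairs whose mother and infant each have one enrollment span
    covering [birth, birth + window_days]."""
    out = pairs
    for person_col in ("infant_id", "mother_id"):
        merged = out[["pair_id", person_col, "birth_date"]].merge(
            enrollment, left_on=person_col, right_on="person_id"
        )
        end = pd.to_datetime(merged["birth_date"]) + pd.to_timedelta(window_days, unit="D")
        covered = (
            (pd.to_datetime(merged["start"]) <= pd.to_datetime(merged["birth_date"]))
            & (pd.to_datetime(merged["end"]) >= end)
        )
        ok_pairs = merged.loc[covered, "pair_id"].unique()
        out = out[out["pair_id"].isin(ok_pairs)]
    return out.reset_index(drop=True)


def max_flags_table(
    claims: pd.DataFrame,
    pairs: pd.DataFrame,
    condition: ConditionDefinition,
) -> dict[str, CaseFlag]:
    """Claims-side case flags for every pair, vectorized."""
    elig = claims[claims["record_type"].isin(ELIGIBLE_TYPES)]
    uniq = elig[["code_system", "code"]].drop_duplicates()
    matched_keys = {
        (s, c)
        for s, c in zip(uniq["code_system"], uniq["code"])
        if condition.code_is_case(c, CodeSystem(s))
    }
    if matched_keys:
        mask = [
            (s, c) in matched_keys
            for s, c in zip(elig["code_system"], elig["code"])
        ]
        hits = elig[np.asarray(mask)]
    else:
        hits = elig.iloc[0:0]

    case_pairs: set[str] = set()
    person_cols = ["infant_id"]
    if condition.use_mother_records:
        person_cols.append("mother_id")
    for col in person_cols:
        merged = hits[["person_id", "service_date"]].merge(
            pairs[["pair_id", col, "birth_date"]],
            left_on="person_id",
            right_on=col,
        )
        if merged.empty:
            continue
        offset = (
            pd.to_datetime(merged["service_date"]) - pd.to_datetime(merged["birth_date"])
        ).dt.days
        in_window = (offset >= 0) & (offset <= condition.window_days)
        case_pairs.update(merged.loc[in_window, "pair_id"])

    flags: dict[str, CaseFlag] = {}
    for pair_id, birth in zip(pairs["pair_id"], pairs["birth_date"]):
        if not condition.year_ok(birth):
            status = FlagStatus.EXCLUDED_YEAR
        elif pair_id in case_pairs:
            status = FlagStatus.CASE
        else:
            status = FlagStatus.NONCASE
        flags[pair_id] = CaseFlag(condition.name, Source.MAX, status)
    return flags


def bc_flags_table(
    bc: pd.DataFrame,
    pairs: pd.DataFrame,
    condition: ConditionDefinition,
) -> dict[str, CaseFlag]:
    """Certificate-side case flags for every pair, vectorized.

    Pairs without a linked certificate are treated as missing
    determinations (they cannot be classified by the certificate).
    """
    col = condition.name.value.lower()
    merged = pairs[["pair_id", "cert_id", "birth_date"]].merge(
        bc[["cert_id", col]], on="cert_id", how="left"
    )
    flags: dict[str, CaseFlag] = {}
    for pair_id, birth, value in zip(
        merged["pair_id"], merged["birth_date"], merged[col]
    ):
        if not condition.year_ok(birth):
            status = FlagStatus.EXCLUDED_YEAR
        elif value == "1":
            status = FlagStatus.CASE
        elif value == "0":
            status = FlagStatus.NONCASE
        else:
            status = FlagStatus.EXCLUDED_MISSING
        flags[pair_id] = CaseFlag(condition.name, Source.BC, status)
    return flags


def flags_frame(
    max_flags: Mapping[str, Mapping[str, CaseFlag]],
    bc_flags: Mapping[str, Mapping[str, CaseFlag]],
) -> pd.DataFrame:
    """Long-format per-pair flag table (one row per pair × condition)."""
    rows = []
    for cond_name, mflags in max_flags.items():
        bflags = bc_flags[cond_name]
        for pair_id, mf in mflags.items():
            rows.append((pair_id, cond_name, mf.status.value, bflags[pair_id].status.value))
    return pd.DataFrame(rows, columns=ncio.FLAGS_COLUMNS)


def phenotype_cohort(
    claims: pd.DataFrame,
    bc: pd.DataFrame,
    pairs: pd.DataFrame,
    enrollment: Optional[pd.DataFrame],
    conditions: Mapping[Condition, ConditionDefinition],
) -> tuple[dict[str, dict[str, CaseFlag]], dict[str, dict[str, CaseFlag]]]:
    """Both sources' flags for every condition, after enrollment filtering."""
    linked = pairs[pairs["cert_id"] != ""].reset_index(drop=True)
    if enrollment is not None:
        window = max(c.window_days for c in conditions.values())
        linked = filter_enrolled(linked, enrollment, window)
    max_flags = {}
    bc_flags = {}
    for cond, definition in conditions.items():
        max_flags[cond.value] = max_flags_table(claims, linked, definition)
        bc_flags[cond.value] = bc_flags_table(bc, linked, definition)
    return max_flags, bc_flags


def agreement_report(
    max_flags: Mapping[str, Mapping[str, CaseFlag]],
    bc_flags: Mapping[str, Mapping[str, CaseFlag]],
    stratum: str = "",
) -> tuple[pd.DataFrame, dict[str, TwoByTwoTable]]:
    """One report row per condition from per-pair flags."""
    tables: dict[str, TwoByTwoTable] = {}
    rows = []
    for cond_name in max_flags:
        table = build_two_by_two(
            max_flags[cond_name], bc_flags[cond_name], Condition(cond_name), stratum
        )
        tables[cond_name] = table
        rows.append(result_row(summarize(table), table))
    return pd.DataFrame(rows), tables


def result_row(res: AgreementResult, table: TwoByTwoTable) -> dict:
    from .agreement import round_half_up

    return {
        "stratum": res.stratum,
        "condition": res.condition.value,
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
        "n": res.n,
        "n_excluded_missing": res.n_excluded_missing,
        "n_excluded_year": res.n_excluded_year,
        "po": res.po,
        "pe": res.pe,
        "kappa": res.kappa if res.kappa is not None else "",
        "kappa_pct": (
            round_half_up(100 * res.kappa, 1) if res.kappa is not None else ""
        ),
        "kappa_category": res.kappa_category.value if res.kappa_category else "",
        "sens_max": res.sens_max if res.sens_max is not None else "",
        "sens_bc": res.sens_bc if res.sens_bc is not None else "",
        "prev_max_per100": res.prev_max_per100,
        "prev_bc_per100": res.prev_bc_per100,
        "pct_discordant_of_union": (
            res.pct_discordant_of_union
            if res.pct_discordant_of_union is not None
            else ""
        ),
    }


def run_pipeline(
    config: SimulationConfig,
    conditions: Optional[Mapping[Condition, ConditionDefinition]] = None,
    date_tolerance_days: int = 0,
    use_true_linkage: bool = False,
) -> dict:
    """Simulate a cohort and push it through linkage, phenotyping and
    agreement; returns every intermediate product.

    ``use_true_linkage`` swaps the deterministic linker for the
    simulation's known pairing, which is convenient for studying the
    measurement model in isolation at large cohort sizes.
    """
    if conditions is None:
        conditions = ncio.load_conditions()
    cohort = simulate_cohort(config)
    if use_true_linkage:
        pairs_df = truth_pairs_frame(cohort.truth)
        link_report = None
        pairs = None
    else:
        people = ncio.persons_to_records(cohort.persons)
        bc_records = ncio.bc_to_records(cohort.bc)
        pairs, link_report = two_step_link(people, bc_records, date_tolerance_days)
        pairs_df = ncio.pairs_to_frame(pairs)
    max_flags, bc_flags = phenotype_cohort(
        cohort.claims, cohort.bc, pairs_df, cohort.enrollment, conditions
    )
    report, tables = agreement_report(max_flags, bc_flags, stratum="synthetic")
    return {
        "cohort": cohort,
        "pairs": pairs,
        "pairs_df": pairs_df,
        "link_report": link_report,
        "max_flags": max_flags,
        "bc_flags": bc_flags,
        "tables": tables,
        "report": report,
    }
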