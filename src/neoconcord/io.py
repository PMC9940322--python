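"""Readers and writers for the delimited-text table schemas.

All tables are comma-separated UTF-8 with a mandatory header, ISO-8601
dates, and the empty string for an absent value. Lines starting with
``#`` are comments; writers echo the generating seed into one. Reading
then writing any table is the identity on its typed content.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .linkage import LinkagePath, MaxPerson, MotherInfantPair, Role
from .phenotyping import (
    BirthCertRecord,
    ClaimRecord,
    CodeSystem,
    Condition,
    ConditionDefinition,
    CodePattern,
    EnrollmentSpan,
    RecordType,
    normalize_code,
)

PathLike = Union[str, Path]

CLAIMS_COLUMNS = ["person_id", "linked_mother_id", "record_type",
                  "service_date", "code_system", "code", "dx_position"]
BC_ID_COLUMNS = ["cert_id", "infant_ssn", "mother_ssn", "birth_date"]
BC_FLAG_COLUMNS = [c.value.lower() for c in Condition]
BC_COLUMNS = BC_ID_COLUMNS + BC_FLAG_COLUMNS
ENROLLMENT_COLUMNS = ["person_id", "start", "end"]
PERSONS_COLUMNS = ["person_id", "role", "ssn", "case_id",
                   "birth_date", "delivery_dates"]
PAIRS_COLUMNS = ["pair_id", "mother_id", "infant_id", "cert_id",
                 "linkage_path", "birth_date"]
FLAGS_COLUMNS = ["pair_id", "condition", "max_status", "bc_status"]


class SchemaError(ValueError):
    """A table violating its documented schema, citing file/line/column."""


def write_table(df: pd.DataFrame, path: PathLike, seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# neoconcord table; seed={seed}\n")
        df.to_csv(fh, index=False)


def _read_raw(path: PathLike, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in columns]
    missing = [c for c in columns if c not in df.columns]
    if unknown or missing:
        raise SchemaError(
            f"{path}: unknown columns {unknown}, missing columns {missing}"
        )
    return df[columns]


def _parse_dates(df: pd.DataFrame, column: str, path: PathLike) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (df[column] != "")
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(
            f"{path}: row {i + 2}, column {column!r}: "
            f"unparseable date {df[column].iloc[i]!r}"
        )
    return parsed.dt.date


def read_claims(path: PathLike) -> pd.DataFrame:
    """Claims table with codes normalized and dates parsed."""
    df = _read_raw(path, CLAIMS_COLUMNS)
    df = df.copy()
    df["service_date"] = _parse_dates(df, "service_date", path)
    bad_rt = ~df["record_type"].isin([r.value for r in RecordType])
    if bad_rt.any():
        i = int(bad_rt.idxmax())
        raise SchemaError(
            f"{path}: row {i + 2}: unknown record_type {df['record_type'].iloc[i]!r}"
        )
    bad_cs = ~df["code_system"].isin([s.value for s in CodeSystem])
    if bad_cs.any():
        i = int(bad_cs.idxmax())
        raise SchemaError(
            f"{path}: row {i + 2}: unknown code_system {df['code_system'].iloc[i]!r}"
        )
    df["code"] = [
        normalize_code(code, CodeSystem(system))
        for code, system in zip(df["code"], df["code_system"])
    ]
    df["dx_position"] = df["dx_position"].astype(int)
    return df


def read_bc(path: PathLike) -> pd.DataFrame:
    """Birth-certificate table; checkbox values must be '', '0' or '1'."""
    df = _read_raw(path, BC_COLUMNS).copy()
    df["birth_date"] = _parse_dates(df, "birth_date", path)
    for col in BC_FLAG_COLUMNS:
        bad = ~df[col].isin(["", "0", "1"])
        if bad.any():
            i = int(bad.idxmax())
            raise SchemaError(
                f"{path}: row {i + 2}, column {col!r}: "
                f"flag value {df[col].iloc[i]!r} not in {{'', '0', '1'}}"
            )
    return df


def read_enrollment(path: PathLike) -> pd.DataFrame:
    df = _read_raw(path, ENROLLMENT_COLUMNS).copy()
    df["start"] = _parse_dates(df, "start", path)
    df["end"] = _parse_dates(df, "end", path)
    return df


def read_persons(path: PathLike) -> pd.DataFrame:
    df = _read_raw(path, PERSONS_COLUMNS).copy()
    bad = ~df["role"].isin([r.value for r in Role])
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(f"{path}: row {i + 2}: unknown role {df['role'].iloc[i]!r}")
    return df


def read_pairs(path: PathLike) -> pd.DataFrame:
    df = _read_raw(path, PAIRS_COLUMNS).copy()
    df["birth_date"] = _parse_dates(df, "birth_date", path)
    return df


def read_truth(path: PathLike) -> pd.DataFrame:
    cols = ["pair_id", "mother_id", "infant_id", "cert_id", "birth_date"] + BC_FLAG_COLUMNS
    df = _read_raw(path, cols).copy()
    df["birth_date"] = _parse_dates(df, "birth_date", path)
    for col in BC_FLAG_COLUMNS:
        df[col] = df[col].astype(int)
    return df


def read_flags(path: PathLike) -> pd.DataFrame:
    return _read_raw(path, FLAGS_COLUMNS)


# ---------------------------------------------------------------------------
# typed-record converters

def claims_to_records(df: pd.DataFrame) -> list[ClaimRecord]:
    return [
        ClaimRecord(
            person_id=r.person_id,
            linked_mother_id=r.linked_mother_id or None,
            record_type=RecordType(r.record_type),
            service_date=r.service_date,
            code_system=CodeSystem(r.code_system),
            code=r.code,
            dx_position=int(r.dx_position),
        )
        for r in df.itertuples(index=False)
    ]


def bc_to_records(df: pd.DataFrame) -> list[BirthCertRecord]:
    flag_map = {"": None, "0": False, "1": True}
    return [
        BirthCertRecord(
            cert_id=r.cert_id,
            infant_ssn=r.infant_ssn or None,
            mother_ssn=r.mother_ssn or None,
            birth_date=r.birth_date,
            condition_flags={
                c: flag_map[getattr(r, c.value.lower())] for c in Condition
            },
        )
        for r in df.itertuples(index=False)
    ]


def persons_to_records(df: pd.DataFrame) -> list[MaxPerson]:
    out = []
    for r in df.itertuples(index=False):
        deliveries = tuple(
            dt.date.fromisoformat(d) for d in r.delivery_dates.split(";") if d
        )
        out.append(MaxPerson(
            person_id=r.person_id,
            role=Role(r.role),
            ssn=r.ssn or None,
            case_id=r.case_id or None,
            birth_date=dt.date.fromisoformat(r.birth_date) if r.birth_date else None,
            delivery_dates=deliveries,
        ))
    return out


def enrollment_to_spans(df: pd.DataFrame) -> dict[str, list[EnrollmentSpan]]:
    spans: dict[str, list[EnrollmentSpan]] = {}
    for r in df.itertuples(index=False):
        spans.setdefault(r.person_id, []).append(
            EnrollmentSpan(r.person_id, r.start, r.end)
        )
    return spans


def pairs_to_frame(pairs) -> pd.DataFrame:
    """Linked-pair objects → pairs table; the certificate id keys linked
    pairs, the infant id keys unlinked ones."""
    return pd.DataFrame({
        "pair_id": [p.bc_cert_id if p.bc_cert_id else f"U:{p.infant_id}" for p in pairs],
        "mother_id": [p.mother_id for p in pairs],
        "infant_id": [p.infant_id for p in pairs],
        "cert_id": [p.bc_cert_id or "" for p in pairs],
        "linkage_path": [p.linkage_path.value for p in pairs],
        "birth_date": [p.birth_date for p in pairs],
    })


def frame_to_pairs(df: pd.DataFrame) -> list[MotherInfantPair]:
    return [
        MotherInfantPair(
            mother_id=r.mother_id,
            infant_id=r.infant_id,
            birth_date=r.birth_date,
            linkage_path=LinkagePath(r.linkage_path),
            bc_cert_id=r.cert_id or None,
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# condition configuration

def load_conditions(path: Optional[PathLike] = None) -> dict[Condition, ConditionDefinition]:
    """Load condition definitions from YAML; the packaged default set
    when no path is given."""
    if path is None:
        from importlib.resources import files

        text = files("neoconcord.data").joinpath("conditions.yml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out: dict[Condition, ConditionDefinition] = {}
    for name, spec in raw["conditions"].items():
        cond = Condition(name)
        codes = tuple(
            CodePattern(CodeSystem(entry["system"]), str(entry["pattern"]))
            for entry in spec["codes"]
        )
        yr = spec.get("year_restriction")
        out[cond] = ConditionDefinition(
            name=cond,
            codes=codes,
            window_days=int(spec.get("window_days", 30)),
            year_restriction=tuple(yr) if yr else None,
            use_mother_records=bool(spec.get("use_mother_records", True)),
        )
    return out
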