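"""Synthetic linked claims + birth-certificate cohorts with known truth.

Each simulated mother–infant pair carries a latent true status for every
condition. The two observation channels then misclassify that truth
independently: the claims channel emits a condition-coded encounter with
probability equal to its sensitivity given a true case (and one minus
its specificity given a non-case), realized as a claim line carrying a
code drawn from the condition's code set at a service date inside the
postnatal window; the certificate channel sets the checkbox by the same
mechanism and additionally blanks it at the missing-determination rate.
Identifiers mimic the linkage structure of the real extracts: unique
SSNs masked at configurable rates, a family case ID shared by mother
and infant, and a maternal delivery claim whose date matches the birth.

Under the default conditional-independence assumption the resulting
2×2 cell probabilities — and hence kappa — have the closed form in
:func:`expected_cells`, which the test-suite uses as an analytic oracle.
A ``severity_correlation`` knob induces positive dependence between the
channels (a shared latent severity shifting both sensitivities) for
sensitivity analyses; the closed form applies only at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .phenotyping import Condition

__all__ = [
    "ConditionParams",
    "SimulationConfig",
    "CohortTables",
    "simulate_cohort",
    "expected_cells",
    "expected_kappa",
]

#: Concrete claim codes emitted per condition, each satisfying the
#: packaged default code set for that condition and no other.
EMISSION_CODES = {
    Condition.NICU: ("CPT", ["99295", "99296", "99297", "99298", "99299",
                             "99300", "99468", "99469", "99477", "99478",
                             "99479", "99480"]),
    Condition.RDS: ("ICD9_DX", ["769"]),
    Condition.SEIZURE: ("ICD9_DX", ["7790"]),
    Condition.AV: ("ICD9_PC", ["9670", "9671", "9672", "9390"]),
    Condition.BIRTH_INJURY: ("ICD9_DX", ["7670", "7671", "7673", "7674", "7679"]),
}

#: Claim codes unrelated to every condition, used for background noise.
NOISE_CODES = ["V3000", "V3001", "7746", "77181", "V202"]


@dataclass(frozen=True)
class ConditionParams:
    """Generative parameters for one condition.

    ``true_prevalence`` is the latent case probability; the four
    operating characteristics give each channel's sensitivity and
    specificity with respect to that latent truth.
    """

    true_prevalence: float
    se_max: float
    sp_max: float
    se_bc: float
    sp_bc: float

    def validate(self, name: str) -> None:
        for f, v in (("true_prevalence", self.true_prevalence),
                     ("se_max", self.se_max), ("sp_max", self.sp_max),
                     ("se_bc", self.se_bc), ("sp_bc", self.sp_bc)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}.{f} = {v} is not a proportion")


def _default_condition_params() -> dict[Condition, ConditionParams]:
    # Prevalences sit near the midpoint of the two states' claims-side
    # rates; claims sensitivities are high and specificities near one
    # (validated code sets report PPV >= 86%), certificate sensitivities
    # are low for everything but assisted ventilation, where the
    # certificate captures more cases than claims. These are documented
    # assumptions, not estimates of any real population.
    return {
        Condition.NICU: ConditionParams(0.08, 0.90, 0.995, 0.55, 0.995),
        Condition.RDS: ConditionParams(0.03, 0.90, 0.998, 0.15, 0.999),
        Condition.SEIZURE: ConditionParams(0.003, 0.85, 0.9995, 0.05, 0.9999),
        Condition.AV: ConditionParams(0.03, 0.40, 0.999, 0.85, 0.985),
        Condition.BIRTH_INJURY: ConditionParams(0.015, 0.80, 0.995, 0.03, 0.9995),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterization of a synthetic cohort."""

    n_pairs: int = 10_000
    seed: int = 0
    condition_params: dict[Condition, ConditionParams] = field(
        default_factory=_default_condition_params
    )
    bc_missing_rate: float = 0.02
    ssn_missing_rate_mother: float = 0.15
    ssn_missing_rate_infant: float = 0.25
    birth_year_range: tuple[int, int] = (1999, 2010)
    noise_claims_per_infant: float = 1.0
    date_tolerance_noise_days: int = 0
    mother_record_claim_rate: float = 0.10
    severity_correlation: float = 0.0
    window_days: int = 30

    def validate(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        for name, v in (
            ("bc_missing_rate", self.bc_missing_rate),
            ("ssn_missing_rate_mother", self.ssn_missing_rate_mother),
            ("ssn_missing_rate_infant", self.ssn_missing_rate_infant),
            ("mother_record_claim_rate", self.mother_record_claim_rate),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} is not a proportion")
        if self.noise_claims_per_infant < 0:
            raise ValueError("noise_claims_per_infant must be >= 0")
        if self.date_tolerance_noise_days < 0:
            raise ValueError("date_tolerance_noise_days must be >= 0")
        if not -1.0 <= self.severity_correlation <= 1.0:
            raise ValueError("severity_correlation must lie in [-1, 1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be increasing")
        missing = set(Condition) - set(self.condition_params)
        if missing:
            raise ValueError(f"condition_params missing {sorted(c.value for c in missing)}")
        for cond, p in self.condition_params.items():
            p.validate(cond.value)

    def with_params(self, **updates) -> "SimulationConfig":
        return replace(self, **updates)


@dataclass
class CohortTables:
    """The five delimited-text schemas, as data frames."""

    claims: pd.DataFrame
    enrollment: pd.DataFrame
    bc: pd.DataFrame
    persons: pd.DataFrame
    truth: pd.DataFrame
    seed: int = 0


def _id_block(prefix: str, n: int) -> np.ndarray:
    return np.char.add(prefix, np.char.zfill(np.arange(n).astype(str), 7))


def simulate_cohort(config: SimulationConfig) -> CohortTables:
    """Generate a full cohort; byte-identical given the same config.

    Randomness is split into per-purpose substreams (truth, claims
    noise, certificate noise, identifiers, dates) spawned from the root
    seed, so toggling one noise source leaves the others' draws intact.
    """
    config.validate()
    n = config.n_pairs
    root = np.random.SeedSequence(config.seed)
    rng_truth, rng_max, rng_bc, rng_id, rng_dates = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    mother_id = _id_block("M", n)
    infant_id = _id_block("I", n)
    case_id = _id_block("C", n)
    cert_id = _id_block("B", n)
    pair_id = _id_block("P", n)

    y0, y1 = config.birth_year_range
    years = rng_dates.integers(y0, y1 + 1, n)
    doy = rng_dates.integers(0, 365, n)
    birth = pd.to_datetime(
        pd.DataFrame({"year": years, "month": 1, "day": 1})
    ) + pd.to_timedelta(doy, unit="D")

    mother_ssn = np.char.zfill((100_000_000 + 2 * np.arange(n)).astype(str), 9)
    infant_ssn = np.char.zfill((100_000_001 + 2 * np.arange(n)).astype(str), 9)
    mother_has = rng_id.random(n) >= config.ssn_missing_rate_mother
    infant_has = rng_id.random(n) >= config.ssn_missing_rate_infant
    mother_ssn = np.where(mother_has, mother_ssn, "")
    infant_ssn = np.where(infant_has, infant_ssn, "")

    severity = rng_truth.random(n)

    claims_parts: list[pd.DataFrame] = []
    truth_cols: dict[str, np.ndarray] = {}
    bc_cols: dict[str, np.ndarray] = {}
    for cond in Condition:
        p = config.condition_params[cond]
        true = rng_truth.random(n) < p.true_prevalence
        truth_cols[cond.value.lower()] = true.astype(int)

        shift = config.severity_correlation * (severity - 0.5)
        se_max = np.clip(p.se_max + shift, 0.0, 1.0)
        se_bc = np.clip(p.se_bc + shift, 0.0, 1.0)

        r = rng_max.random(n)
        max_obs = np.where(true, r < se_max, r < 1.0 - p.sp_max)
        on_mother = rng_max.random(n) < config.mother_record_claim_rate
        offsets = rng_max.integers(0, config.window_days + 1, n)
        system, codes = EMISSION_CODES[cond]
        code_idx = rng_max.integers(0, len(codes), n)
        inpatient = rng_max.random(n) < 0.7
        dx_pos = 1 + rng_max.integers(0, 3, n)

        r2 = rng_bc.random(n)
        bc_obs = np.where(true, r2 < se_bc, r2 < 1.0 - p.sp_bc)
        bc_missing = rng_bc.random(n) < config.bc_missing_rate
        bc_cols[cond.value.lower()] = np.where(
            bc_missing, "", np.where(bc_obs, "1", "0")
        )

        sel = np.flatnonzero(max_obs)
        if sel.size:
            claims_parts.append(pd.DataFrame({
                "person_id": np.where(on_mother[sel], mother_id[sel], infant_id[sel]),
                "linked_mother_id": np.where(on_mother[sel], "", mother_id[sel]),
                "record_type": np.where(inpatient[sel], "inpatient", "outpatient"),
                "service_date": birth.values[sel] + pd.to_timedelta(offsets[sel], unit="D"),
                "code_system": system,
                "code": np.asarray(codes)[code_idx[sel]],
                "dx_position": dx_pos[sel],
            }))

    # background noise claims, some deliberately outside the window
    k = rng_max.poisson(config.noise_claims_per_infant, n)
    rep = np.repeat(np.arange(n), k)
    if rep.size:
        claims_parts.append(pd.DataFrame({
            "person_id": infant_id[rep],
            "linked_mother_id": mother_id[rep],
            "record_type": np.where(
                rng_max.random(rep.size) < 0.5, "inpatient", "outpatient"
            ),
            "service_date": birth.values[rep]
            + pd.to_timedelta(rng_max.integers(0, 61, rep.size), unit="D"),
            "code_system": "ICD9_DX",
            "code": np.asarray(NOISE_CODES)[
                rng_max.integers(0, len(NOISE_CODES), rep.size)
            ],
            "dx_position": 1 + rng_max.integers(0, 5, rep.size),
        }))

    # one maternal delivery claim per pair; its date doubles as the
    # mother's delivery date used by the case-ID linkage step
    jt = config.date_tolerance_noise_days
    jitter = rng_dates.integers(-jt, jt + 1, n) if jt else np.zeros(n, dtype=int)
    delivery_date = birth.values + pd.to_timedelta(jitter, unit="D")
    claims_parts.append(pd.DataFrame({
        "person_id": mother_id,
        "linked_mother_id": "",
        "record_type": "delivery",
        "service_date": delivery_date,
        "code_system": "ICD9_DX",
        "code": "650",
        "dx_position": 1,
    }))

    claims = pd.concat(claims_parts, ignore_index=True)
    claims["service_date"] = pd.to_datetime(claims["service_date"]).dt.date
    claims = claims.sort_values(
        ["person_id", "service_date", "code"], kind="stable"
    ).reset_index(drop=True)

    enrollment = pd.DataFrame({
        "person_id": np.concatenate([mother_id, infant_id]),
        "start": np.concatenate([
            (birth - pd.Timedelta(days=270)).dt.date.values,
            birth.dt.date.values,
        ]),
        "end": np.tile((birth + pd.Timedelta(days=90)).dt.date.values, 2),
    }).sort_values("person_id", kind="stable").reset_index(drop=True)

    bc = pd.DataFrame({
        "cert_id": cert_id,
        "infant_ssn": infant_ssn,
        "mother_ssn": mother_ssn,
        "birth_date": birth.dt.date.values,
        **bc_cols,
    })

    persons = pd.concat([
        pd.DataFrame({
            "person_id": mother_id, "role": "mother", "ssn": mother_ssn,
            "case_id": case_id, "birth_date": "",
            "delivery_dates": pd.Series(
                pd.to_datetime(delivery_date)
            ).dt.strftime("%Y-%m-%d").values,
        }),
        pd.DataFrame({
            "person_id": infant_id, "role": "infant", "ssn": infant_ssn,
            "case_id": case_id,
            "birth_date": birth.dt.strftime("%Y-%m-%d").values,
            "delivery_dates": "",
        }),
    ], ignore_index=True)

    truth = pd.DataFrame({
        "pair_id": pair_id,
        "mother_id": mother_id,
        "infant_id": infant_id,
        "cert_id": cert_id,
        "birth_date": birth.dt.date.values,
        **truth_cols,
    })

    return CohortTables(
        claims=claims, enrollment=enrollment, bc=bc,
        persons=persons, truth=truth, seed=config.seed,
    )


def expected_cells(
    pi: float, se_max: float, sp_max: float, se_bc: float, sp_bc: float
) -> tuple[float, float, float, float]:
    """Joint 2×2 cell probabilities (p11, p10, p01, p00) under
    conditional independence of the two channels given true status."""
    for v in (pi, se_max, sp_max, se_bc, sp_bc):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{v} is not a proportion")
    q = 1.0 - pi
    p11 = pi * se_max * se_bc + q * (1 - sp_max) * (1 - sp_bc)
    p10 = pi * se_max * (1 - se_bc) + q * (1 - sp_max) * sp_bc
    p01 = pi * (1 - se_max) * se_bc + q * sp_max * (1 - sp_bc)
    p00 = pi * (1 - se_max) * (1 - se_bc) + q * sp_max * sp_bc
    return p11, p10, p01, p00


def expected_kappa(
    pi: float, se_max: float, sp_max: float, se_bc: float, sp_bc: float
) -> Optional[float]:
    """Closed-form population kappa for the independent-channel model.

    ``None`` when chance agreement is exactly 1 (degenerate margins).
    """
    p11, p10, p01, p00 = expected_cells(pi, se_max, sp_max, se_bc, sp_bc)
    po = p11 + p00
    pe = (p11 + p10) * (p11 + p01) + (p01 + p00) * (p10 + p00)
    if pe >= 1.0 - 1e-15:
        return None
    return (po - pe) / (1.0 - pe)
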