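# Methods

## The problem

Administrative data sources that record neonatal health — Medicaid
billing claims (the Medicaid Analytic eXtract, MAX) and birth
certificates (BC) — are both collected for purposes other than research,
and each misclassifies clinical conditions in its own way. This package
implements a dual-source concordance analysis for five neonatal critical
conditions (NICU admission, respiratory distress syndrome, neonatal
seizure, assisted ventilation, birth injury): it links mothers and
infants across the two sources, ascertains each condition independently
in each source, and quantifies agreement. Because the real linked
state cohorts are restricted-access, the package also contains a
generative model of such cohorts with known latent truth, so that every
stage of the pipeline is testable end to end, and a reproduction module
that recomputes the published state-level statistics from their printed
case counts.

## Ascertainment model

A condition is a set of billing-code patterns plus a postnatal window.
On the claims side, an infant is a case when at least one inpatient or
outpatient encounter — on the infant's record or the linked mother's —
carries a matching ICD-9-CM diagnosis/procedure or CPT code, in any
diagnosis position, with service date in the closed interval
`[birth, birth + 30 days]` (day of birth is day 0). Delivery-type
claims identify deliveries for linkage but are not qualifying
encounters. On the certificate side, case status is the checkbox value;
a blank checkbox is an exclusion rather than a negative, because the
certificate form forces an explicit yes/no while an absent claim code
means absence of disease. Code matching uses ICD-9 family semantics:
wildcard patterns (`769.xx`) and bare stems (`96.7`) match any more
specific code by prefix after normalization (dots, commas and
whitespace removed); CPT codes match exactly and must be five digits.
The six retired CPT neonatal critical-care codes (99295–99300) stay in
the NICU set with no validity-period enforcement, since pooled
1999–2010 claims legitimately carry them; a per-code `valid_through`
field exists for analyses that want enforcement.

Deliberately open choices, fixed here: the 30-day window is inclusive
at both ends (the inclusive reading maximizes capture and makes the
boundary unambiguous); mother-record ascertainment applies to all five
conditions, with a per-condition switch, because the rule is most
defensible stated globally; enrollment must cover the full window for
both members of the dyad, as a single continuous span. NICU is
restricted to birth years 2004–2010 because the certificate checkbox
only exists on the post-2003 form revision; out-of-range pairs are
excluded (`excluded_year`), not counted as non-cases.

## Linkage model

Linkage is strictly deterministic, in two steps. Certificates carrying
both the mother's and the infant's SSN are linked to claims enrollees
by exact nine-digit SSN match on both identifiers (step 1). For the
remainder, infants and mothers are paired inside the claims data by the
shared Medicaid family identifier (case ID) with the infant's birth
date matched to a maternal delivery-claim date — exactly by default,
within ±k days when configured — and each pair is then attached to a
certificate through whichever SSN is available (step 2). Step order is
fixed; a pair linked in step 1 is never revisited. Every ambiguity (an
SSN shared across people or certificates, a certificate claimed by two
pairs, an infant matching two mothers) is dropped and logged, never
resolved by choice, so linked identifiers are one-to-one by
construction and the output is invariant to input row order. Twins link
as separate pairs to the same mother provided each resolves to its own
certificate. SSNs are normalized by stripping non-digits; anything not
exactly nine digits is treated as absent.

## Agreement statistics

For each condition, analyzable pairs are cross-classified into a 2×2
table (a = both sources positive, b = claims only, c = certificate
only, d = neither), after removing pairs with a missing certificate
determination or an out-of-range birth year into separate counters.
Reported statistics:

- observed agreement `po = (a+d)/N` and chance agreement
  `pe = p_MAX·p_BC + (1−p_MAX)(1−p_BC)` from the margins;
- crude Cohen's kappa `(po − pe)/(1 − pe)`, undefined (reported absent,
  never 0) when `pe = 1`;
- agreement bands on the percent scale: poor ≤ 20 < fair ≤ 40 <
  moderate ≤ 60 < substantial ≤ 80 < high, applied to kappa rounded to
  one decimal percent. The conventional band labels leave gaps such as
  (20, 21); contiguous half-open intervals are used so the mapping is a
  total function;
- cross-source sensitivities `a/(a+c)` (claims' capture of certificate
  cases) and `a/(a+b)` (the converse), each undefined on a zero margin;
- prevalence per 100 pairs, `100·cases/N`;
- the discordance decomposition of the case union:
  `100·(b+c)/(a+b+c)`.

Report rounding is half-up on the final displayed digit (kappa to one
decimal percent, sensitivities and prevalences to two decimals); raw
values are always retained alongside.

## Reproducing the published tables

The published results print, per state and condition, the claims-side,
certificate-side and both-source case counts plus kappa, both
sensitivities and both prevalences, for cohorts of 558,224 (Florida)
and 981,120 (Texas) linked pairs. The sensitivities are exact ratios of
the printed counts and all twenty reproduce. Kappa and prevalence need
a per-row analysis denominator the publication does not state, and the
rows are mutually inconsistent about it, so each fixture row carries an
explicit denominator policy, established once by inverting the
prevalence formula (`reconstruct_denominator`, which also returns the
feasible integer interval implied by the printed rounding):

- `state_total` — the full state cohort (FL RDS, TX AV and the three
  non-reproducing FL rows below);
- `reconstructed_from_max_prev` / `reconstructed_from_bc_prev` — the
  denominator recovered from the row's own printed prevalence
  (FL NICU → 277,676; TX NICU → 604,142; TX RDS → 377,574;
  TX birth injury → 604,603). The NICU rows are consistent with the
  2004–2010 restriction; the TX RDS value suggests a sub-cohort the
  publication does not describe;
- `shared_subcohort` — an explicit denominator taken from another row's
  reconstruction (TX seizure reproduces only under the TX RDS
  denominator 377,574, while its own printed prevalence implies
  N ≈ 1,012,400).

Seven of the ten printed kappas are recovered exactly under these
policies. Three Florida rows (seizure 8.4 vs recomputed 8.5, assisted
ventilation 14.5 vs 14.6, birth injury 1.5 vs 1.6) reproduce under no
candidate denominator; the discrepancy is at most 0.1 on the percent
scale and presumably reflects undocumented per-row exclusions. These
rows are flagged `reproducible=false` in the fixture and surfaced by
the report with their recomputed values — never suppressed or adjusted.
The fixture file is frozen by a checksum test.

## Generative model

For each of `n_pairs` dyads, the simulator draws a latent truth per
condition (`true_prevalence`), then realizes the two channels
conditionally independently given truth: the claims channel emits at
least one coded encounter with probability `se_max` for cases and
`1 − sp_max` for non-cases (code drawn uniformly from the condition's
set, service date uniform on the 30-day window, 10% of condition claims
on the mother's record, 70% inpatient); the certificate channel sets
the checkbox with probability `se_bc` / `1 − sp_bc` and independently
blanks it at `bc_missing_rate`. Defaults: prevalences near the midpoint
of the two states' claims-side rates (NICU 0.08, RDS 0.03, seizure
0.003, AV 0.03, birth injury 0.015); claims sensitivities 0.80–0.90
with specificities ≥ 0.995, consistent with the validated code sets'
reported positive predictive values (86–97%); certificate sensitivities
low (0.03–0.55) except assisted ventilation (0.85 with `sp_bc` 0.985),
mirroring the observed direction that the certificate out-captures
claims for that condition only; `bc_missing_rate` 0.02, matching the
stated sub-2% rate of missing determinations. These defaults are
loosely motivated assumptions, not estimates of the real populations —
true source specificities are not measurable from a two-source design.

Identifiers: unique SSNs masked per person at `ssn_missing_rate_mother`
= 0.15 and `ssn_missing_rate_infant` = 0.25 (so roughly a third of
pairs exercise the case-ID path), shared case IDs, birth dates uniform
over 1999–2010, one maternal delivery claim per pair (jittered by
`date_tolerance_noise_days` when stressing the date-match knob), a
Poisson(1) stream of unrelated claims per infant with dates up to day
60 to exercise window locality, and full enrollment spans (birth −270
to +90 days for mothers, birth to +90 for infants). Randomness uses one
root seed split into per-purpose substreams (truth, claims noise,
certificate noise, identifiers, dates), so toggling one noise source
leaves the others' draws intact; identical configurations are
byte-identical.

Under conditional independence the population 2×2 cells are
`p11 = π·se_M·se_B + (1−π)(1−sp_M)(1−sp_B)` and so on
(`expected_cells`), giving a closed-form kappa used as the oracle for
parameter-recovery tests. A `severity_correlation` knob shifts both
sensitivities by a shared latent severity term for sensitivity
analyses; the closed form then no longer applies.

What the simulator does **not** emulate: real coding practice
(co-occurring codes, billing incentives, position-dependent coding),
demographic structure, multiple births, linkage clerical errors beyond
missing SSNs, enrollment churn, or between-state heterogeneity. Passing
tests therefore show that the pipeline implements the stated rules and
recovers known parameters under the stated error model — not that the
real sources behave like the model.

## Numerical and scale choices

The record-level ascertainment operations define the semantics; the
table-level implementations used for cohort-scale runs are vectorized
and equivalence-tested against them on a 400-pair cohort. Parameter
recovery is tested at 60,000 pairs in the suite and 200,000 pairs in
the acceptance script (a few seconds each), with empirical kappa
required to lie within three Monte-Carlo standard errors (delta-method
`sqrt(po(1−po)/n)/(1−pe)`) of the closed form. Linkage is scored
against truth at 10,000 pairs. Undefined statistics are propagated as
absent values throughout; degenerate tables (empty, single-cell) raise
or report absent rather than returning conventional zeros.

## Known limitations

- No kappa variance or confidence intervals, no weighted kappa, no
  prevalence-adjusted variants; the crude statistic is the analysis
  target.
- Deterministic linkage only; no probabilistic scoring.
- ICD-9-CM era only; no ICD-10, no pharmacy-claim ascertainment.
- The denominator policies for the published rows are reconstructions
  constrained by printed rounding, not documentation; the three
  non-reproducing rows mark the limit of what the printed numbers
  support.
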