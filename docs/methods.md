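# Methods

This note records the statistical model, the data-processing conventions,
the synthetic-data generator's assumptions, and the numerical and design
choices behind `pvdispro`, in the order the pipeline runs.

## Input model

The package reads the FAERS quarterly ASCII distribution: `$`-delimited
tables with a header row (DEMO, DRUG, REAC, OUTC, THER, INDI, and a
deleted-case list), decoded as latin-1 with replacement. Columns are bound
by header name, case-insensitively, because FAERS column sets drift across
quarters; binding by position would silently misread older quarters.
Delimiter, encoding and header handling are overridable.

Dates are classified rather than coerced: an 8-digit string forming a real
calendar date has day precision, 6 digits month precision, 4 digits year
precision; anything else is missing or invalid. Downstream rules
(chronology exclusion, time-to-onset) only ever fire on day-precision
dates — a partial date is treated as "cannot establish ordering", never as
evidence of inconsistency.

Ages are normalized to years (decades×10, months/12, weeks/52,
days/365.25); an unknown unit makes the age unknown rather than guessing.

Drug cohorts are defined by a user-supplied lexicon: exact matching of
punctuation-normalized, case-folded names against both DRUGNAME and
PROD_AI, with an explicit exclusion list applied after synonym matching so
a combination product can be kept out of a monotherapy cohort. Exact
normalized matching was chosen over substring matching because it is
auditable: every cohort member can be traced to a listed synonym. MedDRA
is licensed and not bundled; the PT→SOC mapping is a user-supplied
two-column file, and a PT may map to several SOCs.

## Cleaning

Order: deduplicate → remove deleted cases → assemble reports → require at
least one event → chronology filter.

- **Deduplication** keeps, per CASEID, the record with the latest FDA
  receipt date, breaking ties by largest PRIMARYID (numeric ids compared
  via zero-padding; non-numeric ids fall back to the same zero-padded
  string comparison and are logged). The operation is idempotent and
  commutes with deleted-case removal, since deletion is keyed on CASEID.
- **Chronology filter** drops a report iff some drug start date is
  strictly after the event onset date with both at day precision, or the
  FDA receipt date is not a full valid date. "Missing critical date
  information" is read as the receipt date only: it is the one date every
  analysis needs, whereas a missing event date only disables time-to-onset.
- **Cohorts** require a lexicon drug with the Primary Suspect role code.
  Other suspect drugs on the report are allowed by default (the common
  convention); `strict_single_suspect` excludes reports naming any
  non-lexicon suspect drug.

Every step reports in/kept/dropped counts with reason codes; in = kept +
dropped holds at each step and is asserted in tests.

## Contingency tables

The counting unit is the report, never the reaction row: a PT repeated
within one report contributes once, and a report contributes at most once
to a SOC however many of its PTs map there. This is the reading consistent
with cell definitions phrased in terms of *cases*. The background for each
pair is all non-cohort reports in the cleaned database — including reports
of a paired comparator drug — because the statistics are defined against
the whole database, not a restricted comparator. PT-level tables require
a ≥ 3 (configurable) before any statistic is computed; no extra count
filter is applied at SOC level, so SOC tables can show non-signals.
Unmapped PTs are tallied and excluded from SOC tables.

## Statistics and the signal rule

Formulas as in the README. Numerical and design notes:

- **χ² variant.** Pearson without continuity correction by default, with a
  Yates flag. χ² is reported but deliberately not part of the joint
  criterion: the decision rule pairs each algorithm with exactly the
  threshold conventionally attached to it (ROR and PRR with their CI lower
  bounds, IC with IC025, EBGM with EBGM05), and χ² has no such threshold
  in that rule.
- **BCPNN.** The closed-form posterior moments use Dirichlet/Beta priors
  with defaults γij = 1, αi = βj = 1, α = β = 2 — the standard
  single-drug/single-event choice, under which an exactly balanced table
  (a=b=c=d) has E(IC) = 0 exactly (the prior terms cancel). The variance
  is the standard closed form including the prior terms; published
  renderings of this expression are frequently garbled typographically,
  and the implementation follows the closed form they correspond to.
  IC025 = E(IC) − 2·√V(IC), with the conventional factor 2 (not 1.96).
- **EBGM.** Implemented as the relative reporting ratio aN/((a+b)(a+c))
  with a log-symmetric interval — identical to 2^IC, and asserted to be so
  to machine precision. No Dirichlet-mixture (MGPS) shrinkage is applied;
  none is defined for this closed form, and the identity EBGM = 2^IC is a
  useful cross-check precisely because both are the same ratio.
- **Not-applicable handling.** Tables with a < 3, or with a zero in b, c
  or d, get NaN statistics rather than Haldane-corrected ones; a NaN fails
  its criterion. With the a ≥ 3 count filter upstream, zero cells are
  essentially impossible in practice, so a continuity correction would
  only ever mask degenerate inputs.
- **Boundary semantics.** Point thresholds are inclusive (ROR ≥ 2),
  CI-bound thresholds strict (lower bound > 1, IC025 > 0, EBGM05 > 2).
- **No multiplicity adjustment.** The four-way conjunction is the
  false-positive control; the null-calibration test measures what it buys
  (joint flag rate ≈ 0 on a 50,000-report null database where the ROR
  criterion alone would already be rare).

Relative-error checks against the high-precision oracle use a unit floor
in the denominator, because the log-scale statistics (IC, IC025) pass
through zero on random tables, where a pure ratio is ill-conditioned.

## Subgroups and demographics

Stratified analyses restrict **both** cohort and background to the stratum
before table construction (the standard subgroup-disproportionality
convention; a flag keeps the full-database background instead), then apply
the unchanged contingency + statistics machinery, including the minimum
count within the stratum. Consequences asserted in tests: an `any`/`any`
stratum reproduces the global analysis bit-for-bit, and stratum cells sum
over a partition (F + M + unknown) to the global cells. The age cut is
exactly 60 years: age ≥ 60.0 falls in the elderly group; missing or
unparseable age is its own stratum.

## Time-to-onset

Days from drug start to event onset, whole days, with exclusion statuses
assigned in precedence order: missing date → event before start → invalid
or partial date → extreme interval (default cut 3,650 days ≈ 10 years,
configurable; spontaneous reports above that range are overwhelmingly
data-entry errors). When a report has several matching drug rows, the
earliest day-precision start date is used. Summaries give median and
quartiles by linear interpolation between order statistics (the default
convention in mainstream statistical software, fixed here for
reproducibility) and bin counts over [0,7], (7,28], (28,60], (60,∞) —
shared endpoints are resolved lower-closed for the first bin and
upper-inclusive thereafter, so a same-day onset and a 7-day onset both
fall in the first bin; the convention is configurable.

## Synthetic databases and what they validate

The generator emulates the FAERS table structure with known truth. Each
report carries one Primary Suspect drug from a prevalence mixture (one
cohort drug at 10% by default, the remainder spread over background
drugs); each of 200 PTs (spread over 10 SOCs) is an independent Bernoulli
coin at background probability 0.01, multiplied by the planted rate ratio
for affected (drug, PT) pairs and capped at 1. All-zero rows are redrawn
(50 rounds, then one forced background event), so events are conditionally
distributed on "at least one event per report".

That conditioning matters for recovery testing: a planted rate ratio RR
does not induce an odds ratio of exactly RR. The truth table therefore
computes the induced odds ratio analytically — conditional marginal
p/(1−q) per (drug, sex) profile with q the all-zero probability, mixed
over the prevalence weights — and interval-coverage tests compare against
that, not against RR. At the default settings the residual probability of
exhausting the redraw cap is ~10⁻⁴⁴, so the conditional form is exact for
practical purposes.

Structural realism knobs, with defaults chosen to resemble a typical
antibiotic cohort in a spontaneous-reporting system: 5% duplicate case
versions (clones share the CASEID; half get a later FDA date, half an
identical one, so both deduplication tie rules are exercised
deterministically), 1% deleted cases, ~20% missing event dates, 5%
month-precision start dates, sex split 55/37/8 (F/M/unknown), age mixture
47% under 60 / 30% 60–90 / 23% unknown, geometric time-to-onset with mean
3 days (median 2) and a ~30-day geometric reporting delay. Identical
config ⇒ byte-identical output files.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real FAERS data: within-report event correlation
(events are independent coins), masking/competition between signals,
drug-name free-text noise, realistic country/reporter marginals, secular
reporting trends, and case-version histories beyond a single duplicate.
The synthetic results validate the machinery (counting, formulas,
thresholds, stratification, determinism), not the epidemiology.

A fast counting path (`pair_table` / `tables_for_drug`) computes
post-cleaning tables directly from the generator's arrays — clones are
content-identical to their originals and deletion removes whole cases, so
the cleaned counts equal originals-minus-deleted. A dedicated test proves
this path identical to the full record-level pipeline; the repeated-seed
validation runs use it, while single-run validations go through the full
pipeline.

## Validation problem sizes

The shipped validation suite runs at: 1,000 random tables for the formula
oracle; 1,000 randomized fixtures for the cleaning oracle; one
50,000-report null database (200 PTs) for calibration; 20 seeds at
n=50,000 for planted-signal detection (RR=10, E[a]=500) and 50 seeds at
n=100,000 for interval coverage (RR=5); one 30,000-report database for
stratification conservation. Everything completes in roughly a minute on
one CPU.

## Known limitations

- The EBGM here is the closed-form relative reporting ratio; true
  empirical-Bayes (Dirichlet-mixture) shrinkage is out of scope, so small-
  count stabilization relies on the a ≥ 3 gate rather than shrinkage.
- Only full-date chronology inconsistencies are detectable; month-level
  contradictions pass the filter by design.
- Exact-name lexicon matching will miss misspelled drug names; no
  RxNorm-style normalization is attempted.
- HLT/HLGT MedDRA levels and standardized MedDRA queries are not
  supported; aggregation is PT and SOC only.
- Probabilistic record linkage (same case reported by several
  manufacturers under different CASEIDs) is out of scope; deduplication is
  exact on CASEID.
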