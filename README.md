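# pvdispro

Disproportionality signal detection for spontaneous adverse-event report
databases distributed in the FAERS quarterly ASCII format.

Pharmacovigilance teams mine spontaneous-reporting systems such as the FDA
Adverse Event Reporting System (FAERS) for drug safety signals: drug–event
pairs reported more often than the rest of the database would predict.
`pvdispro` implements that workflow end to end — report-level cleaning,
2×2 contingency construction, four disproportionality statistics with a
joint signal criterion, sex/age subgroup analyses, time-to-onset summaries
— plus a synthetic-database generator with planted effects so the whole
chain can be validated against known ground truth without downloading
FAERS.

## The statistics

For a drug–event pair, reports are cross-classified against the rest of
the cleaned database:

|                    | event reported | event not reported |
|--------------------|----------------|--------------------|
| drug of interest   | a              | b                  |
| all other reports  | c              | d                  |

with N = a+b+c+d. The package computes:

- **ROR** (reporting odds ratio) = ad/(bc), with 95% CI
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d));
- **PRR** (proportional reporting ratio) = [a/(a+b)] / [c/(c+d)], with 95%
  CI exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)));
- **χ²** — Pearson's statistic for the 2×2 table (optionally
  Yates-corrected), reported alongside but not part of the decision rule;
- **BCPNN IC** = log₂(aN/((a+b)(a+c))) with closed-form posterior moments
  E(IC), V(IC) under Dirichlet/Beta priors and lower credibility bound
  IC025 = E(IC) − 2·√V(IC);
- **EBGM** = aN/((a+b)(a+c)) — the relative reporting ratio, equal to
  2^IC — with a log-symmetric 95% interval whose lower bound is EBGM05.

A pair is a **signal** only when all four algorithms agree simultaneously:
a ≥ 3, ROR ≥ 2 with CI lower bound > 1, PRR ≥ 2 with CI lower bound > 1,
IC025 > 0, and EBGM05 > 2. The conjunction is deliberately conservative —
it is the false-positive control in place of any multiplicity adjustment.

Cleaning follows standard FAERS practice: one record per case (latest
FDA receipt date wins, largest PRIMARYID breaks ties), removal of cases
the FDA marked for deletion, exclusion of reports whose drug start date
falls after the event onset date or whose receipt date is unusable, and
cohort restriction to reports where the drug of interest carries the
Primary Suspect role code.

## Worked example

Generate a 20,000-report synthetic database in which `DRUG_A` (10%
prevalence) multiplies the background reporting probability of `PT_001`
(1%) tenfold, then run the full pipeline:

```python
from pvdispro import (SyntheticConfig, PlantedEffect, generate,
                      DrugLexicon, build_cohort, build_tables, signal_table)

config = SyntheticConfig(
    seed=7, n_reports=20_000,
    effects=(PlantedEffect("DRUG_A", "PT_001", 10.0),),
)
dataset = generate(config)
cleaned = dataset.clean()
cohort = build_cohort(cleaned.reports, DrugLexicon("DRUG_A", {"DRUG_A"}))
tables = build_tables(cleaned.reports, cohort)
stats = signal_table(tables)
```

Output (printing the planted pair's row):

```
reports after cleaning: 19813
cohort size: 1949
PT_001  a=203  ROR=10.27 (8.40, 12.56)  PRR=9.30  chi2=762.1  IC025=2.07  EBGM05=4.19  signal=True
signals flagged: ['PT_001']
```

The cleaning step removed the planted duplicate case versions and deleted
cases (20,000 → 19,813). Among the 1,949 cohort reports, 203 carry
`PT_001`, about ten times its background reporting rate, so every
statistic clears its threshold and the pair — and only that pair, out of
200 PTs — is flagged.

The same workflow is available from the shell via `pvdispro simulate`,
`clean`, `signals`, `subgroup`, `tto` and `recover`, driven by a YAML
config (see `pvdispro --help`).

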