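# riskcombine

Tools for combining a normalized SNP-based (polygenic) relative risk score
with Gail-style absolute breast cancer risk projections, and for evaluating
the combination with case-control statistics: OPERA (odds ratio per
age-adjusted standard deviation), AUC with the DeLong paired test,
Hosmer–Lemeshow calibration, and guideline-threshold reclassification with
the net reclassification improvement (NRI).

A fully seeded synthetic cohort generator produces every input the pipeline
needs (SNP panel, Hardy–Weinberg genotypes, questionnaire records, hazard
tables, case/control labels with known ground-truth effect sizes), so the
entire analysis is testable without any study data.

## What it computes

- **SNP score** — for each panel SNP with per-allele odds ratio `OR` and
  risk-allele frequency `p`, the population-average risk
  `mu = (1-p)^2 + 2p(1-p)·OR + p^2·OR^2`; a subject's score is the product
  of `OR^dosage / mu` over all SNPs (missing genotypes contribute a
  neutral factor of 1).
- **Absolute risk** — a coefficient-agnostic competing-risk projection of
  5-year and lifetime (to age 90) risk from questionnaire relative risks
  and user-supplied piecewise-constant hazard tables (official BCRAT/CARE
  tables are external config, not redistributed).
- **Combined score** — SNP score × absolute risk, capped at 1.
- **Evaluation** — OPERA per log score (age-adjusted), AUC + DeLong
  change-in-AUC, Hosmer–Lemeshow.
- **Reclassification** — low/high cross-tabulation of clinical vs combined
  risk at the 1.66% (5-year) and 20% (lifetime) guideline thresholds, with
  NRI = P(up|case) − P(down|case) + P(down|control) − P(up|control) and an
  asymptotic (or optional bootstrap) CI.

## CLI

```bash
# generate a complete synthetic input set (deterministic under --seed)
riskcombine simulate --out sim/ --seed 1

# all-in-one pipeline: scores, evaluation, reclassification, summary.json
riskcombine run --panel sim/panel.csv --genotypes sim/genotypes.csv \
    --questionnaire sim/questionnaire.csv --hazards sim/hazards.yaml \
    --out results/ --seed 1

# or stage by stage
riskcombine score --panel ... --genotypes ... --questionnaire ... --hazards ... --out scores.csv
riskcombine evaluate --scores scores.csv --out evaluation.csv
riskcombine reclassify --scores scores.csv --out reclassification.csv

# NRI straight from eight printed 2x2 counts (low->low low->high high->low high->high)
riskcombine nri-from-table --cases 147 42 34 96 --controls 411 47 44 57
```

Input formats (CSV with header):

- panel: `rsid,risk_allele,or,freq`
- genotypes: `subject_id` + one risk-allele dosage column (0/1/2, blank/NA
  for missing) per rsid
- questionnaire: `subject_id,status,age,n_first_degree_relatives,
  age_menarche,age_first_birth,n_biopsies,hyperplasia` (status is
  `case`/`control`; subjects under 35 are excluded)
- hazards: YAML with `hazard_table` (age bands over [35,90), incidence and
  competing-mortality hazards) and `relative_risk_model` (log-RR per
  questionnaire category; see `riskcombine simulate` output for a template)

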