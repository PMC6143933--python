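# faerspv

Pharmacovigilance toolkit for FAERS spontaneous-report data: quarterly ASCII
ingestion, case deduplication, adolescent cohort extraction, sex-stratified
frequency tables, and designated-control-event disproportionality statistics
(reporting odds ratio via closed form and logistic regression, plus PRR and
RRR), together with a seeded synthetic FAERS generator so the entire
pipeline runs and is testable without any download.

## Layout

| module | role |
| --- | --- |
| `faerspv.faers_io` | read/validate "$"-delimited DEMO/DRUG/REAC/OUTC/RPSR/THER/INDI tables, link them on `primaryid` into case reports, deduplicate by `caseid`/`caseversion` |
| `faerspv.cohort_builder` | age-unit normalization (DEC/YR/MON/WK/DY/HR), adolescent `[12, 18)` filter, sex breakdowns |
| `faerspv.descriptive_stats` | top-N frequency tables, per-drug drill-downs, drug→gene relevance-score ranking from a user TSV |
| `faerspv.disproportionality` | 2×2 tables against a designated control PT, ROR (closed form + logistic, cross-checked), PRR, RRR, multi-drug scans, Haldane–Anscombe handling of zero cells |
| `faerspv.synthetic_faers` | seeded generator of FAERS-dialect quarters with configurable drug/event catalogs, injected log-OR signals, duplicate case versions, and a truth table for recovery tests |
| `faerspv.pipeline` / `faerspv.cli` | YAML-configured end-to-end runs with a deterministic manifest |

## CLI

```bash
# synthesize a quarter (plus its signal truth table)
faerspv simulate --n-cases 5000 --seed 1 -o data/

# one disproportionality scan over the top-20 cohort drugs
faerspv scan --data data/ --case-event Hyperglycaemia --control-event Diarrhoea -o scan.csv

# one frequency table
faerspv freq --data data/ --dimension drug --top-n 15 -o freq.csv

# full pipeline from a YAML config
faerspv run -c run.yaml
```

A minimal `run.yaml`:

```yaml
out_dir: out
seed: 1
synthetic:
  n_cases: 5000
  duplicate_rate: 0.1
  signal_matrix:
    - [RISPERIDONE, Hyperglycaemia, 2.08]
```

Real quarters are used by replacing the `synthetic` block with
`quarters: [{label: 2017q3, dir: /path/to/ascii}]`. Exit codes: 0 ok,
1 configuration error, 2 stage failure.

## Notable conventions

- Duplicate rule: highest `caseversion` wins across all pooled quarters;
  ties break by latest `fda_dt`, then highest `primaryid`.
- Drug names are uppercased/whitespace-collapsed but never salt-stripped:
  `QUETIAPINE FUMARATE` stays distinct from `QUETIAPINE`. An optional
  synonym map can merge spellings.
- Reports mentioning both the case and the control PT are excluded from
  2×2 eligibility (and counted).
- Zero cells get the Haldane–Anscombe +0.5 on all four cells, flagged as
  `corrected`; separated logistic fits are flagged `unstable` and fall back
  to the corrected closed form.
- Cohort-level frequency percentages use the number of cases as the
  denominator; drill-down percentages use total distinct mentions (both
  labeled in the CSV output).
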