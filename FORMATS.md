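# File formats

All tables are tab-separated text with a header row. Missing values may be
written as an empty field, `NA`, `NaN`, `N/A`, `null` or `None`.

## Phenotype / covariate table (`--phenotypes`)

| column | content |
|---|---|
| first column | sample ID (header name free; `sample_id` by convention) |
| `age` | age in years, > 0 |
| `reported_sex` | `M`/`F`, `Male`/`Female` or `1`/`2` |
| `genotype_sex` | as above, plus `NA`/`0`/`U` for unknown |
| one column per trait | quantitative value, `0`/`1` for binary, category label for ordinal |

## Polygenic-score table (`--pgs`)

Generic TSV (sample ID first, one column per trait) or PLINK2 `.sscore`
layout (`#IID` first column; `ALLELE_CT` and `NAMED_ALLELE_DOSAGE_SUM`
columns are ignored).

## Trait configuration (`--traits`)

YAML or JSON list of records:

```yaml
- name: height
  data_type: quantitative        # quantitative | binary | ordinal
- name: hair_color
  data_type: ordinal
  categories: [dark, brown, blonde]   # increasing order, >= 3
  pgs_column: hair_color         # optional, defaults to name
  phenotype_column: hair_color   # optional, defaults to name
```

## Model file (`fit --model-out`, JSON)

`models`: per-trait regression coefficients (intercept, pgs, age, sex,
age_x_sex), ordered-logistic thresholds, age-centring constant, fit_n.
`likelihoods`: per-trait Gaussian parameters or bin breaks plus per-bin
masses (per category for ordinal traits). `significances`: Welch t-test
per trait. `male_fraction`: training male fraction used by the sex-check
LLR.

## Score output (`score --out-prefix`)

`<prefix>.scores.tsv` — per sample: `summed_llr`, `n_traits_used`,
`scaled_llr`, `sex_llr`, `sex_mismatch`, `combined_score`,
`insufficient_data`.

`<prefix>.permuted_scores.tsv` — per permuted genotype-phenotype pairing:
`phenotype_sample`, `genotype_sample`, `summed_llr`, `scaled_llr`,
`combined_score`. This is the empirical mix-up score distribution used for
sensitivity estimation.

## Selection output (`select --out`)

Per sample: `combined_score`, `sensitivity_at_score`, `mr_pass`, `n_pass`,
`passes`.

## Simulated truth (`simulate`, `<prefix>.truth.tsv`)

Per sample: `is_mixup` (0/1) and `source_of_genotype` (the sample whose
genotype-side data this row carries).
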