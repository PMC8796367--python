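# pgsmixup

Sample mix-ups — genotype records attached to the wrong individual's
phenotype record — corrupt genotype-phenotype studies and are a standing
quality-control problem for biobanks. A sex-concordance check (reported sex
vs. sex inferred from genotypes) catches only the swaps that happen to cross
sexes. `pgsmixup` extends mix-up detection to *every* sample by exploiting
polygenic scores (PGSs): if a sample's measured phenotypes consistently
disagree with what its PGSs predict, the genotype probably belongs to
someone else.

The package is for QC engineers and statistical geneticists who have, per
sample, a table of PGSs (one per trait), a phenotype table with age and
reported sex, and genotype-inferred sex. It identifies likely mix-ups,
and can select a subset of samples guaranteed (in expectation) to contain
fewer than a chosen rate of residual mix-ups.

## Method

For each trait *t* the measured phenotype is regressed on its PGS with age,
sex and their interaction as covariates — linear for quantitative traits,
logistic for binary, ordered logistic for ordinal. Residuals are computed
both for the *provided* sample mappings (the pairing recorded by the study)
and for *permuted* mappings (a phenotype paired with another sample's
genotype), which serve as an empirical model of mix-ups. For the logistic
families the residual is the deviance residual

&nbsp;&nbsp;&nbsp;&nbsp;*d* = √(−2 ln *P*<sub>obs</sub>),

where *P*<sub>obs</sub> is the model's probability of the observed outcome
(or, for ordinal traits, of the observed category).

Densities are fitted to the two residual distributions — Gaussian for
quantitative traits, equal-width histogram bins (80 provided samples per bin
on average, minimum 10 per bin, fitted per category for ordinal traits)
otherwise — and each residual *r* is scored with the log-likelihood ratio

&nbsp;&nbsp;&nbsp;&nbsp;LLR(*r*) = ln [ *f*<sub>permuted</sub>(*r*) / *f*<sub>provided</sub>(*r*) ],

so larger values mean more mix-up evidence. Traits whose permuted LLRs do
not exceed their provided LLRs (one-sided Welch *t*-test) are dropped; the
rest are summed per sample and z-scored against the sample's own
permuted-pairing sums. The sex check enters as an additive LLR with mismatch
probability 2 *f*<sub>m</sub>(1−*f*<sub>m</sub>) under a random swap and a
small assay-error rate under a correct mapping.

For subset selection, the cohort mix-up rate is estimated from the
sex-check yield,

&nbsp;&nbsp;&nbsp;&nbsp;mr<sub>estimated</sub> = ( swaps<sub>sex-check</sub> / (2 (1−*f*<sub>m</sub>) *f*<sub>m</sub>) − swaps<sub>total</sub> ) / *N*,

and the residual rate among the *n*<sub>pass</sub> samples at or below a
score threshold with sensitivity *s* (estimated from the permuted-score
distribution) is

&nbsp;&nbsp;&nbsp;&nbsp;mr<sub>pass</sub> = mr<sub>estimated</sub> · (1−*s*) · *N* / *n*<sub>pass</sub>.

Samples whose mr<sub>pass</sub> falls below the configured maximum rate pass.

A synthetic-cohort generator (correlated PGSs/phenotypes/covariates, mixed
trait types, ground-truth derangement mix-ups) and a train/test evaluation
harness (ROC/AUC for the PGS score, the sex check and their combination)
are included; see `docs/methods.md`.

## Worked example

```
$ pgsmixup simulate --n-samples 4000 --seed 7 --mixup-fraction 0.02 --out-prefix demo
wrote demo.{phenotypes.tsv,pgs.tsv,traits.yaml,truth.tsv} (n=4000, seed=7)

$ pgsmixup fit --phenotypes demo.phenotypes.tsv --pgs demo.pgs.tsv \
      --traits demo.traits.yaml --permutation-cap 200 --model-out model.json
fitted 25 traits (25 significant) -> model.json

$ pgsmixup score --phenotypes demo.phenotypes.tsv --pgs demo.pgs.tsv \
      --traits demo.traits.yaml --model model.json --permutation-cap 200 \
      --out-prefix run
scored 4000 samples -> run.scores.tsv

$ pgsmixup select --scores run.scores.tsv --permuted-scores run.permuted_scores.tsv \
      --max-mixup-rate 0.1% --out pass.tsv
2275 of 4000 samples pass at max rate 0.001 -> pass.tsv
```

The simulated cohort contains 2% induced mix-ups. In `run.scores.tsv` the
mean `combined_score` of the induced mix-ups is 2.73 against −1.90 for
correct samples (higher = more mix-up evidence). Of the 2275 samples that
pass the 0.1% budget, the ground truth in `demo.truth.tsv` shows 4 are
mix-ups — an order of magnitude below the cohort's 2% rate. File layouts
are documented in `FORMATS.md`.

The evaluation harness reports discrimination directly:

```
$ pgsmixup evaluate --n-samples 2000 --seeds 1 --permutation-cap 100 --out-prefix ev
{"pgs": 0.8508, "sex": 0.7518, "combined": 0.9285}
```

i.e. on this synthetic panel the PGS score alone reaches AUC 0.85 for
separating mix-ups from correct samples, the bare sex check 0.75 (its
theoretical value for balanced sexes), and the combination 0.93.

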