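# napscan

Quantitative analysis of **nucleoid-associated proteins (NAPs)** in
archaea. Archaeal chromatin is not built around one universal protein:
different lineages rely on different small, abundant, weakly
sequence-specific DNA binders (histones, Alba, HU/HTa, MC1, Cren7, Sul7,
CC1, and uncharacterized proteins). `napscan` is for microbiologists and
comparative genomicists who want to ask, from label-free proteomics
tables and genome annotations: *which proteins act as NAPs in a given
species, and how much of the protein budget does a species spend on
chromatin?* — and to relate that investment to ecology, in particular
optimal growth temperature (OGT).

## What it computes

**NAP investment.** With fractional abundances
$f_p = 100\, I_p / \sum_q I_q$ (percent of total detected intensity),
investment is $\sum_{p\in\mathrm{NAPs}} f_p$, optionally normalized by
housekeeping references (tRNA synthetases, RNA polymerase subunits) as a
ploidy-like control.

**Candidate-NAP prediction.** A detected protein (excluding known NAPs)
is a candidate when it (1) is shorter than 290 aa, (2) has a DNA-binding
domain or a positive DNA-binding SVM score, (3) is a high-side abundance
outlier versus predicted transcription factors under the generalized
extreme studentized deviate (Rosner) test
$R_i = \max_j |x_j-\bar x|/s$ vs
$\lambda_i = (n-i)\,t_{p,n-i-1} / \sqrt{(n-i-1+t^2)(n-i+1)}$,
and (4) sits in a single-gene operon.

**Nucleoid enrichment.** Replicated nucleoid-vs-top sucrose-gradient
intensities are compared per protein with an empirical-Bayes moderated
t-test (left-censored imputation, variance shrinkage, BH q-values), and
a rank-sum test asks whether DNA-binding-domain proteins are
collectively enriched.

**Comparative statistics.** Spearman correlations (exact at small n), a
domain-wide OGT correlation screen, OLS with mean-response and
new-observation intervals for predicting investment in an unseen
species, and phylogenetic generalized least squares under Brownian
motion, $\hat\beta = (X^\top C^{-1}X)^{-1}X^\top C^{-1}y$ with $C$ the
shared-branch-length matrix, with parametric bootstrap CIs.

**Synthetic studies.** A seeded generator produces complete studies —
tree, OGTs evolving by Brownian motion, 2,000-protein proteomes with
spiked ground-truth NAPs and per-filter decoys, domain annotations,
operons, DNA-binding scores, and two-fraction enrichment replicates —
in the exact file formats the readers parse. See `docs/methods.md` for
the model and every default.

## Worked example

Simulate a 19-species study and run every stage:

```sh
napscan run-all --out demo_run --seed 1
# report for 19 species (3184c844e4e6) in demo_run/report.json
```

`demo_run/report.json` then contains (abridged):

```json
"correlation": {
    "spearman_rho": 0.9350877192982456,
    "ols_slope_percent_per_degC": 0.07285526041766881,
    "predict_at_ogt": 37.0,
    "predicted_percent": 0.8431741701697808,
    "prediction_interval_95": [0.0364, 1.6499]
},
"enrichment": {
    "dna_binding_rank_sum_W": 8843.0,
    "dna_binding_wilcoxon_p": 0.0444
}
```

Reading: across the 19 simulated species, NAP investment and growth
temperature are strongly rank-correlated (ρ = 0.935); the fitted line
gains ≈0.073 percentage points of protein budget per °C; a new species
growing at 37 °C is predicted to spend 0.84% of its proteome on NAPs
(95% prediction interval 0.04–1.65%); and in the nucleoid-enrichment
assay of species sp1, DNA-binding-domain proteins are collectively
shifted toward the nucleoid fraction (two-sided rank-sum p = 0.044).

Individual stages are also exposed (`napscan simulate`, `quantify`,
`survey`, `predict-naps`, `enrich`, `correlate`, `pgls`), all operating
on the study directory layout written by `simulate`; equally, everything
is importable:

```python
from napscan.synthetic_data import simulate_study
from napscan.quantification import fractional_abundances, investment

study = simulate_study(seed=1)
sp = study.species["sp7"]
fp = fractional_abundances(sp.quant)
print(round(investment(fp, sp.true_nap_ids), 3))  # 4.604 (% of proteome)
```

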