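# Methods

## Overview

`napscan` analyses investment in nucleoid-associated proteins (NAPs)
across archaea. It takes per-species label-free protein quantification
tables, HMM domain hit tables, operon predictions, DNA-binding SVM
scores, species metadata and a species tree, and produces: fractional
protein abundances, an aggregate NAP-investment metric, candidate-NAP
predictions, presence/absence surveys of known NAP families,
nucleoid-fraction enrichment statistics, and cross-species regressions of
NAP investment on optimal growth temperature (OGT).

## Fractional abundance and NAP investment

For a sample with protein intensities $I_p$, the fractional abundance is
$f_p = 100 \cdot I_p / \sum_q I_q$ (percent of total detected intensity).
LFQ intensities are preferred when present; rows lacking an LFQ value
are then dropped from the basis. NAP investment is
$\sum_{p \in \mathrm{NAPs}} f_p$: the summed fractional abundance of all
detected NAPs (known families plus pipeline candidates). Undetected NAP
genes contribute zero. The metric is invariant to global intensity
scaling. QC requires whole-cell extracts without size selection and more
than 500 identified proteins (strict).

Two normalization variants divide NAP investment by the investment in a
housekeeping reference instead of the whole proteome: tRNA synthetases
(proteins with a tRNA-synt_1 or tRNA-synt_2 domain) or RNA polymerase
largest subunits (RNA_pol_Rpb1_3 or RNA_pol_Rpb2_3). These act as
ploidy-like controls, since reference abundance should scale with the
transcription/translation machinery rather than with chromatin demand.

## Candidate-NAP prediction

A detected protein qualifies as a candidate NAP when it is not a known
NAP and passes four successive filters:

1. **Size** — strictly shorter than 290 amino acids (110% the length of
   TrmBL2, the largest protein with a characterized global chromatin
   role). Configurable via `max_len`.
2. **DNA binding** — at least one hit to a curated DNA-binding domain
   set, OR a DNA-binding SVM score strictly greater than 0.
3. **Abundance** — a high-side abundance outlier relative to predicted
   transcription factors (TFs; proteins with a DNA-binding or GO:0003700
   sequence-specific-TF domain), judged by the generalized extreme
   studentized deviate (ESD, Rosner) test.
4. **Operon** — encoded as a single-gene operon (relaxable via
   `relax_operon`). Proteins absent from the operon map fail
   conservatively.

### Generalized ESD test

For a vector of $n$ values and an outlier allowance $k_{\max}$, step
$i = 1..k_{\max}$ computes $R_i = \max_j |x_j - \bar x| / s$ over the
remaining points, removes the argmax (ties broken by lowest index), and
compares against

$$\lambda_i = \frac{(n-i)\, t_{p,\,n-i-1}}{\sqrt{(n-i-1+t^2_{p,\,n-i-1})(n-i+1)}},
\qquad p = 1 - \frac{\alpha}{2(n-i+1)}.$$

The declared outlier count is the largest $i$ with $R_i > \lambda_i$.
If the remaining points become constant the remaining steps record
$R_i = 0$. Defaults: $\alpha = 0.05$, $k_{\max} = \max(5, \lceil 0.05
n\rceil)$, and a log10 transform of fractional abundances before testing
(abundances are approximately log-normal; the choice of scale is
exposed). The TF population excludes known NAPs. Candidates are appended
one at a time ("leave-one-in"), so an extreme candidate cannot inflate
the spread used to judge another; extreme values already inside the TF
population (e.g. DNA-binding co-candidates) are handled by the iterative
removal itself, which is the point of the generalized test. A pooled
mode (all candidates appended at once) is also provided.

### Isoelectric point

Candidate pI is the pH at which the Henderson–Hasselbalch net charge of
the sequence is zero, found by bisection on [0, 14] (the charge is
monotone decreasing in pH). The EMBOSS pKa set is the default and the
table is configurable, since published pI values vary with the pKa set
used.

## NAP family survey

Presence/absence of the previously characterized families (Alba, CC1,
Cren7, Histone, HU, MC1, Sul7) is called from hmmsearch hit tables
produced with model gathering thresholds, so any hit to a family model
counts as presence; an optional stricter e-value cutoff can be layered
on. CC1 lacks a curated model and is detected via jackhmmer with an
e-value threshold (default 1e-5). The shipped family→model lists are
curated, editable configuration, not a canonical registry. Co-occurrence
counts genomes containing both families; the diagonal is per-family
prevalence.

## Nucleoid enrichment

Replicated log2 intensities from a nucleoid sucrose-gradient fraction
are compared against the top (soluble) fraction as control; positive
log2 fold change means nucleoid-enriched. Missing values are imputed per
sample from $\mathcal N(m - 1.8 s,\ (0.3 s)^2)$ where $m, s$ are the
observed mean and SD of that sample — the standard left-censored
convention for label-free data; shift and width are parameters.
Per-protein pooled variances $s_g^2$ (residual df $d_g$) are moderated
with an empirical-Bayes prior $(d_0, s_0^2)$ fitted by moment-matching
the log sample variances to a scaled-F marginal (solving
$\psi'(d_0/2) = \mathrm{Var}[\log s_g^2] - \psi'(d_g/2)$; $d_0 = \infty$
when the observed spread does not exceed chi-square sampling noise). The
moderated statistic uses $\tilde s^2 = (d_0 s_0^2 + d_g s_g^2)/(d_0 +
d_g)$ with $d_0 + d_g$ degrees of freedom; $d_0 = 0$ recovers the
ordinary two-sample t exactly. Benjamini–Hochberg q-values are computed
across proteins.

Whether DNA-binding-domain proteins are collectively enriched is tested
by a two-sided rank-sum test on log2 fold changes, with exhaustive
enumeration of assignments when both groups have at most 10 members and
the tie-corrected normal approximation otherwise.

## Comparative statistics

* **Spearman correlation** uses average ranks for ties, an exact
  permutation p-value for n ≤ 9 and the t approximation otherwise.
* **OLS prediction** for a new species reports the point estimate with
  both the 95% CI of the mean response and the 95% prediction interval
  for a new observation; published analyses of this kind do not always
  say which is meant, so both are labelled and returned.
* **PGLS (Brownian motion)** estimates
  $\hat\beta = (X^\top C^{-1}X)^{-1}X^\top C^{-1}y$ with
  $C_{ij}$ the shared root-to-tip path length. $\sigma^2$ is the ML
  rate; the slope p-value is a t test on $n-2$ df with the unbiased
  residual variance. Variables are natural-log transformed by default in
  the workflow (non-positive values are excluded with a warning; the
  generator's investment floor keeps values positive). Optional
  parametric bootstrap re-simulates residuals as
  $\mathcal N(0, \sigma^2 C)$ and reports a percentile CI; the default
  1,000 replicates (configurable up to 10,000) keeps desk-scale runtime.
  On a star tree the estimator reduces exactly to OLS, and rescaling all
  branch lengths leaves $\hat\beta$ unchanged.
* **Domain screen**: every domain class's aggregate abundance (a protein
  contributes its full fraction to each of its classes — no splitting)
  is correlated with OGT; classes quantified in fewer than `min_species`
  species (default 10) are dropped, and the NAP aggregate's rank by
  descending rho is reported.
* **RBH correlation**: Spearman rho over log10 fractional abundances of
  reciprocal-best-hit pairs detected in both species.
* **Genes per transcription unit**: arithmetic mean operon size.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
with ground truth recorded for every stage:

* **Tree**: Yule (pure-birth) tree, unit depth, ultrametric, with a
  final waiting interval after the last speciation so terminal branches
  are strictly positive (a degenerate cherry would make the BM
  covariance singular). 19 species by default.
* **OGT**: Brownian motion from a root at 70 °C with rate 3600 °C² per
  unit depth, reflected into [24, 98] °C. The rate is chosen so tip OGTs
  span the mesophile-to-hyperthermophile range of real archaeal panels
  (realized span ≈ 60–70 °C); much smaller rates leave every species
  near the root value, which is not the study design the comparative
  analysis addresses.
* **Investment signal**: each species' summed NAP percent is
  $\beta_0 + \beta_1\,\mathrm{OGT} + \varepsilon$, with
  $\beta_0 = -2.0\%$, $\beta_1 = 0.075\,\%/°C$,
  $\varepsilon \sim \mathcal N(0, 0.6^2)$, truncated below at 0.01%.
  These defaults put a 37 °C species at ≈0.75% and the hottest species
  at ≈5.4% — a calibration to the regime the method targets, not ground
  truth about any organism.
* **Proteomes**: 2,000 proteins; background abundances are
  log10-normal (SD 1.2), renormalized so all components sum to exactly
  100%. 1–3 true NAPs (60–120 aa, DNA-binding domain, single-gene
  operons) split the investment target with minimum share 0.15; when the
  target is below 0.1% a single NAP carries it, so no true NAP falls
  below the outlier-detectable range. Half the NAPs are labelled
  "known" and additionally hit a NAP family model. 100 TFs (5% of the
  proteome) have tightly distributed low abundances
  ($10^{\mathcal N(-2.7, 0.15^2)}$ percent — sequence-specific TFs are
  among the least abundant proteins), which fixes the ESD detection
  threshold near $10^{-2.2}\% \approx 0.006\%$, safely below the 0.01%
  NAP floor. Four decoys per species each fail exactly one filter
  (multi-gene operon; no DNA-binding evidence; 420 aa; TF-level
  abundance). Background DNA-binding scores are
  $\mathcal N(-2, 0.5)$, making a chance score > 0 (~3e-5 per protein)
  vanishingly unlikely to combine with the other three filters at study
  scale — so false discoveries are structural, not sampling accidents.
  Housekeeping references (20 tRNA-synthetase, 2+2 RNA-polymerase
  proteins) have fixed fractional abundances, emulating their low
  cross-species variability. Genome sizes are generated weakly
  negatively associated with OGT (the non-significant regime the
  comparative control reports); metadata records a predicted proteome
  ~43% larger than the detected one (coverage ≈ 0.7).
* **Enrichment**: per-cell log2 intensities are the protein's base
  abundance plus $\mathcal N(\mathrm{effect}, 0.5^2)$ for true NAPs in
  the nucleoid fraction (effect 2.5 log2) and $\mathcal N(0, 0.5^2)$
  otherwise, over 3 replicates per fraction; cells go missing
  preferentially at low abundance with overall rate 0.1.

The generator is a pure function of (params, seed), and every emitted
file round-trips through the IO layer.

**What passing tests do not show about real data.** The generator does
not simulate peptides or spectra, protein sequence evolution, horizontal
transfer, shared detection biases between species, membrane-protein
co-sedimentation in the nucleoid fraction, or correlated missingness
between fractions. Decoys fail single filters deterministically, so the
measured false-discovery proportion reflects the filter logic, not the
full ambiguity of real annotation. Recovery rates on synthetic studies
therefore validate the machinery, not the biological error rate.

## Numerical choices

* ESD argmax ties break to the lowest index (determinism); zero-variance
  remainders terminate outlier search.
* pI bisection to 1e-6 pH; non-standard residues are an error.
* BM covariance is Cholesky-factorized; a non-positive-definite matrix
  (duplicate tips, zero terminal branches) is an error naming the cause.
* Exact rank-sum enumeration uses midranks and a 1e-9 tolerance when
  comparing permuted rank sums to the observed one.
* Quantification readers parse floats with Python's correctly rounded
  parser so write-then-read reproduces intensities to full precision.
* Seeds: every stochastic routine takes an explicit seed or Generator;
  study-level seeding derives per-species streams via SeedSequence
  spawning.

## Problem sizes used in the shipped checks

Validation runs use 19-species studies with 2,000-protein proteomes,
1,000 random vectors for outlier-test oracle comparison, 2,000
simulations for interval calibration, 2,000-protein null matrices for
moderated-test calibration, 200 shuffle trials for the domain screen and
500 seeds for generator calibration. These sizes give Monte-Carlo errors
well inside the asserted tolerances.

## Known limitations

* The moderated-test prior fit uses log-variance moment matching; very
  small protein counts (< ~50) make $d_0$ unstable (it is then reported
  as fitted, and can be overridden).
* PGLS offers BM only as a first-class model; an OU-type alternative is
  not implemented.
* The exact Spearman permutation p is limited to n ≤ 9 (n! growth); the
  t approximation takes over beyond that.
* Operon-map absence demotes a protein to "not single-gene operon"
  rather than treating operon status as missing data.
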