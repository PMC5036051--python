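# Methods

## The model

For each panel gene *g*, tumour mRNA abundance is modelled as a linear
function of its own copy-number value (gene-level segmentation, 0 =
diploid), its promoter methylation beta value (in [0, 1]) and the mRNA of a
candidate pool of transcription factors:

```
y_g = b0 + b_c * CNA_g + b_m * DM_g + sum_k b_k * TF_k + eps
```

`b_c` and `b_m` estimate the cis contributions; the `b_k` capture trans
regulation.  The statistical problem is that the TF pool is large (hundreds
to a thousand candidates) and almost all `b_k` are zero.

## Stage by stage

**Differential expression.**  An empirical-Bayes moderated two-sample t:
per-gene pooled variances are shrunk toward a common scaled
inverse-chi-square prior whose scale and degrees of freedom are estimated by
method of moments on the marginal F distribution of the variance ratios
(numeric root solve; the estimate degenerates gracefully to no shrinkage at
`prior_df = 0` and to complete shrinkage when the observed dispersion is at
the sampling floor).  Two-sided p-values, BH step-up FDR, default threshold
0.05.  Expression is analysed on the scale provided; no internal transform.
The comparison is unpaired (sample pairing information is not modelled).

**Cis association.**  Spearman rho (midranks under ties, large-sample
p-value) of each DE gene's tumour mRNA with its own CNA or DM column; BH FDR
within each (layer, stratum).  Both FDR and raw p are emitted for both
layers.  Strata with fewer than `min_stratum_size` samples (default 10) are
skipped with a warning.  Top-k tables sort by |rho| descending for CNA and
rho ascending for DM (most negative first).  Secondary rank-sum/Fisher
comparisons of DM correlations between up- and down-regulated genes are
reported but feed nothing downstream.

**Constrained LASSO.**  Objective
`(1/2n)||y - b0 - X b||^2 + lambda * sum_{penalised j} |b_j|` with penalty
weight 0 on the CNA and DM columns and 1 on every TF column.  Solved by
cyclic coordinate descent on the Gram matrix with warm starts along a
descending lambda path; penalised columns are standardised to unit variance
internally for the penalty and coefficients are reported on the original
scale (the convention of the standard cross-validated-LASSO tooling, against
which the solver is cross-checked in the test suite to ~1e-6).  The active
working set is grown by explicit KKT checks (one BLAS gradient evaluation
per verification), and partial residual sums exploit sparsity of the
current iterate.  Convergence: maximum coordinate update < `tol` (default
1e-7 on the standardised scale) verified on a full pass.  Degenerate
(constant) columns stay at zero.  If the response gene is itself in the TF
list, it is removed from its own design.

**Lambda draws.**  `lambda_max` is the largest absolute correlation of a
standardised TF column with the residual of y on the forced-in block; the
path descends geometrically over 3 decades in 100 points (both config).
Each of the `runs` draws runs K-fold CV (default 10 folds, fold assignment
re-randomised per draw) over the shared path.  Numerical choices specific to
CV fits: a looser coordinate-update tolerance (1e-4) and a
deviance-plateau early stop along the path — both affect only fits used to
*pick* lambda, where the selected grid point is insensitive to
coefficient wiggle at that scale; final fits always use the tight tolerance.

**CV rule: 1-SE, not minimum.**  Each draw returns the largest lambda whose
mean CV MSE is within one standard error of the minimum (`lambda_rule:
"1se"`, with `"min"` available as a config switch).  This was a genuinely
open design point, and the package resolves it empirically: under the
minimum-MSE rule the handful of noise TFs with the largest chance
correlations are active at *every* drawn lambda, so their selection
frequency saturates exactly like the true regulators' and no frequency
cutoff can separate them (planted-truth precision is then structurally
capped near 0.5).  The stability-selection premise — noise churns across
lambda draws while signal persists — holds under the more conservative 1-SE
rule (observed on planted cohorts: true TFs at frequency = runs, noise at
<= 1-2).

**Frequency cutoff.**  Candidate cutoffs are 0 plus the distinct positive
observed frequencies (together these induce every model an integer cutoff
grid could; 0 is required because under stable selection all true TFs often
share the maximum frequency, and "frequency > cutoff" with only observed
candidates would then test nothing but the empty model).  For each
candidate, OLS of y on (1, CNA, DM, TFs above the cutoff) is fit on
`splits` random 2/3 training subsamples (default 100) and scored by test
MSE; the cutoff with minimal mean MSE wins, with ties (to numerical
precision) broken toward the larger, more parsimonious cutoff.  Cutoffs
whose model is wider than the training set are skipped with a warning.
Selection is strict: a TF is kept when its frequency exceeds the cutoff.

**Model comparison.**  Four OLS models per gene (DM; CNA; CNA+DM;
CNA+DM+selected TFs), refit on random 2/3 splits (default 100 repeats) and
scored on the held-out third by Spearman(pred, obs) and
`R^2 = 1 - SS_res/SS_tot` with SS_tot about the *test-set* mean, which makes
negative out-of-sample R^2 naturally attainable for models that do not
transfer.  All four models share the same seeded split sequence, so
comparisons are paired.  The summary table reports min/median/mean/max
across genes of the per-gene mean rho and R^2, as rounded percentages; raw
values are retained.

**Downstream.**  Regulators are ranked by number of predicted targets (ties
lexicographic).  A predicted (TF, target) pair is supported when the minimum
distance from the target TSS to any peak of that TF on the same chromosome
is <= `threshold_bp` (default 100 kb); the distance is 0 inside a peak and
otherwise to the nearest end of the interval (coordinates 0-based
half-open).  Strand is ignored; TSS positions are expected strand-resolved
upstream.  TFs without peak data are excluded from the support table
(mirroring availability constraints of public ChIP-Seq compendia); targets
without a TSS record count as unsupported, keeping denominators
conservative.

## The synthetic cohort generator

The generator draws data from the model above, with recorded ground truth:

- **CNA**: discrete states {-1, 0, +1} x `cna_scale` (probabilities
  `cna_state_probs`, default 0.2/0.6/0.2) plus N(0, 0.05) jitter — mimics
  gene-level segmentation values centred on the diploid state.
- **DM**: Beta(2, 5) per tumour sample per gene, hence in [0, 1]; normal
  tissue sits at the Beta mean.
- **TF expression**: unit-variance Gaussian; a configurable fraction
  (default 0.3) receives a tumour mean shift, so TFs are themselves
  differentially expressed.
- **Panel genes**: each gets `true_tfs_per_gene` regulators (default 5) with
  effect magnitudes uniform in `tf_effect_range` and random sign, plus a
  direct tumour shift for a `de_fraction` of genes (sign positive with
  probability 0.7, magnitude 1-3 x `tumour_shift_sd`).
- **Normals** are drawn from the same model with CNA fixed at 0, DM at its
  normal-tissue mean and no tumour shifts.
- **Geography** for the binding stage: one synthetic chromosome per 50
  genes, TSS spaced 1 Mb apart, so the 100 kb support rule is geometrically
  meaningful; peaks for supported pairs land within the threshold, the rest
  beyond it or on a decoy chromosome.

**Calibration.**  Defaults decompose a typical panel gene's tumour
expression variance as roughly 22% copy number, 3% promoter methylation,
49% transcription factors and 26% noise (`beta_cna = 1.5` over
Var(CNA) = 0.1025, `beta_dm = -1.0` over Var(Beta(2,5)) = 0.0255,
five TF effects of magnitude ~0.27-0.35, `noise_sd = 0.51`).  This is the
regime the inference stages are designed for: moderate positive cis CNA
correlations (median ~0.4), weak negative methylation correlations, and a
four-model comparison in which the TF block carries most of the explainable
signal.

**What the generator does not emulate** — and hence what passing tests do
not certify about real cohorts: realistic marginal distributions
(percentile-ranked RSEM expression, segmentation noise), batch and platform
effects, correlated TF programs (TFs are independent here, so collinearity
between candidate regulators is milder than in real expression data),
regulation of TFs by other TFs, miRNA effects, and subtype structure beyond
random labels (strata are exchangeable by construction, so stratified and
pooled analyses must agree up to Monte-Carlo error).

## Problem sizes and seeds

Desk-scale defaults used by the acceptance tests and `scripts/acceptance.py`:
50 panel genes, 150 TFs, 300 tumour / 100 normal samples, 5 true TFs per
gene, 25 lambda draws and 25 cutoff subsamples per gene, 50 model-comparison
repeats.  Every stage seed derives deterministically from one global seed
via `numpy.random.SeedSequence`; per-gene seeds hash the gene identifier, so
results do not depend on scheduling or worker count.

## Known limitations

- The moderated-t prior is fit by moments rather than profile likelihood;
  with very few genes the prior df estimate is noisy (it only rescales a
  screening statistic).
- Stability selection inherits LASSO's weaknesses under strong predictor
  collinearity: highly correlated TFs can share or swap selection.
- The frequency-cutoff search optimises prediction MSE, which is only a
  proxy for support recovery; with weak signals it errs toward smaller
  cutoffs (larger selected sets).
- Out-of-sample R^2 is downward-biased for wide models at small test sizes;
  comparisons across models of similar size are unaffected.
- Binding support treats any peak within the distance threshold as evidence;
  it does not model peak strength, summit position (a summit mode is
  available) or cell-type specificity.
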