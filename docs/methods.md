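# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic validation does and does not establish.

## Count model and normalization

Counts are modeled as negative binomial with Var(K) = μ + φμ² (φ the
dispersion). Size factors are median-of-ratios: with g_i the geometric
mean of gene i across samples, s_j = median over "usable" genes (no zero
anywhere) of K_ij/g_i. If no gene is zero-free the operation errors
rather than silently switching reference — sparse matrices should be
handled upstream (filtering) or via the projection path, whose per-gene
pseudo-reference tolerates zeros gene-wise.

Gene dispersions are method-of-moments on normalized counts
φ_i = max(0, (v_i − m_i)/m_i²), summarized by the parametric trend
φ(μ) = a₀ + a₁/μ. The trend is fit by iteratively reweighted least
squares with Tukey bisquare weights on MAD-scaled residuals and a
non-negativity constraint on (a₀, a₁) (NNLS inner step, 10 reweighting
iterations). This deliberately replaces empirical-Bayes shrinkage: the
VST depends only on the trend, and the simpler estimator is directly
testable against simulations with known φ. "Dispersion function" here
means the (a₀, a₁) trend.

The VST is the closed-form stabilizer of Var(μ) = μ(1+a₁) + a₀μ²:

    h(q) = log2( (1 + a₁ + 2a₀q + 2√(a₀q(1 + a₁ + a₀q))) / (4a₀) )

It is strictly increasing, h(0) = log2((1+a₁)/(4a₀)) is finite, and
h(q) − log2(q) converges to a constant, so large counts live on the
familiar log2 scale. Tests verify h against numerical quadrature of
∫dμ/√(Var(μ)) to 1e-6 up to the affine calibration. If a₀ = 0 (no
asymptotic dispersion) the transform degenerates to the square-root
stabilizer 2√(q/(1+a₁)); this branch is not log2-scaled and only arises
for essentially Poisson data.

Train/apply separation is strict and per-sample: a new sample's size
factor is the median of K_i/ref_i over the training pseudo-reference
genes positive in that sample, and the training (a₀, a₁) are applied
unchanged. The output for a sample therefore never depends on which
other samples share the batch, and projecting a training sample
reproduces its training transform exactly. The VST is "blind": no
design information enters the dispersion trend.

## Differential abundance

Per gene, the two-group model is mean_ij = s_j·exp(β₀ + β₁x_j) with
fixed dispersion φ_i set to max(gene-wise estimate, trend value) —
flooring at the trend guards against underestimated dispersions
inflating the Wald statistic. The 2-parameter GLM is solved by IRLS
vectorized across all genes (closed-form 2×2 weighted normal equations;
working weights μ/(1+φμ); η clipped at ±30; convergence at 1e-8 on the
coefficients, 100 iterations max). log2FC = β₁/ln2, Wald p from the
standard normal. All-zero and non-converging genes (e.g. one group all
zero, where the MLE diverges) are reported NA and excluded from the BH
family. BH is the standard step-up, delegated to statsmodels with NA
handling. On null NB simulations the observed type-I rate at p<0.05 is
mildly conservative (≈0.035–0.05), consistent with the dispersion
flooring.

Per-gene ROC-AUC is the midrank U statistic on VST values, oriented as
P(group-B value > group-A value) + ½P(tie); tests pin it to all-pairs
enumeration at 1e-12. Gene-set overlaps use exclusive (UpSet-style)
intersection counts.

## Panels

The filter cascade keeps genes with q < q_max, base mean > min, |log2FC|
> min and — two-sided — max(AUC, 1−AUC) > min, so strong down-markers
survive; optional top-N truncation orders by symmetric AUC (ties by
ascending q, then gene id). Presets: `misc_kd` (q<0.01, bm>100,
AUC>0.65, |lfc|>0.25), `multiclass_pairwise` (q<0.05, bm>50, |lfc|>1,
top 150 by AUC), `covid_vs_other_viral` (misc_kd thresholds + top 150 by
AUC). The multiclass default of 150 is configurable (a panel of 100 is
a supported variant).

## Classifiers

The penalized logistic objective is the elastic-net GLM form

    −(1/n)Σ loglik + λ[(1−α)/2‖β‖² + α‖β‖₁],  intercept unpenalized,

solved by accelerated proximal gradient (FISTA) with warm starts along a
100-point log-spaced λ path from λ_max (smallest all-zero penalty) down
to λ_max·10⁻⁴. Path points used only for cross-validation scoring are
solved to moderate precision (parameter change < 3e-5); the returned
model is polished to 1e-8. The solver is cross-checked in tests against
an independent solver at 1e-6. Features are standardized on the training
set (stored means/sds applied downstream). λ maximizes mean 5-fold
stratified CV ROC-AUC; ties resolve to the largest (sparsest) λ, except
that an all-zero refit is abandoned in favor of the next λ inside the
CV tie — a fully shrunk model is dominated by an equally-scoring model
that retains features.

Youden thresholds search midpoints of consecutive sorted unique training
scores (plus ±∞) for max J = sensitivity + specificity − 1, ties toward
the lowest threshold; a sample is called positive at score ≥ threshold.

The bake-off harness tunes each algorithm on training data only (5-fold
CV grid search, ROC-AUC) and ranks tuned models by validation AUC (ties:
fewer features, then name order). The default set is lasso-logistic,
ridge-logistic, random forest, linear SVM, k-NN and Gaussian naive
Bayes; the harness, not the zoo, is the method, and the registry accepts
extensions behind the same contract.

The one-vs-one stack trains one LASSO model per unordered class pair on
that pair's training samples only (per-pair gene panels), scores *all*
training samples with all C(k,2) models ("classification score" = the
predicted probability of the lexicographically larger class — the only
score shared across model families), and fits a 500-tree random forest
(√p features per split, seeded) on the score matrix. Prediction is the
argmax class probability (ties resolve to lexicographic order); Youden
thresholds play no role in the multiclass path. The full probability
vector is kept for reporting, with a "borderline" flag when the top two
probabilities differ by less than 0.10 (configurable; an invented
convention).

Stratified partitioning allocates samples within each stratum cell
(group × hospital × subgroup) by seeded shuffle and largest-remainder
rounding; cells smaller than the number of sets collapse to group-only
strata with a logged warning. Held-out labels are read only at final
evaluation; an audit test poisons test-set labels under a fixed split
and asserts bit-identical fitted models.

## Deconvolution and reports

Fractions solve θ = argmin‖x − Rᵀθ‖², θ ≥ 0 (scipy NNLS), with x the
sample's relative abundance over the genes shared with the reference and
R the row-renormalized reference; θ is renormalized to sum to 1. The
estimator is deterministic, exact on noiseless mixtures, and invariant
to per-sample count rescaling; a rank-deficient reference on the shared
genes is rejected as non-identifiable. All shared genes are used (no
marker pre-selection). This is a deliberate methodological substitution
for Bayesian deconvolution with the same input/output contract; it
provides no posterior uncertainty.

Group contrasts use the two-sided Wilcoxon rank-sum test per cell type
(exact enumeration when both groups ≤ 10 and untied, otherwise the
normal approximation with tie and continuity correction) with BH across
cell types, reporting group medians of min-max scaled fractions (the 0–1
scaling is computed over the whole contrasted cohort). The ALT contrast
uses normal < 40 IU/L vs high > 100 IU/L, excluding the 40–100 band.

Organ z-scores use *unscaled* fractions: organ fraction = sum of mapped
cell types (endothelium→endothelial cell; heart→cardiac muscle cell;
liver→hepatocyte; lung→club cell + type I pneumocyte; neuronal→Schwann
cell), standardized by the healthy-donor mean and sd (n−1 denominator;
sd floored at 1e-8 with a low-confidence flag). Z-scoring already
standardizes, so cohort min-max scaling is reserved for plotting.

## Synthetic cohorts

Each sample's expected expression is a Dirichlet mixture of cell-type
reference profiles (rows normalized to 1, disjoint elevated marker
blocks so the reference has full rank). Disease groups carry disjoint
planted signatures — per-gene log2 effects centered on the configured
size with proportional jitter, so a zero effect is exactly null — plus
an optional shared "inflammation" signature common to all disease
groups. Counts are gamma-Poisson with log-normal per-gene dispersions
around the configured mean and uniform library sizes. QC metrics are
drawn from passing ranges except for a planted fraction of samples that
each fail exactly one rule. ALT is affine in the true hepatocyte
fraction, the cardiac flag thresholds the cardiac-muscle fraction at a
cohort quantile with a 5% mislabel rate, and a severity ordinal follows
the lung fractions; hospital labels are independent of the counts (no
batch effect is simulated).

Defaults mirror the intended cohort scale: six groups totalling 370
samples (KD 101, MIS-C 97, viral 80, bacterial 30, healthy 40, other
22), 5,000 genes, signature size 60 at log2 effect 1.5 with a
100-gene shared signature, dispersion scale 0.3 (heavily overdispersed,
as plasma cfRNA is), libraries 100k–600k counts straddling the 75k QC
floor via planted low-depth failures, and 5% planted QC failures.
Validation scenarios use 2,000 genes and group sizes of 30–100 per
group so the suite and the acceptance script run in minutes on one CPU.

Null controls are defined as fully exchangeable groups: zero planted
effects *and* identical mixture concentrations, since composition
differences are themselves real signal. Permutation controls shuffle
group labels of a signal cohort.

## What the synthetic validation does not show

The generator reproduces the statistical structure the pipeline assumes
(NB counts, mixture-of-cell-types means, planted effects, covariate
couplings), not real cfRNA biology: no batch effects, no
ribosomal/degradation artifacts beyond the drawn QC metrics, no
correlation structure between genes beyond the shared mixture, and
clean, well-separated planted signatures. Passing tests establish
correctness and calibration of the machinery, and that effect sizes of
the planted magnitude are recoverable — not that real cohorts of this
size yield the same accuracies. Classifier metrics on small held-out
sets (20–45 samples) carry sampling noise of several points.

## Known limitations

- Wald tests with moderated dispersions are mildly conservative; no
  independent filtering or LFC shrinkage is applied.
- The deconvolution provides point estimates only and assumes the
  reference spans the true cell types.
- The a₀ = 0 VST branch is square-root-scaled, not log2-scaled.
- rRNA contamination is recorded but has no filter rule.
- Multi-factor DE designs, covariate adjustment and likelihood-ratio
  tests are out of scope.
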