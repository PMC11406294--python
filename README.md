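# cfrna

Plasma cell-free RNA (cfRNA) diagnostics for pediatric inflammatory
syndromes — a tested, reusable implementation of the full analysis
pipeline: sample QC → normalization → differential abundance → gene-panel
selection → binary and one-vs-one stacked multiclass classification →
cell-type-of-origin deconvolution → per-patient diagnostic / organ-injury
reports, exercised end to end on a seeded synthetic cfRNA cohort
generator with ground truth.

## The problem

Kawasaki disease (KD), multisystem inflammatory syndrome in children
(MIS-C), and viral and bacterial infections present with overlapping
clinical signs, and misdiagnosis carries real cost (e.g. delayed IVIG in
KD). cfRNA in plasma is released by dead and dying cells from blood
*and* solid tissues, so a single assay can carry both a diagnostic host
response signature and a readout of organ-specific injury. This package
implements that analysis for gene-by-sample count matrices plus sample
metadata; it ships a synthetic cohort generator so every stage can be
validated against known truth.

## The methods in brief

- **QC** — a sample fails if intron/exon ratio > 3, total feature counts
  < 75,000, or 5′–3′ coverage bias > 2 (strict inequalities; boundary
  values pass).
- **Normalization** — median-of-ratios size factors
  `s_j = median_i K_ij / g_i`; gene-wise NB dispersions (Var = μ + φμ²)
  by method of moments with a robust parametric trend φ(μ) = a₀ + a₁/μ;
  the closed-form variance-stabilizing transform (VST)
  `h(q) = log2((1 + a₁ + 2a₀q + 2√(a₀q(1 + a₁ + a₀q))) / 4a₀)`.
  Held-out samples are projected one at a time against the frozen
  training pseudo-reference and trend — never refit.
- **Differential abundance** — per-gene NB Wald test with a log link and
  fixed (trend-moderated) dispersion, fit by IRLS vectorized across
  genes; BH adjustment per comparison; per-gene ROC-AUC on VST values.
- **Panels** — filter cascades (q, base mean, symmetric gene AUC,
  |log2FC|, optional top-N by AUC) with shipped presets `misc_kd`,
  `multiclass_pairwise`, `covid_vs_other_viral`.
- **Classification** — elastic-net/LASSO logistic regression along a
  100-point λ path chosen by 5-fold CV ROC-AUC, Youden-J decision
  thresholds from training scores, a model bake-off harness ranked on a
  validation set, and a one-vs-one stack: C(k,2) pairwise LASSO models
  score every sample and a 500-tree random forest maps the score matrix
  to class probabilities.
- **Deconvolution** — per-sample non-negative least squares of relative
  abundance against a row-normalized cell-type reference, renormalized
  to fractions; Wilcoxon/BH group contrasts of min-max scaled fractions.
- **Reports** — organ z-scores `(organ fraction − healthy mean)/healthy
  sd` against healthy donors (endothelium, heart, liver, lung, neuronal)
  plus ranked class probabilities with a borderline flag.

## Worked example

```python
from cfrna import default_config, make_reference, simulate_cohort
from cfrna.pipeline import run_report_pipeline

cfg = default_config(
    group_sizes={"KD": 40, "MIS-C": 40, "viral": 40, "bacterial": 30,
                 "healthy": 30, "other": 20},
    n_genes=2000, seed=3)
ref = make_reference(cfg.n_cell_types, cfg.n_genes, seed=3)
cohort = simulate_cohort(cfg, ref)

result = run_report_pipeline(cohort.counts, cohort.metadata, ref, seed=3)
mc = result.multiclass
print(f"train acc {mc.train_accuracy:.2f}  test acc {mc.test_accuracy:.2f}")
print(f"reports written: {len(result.reports)}")
rep = next(iter(result.reports.values()))
print(rep.ranked_diagnoses[0], round(max(rep.class_probabilities.values()), 3))
```

prints

```
train acc 1.00  test acc 1.00
reports written: 44
KD 0.992
```

i.e. on a 200-sample synthetic cohort the stacked one-vs-one classifier
is perfect on training data and (here) on the held-out test set, 44
passing test samples each get a report, and the first report calls
"KD" with probability 0.992. Each report also carries five organ
z-scores; healthy donors' own z-scores have mean 0 and sd 1 by
construction, so values beyond ±2 indicate organ-specific cfRNA excess.

A CLI mirrors the library: `cfrna simulate|qc|normalize|de|select|
deconvolve|cto-compare|report|run` (see `cfrna --help`).

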