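# monomethir

Analysis of monocyte DNA methylation in insulin resistance, built around
Illumina 450K-style β values (per-CpG methylation fractions in [0, 1]).
The package is for epigenomics analysts who want the full chain — from a
normalized β matrix to biomarker candidates — as a tested, reusable Python
library rather than a one-off script stack.

## What it computes

Given a probes × samples β matrix, sample metadata with HOMA-IR (the
homeostatic model assessment of insulin resistance; glucose·insulin/405,
with ≥ 2.0 defining the insulin-resistant group), probe annotation, and
reference methylomes, the pipeline:

1. **Calls differentially methylated loci (DMLs).**  The statistic is a
   moderated two-sample t: per-probe pooled variances s² are shrunk toward
   an empirical-Bayes prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²)
   moment-matched to a scaled inverse-χ² across probes.  Significance comes
   from a label-permutation null pooled across probes,
   p = (1 + #{null |t| ≥ |t_obs|}) / (1 + B·P), and a DML must additionally
   satisfy the biological effect filter |δ| ≥ 0.10, where δ = mean β(IR) −
   mean β(IS).
2. **Filters probe artifacts**: trimodal β patterns (~0 / 0.5 / 1) that are
   indistinguishable from SNP genotypes, manifest known-SNP probes, and
   overlap with a confounder DML list (e.g. an infection-status contrast).
3. **Scores cell identity/purity**: a CpG panel separating two reference
   cell populations (|δ| > 0.30, permutation-significant) plus the Spearman
   correlation of each sample against the target cell-type profile.
4. **Classifies progenitor-state maintenance**: each DML's group mean vs the
   hematopoietic stem cell (HSC) mean — maintained when |group − HSC| < 0.10,
   hyper-/hypomethylated at or beyond the boundary — with a PCA of DML β
   values to show which group sits nearer the progenitor state.
5. **Derives biomarkers**: rank-sum candidate screen (BH-adjusted p < 0.01),
   simple and forward-AIC stepwise logistic models for the IR outcome, the
   per-CpG decision threshold β\* = −b₀/b₁ (fitted probability 0.5), and
   AUC ranking against clinical covariate models.

A synthetic-cohort generator (`simulate_cohort`, `simulate_references`)
produces Beta-distributed β values with planted effects, SNP-like probes,
cell-type markers and HSC maintenance classes, so every stage is testable
offline with known ground truth.

## Worked example

`examples/` holds one short script per capability.  The end-to-end run
(`python examples/07_full_pipeline.py`) writes a complete demo study to disk
and executes the pipeline on it:

```
load                 n_probes=2000, n_samples=37, n_is=23, n_ir=14
differential_test    n_tested=2000, n_p_significant=222, n_delta_pass=122
confounder_overlap   n_in=122, n_overlap=3, overlap_pct=2, n_out=119
snp_filter           n_in=119, n_pattern=3, n_known=2, n_out=114
call_dmls            ... n_dml=114, pct_hypo_ir=50.0
identity_qc          n_panel=150, mean_purity=0.983, group_diff_p=0.3721
hsc_maintenance      n_dml=114, maintained_ir=44, maintained_is=39, maintained_both=17, ...
pca                  pc1_var=0.5503, pc2_var=0.0661
prediction           n_candidates=114, n_models=10, best_model=cg00000121, best_auc=0.9752
enrichment           n_categories=13, n_significant=2
clustering           two_cluster_purity=1.0
```

Reading the counts: of 2000 probes, 222 pass the permutation test and 122
also pass the 10% effect filter; 3 are subtracted as confounder overlap and
5 more carry SNP flags, leaving 114 DMLs (the generator planted 120).
Purity 0.983 says every sample's methylation ranks match the monocyte
reference profile; `group_diff_p` 0.37 says cell composition does not differ
between groups, so the DML contrast is not a composition artifact.  The
maintenance stage counts DMLs whose methylation stayed within 0.10 of the
HSC state per group, and the best single-CpG logistic model reaches AUC
0.975 — above the clinical covariate models on this cohort, where the
planted signal lives in the methylome.

The same workflow is available from the shell:

```sh
monomethir simulate study --seed 42 --out study/
monomethir run --config study/config.yaml --out results/
```

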