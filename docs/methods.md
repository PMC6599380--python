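# Methods

## Data model

All measurements are Illumina 450K-style β values: per-CpG methylation
fractions in [0, 1] (methylated / total fluorescence).  The pipeline starts
from an already-normalized probes × samples matrix; IDAT preprocessing and
normalization are upstream concerns and out of scope.  Missing cells are
permitted and excluded probewise.  Samples are stratified by HOMA-IR
(fasting glucose [mg/dL] × fasting insulin [µU/mL] / 405; the divisor is
switchable to 22.5 for SI-unit glucose): insulin-resistant (IR) at
HOMA-IR ≥ 2.0, insulin-sensitive (IS) below.

## Differential methylation test

β values are bounded and heteroscedastic — their variance shrinks toward
the 0/1 boundaries — so the test avoids parametric nulls entirely:

1. **Group statistics.**  Per probe: group means, δ = mean(IR) − mean(IS),
   pooled variance s² with d = n₁ + n₂ − 2 degrees of freedom (adjusted for
   missing values; a probe with < 2 usable values in a group is dropped and
   logged).
2. **Variance moderation.**  An empirical-Bayes prior s² ~ s₀²·d₀/χ²(d₀) is
   moment-matched on the log variances: the corrected values
   e = log s² − ψ(d/2) + log(d/2) have mean log s₀² − ψ(d₀/2) + log(d₀/2)
   and excess variance ψ′(d₀/2) beyond the sampling term ψ′(d/2); inverting
   the trigamma function gives d₀ (Newton iteration, 50 steps, relative
   tolerance 1e-10).  The moderated statistic is
   t = δ / √(s̃²(1/n₁ + 1/n₂)) with s̃² = (d₀s₀² + d·s²)/(d₀ + d).
   Degenerate branch: when the observed spread of log variances does not
   exceed the sampling term, d₀ is capped at 1e6 and s₀² is set to the plain
   mean of s² (no log-scale bias correction), so that the moderated t
   collapses *exactly* to the ordinary pooled t — the cap marks "no evidence
   of variance heterogeneity", and in that limit moderation should change
   nothing.
3. **Permutation null.**  For each of B label permutations (default
   B = 1000; exhaustive enumeration of all label arrangements for ≤ 10
   samples) the entire chain — group stats, prior estimation, moderated t —
   is recomputed, which preserves exchangeability.  The prior is
   re-estimated within each permutation by default; a config switch reuses
   the observed-data prior for speed, and a "none" mode gives the plain
   pooled t.  The default null pools all permuted |t| across probes,
   giving p-value resolution ≈ 1/(B·P) instead of 1/B:
   p = (1 + #{null ≥ |t_obs|}) / (1 + B·P), with an add-one correction so
   p > 0; a per-probe mode (denominator 1 + B) is retained for diagnostics.
   In exhaustive mode the observed arrangement is one of the enumerated
   ones and is counted in the null.  Exceedances are counted with an
   absolute tolerance of 1e-9 on |t| so that arrangements that tie the
   observed statistic analytically (notably the complement arrangement for
   equal group sizes) count as ties despite last-ulp float noise; the
   tolerance only ever makes p larger.
4. **FDR.**  q(τ) = (mean permuted exceedances of τ per arrangement) /
   (observed exceedances of τ), evaluated at each observed |t|, monotonized
   from the largest statistic down and clipped to [0, 1].
5. **Calling.**  A DML requires p < 0.05 *and* |δ| ≥ 0.10 *and* no
   exclusion flag.  The effect boundary is inclusive (a probe at exactly
   |δ| = 0.10 passes): the analysis elsewhere states the filter as
   δ ≥ |0.10|, and the inclusive reading is the self-consistent one.
   Direction is summarized as the percentage of DMLs with δ < 0
   (hypomethylated in IR), rounded to one decimal.

Whether the significance gate should be pointwise p or an FDR-adjusted
quantity is genuinely open at the ~10⁴-probe scale this runs at; the
default is pointwise p with q reported alongside in every record.

## Probe exclusion filters

Three independent boolean flags (idempotent, order-free):

* **SNP pattern.**  Samples are assigned to the nearest of {0, 0.5, 1} when
  within tol = 0.12; a probe is flagged when ≥ 80% of samples are assigned
  and ≥ 2 distinct modes are occupied.  The two-mode minimum spares
  constitutively hemimethylated loci (all samples near 0.5).  The defaults
  are declared heuristics — a reproducible surrogate for manual review of
  trimodal distributions — and are exposed in the pipeline config.  Rows
  with < 6 usable values return False with a log note.  The rule is
  invariant to sample order and to the reflection β → 1 − β.
* **Known SNP.**  Direct pass-through of the manifest's known-SNP column.
* **Confounder overlap.**  Set subtraction of an externally derived DML
  list (e.g. a serostatus contrast), reporting the overlap count and its
  percentage of the primary list (nearest whole percent).

## Cell identity

A reference panel is built by running the same permutation test between two
reference sample sets and keeping probes at p < 0.05 with |δ| strictly
greater than the panel threshold (0.30 for the monocyte-vs-PBMC panel;
0.10 for finer subset panels).  Panel profiles are arithmetic means across
reference samples (median optional).  Purity is the Spearman correlation
between a sample and the target profile at panel probes — rank-based, hence
invariant to monotone distortions of a sample's values; Pearson is
available behind a flag but Spearman is the default used everywhere, since
every association in the pipeline is rank-based.  Scores are refused below
20 usable panel probes.  Group comparisons of scores use Mann-Whitney.

## HSC maintenance

Each DML's group mean is compared with the HSC mean profile (the mean of
the HSC reference samples; with reference cohorts of n ≈ 3 a per-sample
treatment would add noise without information).  Classes:
maintained ⇔ |group − HSC| < 0.10; δ ≥ 0.10 hyper; δ ≤ −0.10 hypo.  The
boundary is assigned to the divergent classes (maintenance is the strict
interior of the band), with a 1e-9 tolerance so that means printed to two
decimals classify by their analytic difference rather than float
representation error.  The PCA of DML β values is computed on centered,
unscaled data (β is already on a common scale) via SVD, with a
deterministic sign convention: each component's largest-magnitude probe
loading is made positive.

## Biomarker models

Candidates are DMLs passing a Wilcoxon rank-sum screen at BH-adjusted
p < 0.01 (a threshold ≥ 1 disables the screen).  Logistic models are fit by
maximum likelihood; on perfect separation or a divergent MLE the model is
refit with a weak L2 penalty (inverse strength C = 25) and flagged — the
penalty is deliberately weak because it only needs to keep the estimate
finite, and a strong one drags the probability-0.5 point outside the
observed feature range.  At 37-sample scale separation is routine, so the
fallback is part of the method, not an error path.  Stepwise selection is
greedy forward by AIC (criterion and direction are not externally
prescribed; forward-AIC is the conservative choice at small n and an exact
collinear duplicate can never enter, since it raises AIC by 2 at equal
likelihood).  For a single-feature model the β cutoff is −b₀/b₁, the value
at fitted probability 0.5; the IR side follows the coefficient sign and a
sample exactly at the cutoff is called IS.  Accuracies are per-class
fractions (correct IR / n_IR, correct IS / n_IS).  AUC is in-sample from
fitted probabilities, matching how such small-cohort models are usually
reported; cross-validation is available but changes the question being
asked.  Model comparison ranks by AUC with ties broken by fewer features
and refuses models fit on different sample sets.

## Cohort statistics

Mann-Whitney U is exact (scipy enumeration) for combined n ≤ 12 without
ties, and a tie-corrected normal approximation otherwise.  Genomic-context
enrichment is a two-cell χ² goodness of fit per category (category vs sum
of all others, 1 df) with expected counts from array-wide proportions ×
n_DML, Bonferroni-corrected over the tested categories of the family;
categories with expected < 1 are skipped with a warning.  The background
universe is the analysis's retained probe set (the matrix the DMLs came
from), not the full manifest.  Hierarchical clustering uses Manhattan (L1)
distance with complete linkage; columns are processed in sorted sample-id
order so ties break deterministically.  The power calculation finds the
smallest per-group n for a two-sided two-sample t test by noncentral-t
iteration; at δ = 0.10, sd = 0.08, α = 0.05 the achieved power is 0.796 at
n = 11 and 0.833 at n = 12, so the smallest n meeting 0.80 is 12.
Gene-set over-representation uses Fisher's exact test against a
user-supplied background and set collection (no web services).

## Synthetic data generator

The generator defines the conditions every test and the acceptance script
run under:

* **Cohort**: 23 IS vs 14 IR samples, 5000 probes, 200 planted DMLs at
  δ = 0.15 (sign random per probe), 1% SNP-like probes.  Null probe means
  come from the bimodal mixture 0.45·Beta(0.5, 5) + 0.45·Beta(5, 0.5) +
  0.10·U(0.2, 0.8), mimicking the mostly un/fully-methylated methylome with
  a midrange minority.  Per-sample values are Beta(µκ, (1−µ)κ) with a
  common concentration κ = 50, which reproduces β heteroscedasticity
  (variance µ(1−µ)/(κ+1), shrinking at the boundaries); per-probe variance
  magnitudes are not externally fixed, so κ is a modeling default exposed
  as a parameter.  Planted base means are drawn U(0.2, 0.8) so a ±δ shift
  stays inside (0.01, 0.99).  SNP-like probes draw per-sample genotypes at
  Hardy–Weinberg frequencies (allele frequency U(0.2, 0.8)) over modes
  {0.03, 0.5, 0.97} with tight Beta noise (κ = 800).  HOMA-IR values are
  generated to stratify back into the group labels exactly, with glucose
  U(80, 110) mg/dL and insulin back-computed.  The synthetic manifest draws
  gene-region and island-relation categories from array-like background
  proportions, with planted DMLs body/shore-skewed so the enrichment stage
  has signal.
* **References**: per-type marker probes where that type's mean profile
  differs from all others by ≥ the marker δ (≥ 0.10 enforced), identical
  elsewhere; reference samples add Beta noise at κ = 200 (sorted-cell
  references are cleaner than cohort samples).  When anchored to a cohort,
  the first type's profile equals the cohort baseline and markers avoid
  planted/SNP probes, so the cohort emulates enriched cells of that type.
* **HSC maintenance planting** places the HSC profile relative to the
  cohort's *realized* group means — maintained-in-IR probes get the IR
  mean, maintained-in-IS the IS mean, maintained-in-both the midpoint
  (feasible while |δ̂| < 0.20) — so the downstream classifier reproduces the
  planted totals deterministically rather than within sampling noise.
  Probes diverging from both groups sit 0.15 beyond one group, with the
  side alternating so these probes do not systematically pull the HSC
  profile toward either group.
* **Determinism**: every generator takes a mandatory seed and one
  `numpy.random.Generator`; identical seeds give bit-identical outputs.

What the generator does *not* emulate: spatial correlation between
neighboring probes, chip/batch effects, Infinium type-I/II chemistry
differences, and cell-composition gradients within a group.  Passing tests
therefore demonstrate the statistical machinery under the stated noise
model, not robustness to those real-data artifacts.

## Problem sizes

The shipped tests and the acceptance script run the permutation test at
B = 200 on 5000 × 37 matrices and the demo pipeline at 2000 probes with
B = 200 — sizes chosen so the planted effects are comfortably inside the
detectable regime while the whole suite stays interactive.  The vectorized
permutation engine (three matrix-vector products per arrangement) handles
450K-scale matrices with the default B = 1000 as well; runtime scales
linearly in B × probes.

## Known limitations

* The permutation gate is pointwise p < 0.05 by default; at full array
  scale users should gate on `q_perm` instead (reported in every record).
* Covariate-adjusted differential testing (linear models on M-values) is
  deliberately out of scope; the contrast is the two-group comparison.
* In-sample AUC and cutoff accuracies are optimistic at n ≈ 37; the
  cross-validation option exists precisely because the default mirrors
  common small-cohort practice.
* Full fractional cell-type deconvolution is not implemented; purity
  scoring is correlation-based identity checking only.
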