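# Methods

## Problem setting

High-grade serous ovarian cancer splits into four transcriptional subtypes
(mesenchymal, differentiated, proliferative, immunoreactive); the
mesenchymal subtype carries the worst prognosis and an active EMT program.
The pipeline asks which microRNAs *master-regulate* that program: miRNAs
that are lost in mesenchymal tumors and whose inferred target set (regulon)
is statistically enriched for EMT signature genes. All expression is
assumed to be already log2-scale (microarray RMA or log-transformed
RNA-seq); the package never re-logs.

## Synthetic cohort generator

`simulate.simulate_cohort` draws one cohort from an explicit generative
model so that every downstream stage has a known answer:

- **Subtype**: each sample is mesenchymal with probability 104/462 ≈ 0.225
  (the TCGA-like class balance); non-mesenchymal samples get a random label
  among the other three subtypes.
- **miRNAs**: baselines μ ~ N(7, 1) log2 units (microarray intensity
  scale), i.i.d. N(0, 0.5²) noise. The three *planted regulators* are
  shifted down by δ = 1.0 log2 units in mesenchymal samples.
- **Genes**: each planted regulator drives a disjoint regulon (80 genes at
  full scale, 40 at desk scale) through
  y = μ + sign·0.8·(x − μ_x) + γ·1[mes] + noise, where 90% of edges are
  repressive (sign = −1). The 30-gene signature consists of 60% of itself
  inside the master regulon — including the 10 planted classifier genes,
  which are mesenchymal markers and get γ = 1.5 — plus 10% overlap with
  each decoy regulon and a remainder of free genes; non-classifier
  signature genes get a small γ = 0.4 shift. Repression slots are assigned
  to signature/classifier targets first: the planted master's regulon is a
  *repressed* module overlapping the signature (and classifier genes must
  rise in mesenchymal tumors to clear the log2FC > 1 filter, which an
  induced edge from a downshifted regulator would prevent).
- **Survival**: exponential event times with baseline hazard 0.02/month
  and a mesenchymal hazard ratio of 2.0; independent exponential censoring
  at 0.015/month plus an administrative cutoff at the 95th percentile of
  event times (roughly 30–40% censoring with informative KM curves).

The generator reproduces the *relative* structure the discovery pipeline
relies on — group shifts, signed couplings, signature overlap, censored
survival — but not batch effects, count noise, probe-level artifacts,
correlated regulons or copy-number/methylation layers. Passing recovery
tests therefore demonstrates the statistical machinery is correct and
calibrated, not that real cohorts are this easy.

## Stage-by-stage notes

**Differential expression.** Welch's t (Satterthwaite df) is the default
two-group test, with Mann–Whitney–Wilcoxon as an option (exact null by
enumeration for ≤ 12 tie-free observations, else normal approximation with
tie/continuity corrections; U counts pairs a < b with a from the first
group). A moderated-variance test would be preferable at very small n; at
the cohort sizes simulated (≥ 150 samples) Welch is asymptotically
equivalent and keeps the package self-contained. Benjamini–Hochberg is the
only multiplicity correction, applied per analysis family (per matrix, per
MRA run, per GSEA collection). Degenerate inputs: two constant groups with
equal means give p = 1, with different means p = 0 plus a warning.

**Classifier.** The ordered selection is DE filter → AUC filter → cap at
10 genes by AUC (ties by |log2FC|, then id). NSC uses
m_k = √(1/n_k − 1/n) — not 1/n_k + 1/n — because the overall centroid
includes class k; s0 is the median of the pooled within-class dispersions.
Δ is chosen on a 13-point grid over [0, 3] by stratified 10-fold
cross-validated accuracy with ties resolved toward the largest Δ (sparsest
model); folds are seeded round-robin assignments, so training is
reproducible. Mesenchymal-vs-rest is trained as a two-class problem; the
posterior threshold applies to the mesenchymal class only. New cohorts are
z-normalized against their own samples before classification, mirroring
how the published classifier was transferred across datasets.

**Network inference.** Mutual information uses equal-frequency (quantile)
binning with B = clamp(⌊√(n/5)⌋, 2, 10) bins and stable-rank tie breaking,
reported in nats; this estimator is exactly invariant under strictly
monotone transforms on tie-free data. Significance: each regulator's sample
order is permuted (default 1000 times) against all targets jointly,
p = (1 + #{MI* ≥ MI}) / (1 + N), BH across all pairs at α = 0.05. The
plug-in MI bias is identical across pairs that share a binning, so it
cancels from every comparison the pipeline makes (permutation ranks, DPI
orderings). Stability: bootstrap consensus (default 100 resamples,
threshold 0.95); the per-resample significance cutoff is the 95th
percentile of a pooled null built from one sample-order permutation per
regulator per resample — a full nested permutation test per resample would
cost ~1000× more for no inferential gain in a consensus filter. DPI: for
every (regulator, regulator, target) triangle the weakest MI is flagged
when strictly below (1 − tolerance)× the smaller of the other two
(tolerance 0 by default); only regulator→target edges are removable, and
regulator–regulator MI exists solely for adjudication. Signs come from
Spearman correlation (Pearson available); zero correlation drops the edge
with a warning.

*Known limitation.* DPI removes an indirect edge only when some measured
regulator explains it. When a latent confounder (here, the subtype itself)
drives both a regulator and a strongly subtype-shifted gene, the spurious
edge can exceed the regulator–regulator MI and survives; on planted
cohorts this caps edge precision around 0.75–0.85 (decoy-regulator edges
onto classifier genes), while recall and sign accuracy are ~1.0.
Conditioning the MI on the subtype label would remove these edges but
would change the inference contract (all-samples MI, as used by the
RTN/ARACNe family), so it is deliberately not done.

**Master-regulator analysis.** Upper-tail hypergeometric test within the
universe of candidate target genes that entered network inference — not
the whole genome — matching the conditioning of the inference step.
Signature genes outside the universe are dropped (logged). Ranking is by
BH-adjusted p ascending, ties by signature coverage descending, then id.

**GSEA.** Preranked only: the phenotype is the mesenchymal log2FC vector,
ties broken lexicographically. Default weight p = 1 (hits advance by
|score|^p); p = 0 reduces the statistic to the classical two-sample KS
distance and is used by the exact oracle tests. The null permutes gene
identity (random hit positions), shared across sets of equal size; NES
divides ES by the mean |null ES| of the same sign, nominal p is one-sided
within the same-sign null, and FDR q follows the positive/negative-pool
convention of the original method. Phenotype permutation (re-ranking per
permuted labels) is out of contract.

**Survival.** Kaplan–Meier estimation delegates to lifelines; the log-rank
test is computed directly so per-group observed/expected counts and the
hypergeometric variance are exposed (χ² = (O₁−E₁)²/V, 1 df). Cox fits
maximize the Breslow-ties partial likelihood by Newton–Raphson with
step-halving (the log-likelihood never decreases across iterations),
convergence at score norm < 1e−8 within 50 iterations; covariates are
centered for conditioning. A coefficient escaping |β| > 10 signals
monotone likelihood (perfect separation): the fit is flagged unconverged
and no hazard ratio is reported. Standard errors come from the inverse
observed information; 95% CI = exp(β ± 1.96·SE). Stratification by
expression splits at the cohort *mean* (not median), with values exactly
at the mean assigned "low".

**Target prioritization.** A gene is prioritized when present in the
regulon, the signature and *every* supplied sequence-based prediction list
(an intersection, with a union mode behind a flag). Pearson r between
regulator and gene expression is reported per gene with BH across the
evidence table.

## Determinism and problem sizes

One root seed drives everything: the pipeline derives per-stage seeds by
fixed offsets (recorded in the report), permutation and bootstrap layers
use `numpy.random.default_rng`, and repeated runs produce byte-identical
output bundles. The test suite validates recovery on desk-scale cohorts
(200 genes × 20 miRNAs × 200 samples, regulon size 40, 20 seeds),
calibration on null cohorts (no planted effects) and the hazard-ratio
recovery at n = 2000; these sizes keep the full suite in the low minutes
on a single CPU while leaving every planted effect comfortably detectable.

## Open design choices made here

- Which test produced the published miRNA thresholds is not documented;
  both Welch and Wilcoxon are offered, Welch is the default.
- The Δ-selection scheme for the published classifier is unknown;
  stratified 10-fold CV with sparsest-tie-breaking is this package's
  choice, as is the 2-class (rather than 4-class) formulation.
- The exact MI estimator, permutation scheme and DPI tolerance of the
  upstream network tool are unspecified; the transparent equivalents above
  are deliberate re-designs, not reconstructions.
- Probe-set→gene collapsing of vendor arrays is excluded rather than
  guessed; inputs are assumed to be gene-level already.
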