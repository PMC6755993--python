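# mirmaster

Discovery of subtype-defining microRNA **master regulators** from paired
expression cohorts, built for high-grade serous ovarian cancer-style data:
a poor-prognosis *mesenchymal* transcriptional subtype, an EMT
(epithelial–mesenchymal transition) gene signature, and miRNAs whose loss
de-represses that program.

The package implements the full discovery chain as a reusable, tested
library:

1. **Subtype classifier** — two-step gene filtering (differential
   expression at log2FC > 1, BH *P* < 0.05, then per-gene ROC AUC > 0.9)
   followed by a nearest-shrunken-centroid (PAM) model. For gene *i* and
   class *k*,

       d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n)

   soft-thresholded at Δ (chosen by stratified 10-fold CV), with Gaussian
   discriminant posteriors; a mesenchymal posterior > 0.5 calls the subtype.
2. **Network inference** — candidate regulators are miRNAs downregulated in
   the mesenchymal subtype (log2FC < −0.5, BH *P* < 1e−4); candidate
   targets are differentially expressed genes (|log2FC| > 0.25, BH
   *P* < 0.05). Both matrices are independently z-normalized, association
   is mutual information on equal-frequency bins, significance comes from
   regulator-wise permutation (BH-corrected), stability from bootstrap
   consensus, indirect edges are pruned by the data-processing inequality,
   and each surviving edge is signed by Spearman correlation
   (induction/repression).
3. **Master-regulator analysis** — each regulon *R* is tested for
   overrepresentation of the signature *S* inside the candidate-target
   universe *U* with an upper-tail hypergeometric test,
   P(X ≥ |R∩S|), X ~ Hypergeom(|U|, |S∩U|, |R|), BH-corrected across
   regulators and ranked together with the coverage |R∩S|/|S∩U|.
4. **Preranked GSEA** — genes ranked by mesenchymal log2FC; weighted
   Kolmogorov–Smirnov enrichment score, gene-permutation null (1000
   permutations), NES and positive/negative-pool FDR.
5. **Survival** — Kaplan–Meier curves, a log-rank test reporting per-group
   observed/expected events, mean-expression stratification (high = above
   cohort mean), and Cox proportional hazards (Breslow ties,
   Newton–Raphson with step-halving) uni- and multivariate with
   age/stage/grade covariates.
6. **Target prioritization** — the Venn intersection
   regulon ∩ signature ∩ (all sequence-based prediction lists), with
   Pearson anticorrelation evidence per gene.

Because the original cohorts (TCGA, GEO series) are not redistributable,
the package ships a first-class **synthetic cohort generator**
(`mirmaster.simulate`) that plants all of this structure — subtype labels,
a downshifted master regulator with a repressed regulon overlapping the
signature, decoy regulators, classifier genes, censored survival — so every
stage can be validated against known ground truth.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/05_full_pipeline.py` (a 200-gene × 20-miRNA × 200-sample
planted cohort, seed 5) prints:

```
top master regulator: miR-015 (BH-adjusted p = 8.56e-06, signature coverage = 73%)
planted truth       : miR-015
classifier panel    : G0113, G0185, G0026, G0090, G0031, G0159, G0058, G0118, G0169, G0074
network             : 156 signed edges
GSEA top set        : SIGNATURE (FDR q = 0.000)
prioritized targets : 18 genes in regulon ∩ signature ∩ both prediction lists
log-rank subtype p  : 1.7e-07
```

Reading: the pipeline rediscovers the planted master regulator as the most
significant regulon (hypergeometric BH-adjusted p), its regulon covers 73%
of the signature genes that entered the network universe, the EMT-like
signature is the top GSEA hit on the mesenchymal log2FC ranking, the
three-way Venn narrows candidates to 18 direct-target genes, and the
mesenchymal subtype carries significantly worse survival.

The same stages are available from the shell:

```bash
mirmaster simulate --seed 1 --outdir cohort/
mirmaster run-all --expr cohort/gene_expr.tsv --mirna-expr cohort/mirna_expr.tsv \
    --samples cohort/samples.tsv --signature sig.gmt --seed 1 --outdir results/
```

Input contracts: expression matrices are TSV/CSV with features in rows
(first column = feature id, header = sample ids, log2 scale); gene sets are
MSigDB-dialect GMT; sample annotations are TSV with a `sample_id` column
plus optional `subtype`, `time`, `event`, `age`, `stage`, `grade`;
prediction lists are two-column TSV (`regulator_id`, `target_id`).

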