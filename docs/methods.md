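# Methods

`imlnc` re-implements, as a tested and reusable pipeline, an analysis style
used to immunophenotype bulk tumor transcriptomes and to distill the
phenotype into a minimal lncRNA signature. This note documents the models,
the defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions.

## The analysis, end to end

1. **Filtering.** Features (genes and lncRNAs, FPKM scale) are kept when
   they are expressed (FPKM > 0) in at least 70% of all samples. The
   boundary is inclusive and the fraction is counted over tumors and normals
   jointly; both choices are configurable (`min_expr_frac`).

2. **Immunophenotyping.** Each tumor is scored against five immune
   expression signatures — IFN-γ response, overall lymphocyte infiltration,
   macrophages/monocytes, TGF-β response, wound healing — with single-sample
   GSEA. With per-sample ascending average ranks `r_i` and exponent
   `α = 0.25`, the enrichment score of a set S in a sample is

       ES = Σ_{positions j in descending expression order} [ F_in(j) − F_out(j) ]

   where `F_in` steps by `r^α / Σ_{i∈S} r^α` on set members and `F_out` by
   `1/(N − |S|)` otherwise. When `normalize=true` all scores are divided by
   the (max − min) of the whole score matrix. Ties take average ranks so
   zero-inflated data score deterministically; a set covering every feature
   has no out-of-set ECDF and scores 0 with a warning.

   The score matrix (columns z-scored by default) is consensus-clustered:
   500 subsamples of 80% of the tumors, k-means (k = 2, 10 restarts) per
   subsample, consensus(i,j) = co-clustered / co-drawn, final partition by
   average-linkage hierarchical clustering of 1 − consensus. The cluster
   with the higher mean score over the IFN-γ, lymphocyte-infiltration and
   macrophage columns is named Immune-High (IH), the other Immune-Low (IL);
   those three columns are the ones that discriminate the clusters (TGF-β
   and wound healing do not). k = 2 is fixed by default; a k-scan is not
   part of the headline path.

3. **Differential lncRNAs.** For each phenotype versus the normal samples:
   log2FC = mean log2(FPKM+1) difference (pseudocount 1 tolerates zeros);
   two-sided equal-variance Student's t on the per-row Z-scores of the log2
   values, standardized over the union of the compared samples (the Z-then-t
   order is kept for fidelity even though the t statistic is affine-invariant
   and therefore equals the raw-scale t; a Welch option exists);
   Benjamini–Hochberg adjustment within each comparison separately (two BH
   families — the joint option is a flag). Significance: FDR < 0.01 and
   |log2FC| > 2. Significant-in-both = Constitutive, in one =
   IH-/IL-specific, else none; the four categories partition the universe.

4. **Signature discovery.** Repeated stratified 3-fold CV over tumors
   (1000 repeats by default). Per training split: greedy mRMR (MID
   criterion, mutual information on features discretized into 3 bins at
   mean ± sd) screens candidates to the top 5%; one random forest fit on the
   screened set ranks them by mean decrease in Gini impurity; for each size
   s on the grid (1..15 by default) a forest on the s top-ranked features is
   scored on the held-out fold with the balanced error rate
   BER = ½(err_IH + err_IL). Each repeat is mirrored by a negative-control
   run of the identical procedure on permuted labels — the chance floor,
   which sits at BER ≈ 0.5 by construction.

   The final size is the smallest s beyond which the mean BER no longer
   improves; "no improvement" means no larger size undercuts BER(s) by more
   than `ber_tolerance` (default 0.01 — one BER percentage point is the
   smallest gain we consider worth an extra signature feature). Every
   (repeat, fold) then contributes one candidate of that size, features
   ordered by descending Gini importance, and candidates are compared with
   the signature distance

       D(S1, S2) = 1 − (1/k) Σ_{i=1..k} ρ(F1_i, F2_i),   D ∈ [0, 2]

   with ρ the Spearman correlation of the paired features' expression over
   the tumor samples and pairing positional after the Gini sort (an
   optimal-assignment pairing via
   maximum-weight bipartite matching is available as `pairing="matching"`).
   The representative signature minimizes the summed distance to all other
   candidates; ties break on lower test BER, then candidate index.

   Why Gini ranking between mRMR and the per-size models: the procedure's
   description sorts signature features "by the change in Gini index", and
   mutual-information estimates on ~60-sample training splits are noisy
   enough that pure mRMR ordering lets null features into the top ranks —
   a forest over the screened set is the more faithful and the more stable
   ranker. mRMR remains the screening step that enforces low redundancy.

5. **im-lncScore.** PC1 of the Z-scored signature submatrix (samples as
   observations; no re-centering beyond the Z-scores, so the SVD runs on the
   matrix as-is). The component sign is arbitrary, so the score is oriented
   to correlate positively with the per-sample mean Z across signature
   features, or, when labels are available, so the IH mean exceeds the IL
   mean. Discrimination: Mann–Whitney rank AUC with tie correction,
   stratified percentile-bootstrap 95% CI (2000 resamples), and the Youden-J
   optimal cutoff (ties toward the score median). Youden's J and the
   percentile bootstrap are this package's choices for "optimal cutoff" and
   "confidence interval" — other conventions exist and would give slightly
   different numbers.

6. **Infiltration associations.** Infiltration estimates are consumed as a
   samples × cell-types table (six cell types: B cell, CD4 T, CD8 T,
   macrophage, neutrophil, myeloid dendritic cell); estimating them is out
   of scope. Each column is dichotomized at its median (ties to "low").
   Each predictor (signature lncRNA Z-score or im-lncScore) enters a
   univariate logistic regression against each binary outcome; predictors
   are standardized so odds ratios are per SD and comparable across
   lncRNAs. Wald 95% CI and p. Perfect separation yields a flagged sentinel
   (OR = ∞ or 0, NaN CI) instead of a crash.

7. **Co-expression.** Spearman ρ between each signature lncRNA and every
   gene over tumors, raw p from the large-sample t approximation. The
   permutation correction holds the gene fixed and redraws the lncRNA:
   n_perm (default 1000) random lncRNAs from the expressed pool (target
   excluded, without replacement; an option samples with replacement when
   the pool is small, and the pipeline enables it automatically and records
   that in the manifest) give permutation p-values P_p, and

       P_e = (#{P_p ≤ P_r} + 1) / (n_perm + 1)

   so P_e ≥ 1/(n_perm+1) and is never 0. Edges with ρ > 0.6 and P_e < 0.01
   (both strict) form the reported network. The pipeline runs the
   permutation test only for edges passing the ρ filter; the others cannot
   be retained and carry P_e = NaN. An alternative null that permutes sample
   labels instead of redrawing lncRNAs was considered and not used: the
   stated procedure redraws "random lncRNAs", which also calibrates against
   the dataset's generic lncRNA–gene correlation structure.

## The synthetic cohort

`generate_cohort` is a pure function of its spec (same seed ⇒ bit-identical
outputs). It emulates exactly the structure the analysis assumes:

* log2-normal expression (Gaussian on the log2 scale, exponentiated to
  FPKM) — the pipeline consumes FPKM, not counts, so no count model;
* a latent binary immunophenotype over tumors (`frac_ih`, default 0.4)
  that raises the five immune gene sets and the planted lncRNAs by
  `effect_size` (default 2 log2 units) in IH tumors;
* planted lncRNAs additionally carry `tumor_shift` (default 3) in all
  tumors versus normals, so they survive a tumor-vs-normal differential
  screen, as the signature lncRNAs do in real cohorts;
* a `frac_tumor_de` fraction (default 0.3) of background features gets a
  random-sign tumor-vs-normal shift with no phenotype dependence — the
  decoy differential pool;
* infiltration proxies: log-normal, six cell-type columns, mean shifted up
  by `infiltration_shift` (default 1.0 on the log scale) in IH tumors;
* zero inflation: exactly `zero_frac` (default 0.1) of entries are set to
  0, chosen as the lowest Gumbel-perturbed log2 abundances, i.e. dropout
  concentrates in weakly expressed entries as it does in real FPKM data.
  (Uniform dropout would place zeros on strongly expressed entries and
  create log2 outliers of −10 that no small-n t-test survives — a structure
  real data does not have.)

The `tcga_gbm_preset` mirrors a typical TCGA glioblastoma cohort layout:
144 tumors + 5 normals (149 samples). Its default feature space (2000 genes, 1500
lncRNAs) is a deliberate scale-down of the real ~18k/~18k; override
`n_genes`/`n_lncrnas` to emulate full size. No distributional parameters of
the real cohort are published, so all generator parameters are free choices
documented here.

What the generator does **not** emulate: read-count noise, batch effects,
tumor molecular subtypes, correlated gene modules beyond the immune sets,
library-size variation, or expression-dependent variance. Passing the
planted-recovery tests therefore shows that the pipeline recovers the
structure it assumes, not that it is robust to everything real data does.

## Numerical conventions and degenerate inputs

* "Not expressed" = FPKM ≤ 0; the 70% filter boundary is inclusive.
* Z-scores use the sample (n−1) standard deviation; constant rows are
  rejected with the offending ids listed.
* Ranks break ties by averaging everywhere (ssGSEA, Spearman, AUC).
* mRMR ties break on feature order; constant features are excluded with a
  warning; MIQ (quotient) criterion available.
* The consensus matrix is symmetrized and gets a unit diagonal; pairs never
  co-drawn (possible only at very low resample counts) score 0.
* PCA on a rank-deficient all-identical matrix raises; a single-feature
  signature score is that feature's Z-score up to orientation.
* Equal cluster activation means, one-class inputs, and size-mismatched
  signatures raise instead of guessing.
* All stochastic stages take explicit seeds; the pipeline derives per-stage
  seeds as sha256(f"{seed}:{stage}") mod 2^31, so any stage can be re-run
  in isolation and reproduce its outputs bit-identically.

## Scaled problem sizes

The repository's tests and the acceptance script run everything on synthetic
cohorts sized for a single CPU: the candidate-count check uses a small
cohort (30 tumors, 40 lncRNAs, size grid {1, 2}, 16-tree forests, no
negative controls — the count does not depend on them) under the full
1000-repeat protocol, and the parameter-recovery check uses 90 tumors,
6 planted among 300 decoy lncRNAs, 50 CV repeats, 32-tree forests and a
size grid of 1..10. Forests of 500 trees (the library default) behave the
same but slower; the per-fold importance noise of small forests averages
out over the 150–3000 CV folds these checks aggregate.

## Known limitations

* The BER plateau rule depends on `ber_tolerance`; a profile that keeps
  improving by just under the tolerance at every size selects the smallest
  size on the grid segment, which is the intended "parsimony first"
  behavior but worth knowing when grids are dense.
* mRMR mutual information uses 3-bin discretization; very small training
  splits (< ~30 samples) make the estimates noisy and the screen unstable.
* The empirical p-value resolution is 1/(n_perm+1); with the default 1000
  permutations the strict P_e < 0.01 filter requires ≤ 9 of 1000
  permutation p-values at or below the raw p.
* Consensus clustering assumes k = 2; cohorts with more immunophenotypes
  need the `k` knob and their own annotation rule.
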