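# Methods

This note records the models, conventions and numerical choices behind
`immunostrat`, the assumptions the synthetic-data generator makes, and the
limits of what the test suite demonstrates.

## Rank-based signature scores

Every score is computed per sample from the ascending ranks of that
sample's expression values (ties receive average ranks). For a gene set of
size *n* in a transcriptome of *N* genes the mean rank *R̄* of the set
genes is rescaled by its attainable extremes — (n+1)/2 when the set
occupies the bottom *n* ranks and (2N−n+1)/2 when it occupies the top *n*
— and centered, giving a uni-directional score in [−0.5, 0.5] with 0 ≈ no
enrichment. The bi-directional score adds the expected-down genes' score
computed on reversed ranks (N+1−rank) and spans [−1, 1]; swapping the up
and down lists negates it.

Conventions: genes in a set but absent from the matrix are dropped with a
warning (never imputed) and at least two must remain; all-constant samples
are rejected because their ranks are undefined; sets overlapping a
collection-scoring run by fewer than two genes are skipped. Because only
within-sample ranks enter, scores are invariant to any strictly monotone
per-sample transform — this is why the package is indifferent to whether
expression arrives as counts-per-length-normalized values or logs, and why
the RPKM module deliberately omits between-sample scaling corrections
(TMM-style factors are monotone within a sample).

An important systemic property: scores of different sets within one sample
are *compositional in ranks*. If one set's genes rise, every other set's
mean rank must fall slightly. With strong planted structure this induces
small negative couplings between unrelated set scores; it shrinks as the
transcriptome grows relative to the structured genes.

## Subtyping

k-means (Euclidean, 10 restarts, fixed seed) on raw fraction values —
fractions are already commensurate proportions, so no scaling is applied.
k is chosen by maximum average silhouette width over a user-set range
(default 2–6), ties to the smallest k. Cluster numbering is canonicalized:
the cluster whose centroid has the higher "T cells CD4 resting" fraction
is subtype 1, making "pro-inflammatory = 1, pro-remodeling = 2"
reproducible across seeds. New cohorts are assigned to the nearest
centroid; exact ties go to the lower-numbered subtype.

Cell-type importance ranking wraps backward elimination around an
L2-regularized logistic regression scored by stratified 5-fold CV
accuracy: at each step the feature whose removal least degrades accuracy
is dropped (first dropped = worst rank). On strictly compositional rows
the complement of an informative column is itself informative, so the
ranking reflects joint rather than marginal importance; the contract
tested is ordinal (a separating feature ranks first, a constant last), not
the numeric profile.

Between-subtype fraction comparisons use the two-sided Student's t-test
(equal variances) with Benjamini–Hochberg adjustment across cell types,
matching the convention of the original analysis; the package's
gene-level differential expression uses Welch's t-test instead (below).

## Fibrosis scoring and group accounting

The fibrosis score is the uni-directional score of POSTN, COL1A1, TIMP1,
MMP2 and ACTA2 (extracellular-matrix deposition, matrix-remodeling
enzymes, activated-fibroblast actin). Samples are split at the median
score with a strict rule — high ⇔ score > median — so an odd cohort of
distinct scores splits (n−1)/2 high / (n+1)/2 low, e.g. 51/52 of 103; all
ties (including the all-equal degenerate case) go low. Partition reports
cross-tabulate subtype × level and express each cell as a percentage of
*all* samples, rounded half-up to two decimals, so the four percentages
sum to 100 within ±0.02.

Differential expression is a per-gene Welch two-sided t-test on
log2(x+1), with log2 fold change defined as the difference of group means
on that scale and BH adjustment across genes. This deliberately replaces
the negative-binomial count model a full reanalysis would use: the
package's contracts downstream (fold-change filters, over-representation)
only consume the table's shape, and the t-test keeps the pipeline
dependency-light and exactly reproducible. Genes constant within both
groups get t = 0, p = 1 and a `constant` flag. Absolute DEG counts from
any count-model reanalysis are therefore not comparable to this table.

The double-fold filter keeps genes with log2fc₁ > 0 and
log2fc₁ ≥ 2·log2fc₂ — when the subtype-2 fold change is negative, any
positive subtype-1 fold passes, a documented resolution of an ambiguous
rule. Over-representation is the one-sided hypergeometric tail over a
user-supplied universe (a stand-in with the same filtering role as
concept-level enrichment tools, which are out of scope), BH-adjusted
across sets.

## LAFSAA

The screen operationalizes "significantly and specifically correlated"
as: Spearman p < α within the flagged subtype AND p ≥ α in the other
subtype (α = 0.05). Spearman p-values use the t-approximation on n−2
degrees of freedom. Zero-variance score columns are skipped. Validation
in an independent cohort requires p < α *and* the same correlation sign
within the record's subtype. The enrichment filter keeps a record when
its set's raw hypergeometric p against its subtype's high-vs-low-fibrosis
up-regulated genes is below α.

The correlation matrix of surviving sets is computed over *all* discovery
samples (not per subtype), clustered hierarchically with distance 1 − ρ
and average linkage; k is user-set or chosen by silhouette on the
precomputed distances over 2..min(12, n−1).

The intra-cluster correlation score is implemented literally as the mean
of a set's Spearman correlations over all n members of its cluster,
*including* the self term (so singleton clusters score 1). An
exclude-self variant is exposed; within any fixed cluster the two are
affine transforms of each other ((n·ICS − 1)/(n − 1)), so the top-30 %
representative selection — ⌈0.3·n⌉ per cluster, boundary ties all
included — is provably identical under either reading, and this is
property-tested. Fibrosis-specific intersection keeps sets flagged (and
validated, where validation was run) for the *same* subtype against both
the EMT target and the fibrosis score.

## Biomarker panel

Candidate screen: Student's t on log2(x+1) restricted to the secretory
list, BH, padj < 0.05, direction = sign of the subtype-1 − subtype-2 mean
difference. LASSO: features standardized once on the full training set; a
100-value λ path log-spaced over 4 decades down from λ_max = max|Zᵀ(y−ȳ)|/n
(the smallest λ zeroing all coefficients of the (1/n)·loss + λ‖w‖₁
objective); stratified 10-fold CV of misclassification error; λ* is the
largest λ with CV error ≤ min + 1 SE (SE = fold-error SD/√folds); the
panel is the nonzero-coefficient genes at λ*, refit on all training data.

Backward elimination mirrors the published procedure's logic where its
details are unstated: candidates are the panel genes whose
between-subtype difference is *not* highly significant (BH p > 0.01),
tried in order of decreasing adjusted p; a removal is accepted iff the
tuning-cohort AUC strictly increases while the training AUC drops by at
most 0.01 (the tolerance reflects that a small training-set drop is
acceptable when held-out performance improves); a panel side never
shrinks below the two-gene scoring minimum. In the pipeline the tuning
cohort is a stratified 30 % split of the discovery cohort; any second
cohort can be passed instead.

AUC is the tie-corrected rank statistic (probability a positive outscores
a negative, ties ½), exactly equal to the exhaustive pairwise-comparison
count; the ROC curve sweeps thresholds over the unique scores.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with planted
truth for every stage. Defaults are the study conditions used throughout
the tests; each is listed with its rationale.

* **Fractions.** 22 LM22 cell types. Per-subtype Dirichlet draws with
  concentration 150 (within-subtype component SD ≤ ~0.035 at these
  means, i.e. tight but realistic deconvolution spread). The baseline
  mean profile is a plausible bulk cardiac immune mix; subtype 2 adds
  `fraction_effect` (default 0.15 proportion units) to M2 macrophages and
  neutrophils, subtype 1 to resting CD4⁺ T cells, memory B cells and
  monocytes, with the added mass taken proportionally from the
  non-signature cell types so each signature type's between-subtype mean
  difference equals the configured effect exactly.
* **Expression.** Generated on log2 scale and exponentiated
  (unit = rpkm): per-gene baselines uniform on [2, 8] log2 units, i.i.d.
  Gaussian noise with SD 1.0 — a typical per-gene dispersion for bulk
  log-scale data, and the regime in which individually-informative panel
  genes remain jointly necessary, so feature selection is non-trivial.
* **Fibrosis/EMT axis.** A per-sample latent, N(0,1) in failing samples
  and N(−2,1) in healthy controls (controls sit clearly but not
  disjointly below patients), loads with weight `fibrosis_effect`
  (default 1.5) on the five marker genes and the EMT set.
* **Subtype-specific sets.** Each planted set has its own latent equal to
  ρ·(fibrosis latent) + √(1−ρ²)·noise *inside its target subtype*
  (ρ = `coupling_rho`, default 0.7) and an independent latent elsewhere,
  loading on the set's genes with weight `fibrosis_effect`. Score-level
  coupling therefore approaches ρ within the target subtype (attenuated
  by scoring noise) and 0 outside it.
* **Panel genes.** `n_panel_genes_per_subtype` (default 15) secretory
  genes per subtype shifted by `panel_shift` (default 1.0 log2 units) in
  failing samples of that subtype, plus twice as many unshifted secretory
  decoys so the candidate screen has something to reject.
* **Structure vs values.** Gene roles and set membership are a
  deterministic function of the configuration (null-set membership uses a
  fixed structural RNG); only sampled values depend on the run seed. Two
  seeds with one configuration therefore yield discovery/validation
  cohorts sharing planted structure, which is what the screen-validation
  chain requires.

What the generator does *not* emulate: read-level sampling and
library-size variation, between-dataset batch effects, gene–gene
correlation beyond the planted latents, non-Gaussian expression noise,
and deconvolution estimation error in the fractions. Passing tests
demonstrate that the implementation recovers the structure it targets
under its stated statistical model — not that the biological findings of
any particular cohort would replicate.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 150 samples per subtype (50
healthy), 2 000 genes, 10 planted specific sets per subtype, 200 null
sets and 15 + 15 planted panel genes — large enough for stable rank
scores and correlation screens, small enough that the entire suite runs
in about a minute on one CPU. Spearman p-values use the t-approximation;
silhouette ties break to the smallest k; centroid-assignment ties to the
lower label; representative-selection ties at the top-30 % boundary are
all included; percentages round half-up to two decimals. Reported AUCs
near 1.0 on synthetic cohorts reflect the planted effect sizes, not an
expectation for real data.

## Known limitations

* Welch-on-log DE and hypergeometric ORA are simple stand-ins for count
  models and concept-level enrichment; absolute DEG/enrichment counts are
  not comparable to such tools.
* The specificity rule (significant inside, non-significant outside) is
  sensitive to per-subtype sample size: with very large cohorts the
  "outside" test gains power against tiny leakage correlations and
  retention drops. A margin rule (|ρ_in| − |ρ_out| ≥ δ) would be more
  stable; the package keeps the simple rule as the default contract.
* Backward elimination is greedy and order-dependent (decreasing adjusted
  p); joint subset search is out of scope.
* The RFE ranking on compositional inputs measures joint importance (see
  above); it is not a per-cell-type effect size.
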