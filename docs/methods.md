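# Methods

This note documents the statistical model behind `cagnet`, the defaults
and why they are set where they are, and the known limits of what the
synthetic validation demonstrates.

## The analysis model

The pipeline treats a genus-level relative-abundance table (samples ×
genera, rows closed to 1) as the unit of analysis and asks three
questions per disease subtype: (i) which genera co-vary as groups (CAGs),
(ii) whether those groups' abundances and internal connectivity differ
between matched cases and controls, and (iii) whether the groups' links
to predicted metabolic pathways differ.

**Matching.** Covariates are encoded numerically (sex: 1 = male,
0 = female; frequency scales as ordinal codes), z-scored over the pooled
case+control sample with the n−1 sd, and cases are paired to controls by
Euclidean distance. Two algorithms are provided: greedy (repeatedly take
the globally closest remaining pair; ties broken by lowest case index,
then lowest control index) and optimal (Hungarian assignment minimizing
total distance, the default — it is never worse than greedy and is
order-invariant). An optional stratum constraint restricts pairs to equal
values of chosen covariates. Balance is reported as standardized mean
differences (pooled-sd denominator) and paired t-tests; subtype
comparability as one-way ANOVA.

**Networks and CAGs.** Within each cohort group, every genus pair gets a
Spearman ρ (mid-rank ties) with a t-approximation p-value; BH correction
runs over all pairs of that group; edges require q < 0.05 and ρ > 0.4
(positive-only by default; an absolute-value mode exists because both
conventions appear in practice). Clustering uses the *pooled*
(cases+controls) unthresholded correlation matrix: the threshold defines
network edges, but Ward linkage needs a complete dissimilarity, so the
tree is built on d = 1 − ρ with the Ward.D2 convention and cut at k = 8.
A per-group clustering mode would be a one-line change but the pooled
matrix is the default because co-abundance is computed "across all
samples" of a subtype cohort. The 2–10 size band is a quality report, not
a constraint — there is no principled re-clustering rule when a cut
violates it, so violations are flagged instead of hidden.

**Differential abundance.** Per-CAG mean relative abundance, Wilcoxon
rank-sum case vs control, two-sided, stars at 0.05/0.01/0.001/0.0001.
The rank-sum switches to exact enumeration when the combined sample is
≤ 12 and tie-free (recorded in the result); otherwise the normal
approximation with tie and continuity correction is used.

**Pathway association.** Genus × pathway Spearman per group; |ρ| > 0.2
defines bipartite network edges, sign kept. For the per-(CAG, category)
contrasts the *unthresholded* ρ values are used inside cells — if the
threshold were applied first, the disease and control vectors would have
unequal, selection-biased composition and the rank-sum would be
meaningless. No multiplicity correction is applied across cells by
default (raw stars are the convention in this workflow); a BH-across-cells
switch exists. Focal pathway groups (SCFA/LPS/tryptophan-style lists) are
aggregated by summing member pathway abundances per sample — the additive
reading of "pathway abundance" — and tested by paired t over matched
pairs; a per-pathway-mean mode is provided.

**Classifier.** CAG-summed abundances, 500-tree random forest, per-class
70/30 split (floor(0.7·n) per class, shuffled deterministically by seed),
10-fold cross-validation on the training set, confusion metrics at the
0.5 probability threshold, AUC via the rank statistic (identical to the
trapezoidal ROC area), mean-decrease-Gini importance. All other forest
hyperparameters are sklearn defaults and are echoed into the run
manifest.

**Shapley attribution.** A from-scratch Monte-Carlo permutation
estimator: for each explained instance, 50 random feature permutations
are walked from a sampled background row to the instance, and feature j's
contribution is the prediction change at its step. One *shared* set of
background draws is used for all instances, so the per-instance sum of
contributions telescopes to f(x) − mean(f(background draws)) exactly;
reporting that Monte-Carlo background mean as the baseline makes the
efficiency identity Σφ = f(x) − baseline hold to machine precision rather
than only within sampling error. Per-feature Monte-Carlo standard errors
(sd/√S) are reported alongside. The background is the training-set
marginal distribution. "Sample size 50" is read as 50 permutations per
instance; both the permutation count and the number of explained
instances (default 100 test samples) are configurable.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

- **Genus layer**: Gaussian copula with log-normal marginals. Latent
  z ~ MVN(0, R), where R has `within_block_rho` inside planted blocks and
  `between_block_rho` (default 0) across; background genera are latently
  independent. Abundances exp(μ_g + σ z) with heterogeneous per-genus
  baselines (μ_g ~ N(0, 1.5)) giving the uneven composition of real
  tables; case-group genera in effect blocks are multiplied by
  exp(log-fold-change) *before* per-sample closure to 1.
- **Metadata**: normal, binary, or thresholded-latent ordinal covariates,
  each with an optional group-association strength (case mean shift in sd
  units / probability points).
- **Pathway layer**: pathway = genus abundances × nonnegative sparse
  contribution matrix (density 0.10, weights U(0.5, 1.5), every pathway
  has ≥ 1 contributor), times multiplicative log-normal noise
  (sd 0.3). Categories are assigned round-robin from the six standard
  metabolic classes (energy, carbohydrate, amino-acid, lipid,
  nucleic-acid, vitamin/cofactor).

One global seed feeds named substreams (baseline/table/metadata/pathways)
so each layer can be regenerated independently. Identical configurations
produce byte-identical tables.

**Defaults** mirror the largest arm of the study design this package
targets: 365 cases + 365 matched controls, 44 genera in 8 blocks of sizes
9, 8, 7, 6, 5, 4, 3, 2, within-block latent ρ = 0.8, and case effects on
three blocks (+0.5 log-fold on block 3; −0.4 on blocks 1 and 2),
emulating one CAG rising and two falling in disease. Covariates default
to no group association, as appropriate for an already-matched design.

**Known distortions, by construction.** Realized Spearman ρ is slightly
below the latent Pearson value (rank transform of the copula). Closure
induces a negative spillover: raising one block in cases slightly lowers
every other genus's relative abundance. Closure also attenuates
within-block correlation in proportion to the block's share of total
composition — with a 5-genus block at latent ρ = 0.8 among 40 genera the
empirical ρ stays ≈ 0.75, but if that block were half the table's mass it
can drop below 0.4. Tests therefore embed planted blocks in a realistic
background. Zero-inflation and sequencing-depth variation are *not*
modeled; passing tests show the machinery recovers planted structure
under log-normal compositional noise, not that it is robust to the
sparsity of real 16S tables.

## Calibration studies and their designs

- **Wilcoxon type-I error**: 10,000 null draws, N(0,1), n = 30/30,
  α = 0.05 → empirical rejection must lie in [0.04, 0.06].
- **BH false-discovery proportion**: 10,000 independent null p-vectors,
  m = 100. Under independent continuous nulls the BH procedure's FDR
  equals α·m₀/m = 0.05 *exactly*, so the empirical mean sits on the
  boundary; the check allows the three-standard-error Monte-Carlo margin
  of the estimate, the same convention used for every other simulated
  bound in the suite.
- **Per-cell pathway contrasts**: the global-null calibration decouples
  the pathway layer from the genera entirely (pathways generated from
  row-shuffled genus input, no group effects), giving homogeneous
  within-cell ρ values; rejection over 1,000 simulations must lie in
  [0.03, 0.07]. Two caveats of the per-cell rank-sum are worth knowing:
  when genera within a CAG are strongly co-abundant their ρ values with
  a pathway are positively dependent and the unstratified rank-sum
  over-rejects; when cells mix strong and null true associations shared
  by both groups it under-rejects. Both are properties of treating
  correlated genus×pathway pairs as independent observations — the
  method's standard reading — and the power test therefore checks the
  directional contrast (rewired CAG flagged far more often than
  untouched ones) rather than exact nominal behaviour of the untouched
  cells.
- **Planted-CAG recovery**: default 8-block design, 400 samples per
  group, ARI ≥ 0.9 against ground truth in ≥ 18/20 seeds.
- **Classifier sanity**: with pure-noise features the held-out AUC lands
  in [0.35, 0.65] in ≥ 90/100 runs; a perfectly separating feature gives
  AUC 1.0 and the top Gini rank.

Problem sizes for the repeated-simulation studies (e.g. 40 + 40 samples,
12 genera, 6 pathways per replicate for the cell-test calibration; 200
samples, 8 features for the repeated classifier runs) were chosen as the
smallest designs at which the quantities under study are stable; the
single end-to-end checks run at the full default design.

## Numerical and interface choices

- Correlation matrices are computed by ranking columns then forming the
  Pearson matrix of ranks (exact mid-rank handling, vectorized).
  Constant columns yield NaN correlations and are excluded from network
  edges with a logged warning, never silently treated as ρ = 0.
- 1 − ρ distances are symmetrized and clipped at 0 before linkage;
  CAG ids are relabelled in order of first appearance along the genus
  axis so partitions are deterministic and label-stable.
- Undefined statistics (zero-variance paired differences, degenerate
  ANOVA, constant vectors in Spearman) return explicit NaN-with-flag
  markers, not silent zeros or exceptions.
- The low-count feature filter removes a feature only when it fails
  *both* the presence (< 30 samples) and total-reads (< 10) thresholds;
  a stricter either-threshold mode is available
  (`exclusion_rule="any"`). The genus prevalence/abundance filter
  (≥ 20% prevalence and mean ≥ 0.05%) does not re-close rows; survivors
  keep their original scale.
- Tables are TSV, UTF-8, samples in rows canonical; `#`-comment lines
  are ignored, and a `#OTU ID`/`feature_id`-style first header triggers
  transposition. Abundance I/O rejects duplicate ids and negative values
  with cell-level error messages. Network exports are edge-list TSV and
  GraphML (Cytoscape-importable). BIOM container export is not
  implemented; TSV is the interchange format.

## Limitations

- Plain Spearman co-abundance is used, as is standard for this workflow;
  no compositional-aware correlation (SparCC/SPIEC-EASI-style) is
  attempted, so strong compositional effects can induce spurious negative
  correlation.
- The per-cell pathway contrast treats genus×pathway pairs as
  independent observations (see above).
- The Shapley estimator is the model-agnostic permutation sampler; it is
  unbiased but slower and noisier than tree-specific exact methods.
- The synthetic generator's fidelity bounds what green tests prove about
  real 16S data (no zero-inflation, no depth variation, flat category
  ontology).
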