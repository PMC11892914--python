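# Methods

This note documents the statistical models implemented in `gutbrain`, the
defaults and why they were chosen, what the synthetic cohorts emulate, and
the numerical choices made where the design was genuinely open.

## Ghrelin indices and group tests

The age-adjusted ghrelin ratio is `AAGR = 6 + log10(AG/UAG) − age/10`, with
AG and UAG in ng/mL and age in years; the base-10 logarithm and the additive
constant 6 are implemented exactly as defined. AAGR is strictly increasing
in AG and decreasing in UAG and age, and is undefined unless both hormones
are strictly positive.

Group comparisons default to Welch's t (Welch–Satterthwaite degrees of
freedom) because it is robust to unequal group variances; Student's t and
the Wilcoxon rank-sum test are also exposed. The rank-sum p-value is exact —
computed by full enumeration of all C(n₁+n₂, n₁) group assignments of the
pooled midranks — whenever both groups have at most 8 observations, which
covers the 9+9 microbiome subsets this pipeline targets; larger samples use
the normal approximation. All tests are two-sided at α = 0.05.

Power for the two-sample two-sided t-test uses the noncentral t distribution
with df = 2n−2 and noncentrality d·√(n/2). At d = 0.631 and n = 40 per group
this gives 0.796, i.e. the 80% design power of the cohort the simulator
emulates.

## OTU processing

Filtering keeps species whose total count across samples is **strictly
greater than** 10; incidence counts a species as present in a sample when
its relative abundance is **strictly greater than** 1%. Both boundaries are
deliberate verbatim readings of the filtration rules. The top-15 ranking for
the abundance/incidence summary uses the overall (not per-group) mean
relative abundance; rank ties break by species name so output is
deterministic. ln(F/B) is undefined for samples with a zero Firmicutes or
Bacteroidetes total; such samples are flagged NaN and excluded pairwise from
group tests rather than failing the analysis.

## Diversity

Alpha indices are richness, Shannon entropy in nats, **Gini-Simpson**
(1 − Σp²; the inverse-Simpson variant can be derived trivially but the
bounded [0,1] form is reported), and Pielou's evenness `H/ln(S)`, reported
as missing when S = 1.

Beta diversity uses Bray-Curtis dissimilarity. PCoA is classical scaling:
eigendecomposition of the double-centered squared-distance matrix;
coordinates use the positive eigenvalues, negative eigenvalues are reported
uncorrected (no Lingoes/Cailliez adjustment), and explained proportions are
taken over the positive spectrum.

PERMANOVA is the one-way distance-based pseudo-F with free (unrestricted)
label permutations. When the number of distinct relabelings N!/∏nᵍ! is at
most 10,000 the null is enumerated exhaustively and the p-value is exact
(p = #{F* ≥ F}/total, identity included); otherwise 999 sampled permutations
(seeded) give p = (#{F* ≥ F}+1)/(n_perm+1). The exhaustive path makes the
9-vs-9 and smaller designs exactly reproducible.

SIMPER decomposes the mean between-group Bray-Curtis into per-species terms:
for species k, the mean over between-group sample pairs of
|xᵢₖ−xⱼₖ|/Σₗ(xᵢₗ+xⱼₗ). The terms are nonnegative and sum exactly to the mean
between-group dissimilarity (verified to 1e-9 on random tables); percent and
cumulative-percent columns are emitted. Only percent-of-total contributions
are reported — per-species percentages that sum past 100 under other
aggregation conventions are not produced.

## SparCC co-occurrence networks

SparCC infers "basis" (absolute-abundance) correlations from compositional
data via log-ratio variances t_ij = w_i² + w_j² − 2 r_ij w_i w_j. Under the
sparsity assumption the basis variances solve the linear system
t_i = d_i w_i² + Σ_j w_j² over included pairs; the most strongly correlated
pair is then excluded from the system and the variances re-solved, up to 10
rounds or until the strongest remaining estimate is below 0.1, so a few
genuine correlations do not contaminate the variance estimates. The
procedure runs for 20 outer iterations: the first uses the pseudocount point
estimate of fractions (count+1)/(total+D), the rest resample fractions from
the per-sample Dirichlet(counts+1) posterior; the final matrix is the
element-wise median, symmetric, unit-diagonal, clipped to [−1, 1].

Dirichlet streams are keyed by the sample's count content (not its column
position), so the estimate is exactly invariant to sample reordering.

Sampling noise: with n samples the basis-correlation estimate has null
standard deviation ≈ 1/√n, the same floor as any correlation estimator.
At n = 200 that is ≈ 0.07, so over ~400 taxon pairs the *maximum* null
estimate is expected near 0.20 even though the bulk is tightly concentrated
at zero. Recovery of individual planted correlations (e.g. 0.8 within
±0.15) is well inside the estimator's accuracy at that n.

Network construction keeps taxa with total abundance strictly > 10 as nodes
and pairs with |r| ≥ 0.3 as signed edges (edge weight = signed correlation,
strength = |r|); 0.3 is a conventional co-occurrence magnitude cutoff and is
exposed in the run config. Communities come from Louvain modularity
maximization on |r|-weighted edges with a fixed seed and sorted node order
for determinism. Each community's maximum-degree node is labeled its
representative only if it ranks in the global top-20 by degree centrality
(ties break lexicographically). Keystone screening takes the union of both
networks' node sets (absent nodes contribute centrality 0), differences the
normalized degree centralities (degree/(n−1) on each node's own network,
control − case), and flags Tukey 1.5×IQR outliers of the delta
distribution; the outlier rule is pluggable.

## Association screens

The Mantel statistic is the Pearson correlation of the upper-triangle
entries of two distance matrices; significance is one-sided (greater) by
permuting the sample order of one matrix — exhaustive over all n! orders
when n ≤ 7, else 999 seeded permutations. Clinical distances are Euclidean
on z-scored variables (an explicit choice: unstandardized clinical scales
would let the largest-variance instrument dominate). Both r and r² are
reported since only r² is conventionally quoted and the sign is otherwise
lost.

The regression screen fits one simple OLS per (species, clinical variable)
pair, retaining pairs with R² strictly > 0.55 and p < 0.05. No multiplicity
correction is applied to the retention rule — mirroring the screening
convention this pipeline reproduces — but a Benjamini–Hochberg column is
emitted alongside for the reader.

ROC analysis is the empirical curve with AUC equal to the Mann–Whitney
statistic scaled by n₁n₀ (ties count ½). Classification cutoffs of 0.65
(clinical features) and 0.70 (microbial features) are applied to min-max
scaled scores; cutoffs and scaling live in the run config.

## Classifier

Features are standardized species abundances plus clinical parameters;
subjects are split 60/20/20 into stratified shuffled train/validation/test
sets, with the scaler fit on the training partition only. The network is a
single 16-unit ReLU hidden layer with a logistic head, trained by
adaptive-moment gradient descent with early stopping on validation
log-loss (patience 30, max 400 epochs) and restored to its best epoch.
Architecture and schedule are exposed; the defaults are the smallest
configuration that reliably separates the planted signal.

Feature contributions are model-agnostic permutation contributions: the mean
drop in test accuracy over 50 permutations of each feature column, floored
at zero and normalized to percentages summing to 100. This reproduces the
*artifact* of a percentage-contribution chart without game-theoretic
attribution; it is a behavioral substitute, not the same algorithm, and is
documented as such.

## Two-latent-variable structural model

The model: each latent factor (unit variance, free factor correlation φ) is
measured by its own indicators, and the binary outcome regresses on both
factors with opposite expected signs. The outcome is fitted as numeric 0/1
inside the covariance structure under normal-theory ML — a documented
approximation to a categorical (weighted-least-squares) estimator; recovery
tests confirm that loading magnitudes and structural *signs* survive the
approximation when data come from the thresholded generative model.

Fitting minimizes F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − k by L-BFGS from three
seeded starts (guarding local minima); χ² = (n−1)F with
df = k(k+1)/2 − (2p+4) free parameters, GFI = 1 − tr[(Σ⁻¹S−I)²]/tr[(Σ⁻¹S)²],
and CFI against the independence baseline, clamped to [0,1]. Wald standard
errors come from the numerical Hessian of F. Factor sign indeterminacy is
resolved by flipping each factor so its first indicator loads positively;
for the intended orientation (positive loadings, positive lv1 effect) this
also leaves the lv1 structural coefficient nonnegative. Indicators are
z-scored internally so reported loadings are standardized.

Pruning refits after dropping, one at a time, the weakest indicator whose
Wald p ≥ 0.05 or |standardized loading| < 0.2, and halts with a warning
rather than reduce a latent below two indicators. The 0.2/0.05 thresholds
are documented defaults for an otherwise unspecified "remove weak
indicators" rule.

Factor scores use the regression method, Cov(η, z)Σ⁻¹(z − z̄), which has
mean zero over the fitting sample; score comparisons between groups use the
Wilcoxon rank-sum test.

Identifiability caveat: when all true loadings are zero the loading vector
itself is not identified (a single unit loading with vanishing residual
variance is likelihood-equivalent), so null-structure checks assert the
identified quantity — a near-diagonal model-implied covariance — rather
than the loadings.

## Synthetic cohorts

The generator emulates a case-control design of 40 cases and 40 matched
controls aged 60–85, of which 9 per group carry 16S-style species counts at
50,000 reads per sample over 53 species (magnitudes chosen to match a
typical elderly cohort's instruments and a desk-scale sequencing depth).

* **Hormones**: AG is lognormal (baseline median 0.58 ng/mL, log-sd 0.45)
  with the case group shifted by a configurable Cohen's d **on the log
  scale** (default 0.631, the design effect size); UAG and insulin are
  group-neutral. Calibration tests therefore run the Welch test on log-AG,
  where the planted d is exact: the null rejects at ≈5% and d = 0.631
  rejects at ≈80%, reproducing the design power empirically.
* **Counts**: log-basis abundances are multivariate normal with unit
  variances and a configurable correlation matrix (positive-definiteness
  checked, offending pair named), closed to proportions by softmax and
  sampled multinomially — exactly the logistic-normal model SparCC assumes,
  which makes the planted basis correlations the recoverable target.
  Differential taxa get ±lfc/2 group-specific mean shifts.
* **Clinical scores**: group-shifted normals truncated to instrument ranges
  (MMSE/MoCA 0–30, GADL 0–27, HADS 0–21).
* **Factor structure**: `generate_factor_cohort` draws two independent
  standard-normal factors, builds indicators as loading·factor + residual
  (residual sd defaults to √(1−λ²) so planted loadings are directly the
  standardized loadings), and thresholds b₁η₁ + b₂η₂ + logistic noise at
  zero for the binary outcome. The cohort's group label is exogenous (fixed
  group sizes) and deliberately decoupled from the factor model: coupling
  them would confound the planted hormone effect with outcome-dependent
  selection and break the null calibration the generator must support.

What passing tests on these cohorts do **not** show: real 16S data have
sequencing error, chimeras, taxonomic misassignment, overdispersion beyond
the logistic-normal, and covariate structure (diet, medication) that the
generator does not emulate; recovery results here certify the estimators,
not the biology.

## Simulation sizes and numerical choices

Null calibrations use 200 replicate datasets (Welch on full 80-subject
cohorts; PERMANOVA on 6-vs-6 designs where the 924-split null is enumerated
exactly; Mantel at n = 10 with 199 permutations). The latent-model pattern
check uses 200 replicate cohorts of 80 subjects. These sizes give
Monte-Carlo standard errors of ~1.5 percentage points on a 5% rate while
keeping the whole suite fast on a single CPU.

Tolerances: SIMPER identity to 1e-9; fit-index cross-evaluation to 1e-6;
PCoA Euclidean-embedding reproduction to 1e-9; permutation tests compare
statistics with a 1e-12 slack so ties count as exceedances. Degenerate
inputs (zero-variance groups, zero-total samples, edgeless graphs, constant
distance matrices, sub-minimum taxon counts) raise informative errors or
produce flagged missing values as documented per module.

## Known limitations

* The SEM outcome is fitted as numeric 0/1; structural coefficient
  *magnitudes* are attenuated relative to a categorical estimator and only
  their signs and the score-comparison pattern are interpreted.
* SparCC edge selection uses a magnitude threshold, not bootstrap
  significance; bootstrapped edge p-values are out of scope.
* The pipeline's default SEM specification (top differential species from
  SIMPER, plus age and AG on the second factor) is a heuristic for demo
  runs; real analyses should supply indicator lists in the config.
* Mantel/OLS screens are reported uncorrected by design; the BH column is
  informational.
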