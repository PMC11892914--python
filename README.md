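# gutbrain

A tested Python implementation of a gut-microbiome / acylated-ghrelin /
cognition analysis pipeline for case-control dementia cohorts, built so
every stage is exercisable on synthetic cohorts with planted, recoverable
structure.

## Who this is for

Microbiome and gut-brain-axis researchers who want the full analytic chain —
hormone indices, diversity statistics, compositional co-occurrence networks,
association screens, a neural-network classifier, and a two-latent-variable
structural model — as reusable, seedable library functions rather than a
one-off script pile, plus a cohort simulator for method validation when raw
cohort data are unavailable.

## What it computes

* **Ghrelin indices** — the AG/UAG ratio and the age-adjusted ghrelin ratio
  `AAGR = 6 + log10(AG/UAG) − age/10` (AG/UAG in ng/mL, age in years), with
  Welch/Student t and exact Wilcoxon rank-sum group comparisons, and
  noncentral-t power for a two-sample design.
* **OTU processing** — species filtering (total count strictly > 10),
  per-sample closure to relative abundances, the top-15
  abundance-vs-incidence core-microbiota summary (incidence = share of a
  group's samples where a species exceeds 1% abundance), and the per-sample
  ln(Firmicutes/Bacteroidetes) ratio.
* **Diversity** — richness, Shannon, Gini-Simpson, Pielou; Bray-Curtis
  `BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`; classical-scaling PCoA; one-way PERMANOVA
  (pseudo-F, permutation p, enumerated exhaustively for small designs);
  SIMPER decomposition of mean between-group dissimilarity into additive
  per-species contributions.
* **Co-occurrence networks** — iterative SparCC basis correlations (20
  Dirichlet-resampled iterations, median-aggregated), signed weighted
  networks over taxa with total abundance > 10, Louvain communities,
  per-community representative species (top-20 rule), and keystone screening
  by differencing normalized degree centralities between the control and
  case networks with Tukey-fence outlier flagging.
* **Association screens** — Mantel tests between species Bray-Curtis and
  z-scored Euclidean clinical distances (exhaustive for n ≤ 7), a per-pair
  OLS screen retaining R² > 0.55 associations, and ROC/AUC analysis with
  configurable cutoffs (0.65 clinical, 0.70 microbial).
* **Classifier** — a small MLP (adaptive-moment optimizer, early stopping on
  validation loss) over standardized abundances + clinical features with
  stratified 60/20/20 splits and permutation-based percentage feature
  contributions summing to 100%.
* **Latent structural model** — maximum-likelihood fit of two latent
  factors with opposite-signed effects on the binary dementia outcome,
  indicator pruning, χ²/df, GFI, CFI, regression-method factor scores, and
  Wilcoxon comparison of scores between groups.
* **Synthetic cohorts** — a logistic-normal/multinomial count generator
  with plantable basis correlations and differential taxa, group-shifted
  lognormal hormones, instrument-range clinical scores, and a two-factor
  generative twin of the structural model; all byte-reproducible under a
  fixed seed.

## Worked example

```python
from gutbrain.clinical_stats import ghrelin_indices, power_two_sample_t
from gutbrain.synthetic_data import CohortConfig, generate_cohort
from gutbrain.otu_processing import filter_by_total, relative_abundance
from gutbrain.diversity import bray_curtis_matrix, permanova, simper

idx = ghrelin_indices(ag=0.97, uag=0.021, age=66.2)
print(f"AG/UAG ratio = {idx.ratio:.2f}, AAGR = {idx.aagr:.3f}")
print(f"planned power at d=0.631, n=40/group: {power_two_sample_t(0.631, 40):.3f}")

cfg = CohortConfig(seed=1, differential_taxa={"sp001": 1.5, "sp002": -1.5})
cohort = generate_cohort(cfg)                  # 40+40 subjects, 9+9 with 16S
filtered = filter_by_total(cohort.otu, min_total=10)
props = relative_abundance(filtered)
dm = bray_curtis_matrix(props.T)
res = permanova(dm, filtered.sample_group.values, n_perm=999, seed=0)
print(f"retained taxa: {len(filtered.taxa)}; "
      f"PERMANOVA pseudo-F = {res.pseudo_F:.2f}, p = {res.p_value:.3f}")
for taxon, row in simper(props.T, filtered.sample_group.values).head(3).iterrows():
    print(f"SIMPER {taxon}: {row['percent']:.1f}% of between-group dissimilarity")
```

prints

```
AG/UAG ratio = 46.19, AAGR = 1.045
planned power at d=0.631, n=40/group: 0.796
retained taxa: 53; PERMANOVA pseudo-F = 2.10, p = 0.028
SIMPER sp036: 25.4% of between-group dissimilarity
SIMPER sp018: 9.5% of between-group dissimilarity
SIMPER sp020: 8.1% of between-group dissimilarity
```

The AAGR of 1.045 places this subject in the elevated-ghrelin range typical
of cases; the 0.796 power is the design value for detecting a d = 0.631
group difference with 40 subjects per arm; and the PERMANOVA p below 0.05
reflects the two differential taxa planted in the simulated cohort, whose
community shift the top SIMPER species absorb.

A full configured run (all stages, TSV/JSON reports, GraphML networks) is
available from the command line:

```bash
gutbrain run --seed 7 --out results_demo          # synthetic demo cohort
gutbrain simulate --seed 5 --out cohort_demo      # write cohort files only
gutbrain sem --config my_run.yaml --out sem_out   # structural model stage
```

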