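# Methods

`micronetfun` re-implements, end to end, an analysis chain that links soil
microbiome richness and association-network complexity to ecosystem
multifunctionality in a taxon-removal experiment.  This note records the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic-data experiments do and do not demonstrate.

## The experimental design being emulated

The target design is a soil-diversity gradient: a common soil inoculum is
passed through progressively finer filters, producing six treatment levels
in which progressively more taxa are excluded, down to a near-sterile
control; each level is replicated (8 microcosms per level, 10 for the
sterile control, n = 50).  Bacterial (16S) and fungal (ITS) OTU tables are
profiled per microcosm, and ten ecosystem functions are measured: N and P
uptake by forbs, legumes and grasses, litter decomposition, N leaching,
P leaching and N₂O emission.  The last three are *loss-type* functions —
high values mean nutrient loss — and are sign-inverted before any aggregate
is formed.

## Synthetic data generator

The generator produces datasets with the statistical structure the analysis
assumes, plus the planted ground truth every downstream stage is scored
against.

**Association structure.** Taxon dependence is modeled with a latent
Gaussian copula: a sparse precision matrix Ω over all p OTUs is planted by
assigning off-diagonal entries of magnitude `edge_strength` (default 0.35,
on the partial-correlation scale; 70% of edges positive) to a uniformly
random edge set of the requested density, then enforcing positive
definiteness by diagonal loading.  If the loading required would shrink the
planted partial correlations below 0.02, the requested density is too high
for the dimension and the generator refuses.  Latent log-abundances are
multivariate normal with the correlation implied by Ω⁻¹.  This matches the
generative assumption of neighborhood-selection graph estimators, so graph
recovery is a well-posed question.

**Taxon loss.** A single random taxon order is drawn; level k retains the
first ⌈retention_k·p⌉ taxa, giving nested level masks (the mesh-filtering
design: anything absent at a coarse level is absent at all finer levels).
Retention defaults are (1.0, 0.8, 0.6, 0.4, 0.2, 0.05); the "sterile" level
keeps a 5% rump rather than literally nothing so downstream indices stay
defined.  Within-treatment richness variance is controlled by a small
per-replicate detection dropout (default 0.05 per taxon), a free parameter
of the design that real data would fix.

**Counts.** Per sample, the present taxa's latent log-abundances (plus
lognormal baseline heterogeneity, SD 1) pass through a softmax and a
multinomial draw at `sequencing_depth` (default 5000 reads), giving
compositional counts whose rows sum to the depth.

**Functions.** Each function gets `supporters_per_function` (default 6)
supporter taxa drawn from those retained at gradient level 3 (retention
0.6) — taxa detectable across most of the design, as function-supporting
taxa identified from data necessarily are.  Per-taxon weights are
proportional to signed Uniform(0.5, 1.5) draws (80% positive) and are
normalized so the planted signal has total SD `effect_size`; the function
value is that weighted sum of z-scored relative abundances plus
Normal(0, `noise_sd`) noise.  At the defaults (effect_size 1, noise_sd 0.5)
an oracle regression on the true supporters attains R² ≈ 0.8 — a strong but
noisy signal.  Weights are defined on the direction-adjusted scale;
loss-type functions store the negated value.  Because supporters vanish
along the gradient, function levels decline with taxon loss, which is
exactly the positive diversity–functioning coupling the pipeline is meant
to detect.

**What the generator does not emulate:** phylogenetic structure, taxon
interactions beyond pairwise partial correlations, overdispersion beyond
multinomial noise, non-linear or interactive effects of taxa on functions,
and spatial/temporal structure.  Passing recovery tests therefore shows the
estimators work when their generative assumptions hold at this scale — not
that the biological conclusions of any particular real dataset are correct.

## Preprocessing

Counts are converted to proportions of total reads per sample; OTUs with
mean proportion below `mean_abundance_threshold` or detected in fewer than
`min_prevalence` samples are removed (both criteria computed on the
unfiltered proportion table, making the filter idempotent); retained
columns are z-scored to overall mean 0, unit sample variance.  The default
mean-abundance cutoff is 1e-4 (0.01%): a literal 1% mean-abundance cutoff
would discard all but a handful of OTUs in any amplicon table and is kept
only as a selectable option.  The prevalence default of 6 removes OTUs
present in five or fewer replicates, counted over all samples (a
per-treatment variant is not implemented; the scoping is ambiguous in this
design and the global count is the conservative reading).

## Network inference

The meta-network over all OTUs (both kingdoms, one matrix) is estimated by
Meinshausen–Bühlmann neighborhood selection: each OTU is lasso-regressed on
all others.  Penalties are scaled so that a single-predictor solution is the
soft-thresholded sample correlation, and the path has 50 log-spaced values
from λ_max (the largest absolute off-diagonal correlation) down by a factor
of 0.01.

The penalty is chosen by StARS stability selection: 100 random subsamples
of size b = min(⌊10√n⌋, ⌊0.8n⌋) (the method's canonical b(n) rule, capped
so small designs still hold out samples — at n = 50 both rules give b = 40),
the graph re-estimated per subsample over the path, per-edge instability
2θ̂(1−θ̂) from selection frequencies θ̂, averaged over all possible edges,
monotonized along the path, and the densest graph whose monotonized
instability stays ≤ 0.05 (the published default) selected.  If no penalty
qualifies, the minimal-instability penalty is used with a warning.  The
final adjacency is the OR-symmetrized neighborhood graph on the full data
at the selected penalty, with per-edge subsample frequencies kept as
stability scores.  A centered-log-ratio transform of the proportion table
is available upstream for users who prefer the compositional correction,
but is off by default to match the standardized-proportions procedure.

Connectedness is reported in the ordered-pair convention —
100 × (2 × unordered links) / p² — matching connectedness figures quoted
with a p² denominator (e.g. 70,830 of 1814² = 3,290,596 possible links is
2.2%).

## Function-supporting taxa

Per function, an elastic net over all OTUs simultaneously: mixing parameter
α from 0 to 1 in steps of 0.01; per α a 100-value log-spaced λ path from
λ_max(α) (for α = 0 the path is anchored at α = 0.001's λ_max, since exact
ridge has no finite λ_max) down by a factor 1e-3; leave-one-out
cross-validation; the global minimum-MSE (α, λ) refit on all data.  Exact
MSE ties resolve to the larger α, then the larger λ (parsimony).  Nonzero
coefficients classify taxa as supporting (positive after direction
adjustment) or inhibiting.  A per-taxon randomization test (observed
Pearson correlation vs a permutation null, central 95% range) is the
independent single-taxon cross-check.

A calibration caveat, measured here and reproducible with any CV
implementation: minimum-MSE selection over a 10,100-cell grid over-selects.
On planted-signal scenarios it recovers essentially all supporters but also
admits substantial numbers of spurious taxa (false-positive rates around
0.2–0.3 at n = 50, p = 100), and on pure-noise responses near-ridge cells —
where every coefficient is nonzero — can win the CV minimum by a percent or
two of MSE.  This is the documented behavior of CV-minimum penalized
selection, not an artifact of this implementation (the LOO MSE surface here
matches scikit-learn's to five decimals); interpreting selected-taxon lists
should lean on the randomization cross-check and on effect sizes, not on
selection alone.

## Diversity, redundancy and complexity indices

* **Redundancy** — per sample, the number of detected taxa supporting each
  function, averaged over functions.
* **Functional uniqueness** — Rao's quadratic entropy Q = Σᵢⱼ pᵢpⱼdᵢⱼ times
  the inverse Simpson index D = 1/Σpᵢ², with abundances renormalized over
  taxa having a support profile and dᵢⱼ the Jaccard dissimilarity of binary
  support profiles (the index needs a trait distance; Jaccard is the natural
  choice for binary profiles).  For m equally abundant, maximally distinct
  taxa the index equals m − 1.
* **Combination coverage** — share of the community needed to support every
  function in a k-subset, averaged over subsets (exhaustive up to 500
  subsets, seeded random sampling beyond).
* **Linkage density ("complexity")** — links per OTU in the sample's induced
  subnetwork, for bacteria–bacteria, fungi–fungi, bacteria–fungi and all
  pairings.  The cross-kingdom and "all" denominators are all present OTUs.
* **Functional complexity** — linkage density restricted to present
  supporting taxa; by default a link counts only when both endpoints
  support a common function ("strict"), with a relaxed any-function variant
  for pooled displays.

## Multifunctionality and statistics

The averaging index is the per-sample mean of direction-adjusted, z-scored
functions (grand mean 0 by construction).  The multidimensional index — the
named construction is not fully specified in the source literature chain,
so the implementation here is a documented choice — is a PCA on the same
matrix: per-sample scores summed over all axes with eigenvalue-share
weights, each axis oriented to correlate non-negatively with the averaging
index.  Its only asserted property is the one that can be checked: a high
correlation with the averaging index (rank-1 function tables give |r| = 1;
the default generator gives r ≈ 0.9).

Regressions z-score both variables, so the standardized slope (SES) equals
the Pearson correlation; detrended variants residualize both variables on a
covariate (typically combined richness — the mean of per-kingdom richness
each min–max scaled to [0, 1]) before regressing.  Variance partition uses
sequential (Type-I) sums of squares computed by explicit nested
least-squares fits, in the order block, richness, average supporters,
uniqueness, functional complexity, then the treatment factor (with an
optional sterile-vs-rest contrast before it); %SS including block and
residual sums to 100 by construction.  Treatment comparisons use one-way
ANOVA plus Tukey HSD at 0.05 with a compact letter display (contiguous-run
insert–absorb on means sorted descending).  P-values are two-sided and
uncorrected throughout, matching the reporting style of the analysis
surface.

## Numerical choices

* All lasso/elastic-net problems are solved by an in-package coordinate
  descent on normalized Gram matrices with active-set updates and warm
  starts, validated against closed forms, a proximal-gradient optimizer and
  scikit-learn.  Final refits use coefficient tolerance 1e-10; CV-surface
  and path fits use 1e-4–1e-5 with capped passes, which is far below the
  noise level of the quantities they feed.
* l1-dominated paths are truncated once the active set reaches 90% of the
  training-sample count (the saturation/interpolation regime, where
  coordinate descent stalls and which can never win CV-minimum selection);
  the last solved solution is carried forward.
* LOO folds re-center via rank-one Gram downdates; λ paths are computed on
  the full data and shared across folds (the glmnet convention).
* Ties, degenerate inputs: empty samples, constant OTU columns, constant
  functions and rank-deficient ANOVA terms raise or warn explicitly rather
  than propagating NaNs; zero-node pairings yield density 0 with a warning.

## Problem sizes used in the shipped experiments

The shipped recovery experiments run at the study's own design scale
(n = 50 samples, 60 + 40 OTUs, 6 levels) for the pipeline checks, with five
seeded replicate runs; graph recovery is scored in the estimator's clean
regime (p = 50, density 0.02, n = 200 latent-Gaussian samples, five seeds);
byte-level determinism is exercised at a reduced scale.  These sizes were
chosen so the whole battery runs comfortably on a single CPU while keeping
every procedure at its stated grid resolution (50-λ StARS path with 100
subsamples; 101-α × 100-λ LOO elastic-net grid).

## Known limitations

* The multidimensional multifunctionality construction is one reasonable
  reading of a name, validated only through its correlation with the
  averaging index.
* Minimum-MSE elastic-net selection over-selects (see above); supporter
  lists are best treated as high-sensitivity candidate sets.
* StARS instability is computed from OR-symmetrized subsample graphs; AND
  symmetrization is available but changes edge counts.
* The generator's compositional closure induces weak global negative
  dependence between taxa beyond the planted graph; at the default density
  this is negligible for the indices but visible to the graph estimator on
  count-derived (as opposed to latent-Gaussian) data.
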