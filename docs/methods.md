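# Methods

## Model and assumptions

A tumor specimen is modelled as a mixture of cell populations.  Each
somatic mutation is carried by a fraction of the tumor cells (its
cancer-cell fraction, CCF); the specimen contains a fraction `purity` of
tumor cells; and the mutated locus is diploid and copy-neutral.  Under
these assumptions the expected VAF of a mutation with CCF `c` is
`purity · c / 2`, and dividing the observed VAF by purity yields an
estimate of `c / 2` on a common scale across samples.  Mutations in
copy-altered regions violate the `/2` and are removed rather than
modelled; mutations covered by no segment are also removed, because
unknown copy status is not evidence of neutrality.

The analysis deliberately restricts itself to "more functional" (MF)
point mutations — PolyPhen-2 probably/possibly damaging missense
changes — on the grounds that these are the mutations most likely to be
under selection during tumor evolution.  Unannotated mutations count as
non-MF: the MF definition is a strict whitelist of the two damaging
classes.

### The three shape parameters

For a sample's vector of purity-adjusted VAFs (minimum two mutations):

* `m_count = log2(n)` — burden on a doubling scale.
* `m_math = 1.4826 · MAD / median` — dispersion relative to location.
  1.4826 is the usual consistency constant making the MAD estimate a
  normal standard deviation.  The score is kept on the ratio scale
  (≈ 0.1–0.5 for real tumors); a `percent` flag multiplies by 100 for
  compatibility with the original head-and-neck MATH formulation.
  It is undefined (error) when the median VAF is 0.
* `m_peak` — the arg-max over [0, 1] of a Gaussian KDE of the VAFs.
  Kernel and bandwidth are not canonical anywhere, so the package uses
  scipy's `gaussian_kde` with Silverman's rule-of-thumb bandwidth and a
  512-point grid on [0, 1]; all three choices are exposed in config.
  The grid spans [0, 1] rather than the data range so peak positions
  are comparable across samples.  Ties resolve to the smallest grid
  value; a zero-variance vector returns its common value directly.

## Clustering

PCA is fitted to the three parameters after standardization (default
on: `m_count` spans ≈ 1–10 while the other two live in [0, 1], so
unscaled PCA would be dominated by burden).  Component signs are fixed
so each component's largest-magnitude loading is positive, making fits
reproducible.  Clustering runs on the first two component scores —
which in practice carry > 90% of standardized variance — with full
3-D clustering available as an option.

K-medoids uses the PAM algorithm under squared Euclidean distance:
greedy BUILD initialisation, then steepest-descent SWAP to a local
optimum.  All ties break to the lowest point index, so the fit is a
pure function of the input order; the `seed` argument exists for
interface symmetry only.  Because SWAP is a local search it can miss
the global optimum on small instances; whenever the entire search space
is small (`C(n, k) ≤ 3000` candidate medoid sets) the optimum is found
by exhaustive enumeration instead, so small problems are always solved
exactly while cohort-scale problems use PAM.  `k = 5` is the analysis
default; `choose_k_diagnostics` reports cost and mean silhouette over a
k range but performs no automatic selection, since the cluster count is
an interpretability decision.

After fitting, clusters are renumbered by descending median `m_count`,
then descending median `m_peak`.  This approximates the canonical 1–5
archetype ordering (1–2 high burden, 3–5 low) but is only an
approximation: when burden medians nearly tie, neighbouring low-burden
clusters can swap numbers.  Quantitative checks therefore compare
partitions by adjusted Rand index, not by label equality.

## Survival analysis

Overall survival in days with death as the event.  Clusters with fewer
than 10 samples in a cancer type are excluded before fitting.  Cluster
membership enters as indicator variables against a reference cluster;
the model is fitted by lifelines' Cox partial likelihood with the Efron
tie approximation, and Wald 95% CIs and p-values are reported per
cluster, plus a scaled-Schoenfeld proportional-hazards test per term.
Optional covariates (age; gender 0/1; stage binarised I/II vs III/IV,
configurable to 4-level) use complete-case analysis with the dropped
count recorded.  A non-reference cluster with zero events produces a
numerically unstable HR and is flagged rather than hidden.

The reference cluster is selected by refitting with every eligible
candidate as reference and choosing the one that yields HR > 1 against
all others — the uniformly lowest-hazard group.  Within one joint model
this is equivalent to the smallest cluster coefficient and always
exists up to ties; the selection API nevertheless accepts arbitrary
tables of pairwise fits, where inconsistent HRs can leave no qualifying
cluster — it then falls back to the cluster minimising its worst
inverse HR (lowest id on ties) and flags that the rule did not hold.

## Cohort statistics

* Mutation spectrum: the 12 ordered substitutions are collapsed onto the
  pyrimidine strand (G>A ≡ C>T etc.), giving six classes whose fractions
  sum to 1.
* CNV abundance: fraction of the segment-covered genome with
  `|log2 ratio| > 0.2` (strict inequality, so the copy-neutral window
  boundary is not "altered"); missing when no segments exist.  The
  threshold mirrors the copy-neutral window and is configurable.
* Per-gene MF frequency: fraction of a cluster's samples with ≥ 1 MF
  mutation in the gene — sample-level indicator, so hypermutated samples
  do not inflate it.
* Categorical comparisons compute chi-square expected frequencies first
  and switch to Fisher's exact test when any expectation is ≤ 5.  For
  2×2 tables Fisher is exact (scipy); for larger tables the p-value is
  estimated by Monte-Carlo sampling of margin-preserving tables
  (`scipy.stats.random_table`, 200,000 draws, fixed seed, add-one
  correction), since exhaustive enumeration of r×c tables is
  infeasible in general.
* Continuous traits use one-way ANOVA followed by Tukey's HSD.
* p-values within a comparison family are Benjamini–Hochberg adjusted.
  Note that BH is not idempotent in general (a second pass rescales by
  m/j again); only flat adjusted vectors re-adjust to themselves.

## Decision-tree classifier

A self-contained CART: Gini impurity, thresholds at midpoints between
consecutive sorted unique feature values, values exactly at a threshold
routed to the right (≥) branch, ties in impurity decrease broken by
lower feature index (m_peak < m_count < m_math) then lower threshold —
so a fit is deterministic given the input order.  Growth stops at
purity or `min_leaf = 5`.

Pruning follows the rpart convention: the weakest-link value of an
internal node is `g(t) = (R(t) − R(T_t)) / (|leaves(T_t)| − 1)` with R
the training misclassification count, and subtrees are collapsed while
`g < cp · R(root)` (`cp = 0.1` default; absolute-risk pruning, i.e.
scaling by n instead of root risk, is available).  With two balanced
classes this keeps a split only if it removes ≥ 10% of the root's
errors — enough to prune label-noise trees to the root at realistic n,
while a borderline chance split at small n can legitimately survive.

Accuracy is estimated by stratified 10-fold cross-validation (per-fold
fit on 9/10, evaluation on 1/10; mean, SD and max reported).  When a
class has fewer members than folds, stratification is impossible and a
plain shuffled split is used, with a warning.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
per sample, an archetype-specific mixture of subclones (CCF, weight)
with Gaussian CCF spread, purity ~ U(0.5, 0.9), read depth ~
Poisson(120) floored at 20, alt reads ~ Binomial(depth, purity·CCF/2).
Around the signal it plants what the filters must remove: 15% of
mutations carry a benign PolyPhen class, 2% get sub-threshold depth
(U{5..19}), and 8–20% of the abstract 10-Mb genome (10 equal segments)
is copy-altered with mutations placed uniformly, so a matching share
lands in excluded territory.  Substitution classes are drawn from a
per-archetype six-class spectrum (archetype 1 is C>T-enriched, mimicking
a UV-like clonal trunk); survival is exponential with per-archetype
hazard multipliers (1.5, 1.0, 2.0, 2.5, 1.6) over a 1/1500-per-day
baseline and independent exponential censoring (≈ 50% censoring), so
archetype 2 is the lowest-hazard reference under the selection rule.
Ages are N(63, 11) clipped to [25, 90]; gender, stage and smoking are
categorical draws.  Everything flows from one numpy Generator, so a
cohort is a pure function of (spec, seed) and written files are
byte-identical across reruns.

The five default archetypes are calibrated to canonical per-cluster
medians of (m_peak, m_count, m_math): subclone CCFs sit at twice the
target m_peak; mixture weights and CCF spread set the target m_math
given binomial read noise; and emitted mutation counts for archetypes
1, 2, 4 and 5 are inflated for the expected loss to decoys and altered
segments so the *filtered* MF count matches the m_count target
(archetype 3 keeps the nominal median of 16 = 2⁴ emitted mutations,
accepting a ≈ −10% m_count bias).  On the default 500-sample cohort the
recovered medians sit within ≈ 12% of all 15 targets and k-medoids
recovers the archetype labels with ARI ≈ 0.82.

What the generator does **not** emulate — and hence what passing tests
do not show about real tumors: trinucleotide mutational-signature
context, genomic position effects, copy-number-driven VAF distortion
beyond exclusion, purity estimation error, inter-cancer-type structure
(one synthetic cancer type by default), and non-exponential hazards.
Cohort proportions are equal fifths so every archetype is equally
testable, unlike real cohorts where archetype prevalence varies by
cancer type.

## Pipeline and reproducibility

`run_pipeline` chains filter → shape → cluster → survival → stats →
tree, writes every report TSV and model JSON under the output
directory, and records a manifest with the config, derived seeds,
per-stage counts and SHA-256 of every output.  The single config seed
fans out per stage via `SeedSequence(seed, spawn_key=(stage_index,))`
collapsed to 31 bits, so running a stage in isolation (CLI subcommands)
reproduces its in-pipeline randomness exactly.  Numerical results in
this package's documentation and acceptance report are computed at
n = 500 samples, the default cohort size, which keeps a full pipeline
run in seconds while giving ≈ 100 samples per archetype.

## Known limitations

* The purity adjustment `min(raw/purity, 1)` is the simplest scaling;
  it ignores purity-estimate uncertainty and local copy number (the cap
  count is reported, and an uncapped variant is available).
* The KDE bandwidth choice affects m_peak for small mutation counts;
  with n near the minimum of 2 the "mode" is closer to a midpoint than
  a density peak.
* The canonical 1–5 cluster numbering after relabelling is heuristic;
  compare partitions with ARI.
* Monte-Carlo Fisher p-values carry sampling error ≈ 1/√draws; the
  fixed seed makes them reproducible, not exact.
* PAM beyond the exact-enumeration cap is a local optimiser; its cost
  is a certified local (not global) optimum.
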