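# vafshape

Multidimensional intratumor-heterogeneity (ITH) profiling from the shape
of somatic variant-allele-frequency (VAF) distributions.

## The problem

A tumor is rarely one clone.  As it evolves it accumulates subclones, and
the VAFs of its somatic mutations — the fraction of reads carrying each
variant — trace that history: clonal "trunk" mutations sit at high VAF,
subclonal "branch" mutations at low VAF.  One-dimensional ITH indices
(e.g. the MATH score alone) compress this structure into a single number
and lose the distinction between, say, a tumor with many clonal mutations
and one with few dispersed subclonal ones — architectures with very
different prognostic implications.

`vafshape` characterises each tumor's VAF distribution with three
parameters:

* **m_Peak** — the VAF at the maximum of a Gaussian kernel density
  estimate of the distribution (position of the dominant mode;
  ≈ CCF/2 of the dominant clone in a diploid, copy-neutral genome),
* **m_Count** — log₂ of the number of "more functional" (MF) mutations
  (PolyPhen-2 probably/possibly damaging),
* **m_MATH** — the MATH score,
  `1.4826 · median(|v − median(v)|) / median(v)`,
  the scaled MAD of the VAFs relative to their median.

Samples are embedded by PCA of the standardized parameter triples and
partitioned into **five archetypes** with PAM k-medoids (squared
Euclidean, first two components): (1) many mutations, mostly clonal;
(2) many mutations, subclone-heavy; (3) few mutations, tight clonal;
(4) few mutations with a selected mid-CCF subclone; (5) few dispersed
low-CCF mutations.  Cluster-level prognosis is compared with
Kaplan–Meier curves and Cox proportional-hazards models (clusters with
< 10 samples per cancer type are excluded; the reference cluster is the
one with HR > 1 against all others), cluster genetics with the six-class
mutation spectrum, per-gene MF frequencies and CNV abundance, and the
clustering is distilled into a CART decision tree (CP = 0.1, 10-fold CV)
that assigns new tumors from their parameter triple alone.

Mutations enter the analysis only if they are single-nucleotide
substitutions with total depth ≥ 20, PolyPhen-2 damaging, inside a
copy-neutral segment (|log₂ ratio| ≤ 0.2, ≥ 10 probes), and their VAFs
are divided by tumor purity (capped at 1).  Samples need ≥ 2 surviving
MF mutations.

Because the analysis was designed for controlled-access tumor cohorts, a
**synthetic cohort generator** is part of the package: it simulates
subclone mixtures sampled to binomial read counts at configurable depth
and purity, plants benign and copy-altered decoys the filters must
remove, and attaches cluster-dependent exponential survival — so every
stage is testable against known ground truth.

## Worked example

```bash
vafshape simulate --n-samples 200 --seed 1 --out-dir cohort
vafshape run --mutations cohort/mutations.maf.tsv \
             --segments cohort/segments.seg.tsv \
             --clinical cohort/clinical.tsv \
             --seed 1 --out-dir results
```

`results/shape_params.tsv` holds one parameter triple per sample:

```
sample_id   cancer_type  m_peak        m_count       m_math        n_mf_mutations
SYN-0000    SYNTH        0.4187866928  3             0.1317232619  8
SYN-0001    SYNTH        0.1115459883  4.087462841   0.4998845435  17
SYN-0002    SYNTH        0.3659491194  5.906890596   0.1972686659  60
```

SYN-0001, for instance, is a low-peak, high-MATH tumor: few mutations,
dispersed at low VAF — archetype-5 territory.  `results/tree_rules.txt`
shows the fitted classifier (burden first, then peak position):

```
split on m_count @ 5.042
  m_count < 5.042 split on m_peak @ 0.3659
    m_peak < 0.3659 split on m_peak @ 0.2114
      m_peak < 0.2114 -> cluster 3 (n=41, purity=0.854)
      m_peak >= 0.2114 -> cluster 4 (n=44, purity=0.932)
    m_peak >= 0.3659 -> cluster 5 (n=38, purity=1.000)
  m_count >= 5.042 split on m_peak @ 0.2886
    m_peak < 0.2886 -> cluster 2 (n=45, purity=1.000)
    m_peak >= 0.2886 -> cluster 1 (n=32, purity=1.000)
```

and `results/hr_adjusted.tsv` the covariate-adjusted hazard ratios
against the automatically selected reference cluster (here cluster 2,
the lowest-hazard group, so every HR > 1):

```
cancer_type  cluster  reference  hazard_ratio  ci_low  ci_high  p_value
SYNTH        1        2          1.542         0.817   2.914    0.182
SYNTH        3        2          2.440         1.344   4.431    0.003
SYNTH        4        2          2.854         1.597   5.098    4.0e-04
SYNTH        5        2          4.033         2.267   7.175    2.1e-06
```

The run manifest reports 200/200 samples profiled and a 10-fold CV
classifier accuracy of 89.9% on this cohort.  Other subcommands:
`profile`, `cluster`, `survive`, `classify` run single stages on each
other's outputs; `vafshape run --config config.yaml` drives everything
from a YAML file (defaults reproduce the canonical thresholds).

## Layout

```
src/vafshape/
  io_formats.py       MAF-like / SEG / clinical TSV readers and writers
  mf_filter.py        depth, functional-class, copy-neutral, purity-VAF chain
  shape_params.py     m_peak, m_count, m_math and cohort profiling
  cluster.py          PCA embedding, PAM k-medoids, model persistence
  survival.py         Kaplan-Meier, Cox HRs, reference-cluster selection
  cohort_stats.py     spectrum, CNV abundance, gene frequencies, group tests
  tree_classifier.py  CART with rpart-style CP pruning and stratified CV
  synthetic.py        calibrated five-archetype cohort generator
  pipeline.py / cli.py / config.py   orchestration and CLI
docs/methods.md       model, assumptions, parameter choices, limitations
```
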