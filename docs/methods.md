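# Methods

## The analysis model

The unit of observation is the number of shotgun reads from one dataset
assigned to one COG (Cluster of Orthologous Groups of proteins). After
rarefaction to a common depth `n`, the counts of a dataset are treated as
a multinomial draw over COGs, so comparisons between two datasets reduce
to 2×2 tables (COG count vs remaining reads) and exact conditional tests
apply without a dispersion estimate.

### Exact count tests

`fisher_exact_2x2` conditions on all table margins; the two-sided p-value
follows the point-probability (minimum-likelihood) rule: the total
hypergeometric probability of every table whose point probability is at
most that of the observed table, with a relative tolerance of 1e-7 in the
comparison so that symmetric ties are always counted. Log-probabilities
are computed from log-gamma functions, and the screening path
(`fisher_exact_many`) evaluates all COGs of a dataset pair in one
vectorized sweep. `binomial_exact_counts` is the dispersion-free
alternative for a pair of libraries of known size: conditional on the
two-dataset total `t`, the first count is Binomial(`t`, n1/(n1+n2)) under
the null, with the same two-sided rule. Both tests are checked against
brute-force enumeration oracles in the test suite; a zero total carries no
information and is reported as p = 1.

### Rank-sum test

`ranksum_exact` uses pooled midranks and enumerates every assignment of
the pooled values into the two groups (for the survey's 3-vs-21 design,
C(24, 3) = 2024 assignments). The two-sided p-value is the exact
permutation probability of a rank sum at least as far from its null
expectation as the observed one; for tie-free data this equals the
classical two-tailed rule, and with ties it remains well-defined even
though the permutation distribution need not be symmetric. Beyond 10⁶
assignments the implementation falls back to a normal approximation with
tie correction and says so in the method string.

### Welch's t and FDR

The photic/aphotic core derivation uses Welch's unequal-variance *t* with
Welch–Satterthwaite degrees of freedom. Rows where both groups are
constant get p = 1 when the means agree (and are therefore never
significant) — the degenerate case a constant COG produces. All screening
stages adjust p-values with the Benjamini–Hochberg step-up procedure;
adjustment granularity is per column across all (COG, depth-pair)
hypotheses jointly for the depth screens (the more conservative choice;
the alternative granularities are not exposed), across COGs for the Welch
stage, and across candidates for the rank-sum stage.

## Pipeline decision rules

* **Zone labels.** A dataset is photic iff PAR at its depth is at least
  1% of surface PAR; measured PAR is used when available, otherwise
  Beer–Lambert decay `PAR(z) = PAR(0)·exp(−k z)` from the site's diffuse
  attenuation coefficient. The 1% fraction is a parameter
  (`photic_par_fraction`).
* **Depth-related COGs.** All depth pairs within a column are tested
  (4 depths → 6 pairs); a COG is depth-related if any pair's adjusted p is
  ≤ α (default 0.01). The global set is the intersection of the per-column
  sets; an optional presence filter additionally requires a nonzero count
  in at least one dataset of each column.
* **Clustering.** Average-linkage, Euclidean distance on row-Z-scored
  normalized abundances (n−1 denominator). Bootstrap support of a node is
  the percentage of COG-resampled replicate trees containing the node's
  exact leaf set; scipy's deterministic linkage resolves distance ties, so
  trees are reproducible for a given seed. Dendrograms export to newick
  with supports as internal node labels.
* **Ratio diagnostic.** log₂((mean photic-core abundance + c) /
  (mean aphotic-core abundance + c)) with pseudocount c = 0.5
  normalized-abundance units guarding zero means on sparse inputs.
  Reference bands are mean ± 2·SD of the reference columns' photic and
  aphotic ratios. A value within or beyond the photic band is photic,
  within or beyond the aphotic band is aphotic, anything else (including a
  value covered by both bands) is intermediate: the bands indicate
  enrichment, not intervals of exclusion. Reports carry both the log₂
  photic:aphotic and the linear aphotic:photic conventions, explicitly
  labeled, since both are in common use.
* **Core-derivation α.** The default is 1e-4. The screening literature
  this pipeline follows quotes both 0.05 and 1e-4 for this stage; the
  stricter value defines the reference core and the parameter
  (`alpha_core`) accepts either.
* **OMZ analysis.** The low-oxygen group is derived from metadata by a
  dissolved-oxygen cutoff (default 20 µmol·kg⁻¹) rather than hard-coded
  dataset names. Group I/II assignment formalizes the heatmap reading as
  a k = 2 cut of the members' average-linkage profile tree, with group I
  the group whose mean abundance in the low-O2 datasets is higher. When
  every significant COG shares one profile the cut is noise-driven, but
  group I remains the induced profile by construction.
* **Oxygen threshold.** An explicitly labeled change-point *estimate*:
  datasets are ordered by O2, every split between distinct O2 values is
  scored by the standardized mean difference (pooled-SD units) of the
  group-I mean abundance, and the best split's O2 gap midpoint is
  reported. The separation statistic accompanies the estimate; below 5.0
  pooled-SD units the estimate is flagged low-confidence, since smooth
  monotone trends reach ≈4 at their best split while a genuine switch
  scores far higher.
* **Taxonomy.** Sequence search and taxid resolution are upstream; the
  module consumes per-read best-hit tables. "Unidentified" means a
  missing phylum or superkingdom; those and Eukarya reads are discarded.
  Counts are raw, not normalized. Phyla are ranked by mean per-dataset
  total with lexicographic tie-breaks.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not sequencing itself (no read sequences, error models, or assembly).

Reference design: three reference water columns and one OMZ column of four
depths each, plus eight single-depth sites — 24 datasets, 12 photic / 12
aphotic under the 1%-PAR rule. The OMZ column has a shallow sunlit zone
(attenuation 0.12 m⁻¹, photic floor ≈ 38 m) and dissolved O2 falling to
25 / 11 / 4 / 3.2 µmol·kg⁻¹ at 50 / 85 / 110 / 200 m, so the three deep
OMZ datasets form the low-oxygen group under the 20 µmol·kg⁻¹ rule. The
remaining datasets span 30–210 µmol·kg⁻¹ with the first level above the
switch at 25 µmol·kg⁻¹, which fixes the bracketing gap for threshold
recovery.

Per dataset, expected composition starts from a shared lognormal base
(σ = 0.6, a moderate spread of COG abundances); photic markers (54) are
multiplied by the fold change (4) in photic datasets, aphotic markers (28)
in aphotic datasets, and oxygen markers (18) wherever O2 ≤ 11 µmol·kg⁻¹
(a hard switch — a logistic dose-response would blur the change point the
threshold estimator is meant to recover). Mixed-layer datasets (two
shallow OMZ-column depths and one deep two-layer-circulation site) use a
convex combination λ·photic + (1−λ)·aphotic with λ = 0.4, reproducing the
facultatively-photic intermediate ratio signature. The realized
composition of each dataset is a Dirichlet draw around its expected
composition (concentration 2×10⁵ ≈ 10% per-COG between-dataset noise),
and counts are one multinomial draw at a library size uniform in
50,000–60,000 — so rarefaction to the smallest library is always
exercised. Each read then receives a phylum from its COG class's profile:
photic markers 91% from two phyla (five phyla above a 1% share), aphotic
markers spread over ten phyla (all above 1%), plus 5% Eukarya and 2%
unidentified reads that the taxonomy stage must discard.

What the generator does **not** model: sequencing error and chimera
artifacts, genome linkage between COGs (counts are conditionally
independent given the composition), library-preparation batch effects,
gradual (non-switch) oxygen dose-responses, and within-site temporal
variation. Passing recovery tests therefore demonstrates that the
statistical machinery is correct and calibrated under the design's
assumptions, not that those assumptions hold for any particular ocean
survey.

The **calibration null** (`null_config`) removes all planted markers *and*
the Dirichlet noise (concentration 10¹²), leaving pure multinomial
counting noise with identical expected compositions. This is deliberate:
site-to-site compositional noise constitutes genuine abundance differences
between datasets, which the exact tests rightly detect; a false-positive
calibration must contain no true differences at all.

Rarefaction draws are made order-independent by canonicalizing each
dataset's reads lexicographically by COG id, assigning one uniform
priority per read, and keeping the `target` smallest — permuting the rows
of a count matrix permutes the subsampled output exactly.

## Problem sizes and reproducibility

Validation runs 20 replicate surveys of the full reference design (2,100
COGs × 24 datasets, ≈1.3 M reads each) for marker recovery, clustering,
ratio classification, threshold recovery and the taxonomy contrast, with
100 bootstrap replicates per dendrogram, plus 20 null surveys for
false-positive calibration and ≥10⁴ random tables per exact-test oracle
sweep. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; a configuration plus seed determines every
output byte. Library code never seeds implicitly.

## Known limitations

* The exact tests assume independent multinomial sampling within each
  dataset; residual overdispersion in real data (which the Dirichlet term
  emulates) makes pairwise screens anti-conservative — the intersection
  across columns and the strict core-stage α are the guards, not the
  pairwise p-values themselves.
* With three low-oxygen datasets the rank-sum test's smallest attainable
  two-sided p is ≈ 2/2024, bounding its power at stringent FDR levels.
* The oxygen-threshold estimator assumes one switch; staged or gradual
  responses yield a low separation statistic rather than a meaningful
  threshold.
* Bands from few reference datasets are noisy: a pure dataset has a
  few-percent chance of falling just outside its band, and the
  intermediate call should be read as "inconsistent with both references",
  not as a calibrated probability statement.
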