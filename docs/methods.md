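# Methods

`npdiv` models a question that natural product discovery programs face
when assembling screening libraries from culture collections: given a
set of microbial isolates organized into barcode clades (e.g. ITS
phylogeny) and profiled by LC-MS/MS, how much chemical diversity does
the collection hold, how is it distributed across genetic and chemical
groups, and how many isolates are needed to reach a stated fraction of
it? This note records the models, the defaults and why they were
chosen, and the limits of what the synthetic benchmark can show.

## Data model

A **feature** is a detected LC-MS component identified by its (m/z,
retention time) pair; the **feature table** holds nonnegative peak
areas for features × samples, where samples are replicate cultures of
isolates plus blank injections. All diversity analyses run on the
**incidence matrix**: binary presence of items (features, or scaffolds
after networking) per isolate. Incidence summaries follow the standard
notation: `T` sampling units (isolates), `T_i` the number of isolates
containing item i, `Q1`/`Q2` the items found in exactly one/two
isolates, `S_obs` the observed total.

## Preprocessing

The canonical order is blank filtering → total-ion-current (TIC)
normalization → replicate merging → binarization.

- **Blank rule (default `strict`)**: any feature with nonzero abundance
  in any blank is removed entirely. This is the categorical reading of
  standard practice; a fold-change mode (keep a feature when its
  maximum culture abundance is ≥ F × its maximum blank abundance,
  default F = 3) is provided but off by default, since a ratio rule
  admits borderline contaminants.
- **TIC normalization precedes merging** because total ion current is a
  per-injection property; after normalization every sample column sums
  to one.
- **Replicates merge by mean** of normalized abundances (preserves
  quantitative Bray-Curtis structure, keeps column sums at one);
  `union` (per-feature maxima) is available for presence/absence-only
  workflows.
- **Presence threshold defaults to 0**: after blank filtering, any
  detected peak counts. Binarization is monotone in the threshold and
  drops all-zero rows.

## Chemistry-based partitioning

Isolate metabolome profiles are compared with **Bray-Curtis**
dissimilarity on TIC-normalized abundances (not binarized data, which
would discard quantitative structure). Ordination is classical
**PCoA**: Gower double-centering of −½D², eigendecomposition,
coordinates scaled by √eigenvalue. Negative eigenvalues (Bray-Curtis is
not Euclidean-embeddable in general) are **dropped and flagged**, not
corrected: Cailliez/Lingoes corrections change all coordinates, while a
flag preserves auditability. Axis signs are fixed (largest loading
positive) so runs are reproducible.

Clusters come from **average-linkage (UPGMA)** on the distance matrix —
the common default of the ecology toolchains this workflow descends
from — isolated behind a `linkage_method` parameter. The number of
clusters is chosen by the **mean silhouette width** computed from the
distance matrix over a candidate range (default 2–10), with ties broken
toward smaller k (parsimony). Tied linkage heights are resolved by
scipy's deterministic merge order.

**PERMANOVA** tests group separation: pseudo-F from squared-distance
sums of squares, p-value by label permutation with the observed
statistic included in the permutation set (+1 convention), so p is
never zero and is calibrated at small permutation counts. The
implementation was cross-checked against an independent reference
implementation to ~1e-12 on random data; a test verifies the null
rejection rate at α = 0.05 is 0.05 ± 0.02 over 500 simulated datasets.

## Richness, accumulation and coverage

- **Alpha richness** is the per-isolate item count; group comparisons
  use one-way ANOVA plus Tukey HSD with Tukey-Kramer standard errors
  (clade sizes are unequal by design). **Balanced subsampling** draws n
  isolates without replacement from every group larger than n (smaller
  groups are kept whole), removing sample-size artifacts from richness
  comparisons.
- **Interpolation** uses the exact sample-based (incidence) rarefaction
  expectation `E[S(t)] = S_obs − Σ_i C(T−T_i, t)/C(T, t)` — the mean
  over all size-t isolate subsets — computed with log-space binomial
  coefficients so T in the hundreds is safe. No Monte Carlo noise
  enters the headline solver. The resampled **collector curve** (mean
  over seeded shuffles) is retained as a cross-check; its permutation
  mode stratifies first positions evenly across isolates, an unbiased
  variance reduction aimed at small t where the Monte Carlo error of a
  plain mean is largest.
- **Extrapolation** uses the incidence-based Chao2 unseen-richness
  estimate (`(T−1)/T · Q1²/(2Q2)`, bias-corrected branch when Q2 = 0)
  in `S(T+t*) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^t*]`, with a
  default endpoint of 500 samples.
- **Coverage targets** invert the interpolated curve: the smallest t
  with `E[S(t)] ≥ p·S_obs`. Coverage is defined **relative to the
  observed total**, not the Chao2 asymptote — the convention under
  which "all but a few isolates give 99%" statements are meaningful;
  with singletons present, p = 1 always requires all T isolates.
- **End slope** `E[S(T)] − E[S(T−1)] = Q1/T` is the saturation
  diagnostic: groups with a small end slope are close to exhausting
  their observed chemistry.

## Molecular networking

Features are consolidated into **scaffolds** (molecular families) by
feature-based molecular networking. The **modified cosine** aligns
fragment peaks directly (|Δmz| ≤ tol) or shifted by the precursor mass
difference, takes a greedy one-to-one assignment in descending
intensity-product order, and scores on √intensity vectors normalized to
unit length (√ weighting is the common networking convention; `raw` is
available). Greedy assignment rather than optimal bipartite matching is
standard practice, deterministic, and immaterial at the tested
tolerances; it is a documented approximation. The implementation agrees
with an independent reference implementation to ~1e-10 on random
spectra.

Network edges require score ≥ `min_cosine` (0.7), matched peaks ≥
`min_matched` (6) and mutual top-K rank (K = 10) at fragment tolerance
0.02 Da — standard feature-based networking defaults, all
config-exposed. Connected components are scaffolds; maximum-component
splitting is deliberately not implemented (it only affects very large
components and is orthogonal to counting analyses). Scaffold presence
in an isolate is the union over member features; singleton scaffolds
can be dropped with their count reported.

## Reporting

Venn partitions assign each item to the exact subset of groups
containing it (group presence = any member isolate). Percentages are
rounded **half away from zero at one decimal** — the convention that
reproduces printed survey percentages from their (count, total) pairs.
Ordered accumulation reports each group's incremental coverage of the
grand total for a stated group order (built-ins: largest-first,
smallest-first); the final rounded increment absorbs the rounding
residue so cumulative coverage prints as 100.0%, and raw unrounded
increments are also emitted. Geographic summaries reduce to per-group
bounding boxes with a longitudinal-span flag for range-restricted
groups; map rendering is out of scope.

The pipeline writes one `summary.json` validated against a bundled
structural schema; the CSV outputs are views of the same numbers.
Reruns with identical configuration and seed are byte-identical.

## The synthetic survey

The generator emulates the statistical structure such a survey
analyzes, with defaults stylized after a ~200-isolate collection:

- **198 isolates in 5 clades** (111, 30, 25, 18, 14) — one dominant
  clade and a long tail; documented as stylized, not fitted.
- **Six chemotypes in five clades**: each clade carries one chemical
  cluster except the second (30 isolates), which hides two; a
  `split_pool_overlap` parameter controls how chemically distinct the
  hidden pair is (default 0: fully distinct, since no evidence pins the
  overlap). ~3% of isolates in three host clades are **chemically
  embedded**: they express the donor clade's cluster wholesale,
  mimicking culture-dependent loss of clade chemistry.
- **Feature pools**: a 60-feature core shared by all chemotypes
  (detection p = 0.95 per isolate), clade pools (300, 200, 80, 60, 140;
  p = 0.9) sized so per-isolate richness ranks U > Y > V > W > X, and
  100 features shared by random clade pairs. Detection is Bernoulli per
  eligible isolate.
- **Rare tail**: single-isolate features are injected until they are
  18% of all features (±1 feature), making the singleton statistic a
  recoverable parameter rather than an emergent one; a 3% doubleton
  tail (two isolates of one clade) keeps Q2 positive so the Chao2
  asymptote stays finite, as in real data.
- **Replicates and blanks**: two cultures per isolate share presence
  with independent log-normal peak areas (μ = 10, σ = 1 on the log
  scale); 30 blank-artifact features appear in every blank (so the
  strict filter is exactly verifiable) and in a random 30% of cultures
  at lower abundance.
- **Spectra**: every non-blank feature belongs to a scaffold; 70% of
  scaffolds are single-feature, the rest share a template of 10–16
  fragment peaks. Each scaffold fixes a "shiftable" subset of peaks
  (~30%) — its variable modification site — and each member applies its
  own precursor offset to that subset, plus intensity jitter and two
  low-intensity noise peaks. Co-members therefore share all template
  peaks under shift-aware matching while cross-scaffold spectra share
  essentially none.
- **Geography**: isolates draw uniform coordinates inside their
  cluster's bounding box; one hidden chemotype's box is far-western and
  two others are regionally restricted. No spatial autocorrelation is
  modeled.

Everything derives from one integer seed; fixed seed ⇒ byte-identical
outputs.

### What the benchmark does and does not show

Recovery tests verify that the chain finds what was planted: the blank
filter removes exactly the artifact set; the silhouette criterion finds
all six chemotypes; networking reconstructs the scaffold partition
(adjusted Rand ≈ 1); the realized singleton fraction matches the dial.
These are necessary checks of correctness, not evidence about real
data: the generator has no retention-time drift, adducts or in-source
fragments (which inflate feature counts), no chimeric spectra, no
intensity-dependent detection, cleanly separated chemotypes, and
independent isolates with no phylogenetic signal in detection
probabilities. Passing therefore demonstrates that the estimators and
the pipeline are implemented correctly, and that effect sizes of the
configured magnitude are detectable — not that real surveys will be
this clean.

## Numerical choices

- Binomial coefficients in log space (`gammaln`); rarefaction is exact
  to ~1e-10 against brute-force subset enumeration for T ≤ 8.
- Silhouette ties go to smaller k; cosine tie-breaks order candidate
  peak pairs by (product, index) so scores are deterministic.
- The PERMANOVA p-value denominator is `n_perm + 1`.
- Percent rounding uses decimal arithmetic, not binary floats.
- Problem sizes in the test-bench runs: the default survey (~1,200
  features, 198 isolates, ~600 scaffolds) keeps a full pipeline run
  around ten seconds; recovery checks average five seeds.

## Known limitations

- Group labels are consumed as input; no phylogenetic inference.
- No Hill numbers of order q > 0 and no coverage-standardized
  comparisons — richness (q = 0) only.
- No spectral library annotation, analog search or ion-identity
  networking; no GIS rendering beyond bounding boxes.
- Whether replicates should be merged or treated as independent samples
  is workflow-dependent; both modes exist, tests exercise `mean`.
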