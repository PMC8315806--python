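# Methods

This note documents the statistical models and procedures implemented in
`bbspace`, the design choices behind them, and what the synthetic study can
and cannot show.

## Overview

The package implements a univariate-first brain-behavior-space (BBS)
mapping workflow for psychosis-spectrum cohorts:

1. summarize each subject's resting-state connectome as parcellated global
   brain connectivity (GBC);
2. reduce a 36-item clinical battery (psychopathology + cognition) to a few
   permutation-validated principal axes;
3. map each symptom axis onto GBC by mass-univariate regression with
   max-statistic family-wise error control, and contrast that with a
   multivariate CCA of the same data;
4. quantify stability (leave-site-out, k-fold, split-half, leave-one-out)
   for every estimator;
5. select a maximally predictive parcel subset by step-down elimination on
   a dot-product (dpGBC) index, and benchmark the resulting maps against
   external reference topographies.

Because the motivating clinical data are access-restricted, the package is
exercised end to end on synthetic cohorts with planted ground truth; the
generator is first-class, tested code.

## Global brain connectivity

For parcel time series the functional connectivity matrix is the Pearson
correlation between all parcel pairs; GBC(p) is the mean Fisher z
(`atanh r`) over all pairs involving p. The self-correlation term is
excluded: including it would add `atanh(1) = inf`, so the mean over "all
other" regions is the only finite reading of the definition. GBC is
therefore in Fisher-z units. The same operation applies unchanged to dense
vertex-level matrices; the supported workflow parcellates first (mean
member-vertex series) because averaging raises within-parcel signal-to-noise
before the nonlinear correlation step. Our simulations show this ordering
advantage is regime-dependent: with weak correlations and i.i.d. vertex
noise, averaging vertex-level GBC estimates compensates almost exactly, and
the parcellate-first advantage emerges only when parcel-level correlations
are strong enough for the Fisher-z nonlinearity and estimation-error
shrinkage to matter (the regime the tests exercise).

Movement scrubbing flags a frame when frame displacement exceeds 0.5 mm or
the normalized intensity RMS exceeds 1.6 times the scan median; flagged
frames and their immediate neighbors are deleted (column censoring, no
interpolation). Neighbor removal is single-pass: frames removed only as
neighbors do not trigger further removals — the cascading alternative would
couple distant frames through chains of removals with no physical
rationale. Subjects with more than 50% flagged frames should be excluded
(`frame_flag_fraction`). Nuisance regression is plain OLS residualization
of each parcel series on a supplied regressor matrix; constructing those
regressors from imaging volumes is out of scope.

## Symptom PCA

The symptom decomposition is an eigendecomposition of the item correlation
matrix (items scaled to unit variance across subjects). Components are
ordered by variance fraction; signs are fixed by making each loading
column's largest-magnitude element positive (principal axes have arbitrary
sign, and every cross-fit comparison elsewhere matches components by
absolute correlation before comparing).

Significance is permutation-based in the spirit of Horn's parallel
analysis: each item column is shuffled independently across subjects
(destroying inter-item structure, preserving marginals), the PCA refit, and
component k compared with the null distribution of the rank-k variance
fraction. p-values use the add-one estimator `(1 + #{null >= obs}) /
(1 + n_perm)`, so they are bounded away from zero. Each permuted dataset is
re-standardized before refitting; since shuffling preserves marginals this
is a formality, but it keeps the null pipeline identical to the observed
one. Missing data are rejected rather than imputed.

Held-out subjects are projected by standardizing with the stored item
means/SDs and applying the loadings; projecting the training data
reproduces the stored scores exactly.

## Resampling harness

One harness drives all stability analyses. Folds are stratified by
diagnosis by default for every scheme — the half-split demands preserved
diagnosis proportions, and we extend the same stratification to k-fold for
consistency — keeping label proportions within one subject per fold. Two
readouts:

* predicted-versus-observed — fit on retained subjects, project held-out
  subjects, correlate with the full-sample fit's scores. Fold components
  are aligned to the full-sample components by greedy maximum absolute
  correlation with sign alignment. Note this statistic is not nulled at
  zero for unstructured data: the fold fit and the full-sample fit share
  training subjects, leaving a residual positive association (~0.65 in our
  null simulations) — collapse relative to the planted-structure level
  (~1.0), not distance from zero, is the informative contrast.
* split-half replication — independent fits on disjoint stratified halves,
  compared by matched-column absolute correlation. Greedy matching biases
  the null level upward (best of k x k pairings), another reason these
  statistics are interpreted comparatively.

Failed folds are recorded with diagnostics; a run containing a failed fold
is excluded from the aggregate and counted, never silently dropped.

## Mass-univariate mapping

Each parcel's GBC is regressed on one symptom score (simple OLS with
intercept; an optional covariate matrix is residualized out of both sides
first — the default model has no covariates). The coefficient map is
Z-scored across parcels so maps from different predictors are comparable by
construction (mean 0, SD 1).

Family-wise error control is the max-statistic permutation test at parcel
resolution: shuffle the predictor across subjects, recompute all parcel |t|
values, record the maximum; a parcel's corrected p is the add-one tail
probability of its observed |t| under that max-null. Shuffling the
predictor rather than the brain data preserves the spatial covariance of
GBC, giving strong FWE control. (Dense-resolution cluster-enhancement
inference is deliberately out of scope; the parcel-level max-statistic test
provides the equivalent guarantee at the resolution the rest of the
pipeline uses.)

A PCA of the subjects-by-parcels GBC matrix exposes the large shared
variance components common to patients and controls. Its permutation
variant shuffles parcels within subject (breaking topography, preserving
each subject's value distribution). `partial_out_neural_pcs` reconstructs
the patient GBC matrix from all but the first k components (projection in
standardized space, original scaling restored); the residual is orthogonal
to the dropped components, and on the synthetic cohorts removing the
leading shared component leaves the symptom-neural map nearly unchanged
(r > 0.95), as the planted symptom-coupled variance is independent of the
shared components.

## Canonical correlation analysis

Both feature blocks are standardized; the CCA is solved by SVD of the
whitened cross-covariance (orthonormal score bases from economy SVDs of
each block). Latent variates have unit variance; mode k's variate pair
correlates exactly at the k-th canonical correlation; the sign convention
follows the symptom-side transformation. A fit requires more subjects than
total features — with p + q >= n the solution is degenerate and the fit
raises an error suggesting feature reduction (cortical symmetrization from
360 to 180 parcels is the supported route; homologous left/right parcels
are averaged).

Mode significance shuffles the symptom block's subjects, compares each mode
against the same-rank permutation null, and applies Benjamini-Hochberg FDR
across modes (the procedure behind an unqualified "FDR correction").
Variance explained by each latent neural variate is the variance-weighted
mean squared correlation with the symptom features. Leave-one-subject-out
latent prediction refits the CCA without each subject, aligns the refit
modes to the full solution, computes the held-out subject's latent scores,
and correlates the assembled predicted variates — a collapse of these
correlations relative to the in-sample canonical correlations is the
overfitting readout.

## CCA power analysis

The generative model places a joint Gaussian over p + q features with
exactly one canonical mode at a specified true correlation: within-set
covariances have a power-law eigenvalue spectrum `lambda_i ~ i**-decay` in
a random orthogonal basis (trace normalized to the feature count;
`decay = 0` gives the identity), true weights are random directions
normalized to unit score variance, and the cross-covariance is the rank-one
`r (Sx wx)(Sy wy)'`. True weights, scores and loadings are then known in
closed form. The default `decay = 0.5` is a mild within-set structure
chosen once as the documented operating point; at p = 180, q = 5, r = 0.3
the identity spectrum yields a required sample size near 9,000, decay 0.5
near 10,500 and decay 1.0 near 16,000, so the conclusion — a sample an
order of magnitude beyond typical clinical cohorts — is insensitive to the
choice.

Four error metrics are computed per Monte-Carlo replicate against the
planted truth (the literature defines the metrics' names, not their
formulas; these are this package's definitions): relative error of the
leading canonical correlation; `1 - |cos|` between estimated and true
weight vectors (worse of the two sets); `1 - |corr|` between estimated and
true scores; `1 - |cos|` between estimated and true structure loadings.
Detection power is the fraction of replicates whose leading canonical
correlation exceeds the 95th percentile of a permutation null; that null
threshold is calibrated once per sample size (on the first replicate) and
reused, since under subject shuffling its distribution depends on the block
dimensions rather than the draw. The required sample size is the smallest
point on a geometric grid (ratio 1.25) at which power >= 90% and all four
mean errors <= 10%, found by a coarse upward scan followed by bisection;
per-point seeds make repeated evaluations reproducible.

## dpGBC step-down selection

A subject's deviation map is their GBC minus a group-mean map (within
sample, or an external reference group's mean when scoring a replication
sample). The dpGBC index is the dot product of the deviation map with a
reference coefficient map over a parcel subset — signed, unbounded, and
linear in the deviation map.

The leave-one-out evaluation is strict: for subject i both the coefficient
map and the group mean come from the other N-1 subjects (rank-one downdate
formulas, vectorized over subjects), so the index is never inflated by
self-similarity. The scalar regression of dpGBC on the symptom score (with
intercept), also fit leave-one-out, yields each subject's predicted index.
Two criteria trace the step-down elimination: metric A, the correlation
between symptom scores and observed dpGBC values, and metric B, the
correlation between observed and predicted dpGBC values. (A transcription
of the selection criterion that correlates the predicted index with the
score it was predicted from is tautologically ~1 and is not used.)

Elimination ranks parcels once by |coefficient| in the full-sample map
(ties broken by parcel index) and removes the weakest per step;
`rerank_each_step=True` recomputes the ranking per iteration as a
sensitivity analysis. The leave-one-out evaluation runs at every retained
count up to 100 and every 5th count above, with exact refinement around the
provisional peak. The selected subset maximizes metric A; metric B's argmax
is reported alongside (on planted cohorts the two peak together).

A caution the implementation makes measurable: because the subset ranking
uses the full sample, the null distribution of peak metric A is biased
above zero (~0.14 median at 436 subjects and 100 parcels when parcel noise
shares structure; ~0.25 with independent parcels). Leave-one-out removes
coefficient overfitting, not subset-selection overfitting. Planted-signal
peaks (~0.4-0.6) sit well clear of this ceiling, but near-threshold peaks
on real data should be judged against a permutation null of the full
step-down, not against zero.

## Patient selection and benchmarking

Two-stage selection on a bi-directional symptom axis: stage 1 keeps
subjects with |score| above a symptom threshold (both poles are
symptomatic); stage 2 keeps those whose deviation-map similarity to the
reference coefficient map (over the selected subset) exceeds a neural
threshold in magnitude with sign consistent with their score. Thresholds
default to the 75th percentile of |score| and 0.25 similarity. Raising
either threshold never adds subjects.

Reference-map similarity is Spearman rank correlation by default (reference
maps live on arbitrary scales; rank correlation is invariant to monotone
transforms), Pearson by flag. Maps in different parcel spaces must be
symmetrized explicitly before comparison. Pharmacological contrasts are
per-parcel paired (or unpaired) t statistics Z-scored across parcels.
`generate_reference_map` manufactures reference vectors at a controlled
correlation to a planted map by orthogonal-residual mixing, standing in for
external pharmacological or gene-expression maps.

## Synthetic cohorts

The generator emulates the statistical skeleton of a multi-site psychosis
cohort, not its content:

* **Symptoms.** Five independent standard-normal latent factors (an oblique
  factor correlation is available, default identity). Each factor loads on
  its own disjoint block of items — mirroring distinct clinical subscales —
  with random magnitudes and signs expressed directly in the unit-variance
  item metric (`item = a z + noise_scale * sqrt(1 - a^2) eps`). Disjoint
  support keeps factor directions exactly orthogonal after per-item
  standardization; dense random loadings would mix factors at the
  population level once items are rescaled. Default variance fractions
  (0.16, 0.12, 0.10, 0.08, 0.06) sum to ~0.52, chosen so the weakest
  factor's eigenvalue clears the permutation null at a few hundred subjects
  while about half the item variance stays unexplained.
* **GBC.** Per subject: a fixed parcel baseline, three shared
  symptom-irrelevant components with geometrically decaying shares of 45%
  of parcel variance (leading component ~22%, so the first neural PC always
  dominates), plus, for each factor, `coupling x factor score x planted
  map` on a disjoint random set of 60 parcels (of 718), plus independent
  parcel noise completing unit variance. Planted map magnitudes are
  near-unit (1 +- 0.2, random signs): every planted parcel carries a
  comparable, resolvable effect, which is what makes subset recovery a
  well-posed target. The default coupling 0.7 makes the dominant factor's
  coefficient map recoverable (r > 0.9 versus truth) at 436 subjects.
* **Labels.** Diagnosis labels are quantiles of the first factor score —
  overlapping group distributions — and never enter the neural model; they
  only stratify resampling. Site labels are balanced; optional per-site
  additive intercepts on items and parcels (default 0) support
  leave-site-out analyses.

All randomness flows from one seed through named sub-streams, so each block
is independently reproducible and identical seeds give bit-identical
cohorts.

What the synthetic study does not emulate: spatial autocorrelation of
parcels, heavy-tailed or ordinal item distributions, site differences in
noise level or covariance (only mean shifts), scanner artifacts,
medication effects, and any nonlinearity in the symptom-neural coupling.
Passing tests therefore demonstrate that the estimators recover the
structure they assume, at realistic sizes and noise levels — not that real
cohorts satisfy those assumptions.

## Numerical choices

* Whitening and rank decisions use a relative singular-value cutoff of
  1e-10; rank-deficient blocks raise errors rather than being silently
  regularized.
* Permutation p-values always use the add-one estimator.
* All ties (component matching, elimination order) break deterministically
  (greedy maximum, then lowest index).
* Degenerate inputs fail loudly with the offending item/parcel named:
  zero-variance items or parcels, constant score vectors, empty subsets,
  constant maps.
* Strict text I/O: tab-delimited with header row and row labels, full
  double precision, duplicate labels and ragged or non-numeric rows
  rejected with line numbers. No binary neuroimaging formats.

## Study sizes used in the automated checks

The test suite and the acceptance script run the full study at the default
conditions (436 subjects, 718 parcels, 36 items) where a single fit is
involved, and use reduced designs where a quantity needs hundreds of
Monte-Carlo repetitions: type-I calibration uses 120 x 8, 60 x 40 and
80 x (6+3) null designs with 500 permutations over 200 seeds; step-down
recovery uses 100-parcel cohorts with 20 planted parcels over 20 seeds;
the required-sample-size search uses 24-32 replicates and 50-64
permutations per grid point. These sizes were chosen so every check
completes in seconds to a few minutes while keeping Monte-Carlo error well
inside the asserted margins.

## Known limitations

* The dpGBC null ceiling (selection circularity) documented above.
* Predicted-versus-observed and matched split-half statistics have positive
  null levels (overlap and matching bias); they are comparative readouts.
* The power model's within-set spectrum and error-metric formulas are this
  package's definitions; required-sample-size numbers are comparable within
  the package, not across differently specified generative models.
* `partial_out_neural_pcs` reconstructs exactly only within the span of the
  fitted components (rank `min(n-1, p)`).
* The pipeline's CCA stage requires more subjects than neural + symptom
  features; with full 718-parcel maps and typical cohort sizes the
  supported route is cortical symmetrization or a neural PCA reduction
  before the CCA.
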