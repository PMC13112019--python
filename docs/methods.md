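# Methods

This note documents the statistical procedures the package implements,
the conventions and tunable parameters, the design of the synthetic
cohort generator, and the numerical choices that matter for
reproducibility.

## Connectivity construction (`connkit.fc`)

Regional time series (T timepoints × N regions, TR = 2 s by default)
are cleaned in a fixed order: linear detrend → zero-phase 4th-order
Butterworth bandpass (default 0.01–0.08 Hz, applied forward–backward
with `sosfiltfilt`) → OLS residualisation against confound columns that
were themselves detrended and filtered identically (plus an intercept).
The order is a convention; the literature frequently leaves it
ambiguous, and regressing filtered confounds from filtered data avoids
re-introducing filtered-out frequencies. Rank-deficient confound sets
are reduced to a full-rank pivot subset with a warning.

Connectivity is the Pearson correlation between all region pairs,
Fisher-z transformed (`z = atanh r`), diagonal set to zero. Perfect
correlations are clipped to |r| = 1 − 1e-7 (with a warning) so the
transform stays finite on degenerate input. The edge vector is the
strict upper triangle in **0-based row-major order** — (0,1), (0,2), …,
(N−2,N−1) — used consistently by every module and written into output
headers; for N = 116 this is 6670 features. A packaged AAL-116 lookup
table (78 cortical, 12 subcortical, 26 cerebellar labels, with lobe and
coarse canonical-network columns) annotates node-level outputs.

## Network-Based Statistics (`connkit.nbs`)

* **Screen**: an edge enters the analysis if its z-values are
  significantly nonzero (one-sample two-tailed t-test) in at least one
  group at Bonferroni-corrected p < 0.05 across edges. The screen is
  computed once on the observed grouping and the retained set is reused
  across permutations. ("At least one group" resolves source wording
  that cannot apply to a single participant's single edge value.)
* **Edge statistic**: pooled-variance (Student) two-sample t per edge,
  the classic NBS choice; Welch is available as an option. The default
  tail tests patients *below* controls, the usual direction for a
  disease cohort; both other tails are available.
* **Components**: suprathreshold edges (default primary threshold
  p < 1e-4) form a graph whose connected components are measured by
  *edge count* (not node count); singleton nodes are ignored.
* **Inference**: group labels are permuted (default 10,000 times), the
  same retained-edge set and primary threshold are applied, and the
  maximal component size is recorded. The corrected p-value of an
  observed component of size M is `(1 + #{null_max ≥ M}) / (n_perm + 1)`
  — the add-one estimator avoids p = 0 and counts ties as exceedances
  (conservative); it differs from the plain exceedance proportion by at
  most 1/n_perm.

With a fixed seed the permutation stream, and therefore every output,
is bit-reproducible.

At small problem sizes the component-size null is heavily discrete:
with 780 edges and a primary threshold of 1e-4, ~94% of permutations
produce no suprathreshold edge at all and the realised family-wise
error sits far below nominal. The package's own calibration study
(below) therefore scales the primary threshold with the edge count so
that the expected number of null suprathreshold edges matches the
full-size analysis (α·E ≈ 0.667, i.e. α ≈ 8.55e-4 at 40 nodes); the
analysis default remains 1e-4.

## Connectome-based Predictive Modeling (`connkit.cpm`)

Within each cross-validation fold (leave-one-out by default; stratified
shuffled k-fold with a seed as the alternative), edges are selected by
the Pearson correlation between edge values and the behavioural score
across training subjects, thresholded at p < 0.005 via the exact
t-transform of r (two-tailed — the sign is captured separately by the
positive/negative split, implemented as the equivalent critical |r|).
Per-subject network strength is the sum of edge values over a selected
set; simple linear models map positive and negative strength to the
score, and a combined GLM uses both (degrading gracefully when a set is
empty; a fold that selects nothing predicts the training mean, with a
warning). Selection and fitting never see the held-out subjects — a
leakage test corrupting a held-out row asserts exactly this.

The reported networks are the **intersection of per-fold selections**
(consensus); out-of-fold performance is Pearson r between predicted and
observed scores, with negative r reported as zero by default (the
parametric p of a cross-validated r is invalid, so significance comes
from re-running the full pipeline on behaviour-permuted data, one-tailed,
with the add-one estimator). Node-level summaries: per-node degree
within a network (degrees sum to 2·|edges|), top-k hub follow-up
(restrict the network to one hub's incident edges, recompute strength,
partially correlate with behaviour given covariates, BH-correct over
the k hubs), and within-group strength–behaviour correlations.
Covariate control throughout is partial correlation: residualise both
variables on the covariates (with intercept), correlate the residuals,
n − 2 − k degrees of freedom.

## Mediation (`connkit.mediation`)

Observed-variable single-mediator analysis with covariates in every
equation (PROCESS Model 4): `M ~ X + C` gives *a*; `Y ~ X + M + C`
gives *b* and the direct effect *c′*; `Y ~ X + C` gives the total
effect *c*. Continuous variables are mean-centered before fitting
(binary 0/1 indicators are left alone); with a shared covariate set the
OLS decomposition `c = c′ + a·b` is an algebraic identity and is
asserted to 1e-10. Coefficients, SEs and p-values come from
`statsmodels` OLS.

The indirect effect a·b gets a percentile bootstrap CI (default 1000
resamples of subjects with replacement, 95%); bias-corrected-and-
accelerated is available as an option, but percentile is the default in
line with current PROCESS practice. Degenerate resamples (constant
exposure or mediator) are redrawn and counted, with a warning if they
exceed 1% of draws; resamples in which a covariate happens to be
constant are handled by a pseudoinverse (minimum-norm) OLS solve.
"Full mediation" is flagged when the indirect CI excludes zero while
the direct path is non-significant (p ≥ 0.05). In the intended
application the mediator is the mean Fisher-z over the CPM consensus
positive network, exposures (hemoglobin, RDW) are tested in separate
models on patients only, and BH false-discovery-rate adjustment is
applied over the family of tests.

## Synthetic cohorts (`connkit.synthdata`)

The generator emulates a two-group pediatric connectome cohort
(default 25 patients / 35 controls, 116 regions, 120 retained
timepoints at TR 2 s) with three planted, recorded effects:

* **Disrupted component** — a connected edge set whose patient-group
  mean Fisher-z is lowered by `disruption_delta` (default 0.6).
* **Behaviour network** — an edge set sharing a per-subject standard-
  normal "network integrity" factor with loading 0.2 z-units; the
  behavioural score is `intercept + slope · (summed strength) + noise`.
  The shared factor is what makes a functional network's edges
  co-fluctuate across subjects; without it no edge-level selection
  procedure could see network-level signal.
* **Mediated haematology** — patients only: hemoglobin is drawn at the
  reference moments 104.28 ± 13.31 g/L (RDW 42.06 ± 9.21, anti-
  correlated at −0.8), the patients' integrity factor is regenerated as
  `a·hb_std + √(1−a²)·ε`, and the score as
  `b·strength_std + c′·hb_std + ε` — so `c′ = 0` (the default) plants
  full mediation. Requesting haematology for controls raises an
  explicit unsupported-operation error, mirroring designs in which
  blood work is clinically indicated only for patients.

Two routes produce the connectivity data. The **matrix route** draws
each subject's edge vector as the group mean profile (control edges
z ~ N(0.3, 0.15)) plus iid edge noise (sd 0.2 z-units, a typical
between-subject spread for Fisher-z resting-state edges) plus the
factor term; it is exact and fast, and is what the simulation studies
use. The **time-series route** builds a positive-semidefinite target
correlation matrix from a low-rank factor construction calibrated to
the same edge-z moments, plants the disruption by alternating
projection between the PSD cone and the constraint fixing the edited
entries (Higham-style eigenvalue clipping; edits the cone cannot
accommodate within 0.1 z-units raise an error naming the offending
edges), and samples stationary AR(1) series (temporal autocorrelation
0.3) with that cross-correlation — so detrending and filtering have
non-trivial input. Sample Fisher-z differences on planted edges then
match the requested delta to within Monte-Carlo accuracy.

The planted mediation paths default to a = 0.85, b = 0.9, c′ = 0.
These were fixed by a prospective power simulation: the joint
"indirect significant and direct non-significant" flag rate is capped
near 0.95 × (CI power) by the type-I rate of the direct-path test and
is *non-monotone* in a (a strong a makes exposure and mediator
collinear in the outcome model, inflating the b standard error); the
chosen pair gives ~0.97 CI-exclusion power and a ~0.93–0.95 joint flag
rate at n = 25 with three noise covariates, so a ground-truth recovery
suite can demand ≥ 90% detection without being brittle.

Covariates are plumbing: age uniform on [6.3, 15.1] years, sex 0/1,
brain volume standard normal. One RNG stream per cohort derives from
the spec seed; every stochastic operation accepts an explicit seed.
Ground truth serialises to YAML byte-identically.

**What the generator does not emulate** — and hence what passing
simulations do not certify about real data: head motion and its
spike/drift artefacts, physiological noise spectra, spatial
autocorrelation between neighbouring regions, site/scanner effects,
non-Gaussian edge distributions, and any structured relationship
between covariates and connectivity. The validation suite shows the
*estimators* are correct and calibrated, not that real cohorts carry
this much signal.

## Validation suite: designs and sizes

All checks run on one CPU in a few minutes; sizes below are the
package's chosen trade-off between Monte-Carlo error and runtime.

* **NBS FWER**: 500 exchangeable-null cohorts (25/35 subjects, 40
  nodes), 200 permutations each, primary threshold scaled as described
  above; the rate of any corrected p < 0.05 must lie in [0.01, 0.09]
  (observed ≈ 0.02 — valid, conservative because of the discrete
  component statistic and ties-as-exceedances).
* **NBS recovery**: 50 cohorts with a planted 30-edge component at
  delta 0.6; detection with corrected p < 0.05 and edge recall ≥ 0.8
  required in ≥ 90% of replicates (observed 100%).
* **CPM recovery**: noiseless behaviour over a planted 20-edge network
  (35 nodes, 60 subjects, LOOCV): the consensus network must contain
  every planted edge and out-of-fold r ≥ 0.95 (observed ≈ 0.998).
* **CPM null calibration**: 200 exchangeable cohorts (30 subjects, 20
  nodes), 100 permutations each; the permutation p must be uniform on
  its achievable grid (KS test, mean in [0.4, 0.6]).
* **Mediation**: the total-effect decomposition holds to 1e-10;
  percentile-CI coverage for a·b over 500 null-free cohorts at n = 25
  with moderate paths (a = b = 0.5) must lie in [0.90, 0.98]
  (observed ≈ 0.93, the familiar mild under-coverage of the percentile
  interval); the planted full-mediation design is flagged in ≥ 90% of
  300 cohorts (observed ≈ 0.93).
* **Oracles**: component sizes match an independent union-find
  implementation on random graphs; the pooled t matches the hand
  formula; BH adjustment matches a hand-computed example; path
  coefficients and the indirect estimate match `pingouin`'s
  independent mediation implementation.

## Known limitations

* NBS corrected p-values are conservative at small edge counts (see
  above); interpret non-rejection accordingly.
* The CPM permutation test re-runs the entire cross-validation per
  permutation; at the default 1000 permutations and full AAL scale this
  is minutes, not seconds.
* The consensus (intersection) network is strict: a single unstable
  fold empties it. Per-fold sets are retained on the results object so
  union or frequency-weighted summaries can be derived as diagnostics.
* Mediation here is cross-sectional path analysis; it cannot establish
  causal ordering, and no latent-variable (SEM) machinery is provided.
* RDW units are carried as metadata only; source tabulations disagree
  (fL vs g/L) and nothing in the analysis depends on them.
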