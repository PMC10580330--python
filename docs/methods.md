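# Methods

## The CPM procedure and its assumptions

The package predicts a continuous symptom severity score from a subject's
functional connectome with connectome-based predictive modeling. The
connectome is a symmetric N × N matrix of Fisher-z transformed Pearson
correlations between node time series; only the M = N(N−1)/2 upper-triangle
edges are used, indexed canonically as unordered pairs (i, j), i < j, in
`numpy.triu_indices` order.

Within each training set, every edge's strength is partially correlated with
the score, controlling for covariates (by default age, gender coded M=1/F=0,
and disease duration in years): both the edge vector and the score are
residualized on [1, covariates] and the residuals correlated. The two-sided
p-value uses the t approximation with df = n − 2 − k for k covariates — the
standard closed form for partial correlations and the convention of common
CPM implementations. Selection is strict (p < threshold; an edge at exactly
the threshold is excluded), with the 0.01 default. Selected edges form the
positive (r > 0) and negative (r < 0) networks; a subject's network
strengths are the sums of their connectivity over each set; severity is
regressed on (1, S⁺, S⁻) by ordinary least squares.

Under leave-one-out cross-validation, selection and fitting are repeated n
times on n − 1 subjects and the held-out subject is predicted from their own
strengths under that fold's mask. Implementation choices:

- **Consensus connectome.** The reported connectome keeps only edges
  selected with the *same sign* in every fold; an edge that flips sign
  between folds is excluded. Nothing else about a "shared" edge is ambiguous
  once sign consistency is required.
- **Degenerate folds.** A fold with an empty mask predicts the fold-training
  mean and is logged; this keeps the prediction vector length n. A result
  with all folds degenerate is flagged non-informative.
- **Empty networks.** If only one sign survives, the linear model drops the
  empty predictor and records its coefficient as absent.
- **Final (exportable) model.** Edges are selected on the full training
  sample and, by default, restricted to the LOOCV consensus; coefficients
  are refitted on all training subjects. External cohorts are predicted by
  applying the stored mask and coefficients without refitting (a
  `restrict_to_consensus=False` mode uses the plain full-sample selection
  instead).

Evaluation is the Spearman rank correlation between observed and predicted
severity — the scores are skewed, tied integers, so rank correlation is
appropriate — with average ranks on ties.

## Permutation significance

LOOCV folds are not independent, so parametric p-values for the evaluation
correlation are anticonservative. Significance instead comes from rerunning
the entire LOOCV pipeline on shuffled data: the score vector is permuted
against the connectomes (covariates stay aligned with the connectomes, so
the test targets the score–connectome link specifically; a joint
score+covariate shuffle is available via `shuffle_covariates=True`). The
one-sided exceedance p uses the plus-one rule
p = (1 + #{ρ_null ≥ ρ_obs}) / (1 + n_perm), which can never be zero and is
valid under exchangeability. Permutation indices depend only on (n, n_perm,
seed), never on the observed scores. An undefined ρ (constant predictions)
is scored as 0 for both observed and null statistics so the two are computed
identically.

The permutation engine evaluates many score vectors in one pass per fold
(shared covariate projections, batched mask application and normal-equation
solves via batched pseudoinverse on centered predictors). The batched path is
asserted equal to the per-column loop at 1e-10 in the test suite. One
permutation test at n = 60 subjects, 40 nodes, 100 permutations runs in
about 0.2 s on one CPU; that is what makes calibration studies over hundreds
of full pipelines practical.

Calibration, measured on 200 null cohorts, is slightly conservative
(empirical rejection ≈ 0.035 at α = 0.05 rather than the nominal
5/101 ≈ 0.0495). This is a consequence of keeping covariates with the
connectomes while the generator couples age to severity: permuted scores
lose the age association the observed scores have, widening the null very
slightly. The rate remains within the exact binomial 95% interval.

## Regional and lesioned models

Region-based models restrict the edge universe to edges with both endpoints
inside one macroscale region; lesioned models remove one region's nodes and
every edge touching them. Both reuse the full LOOCV + permutation machinery
on the restricted universe. The 11 region-based models form one
Benjamini–Hochberg FDR family and the 11 lesioned models another, each
corrected separately; permutations are rerun per lesion. A lesioned model is
compared with the full model by Steiger's z-test for two dependent
correlations sharing the observed score, with the Fisher-z difference scaled
by the asymptotic SE that depends on the correlation between the two
prediction vectors. The rank-based evaluation correlations are entered into
the formula as computed, and the between-predictions correlation is computed
the same way, keeping the three inputs internally consistent.

A caution established by simulation here: with ~80 subjects, the null
distribution of the LOOCV evaluation ρ has standard deviation ≈ 0.25 (at
atlas sizes from 30 to 160 nodes). Selection at p < 0.01 picks up edges
whose *realized* sample correlation with the score is large by chance
(up to ≈ 0.4 over ~1 700 edges), those edges persist across folds, and
cross-validation cannot remove a correlation that is real within the drawn
sample. A lesioned model stripped of all true signal therefore still shows
|ρ| in the 0.2–0.4 range in roughly a third of replicates. This is exactly
why the permutation test — not the raw ρ — carries the inference, and why
lesion *importance* is read from the performance drop relative to the full
model (the signal-bearing region ranks first in essentially all replicates)
rather than from the lesioned ρ crossing a fixed small threshold.

## Pattern comparison

A node's contribution to a network is the fraction of the network's edges
incident to it (node-level vectors sum to 2); a region's contribution counts
an edge once per distinct endpoint region (within-region edges once, so
region vectors sum to between 1 and 2). Similarity between two connectomes'
contribution vectors is Pearson's r. Edge-set overlap is tested against the
hypergeometric law of drawing n edges from the M node pairs of which K
belong to the other network. The default tail is the exclusive convention
p = 1 − CDF(x) = P(X > x), matching the formula as printed in the field's
MATLAB idiom (`1-hygecdf(x,M,K,n)`); the inclusive enrichment form
P(X ≥ x) is behind a flag. Note the exclusive form gives p = 0 when two
identical sets overlap completely — a property of that convention, asserted
in the tests.

## Group comparison

Patients are subtyped by the ratio of mean tremor item score (7 items) to
mean AR item score (15 items): ARD below 0.8, TD above 1.0, mixed between
(a cohort need not partition into ARD + TD alone). A zero AR mean with
positive tremor maps to TD (ratio +∞); both zero map to mixed; both logged.
Network strength in any group — patients or controls — uses the identical
summation rule as CPM. Strength comparisons use the Mann–Whitney test
(scipy's exact method for small tie-free samples, normal approximation with
tie and continuity correction otherwise); descriptive statistics use the
two-sample t-test, chi-square (continuity correction off by default), and a
Lilliefors-type Kolmogorov–Smirnov normality check.

## Synthetic cohorts

The generator emulates the statistical structure of a drug-naive Parkinson's
disease rs-fMRI cohort, at a reduced default scale chosen for simulation
throughput (80 subjects, 60 nodes over the 11 regions; the 268-node geometry
is a configuration away):

- **Scores.** AR severity is a gamma(2, 7) latent rounded to a nonnegative
  integer (mean ≈ 14, right-skewed — median/range in the style of the
  emulated cohort, and non-normal by construction, which motivates the
  Spearman evaluation); tremor severity is gamma(1.3, 2.8) on its smaller
  scale.
- **Connectivity.** A per-dataset baseline mean per edge ~ Normal(0.3, 0.1)
  (typical Fisher-z magnitudes), i.i.d. edge noise with SD 0.1 z-units, and
  planted coupling z = baseline + slope·(score − mean score) on the chosen
  edge sets. The slope is scaled by the *realized* score SD of the cohort so
  the edge–score correlation magnitude equals the requested ρ_signal for
  that cohort, not merely in expectation over cohorts.
- **Covariates.** Age ~ Normal(57.75, 10.83) with a configurable correlation
  (default 0.3) to severity, acting as the confound the partial correlation
  must remove; gender Bernoulli(44/78); duration log-normal around a median
  of 1.64 years; mean FD gamma-distributed around 0.08 mm.
- **Controls** share the dataset's baseline without score coupling; an
  optional shift (default 0.05 z-units in the CLI and power studies) raises
  control strength on the planted negative edges, so patients present the
  reduced-negative-strength pattern. At 40 vs 40 subjects and 30 negative
  edges this effect yields near-unit power for the Mann–Whitney comparison
  while the positive network stays at the nominal false-positive rate.
- **Time-series mode** maps each target z-matrix back to correlation space,
  repairs it to the nearest positive-semidefinite correlation matrix when
  needed (eigenvalue clipping, unit-diagonal rescale, logged), and samples
  multivariate normal series; FD traces are gamma baselines (well below the
  0.2 mm threshold) with spikes ≥ 0.2 mm at a configurable probability.

What the generator does *not* emulate: spatial autocorrelation between
edges, hemodynamics or scanner noise, site effects, and realistic
correlation structure among non-planted edges (they are independent given
the baseline). Passing recovery tests therefore demonstrates the estimator's
correctness under the stated generative model, not performance on real fMRI.

## Numerical choices

- Fisher transform caps |r| at 1 − 1e−7 (configurable) so z stays finite on
  perfectly correlated series.
- Scrubbing removes volumes with FD ≥ threshold (a volume at exactly
  0.2 mm is removed); "shorter than 120 volumes" excludes only counts below
  120.
- Zero-variance edges (or edges spanned by the covariates) are assigned
  r = 0, p = 1 and can never be selected; a zero-variance score vector is an
  error.
- Per-fold OLS inside the batched engine uses centered predictors and a
  batched pseudoinverse (rcond 1e−12), which degrades gracefully to the
  surviving predictor or the training mean when a network is empty; the
  user-facing `fit_linear` instead raises on rank-deficient designs with a
  collinearity message.
- Per-stage CLI seeds derive from the global seed by folding in a CRC of the
  stage name, so stage results are reproducible independently of execution
  order.

## Known limitations

- Only LOOCV is provided (no k-fold variants), matching the analysis design
  it implements; regularized or nonlinear predictive models are out of
  scope.
- Steiger's test treats rank correlations as product-moment correlations in
  its asymptotic formula; this is the internally consistent choice but
  inherits the approximation.
- The permutation test is mildly conservative when covariates correlate with
  the score (see above); the joint-shuffle mode removes this at the cost of
  also testing the covariate link.
- FD is consumed, never computed: the package starts from denoised node
  time series or matrices, and everything upstream (realignment,
  normalization, nuisance regression, filtering) is explicitly out of scope.
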