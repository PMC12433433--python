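# Methods

## Model

All three candidate models are instances of one adapted multidimensional
nominal response model.  For item *i* with slope vector `a_i` (one entry per
latent dimension), category intercepts `c_ik`, and a fixed scoring matrix
`s` (rows = latent dimensions, columns = the K response categories),

    P(Y_i = k | θ) = exp([a_i ⊙ s_k]ᵀ θ + c_ik) / Σ_m exp([a_i ⊙ s_m]ᵀ θ + c_im).

The scoring matrix is what encodes a response-style hypothesis.  The
substantive row is always the linear scores (0, 1, …, K−1), under which the
model is exactly the generalized partial credit model; the bipolar row
(2, 1, 0, 1, 2) treats extreme and midpoint responding as opposite poles of
one dimension; the ERS row (1, 0, 0, 0, 1) and MRS row (0, 0, 1, 0, 0) treat
them as separate dimensions.  For general odd K the ERS row is the indicator
of the two endpoint categories, the MRS row the indicator of the single
midpoint, and the bipolar row the distance |k − (K−1)/2|; even K has no
single midpoint, so midpoint-style models reject it.  The bipolar row equals
ERS − MRS plus a constant that cancels in the softmax, so a bipolar item is
observationally identical to a two-dimensional item with equal ERS and MRS
slopes and perfectly anti-correlated style traits — the identity that makes
the model-selection question statistically delicate.

Multidimensionality is between-item on the substantive side: each item loads
on exactly one substantive dimension (with two dimensions the test is split
in consecutive halves), while response-style dimensions load on every item.
Identification fixes latent means at 0, variances at 1, and the
first category's intercept at 0; latent correlations and all loaded slopes
and remaining intercepts are free.  The free-parameter count is
J·(1 + R + K − 1) + T(T − 1)/2, with R the number of style dimensions and
T the total dimensionality.

## Synthetic data

The generator emulates Likert responding under each of the three structures:

* substantive traits — independent standard normal;
* style traits — normal, mean 0, SD σ_RS ∈ {0.6, 1, 1.5} (weak / medium /
  strong); in the two-dimensional regime bivariate with correlation
  r_RS ∈ {−.5, 0, .5}, always independent of the substantive traits;
* item slopes — i.i.d. log-normal with log-mean 0 and log-SD 0.3 (median 1),
  for substantive and style dimensions alike; the style-slope correlation
  factor is implemented as independent draws (0) versus copied draws (1);
* intercepts — fixed at (−2, −1, 0, −1, −2), which makes each item's
  category distribution mirror-symmetric in the substantive trait with the
  midpoint most likely at θ = 0.

Responses are drawn categorically from the model probabilities.  If any
(item, category) pair goes unendorsed the whole dataset is redrawn under an
incremented sub-seed (at most 100 times) so that every candidate model can
be fitted; redraw counts are reported.  Simulated data therefore contain no
missing values, equal intercepts across items, normal traits, and
style effects that hit every item through the same scoring row — real
questionnaires meet none of these idealizations exactly, so passing tests
certify the machinery under the stated conditions, not robustness to
violations of them.

Design cells are reproducible in isolation: each replication's seed is a
CRC-based hash of (base seed, condition content, replication index) fed
through numpy's `SeedSequence`, so parallel scheduling and grid subsetting
cannot change any record.

## Estimation

Fitting is marginal maximum likelihood with a Bock–Aitkin EM:

* Quadrature.  A fixed, axis-aligned Gauss–Hermite tensor grid per total
  dimensionality (21 / 15 / 13 / 9 points per dimension for T = 1…4), pruned
  of nodes carrying less than 1e−8 of the maximal prior mass.  A correlated
  latent prior enters through the node weights as the density ratio
  φ_R/φ_I — nodes never move between cycles, which keeps the E- and M-steps
  coherent, and the marginal log-likelihood provably non-decreasing.  (A
  grid re-rotated each cycle by the Cholesky factor of the current
  correlation estimate is more accurate per node but breaks the EM bound; we
  measured systematic log-likelihood *decreases* of 0.2–2 per cycle under
  that scheme, so it was rejected.)  The grid sizes were chosen by measuring
  model-comparison bias: a 9-point three-dimensional grid misstates the
  log-likelihood by −7 to +9 units at N = 300 depending on the latent
  correlation — enough to distort AIC decisions — while the pruned 13-point
  grid is stable within ~0.4 units across the admissible correlation range.
* E-step.  Person-by-node likelihoods come from one dense matrix product
  between the one-hot response matrix and per-node item log-probabilities;
  missing responses are all-zero one-hot blocks and thus contribute no
  factor (ignorable missingness, required by the resampling mode).
* M-step, items.  Each item's slopes and free intercepts solve a weighted
  multinomial-logit problem (concave), advanced by one damped Newton step
  with backtracking, batched over items.
* M-step, correlations.  The expected Gaussian log-density is maximized
  exactly over unit-diagonal correlation matrices via hyperspherical-
  Cholesky angles (≤ 6 parameters, L-BFGS), accepting the update only if it
  improves the objective.  Unit-diagonal rescaling of the posterior second
  moments — the obvious shortcut — is *not* the constrained maximizer and
  demonstrably walks the likelihood downhill.  Pairwise correlations are
  bounded at ±0.85 by a smooth penalty: when the two-dimensional style model
  is fitted to bipolar-truth data the ERS–MRS correlation wants to reach −1,
  a singular, unidentified boundary that the EM otherwise approaches in a
  crawl of hundreds of cycles for log-likelihood gains under 0.3.
* Acceleration.  SQUAREM-style extrapolation over the packed parameter
  vector, with projection back to the feasible region and a likelihood guard
  that falls back to the plain EM point, so the accepted trace stays
  non-decreasing.  The model battery warm-starts each larger model from the
  preceding fit (bipolar slopes seed both style slopes of the
  two-dimensional model).  Both are pure speed-ups: they change the path,
  not the objective.
* Reporting.  The log-likelihood entering AIC/BIC is recomputed once per fit
  on a dense grid (61 / 31 / 21 / 13 points per dimension) rotated by the
  Cholesky factor of the estimated correlation matrix.  The rotated
  evaluation stays accurate near strong correlations and, being common to
  all three models, removes the small working-grid bias from their
  comparison.
* Stopping.  Convergence is declared when the marginal log-likelihood change
  or the largest parameter change falls below tolerance (library defaults
  1e−6 / 1e−4, at most 500 cycles).  Monte-Carlo runs use the looser
  `STUDY_FIT_OPTIONS` (2e−3 / 2e−3, 120 cycles, plus a stall rule that stops
  a fit whose total gain over the last 15 cycles is below 0.15): selection
  decisions rest on criterion differences of whole units, and AIC+BIC
  selections under the loose rule agreed with tight-tolerance cold-start
  fits on 27/27 validation replications spanning all three regimes.  Non-converged fits
  are returned flagged and still scored by the selection layer; an optional
  L-BFGS fallback can polish them.

## Model selection and the study driver

AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln N; the lowest value wins, exact ties
(probability ~0 in floating point) go to the more parsimonious model, and a
non-finite criterion excludes that model with a warning.  The combined rule
answers the two practical questions in sequence: the conservative BIC gates
the presence of *any* response style (null wins unless some style model
beats it on BIC), then the liberal AIC decides between one and two style
dimensions.  The gate compares null against the better (lower-BIC) of the
two style models; comparing against each separately changes nothing when
null loses to either.

The study driver crosses N ∈ {250, 500, 1000}, J ∈ {10, 20}, D ∈ {1, 2}
with the regime-specific factors (12 / 36 / 216 cells), runs replications
with derived seeds, and reports classification accuracy — the percentage of
replications in which a criterion selects the generating model — overall,
per cell, per factor level, and in the two-dimensional regime as
slope-correlation pairs ("corr 1 / corr 0").  The resampling mode draws
people and items without replacement from one large dataset, patches each
unendorsed (item, category) pair by overwriting the item's first missing
entry with that category, and scores selections against a user-declared
assumed-true model.

## Problem sizes for verification

The packaged acceptance checks run the study at reduced scale on one CPU:
the six one-dimensional null crossings at 40–50 replications, and the four
strong bipolar crossings (σ_RS ∈ {1, 1.5} × N ∈ {500, 1000}, J = 20) at 40
replications, about 460 replications (~1400 fits) in total.  Per-cell
accuracy bounds use binomial slack (≥ 38/40 for a nominal 100%).  The
two-dimensional-regime cells and the D = 2 cells (four-dimensional fits)
are exercised for correctness in unit tests but their accuracy aggregates
belong to the long-running full design.

## Known limitations

* Within-item substantive multidimensionality, category-specific free
  slopes, tree and mixture representations are out of scope.
* Latent correlation estimates are truncated at |r| = 0.85; fits whose
  posterior wants a more extreme correlation (notably the two-dimensional
  model on bipolar-truth data) park at the bound, which leaves model
  ordering intact but makes the correlation itself a boundary estimate.
* No standard errors or information matrices are computed; the package
  compares models, it does not test parameters.
* Four-dimensional fits (two substantive dimensions plus separate ERS and
  MRS) use a 9-point-per-dimension pruned grid and are the slowest path;
  precise work at T = 4 should raise `quad_points` and expect minutes per
  fit.
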