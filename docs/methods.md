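# Methods

## Diffusion model

Pathology load per region evolves as f(t) = exp(−αHt) f(0) on the graph
Laplacian H = D − W of the connectome. H is symmetric positive semidefinite,
so the heat kernel is computed by one symmetric eigendecomposition
H = QΛQᵀ, K(t) = Q exp(−αΛt) Qᵀ; a single decomposition serves all N seed
profiles and all time points (the per-grid exponential table is cached).
Eigenvalues are clamped at 0 from below and kernel entries in
(−1e−10, 0) — eigendecomposition round-off — are clamped to 0. At t = 0 the
kernel is returned as the exact identity and trajectories return f(0)
exactly; without this, round-off of order 1e−16 in QQᵀ turns the degenerate
(zero-variance) t = 0 prediction into numerically defined garbage
correlations downstream.

Consequences used as test oracles: every kernel is doubly stochastic
(mass conservation), the uniform vector is stationary, the kernel family is
a semigroup, trajectories match explicit-Euler integration of
df/dt = −αHf, and on a connected graph f(t) → sum(f0)/N.

### Weight scale and the (α, t) grid

The analysis grid is α = 0.25 over integer time indices 0..19. Streamline
counts can be in the thousands; on a raw-count Laplacian this grid is past
steady state by t = 1 and carries no information. The default therefore
divides W by its largest entry before forming D − W
(``max-weight-scaled``), which preserves the operator's form and makes the
grid informative; the raw ``combinatorial`` operator remains selectable.
Time carries no physical unit and no calibration to calendar time is
attempted.

## Atrophy measurement

Per-region z = (X − μ)/σ against the control cohort, with sample (n−1) SD —
material at control cohort sizes around 19. All correlations use the
loss-oriented y = −z so that a positive correlation means the model
predicts the loss pattern. Volumes are taken as prepared upstream; no
intracranial-volume or age adjustment is applied here. Regions with zero
control variance are an error, not silently skipped.

## Epicenter inference

Single-seed screening correlates profile columns with y, excluding the
candidate seed's own data point (anti-circularity; verified by the
invariance of the fit to arbitrary perturbations of y at the seed regions).
Undefined correlations — zero variance on the non-seed points, notably
every seed's t = 0 column — are recorded as 0, flagged, and treated as
−∞ for arg-max purposes.

The initial candidate configuration applies, in order: zero R_i where the
best time index is 0 or T−1 (a boundary optimum means the grid did not
bracket the fit); zero R_i that are both negative and below the median of
the post-boundary-rule R vector (the conjunction is applied literally even
though it is redundant when the median is nonnegative); binarize R_i > 0.
If everything is zeroed, the single region with the highest R is the
fallback pool.

The combination search is greedy forward selection starting from the pool
member with the highest single-seed R, adding at each step the candidate
whose inclusion most increases the seed-excluded correlation, with t_max
re-optimized over interior time indices for every trial set. When no single
addition improves the fit, one *pair* addition is attempted before
stopping: two regions can improve the fit jointly while neither helps alone
(observed in roughly one of twenty noisy replicates against an
exhaustive-subset oracle; without the pair step the greedy result can trail
the exhaustive optimum by ~0.08 in r). A single backward pass then removes
any member whose removal does not decrease the fit (configurable,
default on). Ties break deterministically: smaller time index, lower region
index. Every evaluated candidate set is logged in ``search_trace``; r_best
is non-decreasing along the forward trace by construction.

Known limitation (shared with any correlation-based subset selection under
these exclusion rules): when atrophy noise reaches ~25% of the pattern
peak — which sits at the excluded seed point — the diffusion profiles of a
seed and its strong neighbors become statistically indistinguishable, and
the specific true seed is recovered in only ~40% of patients even though it
survives screening into the candidate pool in ~95%. At the 5%-of-peak
noise level of the default synthetic conditions, recovery exceeds 90%. The
search is also deliberately greedy; the overfitting risk of large seed sets
at high noise is real and visible in the search traces.

## Group analysis

PCA treats regions as variables and patients as observations (components
are spatial maps). It is computed by SVD of the mean-centered matrix
(sklearn backend) with a deterministic sign convention — each component's
largest-magnitude loading is made positive. Explained-variance fractions
are reported over all min(P−1, N) components and sum to 1; five components
are returned by default (configurable). Input is the *predicted* atrophy
map at each patient's t_max; measured-map PCA is available by passing those
maps instead.

Partial correlation is implemented by double residualization (least squares
with intercept on the covariate, Pearson correlation of residuals,
two-sided p from t with n − 3 df), equivalent to the closed form
(r_xy − r_xc r_yc)/√((1−r_xc²)(1−r_yc²)); both routes are asserted against
each other and against pingouin in tests. Peak-time associations use the
plain Pearson correlation (n − 2 df). Zero residual variance is detected
with a relative threshold (residual sum of squares below 1e−24 of the
centered signal), since exact zeros do not survive floating-point least
squares. Significance level 0.05, no multiplicity correction (the two
associations are exploratory).

## Synthetic cohort generator

The generator emulates the target study design: 82 regions, 19 controls,
17 patients, one seed per patient, diffusion to time index 7 on the 0..19
grid at α = 0.25, time-since-injury uniform on [1, 5] years and age at scan
uniform on [10, 17] years, independent of the injected pathology.

* **Connectome**: stochastic block model (default 4 modules,
  intra/inter-module edge densities 0.6/0.1 — a modest modularity typical
  of parcellated structural networks) with log-normal edge weights
  (σ_log = 0.8, right-skewed like streamline counts; mean = ``weight_scale``,
  default 50). Disconnected realizations are redrawn up to a bound.
  Per-control connectomes are small multiplicative jitters (SD 5%) of one
  template so control averaging is exercised.
* **Controls**: log-normal per-region baseline volumes (median 6000,
  σ_log = 0.5, a plausible spread of regional gray-matter volumes in mm³)
  with multiplicative between-subject noise (default 10% — typical
  inter-subject regional volume variability). The noise matrix is
  standardized to exact per-region sample moments, so the z-scoring
  reference satisfies σ_i = 0.1·μ_i exactly and the noise-free patient
  round-trip is algebraically exact rather than approximate.
* **Patients**: pathology g diffuses from the true seeds to the generating
  time; volume = μ(1 − gain·g/max g) + σ·ε with ε ~ N(0, noise_sd).
  Default gain 0.2 (20% volume loss in the most affected region, severe but
  plausible for moderate-to-severe injury; gain ≥ 1 is rejected) and
  noise_sd 0.1 control-SD units, i.e. z-score perturbations of SD 0.1
  against a generating pattern of peak 2 z.

The generating process is exactly the analysis model, by design: with
noise_sd = 0 the pipeline must return the true seeds, t_max equal to the
generating time, and r = 1, which is the module's core oracle. What passing
tests therefore show is correct *inversion* of the stated model at the
stated noise, not that real TBI atrophy follows linear network diffusion;
the generator has no lesion masks, no tractography artifacts, no
longitudinal structure, and its fit-vs-time-since-injury association is
null by construction.

## Problem sizes and determinism

All shipped experiments run at the study scale (82 regions, ≤ 50 patients)
or smaller; the full test suite takes ~10 s and the acceptance script a few
seconds on one CPU. Every random draw flows from a single integer seed
(numpy ``default_rng``/``SeedSequence``); pipeline runs write byte-identical
outputs given the same seed, and file I/O uses correctly-rounded float
parsing so write-then-read round-trips are exact.
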