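# Methods

## Model and estimator

The package estimates the multidimensional linear-nonlinear (LN) model: the
spike probability depends on the stimulus only through projections onto K
relevant dimensions, `P(spike|s) = r̄ g(s·ê₁,…,s·ê_K)`. Given candidate
dimensions, the projection distributions `P(x)` and `P(x|spike)` are
estimated as histograms with equal-width bins per axis spanning the observed
projection range of the current training data; the empirical gain is
`g = r̄ P(x|spike)/P(x)` on occupied bins (undefined, not zero, elsewhere).
The objective is the Kullback–Leibler information captured by the dimension
set (bits/spike); the order-2 Rényi divergence (the least-squares-equivalent
objective) is available as an alternative. Bins with `P(x) = 0` are excluded
from all sums; bins with `P(x) > 0, P(x|spike) = 0` contribute zero
(`p log p → 0`). No pseudocounts are added.

The rate-based information per spike, `I_spike = ⟨(r/r̄) log₂(r/r̄)⟩` over
frames, computed from the known model rates, bounds any reduced description
(data-processing inequality) and normalizes "percent information explained".
For recorded (rather than simulated) neurons this quantity must instead be
estimated from repeated trials; that estimator is not implemented here.

### Gradient discretization

The continuum gradient of the information combines, bin by bin, the
difference of conditional stimulus averages `⟨s|x,spike⟩ − ⟨s|x⟩` with the
derivative of the distribution ratio along the chosen axis. Two
discretizations are provided. The default (`method="flux"`) differentiates
the *histogram objective itself*: the binned information changes only when a
sample crosses a bin edge, so the derivative is the edge density of samples
(box kernel, one bin width) times the exact jump in I from relocating the
sample across its nearest edge. This form is exactly calibrated to the
finite-bin objective (it matches central finite differences of the binned
information to within a few percent at N = 20,000) and is what the optimizer
uses; both it and the textbook central-difference stencil
(`method="stencil"`, which points in the same direction but under-scales by
~5–10% at 6–11 bins) are restricted to bins whose neighborhood is occupied.
Either form evaluates as a single weighted sum over samples (one
matrix-vector product), which is what makes the optimizer fast.

## Optimizer

Each dimension is optimized by annealed gradient ascent: per iteration, one
gradient evaluation, a golden-section line search along the (projected)
gradient (12 objective evaluations over `[0, 2 × last accepted step]`, the
bracket halving when no uphill point is found), uphill moves always accepted
and downhill moves accepted with probability `exp(ΔI/T)`. The temperature is
initialized so the median `|ΔI|` of the first ten steps would be accepted
with ~50% probability, cools by 0.95 per iteration, and on convergence
(|ΔI| < 1e-5 bits for 10 consecutive steps) is multiplied by 100 while the
point is perturbed by a random step of 0.5 in unit-vector units. The bin
count steps from 6 to 11 across the run (every 200 iterations at the default
1200 iterations per dimension). The best accepted point, re-scored at the
final bin count, is returned.

Two search strategies share this machinery. *Sequential*: each new dimension
maximizes the 1D information with gradient and trial points projected onto
the orthogonal complement of all previously found dimensions, which are
never revised. *Joint*: each new dimension maximizes the full K-dimensional
information; every 100th iteration the earlier dimensions each receive one
annealed gradient/line step, and additionally a basin-hopping move — trial
replacement of the earlier dimension by each spike-triggered-covariance
(STC) candidate, polished by three strict-ascent steps, kept only on strict
improvement of the joint objective. Without this move a first dimension
captured by a spurious 1D information maximum (see below) could not be
rescued by local steps. For the first dimension the two strategies coincide.

**Whitened coordinates.** The objective is invariant under any consistent
invertible linear map of stimulus space, but for strongly correlated
ensembles raw-coordinate ascent is badly conditioned. The optimizer works in
symmetric (ZCA) whitened coordinates, with covariance eigenvalues floored at
1e-3 of their mean to bound noise amplification; sequential-mode
orthogonality constraints are mapped so they continue to hold exactly in the
original stimulus space, and all returned dimensions are in original
coordinates. With white-noise stimuli the transform is essentially the
identity.

**Starting points.** Each dimension's start is chosen as the best of several
candidates — a randomly drawn stimulus frame (different per dimension and
fold), the spike-triggered average (first dimension), and the extreme
eigenvectors of the whitened spike-triggered covariance difference — each
orthogonalized into the allowed search space, polished by three strict-ascent
steps, and scored at the coarsest bin count. The STC candidates are
essential: for gain functions symmetric in a projection (energy-, OR- and
divisive-type cells) the STA vanishes and the 1D information basin is
quartically flat in the overlap with the true filter, so ascent from a
random-ish start stalls near zero overlap; candidate polishing before
comparison matters because a suppressive dimension contributes little
information until its gain structure sharpens.

**Jackknife protocol.** Fits are repeated on four training sets, each
omitting a different contiguous quarter of the rows. Per-fold dimension sets
are aligned to the first fold by orthogonal Procrustes within the spanned
subspace (sign flip for K = 1) before averaging; averaged rows are
renormalized. Across-fold per-coefficient |mean|/SD gives the SNR maps;
per-fold overlap and information values give means and standard errors.

## Model cells

Gabor spatiotemporal dimensions are separable: a spatial Gabor (center,
orientation, spatial frequency, phase, Gaussian envelope) times a temporal
weight profile, flattened in embedding order and normalized to unit length.
Defaults: center of the grid, spatial frequency `2/min(H,W)` cycles/pixel,
envelope SD `min(H,W)/4`, biphasic temporal weights `(-0.4, 0.3, 1.0)`
(oldest lag first — sensitivity to feature onset). The standard cells are:

* `or_threshold` — quadrature Gabor pair (phases 0 and π/2); a spike occurs
  when `|sᵢ + nᵢ| > θ` for either projection, `nᵢ ~ N(0, σ²)`. The
  noise-averaged probability is the closed form
  `p = 1 − Π(1 − Q((θ−sᵢ)/σ) − Q((θ+sᵢ)/σ))`. θ and σ are not published for
  this cell; defaults are θ = 2.0 and σ = 0.5 in units of the projection SD
  of the ensemble at hand (on z-scored white noise this gives a spike
  probability of ~0.14/frame — moderately sparse firing with both dimensions
  informative). The rule is binary, so spikes are Bernoulli; the published
  firing rates in Hz for this cell are treated as non-normative.
* `divisive` — `r = γ[(s·ê₁)² + (s·ê₂)²]/[1 + ο(s·ê₃)²]`, the quadrature pair
  plus a suppressive Gabor at the orthogonal orientation. Calibration solves
  ο from `⟨1 + ο(s·ê₃)²⟩ = 4.26` (linear in ο) and then scales γ so
  `⟨r⟩ = 0.56` spikes/frame; spiking is Poisson.
* `quadratic_1d` — `r = γ(s·ê₁)²`, Poisson; the divisive cell with ο = 0 is
  the 2D member of this family.

## Synthetic ensembles

*White noise*: i.i.d. standard-normal pixels. *Naturalistic surrogate*
(stand-in for natural movies, which are not distributable with the package):
white noise spatially filtered to a `1/f²` power spectrum, temporally mixed
by an AR(1) process (coefficient 0.6), pooled pixel marginal histogram-
matched to a log-normal (rank-preserving), and z-scored. The surrogate
reproduces the second-order spatial/temporal correlations and the pointwise
non-Gaussianity (skew + heavy tails) that bias sequential searches; it does
*not* contain edges, occlusions, or phase-aligned structure, so effects that
depend on higher-order *phase* statistics of real scenes are under-expressed
— most visibly, projection pursuit regression is biased but less severely
than published comparisons on real movies show.

The log-normal shape parameter defaults to σ = 0.65 (excess kurtosis ≈ 13,
within the wide range reported for natural scenes). This value was
calibrated to the documented qualitative behavior of natural movies: mild
marginals (σ ≈ 0.5) produce too little higher-order correlation to bias the
sequential search at all, while extreme ones (σ ≥ 1) make a single global
"contrast" direction the maximally informative 1D projection outright, a
regime in which no method recovers the filters. At the default, the
sequential estimate of the 2D OR cell is strongly biased (the 1D-optimal
first dimension lies largely outside the relevant subspace) and joint
optimization recovers the pair — the phenomenon the surrogate exists to
emulate.

## Projection pursuit regression

The baseline fits `r ≈ r̄ + Σ f_k(s·v_k)` term by term on residuals: ridge
functions are piecewise-constant over 15 equal-width bins (degree-5
polynomial optional), alternated with gradient/line-search steps on the
dimension (χ² gradient `−2Σ(resid − f)(f'(x)) s`, with `f'` the
finite-difference slope across bins), until the χ² decrease stalls; one
back-fitting pass revisits each term. Initialization picks the better of the
residual-weighted mean stimulus and the top eigenvector of the
residual-weighted covariance. This is the core additive-model method only —
no multi-resolution schedule or term deletion.

## Evaluation

`subspace_projection` implements the Gram-determinant overlap `O`; it is
symmetric, invariant to invertible recombination within either set, and
reduces to |cosine| for K = 1. `percent_info_explained` re-bins the
projections of the fitted dimensions on held-out rows (11 bins per axis, the
final optimization resolution) and divides by `I_spike`; estimator noise can
push it slightly above 100%, which is reported, not clamped. The convergence
driver scales each cell's firing rate to a target spike budget (multiples of
K·D spikes, so the K·D/N_spikes abscissa is sampled identically across K —
equivalent to using fewer stimulus repetitions), simulates fresh spikes per
seed, and tabulates `O` for joint and sequential fits.

## Problem sizes and what the tests show

The published protocol runs ~50,000 frames at 16 × 16 pixels × 3 lags
(D = 768). The packaged experiments and tests run reduced versions sized for
a single CPU — the acceptance run uses 20,000 frames at 12 × 12 × 3
(D = 432, K·D/N_spikes ≈ 0.3, well-sampled per the convergence analysis);
the test suite uses 6×6 to 10×10 grids — while keeping the annealing
protocol (1200 iterations/dimension, bins 6→11, cooling 0.95, 4 jackknives)
wherever a finding depends on it. Passing tests demonstrate the estimators'
behavior on the synthetic ensembles; for real natural movies the sequential
and PPR biases are expected to be stronger (see the surrogate's limitations
above), and real neurons add history dependence and adaptation that the
Bernoulli/Poisson LN simulators do not model.

## Numerical choices

Stimulus matrices are processed in float32 (the objective is a histogram —
binning is insensitive to the last bits); dimensions are returned in
float64, unit-normalized after every accepted step. Degenerate binning axes
(constant projections) widen to a single occupied bin rather than erroring.
Jackknife folds with no training spikes raise with the fold index. K > 3 is
refused by default (the histogram estimator's curse of dimensionality), and
joint fits renormalize each dimension after every accepted step to prevent
scale drift. All randomness flows from one integer seed per run through
per-(fold, dimension) seed sequences, so jackknife folds explore different
starting frames while runs remain exactly reproducible.
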