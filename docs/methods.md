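# Methods

## Model and procedure

`anmcausal` decides, for a pair of continuous variables (X, Y), whether the
data are better explained by the additive noise model (ANM)

    Y = f(X) + E_Y,   X independent of E_Y        (forward)

or by

    X = g(Y) + E_X,   Y independent of E_X        (backward),

with f, g arbitrary smooth functions.  For generic nonlinear f only one of
the two models can hold; in the linear-Gaussian case both hold and the
direction is unidentifiable.  The assumptions are the usual bivariate-ANM
ones: no feedback, no hidden confounder, no selection bias, continuous
variables.

The procedure:

1. Split the sample at random into a training half and a test half
   (default 50/50; both halves must have at least 10 points).
2. Standardize x and y; fit nonparametric regressions y ~ x and x ~ y on
   the training half.
3. Predict out-of-sample residuals E_Y = y − f̂(x) and E_X = x − ĝ(y) on
   the test half.
4. Compute the dependence of each residual on its predictor with the
   Hilbert–Schmidt independence criterion, HSIC²(E, X) =
   (1/m²) Tr(K_E H K_X H) with Gaussian kernels and the centering matrix
   H = I − (1/m)11ᵀ.
5. Decide X → Y if HSIC²(E_Y, X) < HSIC²(E_X, Y), Y → X if greater,
   undecided on exact equality (a measure-zero event in floating point;
   no tolerance band is applied).

The out-of-sample split matters: in-sample residuals are biased toward
independence by the fit itself.

The presence of causation (in either direction) is tested with the
asymmetry statistic T_C = |HSIC²(E_Y, X) − HSIC²(E_X, Y)| and a
permutation reference distribution (below).

## HSIC details

* Biased V-statistic, exactly the trace form above; no unbiasing
  correction and no Gamma approximation.
* Gaussian kernel k(a, b) = exp(−(a−b)²/(2σ²)).
* Bandwidth: median of all pairwise absolute differences of the vector
  being kernelized, computed separately for each input (fallback 1.0 when
  the median distance is zero).  The median heuristic is scale-adaptive,
  which together with the up-front standardization of x and y makes the
  direction decision invariant to affine rescaling of either variable.
  A shared bandwidth for the two compared HSIC² values was considered and
  rejected: after standardization the per-vector medians are already
  nearly equal, and per-vector adaptation behaves better when the two
  residual distributions differ.
* Tiny negative traces (> −1e−12, pure rounding) are clipped to 0; a
  more negative value raises, since it would indicate a bug.

## Regression methods

* `spline` (default): penalized cubic B-spline (P-spline).  20 basis
  functions on a uniform extended knot grid, second-order difference
  penalty, penalty weight selected by generalized cross-validation
  minimized over a 45-point log-spaced grid (1e−6 … 1e5) using the
  Demmler–Reinsch orthogonalization, so the whole GCV path costs one
  small eigendecomposition.  The uniform knot grid is essential: it makes
  the penalty's null space exactly the linear functions, so straight-line
  data are reproduced to machine precision at any penalty.  The grid cap
  of 1e5 corresponds to ~2 effective degrees of freedom (a straight
  line) at the sample sizes in use and keeps the penalized system well
  conditioned.  This construction was chosen over a classic
  every-point-a-knot smoothing spline for speed — the permutation
  studies need tens of thousands of fits — and a regression test checks
  it against scipy's generalized-cross-validated smoothing spline on a
  common fixture.
* `loess`: local polynomial regression with fixed span 0.75
  (statsmodels lowess); predictions interpolate the fitted curve.
* `bspline`: unpenalized least-squares cubic B-spline with the number of
  interior knots (0–16) selected by GCV.

All methods standardize x and y internally and de-standardize
predictions.  Outside the training range the curve continues linearly
from the boundary value and slope — extrapolation with a cubic tail is
wild exactly where there is no data, and residuals at out-of-range test
points would otherwise be dominated by it.

## Permutation test

H₀: no causation X → Y and no causation Y → X.

Default scheme: both regressions are fitted once on the training half;
for each of n_p permutations the test-half y values are shuffled while x
stays fixed, the permuted values are pushed through the *fixed* fitted
curves, and T_C is recomputed.  Because the residual maps are fixed
functions estimated on an independent half, the observed and permuted
statistics are exchangeable whenever X and Y are independent, so the
test is exactly valid there (up to the discreteness of the plain
proportion p-value, which is used as is, without the +1 correction; the
attainable minimum is 0, displayed as "< 1/n_p").  Under dependence
without causation the permutations destroy the dependence, the permuted
T_C concentrates near zero more slowly than the observed one, and the
test becomes conservative — simulations with a common-cause null at
n = 500 give an empirical type-I error of ~0 at nominal 0.05.

An alternative scheme (`refit=True`) permutes y over the whole sample
and refits both regressions (and bandwidths) per permutation, reusing
the train/test partition (or re-randomizing it with
`reshuffle_split=True`).  It was implemented first and measured: it is
also calibrated under independence but badly anticonservative under the
common-cause null (empirical type-I ≈ 0.38 at nominal 0.05, n = 500),
because refitting on permuted data re-creates the near-cancellation of
the two directional HSIC² values that the associated observed data do
not exhibit.  The fixed-fit scheme is therefore the default: a test that
errs on the conservative side is preferable to one that rejects a true
null a third of the time.

The partition is held fixed across permutations so that permutation
variability reflects the statistic, not the split.

## Synthetic-data generators

All generators draw n observations i.i.d. (equivalent to the
population-then-subsample design they emulate, since every draw is
independent) and are deterministic given (family, parameters, seed).

* `model1`/`model2`: Y = X + b·X² + ε; `model3`/`model4`:
  Y = X + b·log|X| + ε (X values with |X| < 1e−12 are redrawn);
  `model5`/`model6`: Y = X + b·e^X + ε.  X ~ N(0,1); ε ~ N(0,1) for odd
  models, Student t with 5 df for even.  b = 0 is the linear-Gaussian
  limit where the direction is a coin flip; the false-decision-rate
  driver counts backward decisions (ties as 0.5, so the unidentifiable
  case converges to 0.5 rather than depending on tie-breaking).
* `null-independent`: X, Y independent N(0,1).
* `null-associated` / `example-c-confounder`: X = Z + ε₁, Y = Z + ε₂
  with Z ~ N(0,2), ε₁, ε₂ ~ N(0,1).  Closed forms: cov(X,Y) = Var(Z) = 2,
  Var(X) = Var(Y) = 3, ρ = 2/3, cov(X, ε₂−ε₁) = −Var(ε₁) = −1 — derived
  symbolically (sympy.stats) and cross-checked by Monte-Carlo at n = 10⁶.
  The `null-associated` variant divides both variables by √3 so the
  marginals are N(0,1); an additive confounder construction cannot have
  unit-variance marginals otherwise.
* `power-bump`: Y = Σⱼ₌₁³ wⱼ exp(−γ(x−xⱼ)²) + N, wⱼ ~ U(0,1),
  xⱼ ~ N(0,1), γ ~ N(0,1) redrawn until positive (a negative γ makes the
  "bumps" divergent, which cannot be the intent), N ~ N(0, 0.01).
* `example-b-quadratic`: Y = 5X² + ε, X ~ U(−2,2), ε ~ U(−1,1) —
  causation with exactly zero population correlation (odd symmetry).
* `cubic-uniform`: Y = X³ + ε, X ~ U(−1.5, 1.5), ε ~ U(−1,1).

These generators produce clean i.i.d. draws from known mechanisms; real
expression data have library-size and batch effects, heavy tails,
measurement-specific noise and network-wide confounding that none of
them emulate, so passing simulations demonstrate correctness of the
machinery, not performance guarantees on any real dataset.

### Planted regulatory network

`generate_planted_network` builds a genes × samples matrix with a known
edge set for benchmarking the pairwise orientation pipeline.  Genes are
split into a regulator and a target layer and edges are planted
regulator → target, round-robin so fan-in/fan-out stay balanced (at the
default 10 genes / 8 edges: fan-out ≤ 2, fan-in ≤ 2).  The depth-1
layout is deliberate: in deeper cascades, ancestor pairs are genuinely
causal yet count as false against the direct-edge truth set, and
fan-out hubs flood the top ranks with confounded sibling pairs, so
neither variant measures orientation ability cleanly.  Mechanisms are
z + c·z² or z + c·z³ of the standardized parent (alternating, c = ±1 at
random), i.e. the identifiable quadratic/cubic ANMs of the pair studies;
target noise is N(0, 0.25); unregulated genes are N(0,1).

## Network orientation

Every unordered gene pair is scored with the direction procedure
(expression standardized per gene); each pair emits one directed edge in
the inferred direction carrying T_C; exactly tied pairs are omitted.
Edges are ranked by T_C descending (ties broken lexicographically for
determinism).  T_C is used for ranking because it is the package's
single scalar evidence-of-causation statistic; optional permutation
p-values can be attached but are not used for ordering.  No
multiple-testing correction is applied — the intended use is top-k
inspection against a reference pathway, and detection accuracy at k is
matches/k (direction-sensitive or not).

## Problem sizes and numerical defaults

Simulation drivers default to 200 replicates (and 200 permutations per
replicate in calibration runs); the full-scale designs with 1,000
replicates × 500 permutations are available by passing those values
explicitly.  Default train fraction 0.5; default sample size in the
drivers n = 500; HSIC bandwidth as above; spline grid as above.  Seeds:
every driver spawns independent 31-bit child seeds from its master seed
(numpy SeedSequence), so replicate streams are independent and
reproducible.

## Known limitations

* Bivariate only: no conditioning, no confounder detection, no cycle
  handling; pairwise network edges ignore the rest of the network.
* The permutation causation test is conservative under association
  without causation (see above), and its p-value resolution is
  1/n_permutations.
* The direction rule is uninformative in the linear-Gaussian limit by
  the theory itself; near-linear mechanisms need large n.
* LOESS predictions interpolate fitted values at training points, so
  they are slightly less smooth between points than the spline methods.
* Detection accuracy compares against direct edges only; indirect
  regulation is counted as error.
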