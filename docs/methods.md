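# Methods

This note documents the models implemented in `effimarkov`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the known limitations. It states no empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Efficiency measurement: non-oriented SBM with super-efficiency

A decision-making unit (DMU) k converts m inputs x_k into q outputs y_k.
The slack-based measure evaluates k against the convex technology spanned
by the frontier pool:

    min  ρ = (1 − (1/m) Σ_i s⁻_i / x_ik) / (1 + (1/q) Σ_r s⁺_r / y_rk)
    s.t. x_k = X'λ + s⁻,  y_k = Y'λ − s⁺,  λ, s⁻, s⁺ ≥ 0,  Σλ = 1 (VRS).

ρ ∈ (0, 1], and ρ = 1 exactly when no nonzero slack is feasible. The
fractional program is linearized by the Charnes–Cooper change of variables
(scale every variable by t > 0 with the denominator normalized to 1),
which is exact here because the denominator is bounded away from zero for
positive data. Units classified efficient (ρ ≥ 1 − ε, ε = 1e-6) are
re-scored by the super-efficiency SBM: the reference set excludes k, and
the program finds the closest dominating point (x̄ ≥ x_k, ȳ ≤ y_k) on the
peer technology, with score mean(x̄/x_k) / mean(ȳ/y_k) ≥ 1. The pipeline
score is the piecewise combination (SBM if inefficient, super-SBM
otherwise), so scores bracket 1 on both sides and rank efficient units.

Choices and caveats:

- **Returns to scale.** Default VRS (Σλ = 1); CRS available. The
  non-oriented super-SBM with VRS is feasible for any positive data
  (choose any λ on the simplex and take componentwise maxima/minima), but
  a `super_infeasible` status is still propagated rather than silently
  replaced by a number should a solver ever report infeasibility.
- **Frontier pool.** Default `per_year`: each year's cross-section is its
  own frontier, treating efficiency as a relative position within the
  year. A `pooled` intertemporal frontier is available. The packaged
  score panel was produced externally, so neither mode is validated
  against it; DEA correctness is instead established property-based
  (λ-grid oracles, units invariance, monotonicity, synthetic frontier
  recovery).
- **Solver.** `scipy.optimize.linprog` (HiGHS), deterministic and
  seedless; default primal/dual feasibility tolerances (1e-9 scale).
- **Zero data.** The SBM divides by every indicator, so zeros are
  rejected at load; an optional repair substitutes a configurable
  positive epsilon (off by default).

## Distribution dynamics: Gaussian KDE

Each observation year's scores are smoothed by
f(x) = (1/(n·h)) Σ φ((x − Y_i)/h) with bandwidth h = c·n^(−0.2).

- **Bandwidth constant.** Default c = 0.9·min(sd, IQR/1.34) — Silverman's
  rule of thumb with the robust spread. The pure normal-reference
  constant 1.06·sd systematically oversmooths mixtures: on the packaged
  panel it erases the secondary mode of several cross-sections, while the
  robust rule (Silverman's own recommendation for multimodal densities,
  and the default of standard statistical software) preserves the
  two-cluster structure the descriptive analysis tracks. The constant is
  exposed everywhere; peak counts are configuration-dependent and the
  frozen default is recorded in the run manifest.
- **Grid.** 512 points spanning the data range ± 3h (configurable); the
  trapezoid mass on an adequate grid is within 1e-3 of 1.
- **Peaks.** Local maxima with prominence ≥ 5% of the curve maximum
  (scipy `find_peaks`), with boundary maxima included explicitly since
  prominence is undefined at grid edges. Tail masses are reported against
  caller-supplied bounds when comparing years (the bounds of a single
  curve's own quantiles are only a within-curve description).

## State classification: exact Fisher–Jenks

Four ordered states (low, medium-low, medium-high, high) partition the
score line, minimizing the total within-class sum of squared deviations by
an O(kn²) dynamic program — the exact optimum, with ties broken toward the
smallest boundary index for determinism; tests verify equality with
exhaustive partition enumeration for n ≤ 15. Cuts sit at midpoints between
adjacent class boundary values; classes are left-closed (a value equal to
a cut belongs to the upper class), the top class unbounded.

- **Fitting sample.** Default `per_year`: each year's cross-section gets
  its own breaks, so states are relative positions within the year. This
  choice, rather than pooling all unit-years, reproduces the published
  transition matrix, origin totals, initial distribution, and 2010→2019
  transition-type map of the packaged panel exactly; `pooled` (one
  comparable state space across years) is provided as an option and
  yields a visibly different kernel.
- **Lag classification.** Spatial-lag values are discretized by breaks
  refit on the lag values themselves (per year, matching the own-state
  pooling), again because that choice reproduces the published
  lag-conditioned matrices; classification under the own-value breaks is
  available as `classification="shared"`.

## Spatial Markov analysis

The spatial lag of unit i in year t is Σ_j w_ij·ρ_jt with w the
row-standardized first-order contiguity matrix (equal weights over
in-sample neighbors). Each one-step transition t → t+1 is conditioned on
the unit's lag state in the origin year t; the conditional count matrices
sum element-wise to the traditional counts by construction. Empty origin
rows are emitted as zeros and flagged, never renormalized.

The packaged contiguity graph covers land borders among the 20 in-sample
provinces only; neighbors outside the sample (e.g. eastern provinces) are
deliberately dropped, and no isolated unit exists in the fixture. This
reconstruction reproduces the published lag-1, lag-3 and lag-4 conditional
matrices exactly and the lag-2 matrix up to a single boundary observation
(one medium-high province-year falls in lag state 2 here vs. lag state 1
in the published table), consistent with a marginally different weight
matrix in the original computation. Isolated units in user-supplied
graphs are excluded from conditioning with a warning.

## Limiting distributions

Long-run prediction iterates π_{t+1} = π_t P until the L1 change falls
below 1e-12 (cap 1e6 iterations). For irreducible aperiodic kernels this
is the unique stationary distribution (tests check agreement with
eigenvector/linear solves to 1e-10); for reducible kernels the limit is
start-dependent and is returned for the supplied π₀ (tests check the
absorption closed form via the fundamental matrix). Periodic kernels are
handled by an optional Cesàro mode implemented with a doubling scheme
(M_{k+1} = (M_k + M_k·P^(2^k))/2), which converges geometrically where the
plain running average converges only at rate 1/n. Rows of rounded
published matrices are renormalized to sum exactly to 1 before iteration;
without this, the printed 4-decimal tables drift in total mass and the
iteration cannot meet a 1e-12 tolerance.

Two published limit rows for the packaged panel are internally
inconsistent: the no-lag row sums to 0.9895 and the lag-4 row to 1.0156,
although the published lag-4 matrix makes the high state absorbing, so its
exact limit is the point mass (0, 0, 0, 1). These look like
finite-iteration/rounding artifacts in the original computation. The
package returns the mathematically defined limits; the two inconsistent
rows are excluded from the reproduction checks, and the packaged copies
are retained verbatim for comparison.

## Synthetic generators

- **DEA panels.** Frontier units are made efficient *by construction*:
  each gets a dedicated coordinate at which it is the strict global
  extreme (a uniquely largest output, or uniquely smallest input), so no
  convex combination of peers can weakly dominate it; this caps the
  number of frontier units at m + q. Every non-frontier unit is a
  frontier unit with all inputs inflated by a factor > 1, hence strictly
  dominated. No noise by default (the frontier must be exact); the
  generator does not imitate the magnitudes or correlation structure of
  real yearbook data, so frontier-recovery tests establish correctness of
  the scoring, not realism of the data model.
- **State chains.** Units evolve under a known 4×4 kernel, or under four
  kernels indexed by the current lag class on a supplied graph.
  Continuous scores are drawn uniformly inside each state's band with a
  5% margin, so classification recovers the simulated states exactly —
  deliberately removing classification error to isolate the transition
  estimator. Real panels have boundary mass and serially correlated
  scores that this generator does not emulate.
- **Randomness.** All generators draw from `numpy.random.default_rng`
  (PCG64) seeded from the generator's spec object, making outputs
  reproducible across runs
  and platforms; stochastic tests state their seeds.

## Problem sizes used in the checks

The estimation-consistency checks use 2,000 chains × 50 steps for the
unconditional kernel (±0.02 element-wise) and 2,000 units on a ring × 60
steps for the lag-conditioned kernels (±0.03 on rows with > 1,500 origin
observations — at smaller counts the binomial sampling error alone
exceeds the band). Grid oracles for the SBM use 3-DMU instances with
simplex grids of 120–400 steps, chosen so the grid's own resolution error
is below the 1e-3 comparison tolerance.

## Known limitations

- Raw indicator data for the packaged study are not redistributable, so
  the packaged score panel is an input, not a computed output; DEA
  validation is synthetic/property-based.
- Annual means recomputed from the 3-decimal packaged scores can differ
  from originally published means by up to half a unit in the last
  printed place; comparisons therefore use a one-ulp (1e-3) budget.
- Natural-breaks classification is sensitive to its fitting sample by
  design; per-year and pooled modes answer different questions (relative
  position within the year vs. absolute level across the decade).
- The contiguity matrix is a reconstruction; alternatives (distance
  bands, k-nearest, economic weights) are not implemented.
- No Malmquist decomposition, orientation variants, undesirable outputs,
  bandwidth cross-validation, higher-order chains, or map rendering.
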