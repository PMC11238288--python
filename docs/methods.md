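# Methods

## Design and coding

The design machinery targets the rotatable-style 3-factor central
composite design: 8 factorial points (all coded coordinates ±1), 6 axial
points at coded distance α, and replicated center runs. Factors are
stored as (center, step) pairs rather than level lists so off-design
query points (e.g. 4.4 min) are representable; coded coordinates are
always recomputed from the factor definitions when data are read, never
ingested from files. For the bundled parsley-juice experiment the level
sets (4…12 min, 60…100 %, 40…60 °C, with steps 2/10/5 around centers
8 min / 80 % / 50 °C) force α = 2 and six center
replicates, giving 20 runs. The
generator emits a canonical deterministic run order (factorial in Yates
order, axial pairs by factor, then centers); equality with the bundled
layout is asserted as a multiset, since the original run order is an
artifact of the source software.

With α = 2 and six centers the coded columns satisfy Σxᵢ² = 16,
Σxᵢ⁴ = 40 and Σxᵢ²xⱼ² = 8, which the tests assert by direct summation.

## Fitting and ANOVA

Both model orders are fitted by OLS (statsmodels) on the run means in
coded units. Fitting in the coded basis is load-bearing: the per-term
adjusted sums of squares of the ANOVA are basis-dependent, and only the
coded basis reproduces the published decomposition. Replicate standard
deviations are carried for display but not used as weights — the source
analysis fits means, and the replicate SDs are too few to estimate a
stable variance function.

The ANOVA uses adjusted (type-III) sums of squares, computed by
refitting without each term's column(s); for this orthogonal design the
single-df linear and interaction terms coincide with their factorial
contrasts Σ(zy)/Σz², an identity the tests assert against the fitted
coefficients. The three square columns are mutually correlated (their
cross-moment is 8, not 0), so the "square" group SS is legitimately
smaller than the sum of its single-df members — a property visible in
the published table as well (8.20 vs 4.16 + 5.54 + 0.13). Pure error
comes from exact replicate design points only (the six centers);
lack-of-fit is the remainder of the residual. F statistics divide each
adjusted MS by the pooled error MS (lack-of-fit by pure-error MS), with
upper-tail F p-values. Predicted R² uses PRESS via the leave-one-out
leverage identity eᵢ/(1−hᵢᵢ), so no refitting is needed.

The first-order (MLR) model is fitted to all 20 runs. Note that an OLS
first-order fit of a balanced design must predict the grand mean at the
center (7.78 for chlorophyll), whereas the source study's printed MLR
center prediction is 6.76; the preprocessing behind that column is not
recoverable, so the package computes the conventional fit and the
published MLR prediction columns are not used as test oracles.

## Adequacy metrics

RMSE uses denominator n (not n − p): this is the convention that
reconciles the published ascorbic-acid RSM RMSE of 1.110 with the ANOVA
residual SS (√(24.57/20)). AAD normalizes by the experimental value.
The published chlorophyll RSM RMSE of 0.007 is inconsistent with the
same table's SSE (√(0.0973/20) ≈ 0.070) and is treated as a misprint;
the published MLR metrics and RSM AAD values are likewise not
reproducible from the printed prediction columns under the conventional
definitions, so the package computes the conventional definitions and
documents the discrepancy rather than reverse-engineering it.

## Particle swarm

Global-best PSO with synchronous updates: all particles move, all are
evaluated, then personal and swarm bests are refreshed. Defaults follow
the study configuration: 50 particles, 50 iterations, c₁ = c₂ = 0.5,
inertia decayed linearly from w_start = 1.0 to w_end = 0.1 (both
exposed). r₁, r₂ are drawn per particle, per dimension, per iteration
from U[0, 1). Maximization is the native mode; minimization negates the
fitness. Improvement is strict, so the best-fitness trace is monotone
non-decreasing by construction.

Choices the update equations leave open:

- **Position initialization** — uniform over the box.
- **Velocity initialization** — uniform on (lower − x, upper − x), so a
  particle's first move cannot leave the box but carries basin-crossing
  momentum. This matters: the fitted ascorbic-acid surface has a second
  local maximum on the opposite temperature face (140.57 mg/100 g at
  ~(6.9, 66, 40) vs the global 147.51 at (4, 82.5, 60)), and with
  zero-velocity initialization the swarm collapses onto whichever basin
  holds the first swarm best in roughly half of seeded runs. With
  randomized velocities the swarm agrees with a 201³ grid-search oracle
  to 0.01 in ≥ 95 % of seeded runs on both fitted surfaces.
- **Boundary handling** — clamp the violating coordinate to the bound
  and zero that velocity component; the least-surprising box-constraint
  rule, and it lets the swarm settle on active bounds (both fitted
  optima have at least one active temperature bound).
- **No velocity clamping** beyond boundary handling: with w ≤ 1 and
  small attraction coefficients the swarm is stable on these quadratic
  surfaces.

Optimization runs in natural units over the process box (time 4–12 min,
amplitude 60–100 %, temperature 40–60 °C); for an affine coding the
argmax is invariant to this choice, and natural units match how
operating conditions are reported. `grid_search_oracle` provides an
independent exhaustive check (chunked evaluation, refusing lattices
above 10⁸ points).

## Validation arithmetic

Percent difference between a model promise and a confirmatory
measurement is 100·(predicted − experimental)/predicted — the predicted
value is the denominator, which is the convention that reproduces both
published validation percentages (5.78 %, 4.26 %) from the published
predicted/experimental pairs.

## Synthetic data

`GroundTruth` couples a known coded-unit quadratic with homoscedastic
Gaussian noise on the run means — the simplest process consistent with
the OLS/ANOVA assumptions. The default noise_sd of 0.1 sits inside the
bundled experiment's replicate-SD range (0.03–0.65 for chlorophyll).
Seeds are explicit everywhere; there is no global random state. What
the generator does *not* emulate: heteroscedastic or run-order-correlated
errors, replicate structure away from the center, non-quadratic
curvature, and measurement rounding. Passing recovery tests therefore
demonstrate internal consistency of generator + fitter (unbiasedness,
nominal ~95 % t-interval coverage, RMSE monotone in noise), not
robustness to real-data pathologies.

## Assay calculators

The chlorophyll calculator defaults to the classic 80 %-acetone
coefficient set (chl a = 12.7·A663 − 2.69·A645, chl b = 22.9·A645 −
4.68·A663, total = 20.2·A645 + 8.02·A663 mg/L, converted to mg/100 mL),
used with the DMSO/acetone extraction protocol the source study cites;
all coefficients are overridable. The DCPIP titration assumes 1:1
stoichiometry (mass = MVC·CDPIP·VDPIP, scaled by sample volume), with
an explicit density input for the mg/100 g basis. DPPH inhibition is
100·(A0 − A1)/A0. TPC inverts a fitted gallic-acid standard curve. All
calculators are homogeneous of degree 1 in their signal inputs, which
the tests exercise as linearity properties.

## Problem sizes and numerical choices

The acceptance script fits 20-run tables, uses 10 swarm seeds per
surface (deriving sub-seeds from `--seed`), and a 201-points-per-axis
grid oracle; the coverage experiment uses 500 replicates at noise
sd 0.1 — sizes at which every quantity is stable to well within the
comparison tolerances. Degenerate inputs fail loudly: rank-deficient
model matrices raise a singular-fit error, zero-variance responses make
R² undefined, zero experimental values make AAD undefined (naming the
offending run), and invalid swarm configurations are rejected before
any fitness evaluation.

## Known limitations

- Single-response optimization only; the source study's confirmatory
  operating point came from an undescribed multi-response trade-off and
  is treated as an input to evaluate, not an output to reproduce.
- The published MLR prediction columns and MLR-PSO optima are not
  reproducible from the printed data under conventional definitions
  (see above); the package's MLR is the standard OLS first-order fit.
- No blocking, face-centered designs, randomization schedules, or
  neighborhood-topology / constriction-factor PSO variants.
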