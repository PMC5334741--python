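# Methods

## Problem and data model

A panel of m decision makers judges n alternatives by pairwise comparison.
Expert k supplies a reciprocal interval fuzzy preference relation
R^k = (r_ij^k) with r_ij^k = [l_ij^k, u_ij^k] ⊆ [0, 1], diagonal [0.5, 0.5]
and reciprocity l_ij + u_ji = u_ij + l_ji = 1; panel weights ŵ_k ≥ 0 sum
to one and scale each expert's deviations in every model. Validation
enforces these invariants to a configurable tolerance (default 1e-9);
entries outside the conventional elicitation scale [0.1, 0.9] raise a
warning only, since the optimization models constrain judgments to [0, 1].

Two consistency notions are used. *Additive* consistency of a crisp
relation requires r_ij + r_js = r_is + 0.5 on all pairwise-distinct
triples; by reciprocity it suffices to check ordered triples i < j < s, and
degenerate triples with a repeated index are excluded. An interval relation
is additively consistent when some crisp selection inside its intervals is
(an LP feasibility problem over the selections). *Priority-vector*
consistency requires a normalized ω ≥ 0 with l_ij ≤ ω_i/(ω_i+ω_j) ≤ u_ij;
clearing denominators makes the feasibility region linear, and the
implementation maximizes the minimum slack so a returned witness is as
interior as the corridor allows.

## Consensus models

All eight models are goal programs compiled to a backend-neutral linear
program and solved with HiGHS (scipy.optimize.linprog). Variables are
ordered lexicographically so repeated runs are bit-identical. Alternative
optima are a fact of life in these LPs; the optimal *value* is unique and
is what the package reports, while solution points are compared only up to
the optimal face (the tests assert that reference solutions lie on it).

### Regime I (crisp ideal, additive consistency as a goal)

Decision variables: upper-triangle ideal entries r*_ij ∈ [0, 1] (the lower
triangle is 1 − r*_ji by construction; the reported reference ideals are
reciprocal, and reciprocity also halves the variable count), per-expert
selection coefficients α_ijk ∈ [0.1, 1] picking r_ijk = l + α(u − l), and
nonnegative deviation pairs:

* consensus: r_ijk − r*_ij = n_ijk − p_ijk per pair and expert;
* consistency: r*_ij + r*_jl − r*_il − 0.5 = d+_ijl − d−_ijl per ordered
  triple i < j < l (one deviation pair per triple — a two-index pair shared
  across the middle index would force sums to be constant in j, which the
  model cannot intend);
* fraternity bound: ŵ_k Σ_pairs (n + p) ≤ D per expert (the per-expert
  aggregate reading; the max-deviation prose definition is per element, but
  the aggregate is what the reference results realize);
* equality rows: ŵ_k(n_ijk + p_ijk) − ŵ_t(n_ijt + p_ijt) = ρ − η per pair
  and expert pair k < t.

Objectives (all also carry Σ(d− + d+), pulling the ideal toward exact
consistency): freedom Σ_k ŵ_k Σ(n+p); fraternity D; equality Σ(η+ρ);
mixed λ1·D + λ2·Σŵ(n+p) + (1−λ1−λ2)·Σ(η+ρ). The mixed consistency term
is implemented as (d− + d+); a printed signed variant (d− − d+) would
*reward* inconsistency and drive the ideal to the box corners, so it is
treated as a typo. Deviation sums run over upper-triangle pairs by default
(`pair_scope="upper"`); the double-sum literal reading is available as
`pair_scope="full"`.

Default α bounds are [0.1, 1]: with them (and upper-pair scope) the solver
reproduces the reference case study's freedom/fraternity/equality columns
exactly — objective values to 4 decimals, and every tabulated α and ideal
entry lies on the corresponding optimal face. The loosest reading α ∈ [0, 1]
remains available via `SolverConfig(alpha_bounds=...)`.

Priorities for a crisp ideal come from the multiplicative model
r_ij = ω_i/(ω_i+ω_j), inverted by the row geometric mean of the odds
r_ij/r_ji and normalized; the inversion is exact whenever the relation is
multiplicatively consistent. Off-diagonal entries of exactly 0 or 1 have
infinite odds and are rejected; a least-squares variant
(`derive_priorities_least_squares`, closed-form KKT solution) is provided
as a sensitivity check and as the fallback for such degenerate ideals.

### Regime II (interval ideal, priority-vector consistency as a constraint)

The natural model is bilinear (ideal endpoints multiply ω). It is
linearized by introducing, per upper pair, product variables for each ideal
endpoint against ω_i and against ω_j, multiplying the endpoint-deviation
equations through by ω_i and ω_j, and bounding each product deviation by
its plain counterpart (0 ≤ barred ≤ plain); the plain deviations carry the
objective. The consistency corridor becomes
r*l·ω_i + r*l·ω_j ≤ ω_i ≤ r*u·ω_i + r*u·ω_j. One printed corridor row
bounds ω_j instead of ω_i; multiplying the ratio condition by (ω_i + ω_j)
forces ω_i, and that reading reproduces the reference results, so the ω_j
form is treated as a typo. Products of upper ideal endpoints are bounded by
the matching weight (r*u ≤ 1 implies r̄*u ≤ ω). Strictly positive weights
are not enforced (the models do not); reconstruction guards against zero
denominators instead.

The fraternity model bounds per-expert aggregate lower- and upper-endpoint
deviations by D1 and D2 and minimizes D1 + D2; equality equalizes endpoint
deviations per pair and expert pair; mixed combines the three blocks with
λ1/λ2/(1−λ1−λ2) as in regime I.

Priorities are the ω variables at the optimum. Ideal intervals are
recovered as r* = (r̄* + r̄̄*)/(ω_i + ω_j) — both products stand for the
same quantity, so their ratios against ω_i and ω_j should agree, and the
largest disagreement is reported as `reconstruction_residual` (infinite
when a pair's weights both vanish, in which case the entry is undetermined
and reported as [0, 1]). The final report symmetrizes the intervals to
enforce reciprocity; under alternative optima entry-level equality with any
particular reference tabulation is not guaranteed, only the objective value
and the corridor property are.

### λ conventions and the reported mixed value

In the combined models λ1 multiplies the max-deviation block and λ2 the
weighted-total block, so (λ1, λ2) = (1, 0) recovers fraternity and (0, 1)
recovers freedom; the package keeps this placement in both regimes. The
equality block is weighted by 1 − λ1 − λ2.

For the mixed principle the package distinguishes the LP optimum
(`objective_value`) from the conventionally tabulated value
(`reported_objective` = optimum − λ1 × max-deviation term): in the
reference regime-II results the tabulated mixed minimum equals exactly the
consensus-plus-equality part of the objective at the optimum (whose ω
vector the solver reproduces to 4 decimals), with the worst-off expert
entering through the bounding constraints only.

Known discrepancy: the reference regime-I mixed minimum (0.0481) is not
attainable under any reading of the combined model. Since each deviation
block is bounded below by the corresponding single-principle optimum, the
mixed objective is at least λ1·0.096 + λ2·0.2010 ≥ 0.069 for the case
study's λ values under either λ placement, and the reference mixed ideal is
itself not additively consistent — its own objective evaluates above the
package's optimum. The package reports its true optimum (reported value
0.1089) and makes no attempt to match 0.0481.

## Synthetic data

`generate_consistent_panel` plants a priority vector ω and builds each
expert's interval for i < j around c = ω_i/(ω_i+ω_j): the midpoint is
c plus truncated Gaussian jitter (sd `noise_scale`, clipped to the
half-width so c always stays inside), the interval extends `half_width`
each side, is clipped to [0, 1], and the lower triangle follows by
reciprocity. Every generated relation is II-consistent by construction;
with zero width and zero noise it is crisp and exactly multiplicative, and
the regime-II freedom solve recovers ω exactly at objective zero.
`generate_random_panel` draws interval endpoints uniformly — valid but
deliberately structureless. Defaults (n = 4, m = 3, half-width 0.1, noise
0.02) mirror the case study's shape with interval widths typical of its
matrices. What the generator does *not* emulate: systematic inter-expert
bias, correlated judgments across pairs, or strategic misreporting — tests
passing on synthetic panels say nothing about those. All randomness flows
through a single integer seed (numpy PCG64), so panels are reproducible
across platforms.

`perturb_panel` shifts chosen upper-triangle entries of exactly one expert
by ±magnitude (endpoints jointly, clipped, order preserved, reciprocity
re-completed). The `perturb-study` routine re-solves all requested
principles and regimes for each perturbed panel and counts exact priority
ties at 4 decimals. The exact entries behind the reference robustness
tables are unspecified ("some data were changed"), so the study makes the
qualitative claim assertable instead: regime II collapses to tied
priorities far more often than regime I, i.e. regime I discriminates more
robustly. No attempt is made to match the reference perturbation tables
numerically.

## Numerical choices

* LP backend: HiGHS via scipy, primal/dual feasibility tolerance 1e-8
  (configurable). Infeasibility and unboundedness are reported as a status,
  never an exception.
* Reciprocity/validation tolerance 1e-9; case-study matrices satisfy the
  invariants exactly.
* Ranking merges weights whose consecutive sorted gap is ≤ `tie_tolerance`
  (default 1e-4, the display precision of the reference tables); ties chain
  transitively and keep panel order within a group.
* Uniqueness at the optimum is probed by pinning the objective (slack 1e-7)
  and minimizing/maximizing a variable over the optimal face; the test
  suite uses this to compare against tabulated alternative optima honestly.
* Brute-force oracles (tests/oracles.py): regime-I freedom on 3×3 panels by
  exhaustive enumeration of the ideal entries at pitch 0.005 with per-entry
  optimal selections; priority-vector feasibility by a 2-simplex grid at
  pitch 0.001; additive feasibility by an α-grid at pitch 0.01; regime-II
  freedom by a simplex grid with per-pair closed-form optimal scalar ideal
  endpoints (weighted-L1 medians clipped to the corridor). Grid oracles are
  restrictions, so they can never beat the LP; tests assert agreement
  within the grid resolution.

## Problem sizes used in the test suite

Case-study solves are 4 alternatives × 3 experts (LPs of some tens to a few
hundred variables; milliseconds each). Oracle-equivalence batteries use 100
random 3×3, two-expert panels; property-based suites run up to n = 6.

## Limitations

* Only the two consistency notions above; no consistency *repair* of an
  inconsistent expert's matrix.
* Only the p = 1 and p = ∞ instances of the distance family (plus equality
  and mixtures); no least-squares (p = 2) consensus.
* The bilinear regime-II model is solved only through its linearization;
  with many alternative optima the reconstructed interval ideal is one
  representative among equals.
* Linguistic, intuitionistic, hesitant and triangular fuzzy preference
  formats are out of scope.
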