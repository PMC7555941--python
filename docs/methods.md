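# Methods

## The design model

A U-type uniform design U_n(q^s) with q = n places n runs in an
s-dimensional discrete level space so that every column is a permutation
of 1..n.  Uniformity is measured on the point set obtained by mapping
level u to the cell midpoint x = (u − 0.5)/q in (0, 1); this is the
standard normalization for U-type tables, and it is the one under which
the packaged 17×8 table reproduces its published CD² to print precision.
Two squared discrepancies are implemented, both in their closed
double-sum (Hickernell) forms:

- centered L2: CD² = (13/12)^s − (2/n) Σᵢ Πₖ(1 + ½|xᵢₖ−½| − ½|xᵢₖ−½|²)
  + (1/n²) ΣᵢΣⱼ Πₖ(1 + ½|xᵢₖ−½| + ½|xⱼₖ−½| − ½|xᵢₖ−xⱼₖ|),
  invariant to reflections of any coordinate about ½;
- wrap-around L2: WD² = −(4/3)^s + (1/n²) ΣᵢΣⱼ Πₖ(3/2 − |xᵢₖ−xⱼₖ|(1 −
  |xᵢₖ−xⱼₖ|)), which treats coordinates as periodic and is therefore
  invariant to per-column cyclic level shifts.

Both are evaluated vectorized; the test suite checks them at 1e−12
against literal triple-loop implementations of the definitions, and
checks the permutation/reflection/shift invariances property-wise.

A note on the packaged table: its recomputed WD² is 0.3344798, which
disagrees in the sixth decimal with the 0.334477 that circulates for this
table.  No standard normalization (midpoint, u/(q+1), (u−1)/(q−1), u/q)
reproduces 0.334477 while the midpoint normalization reproduces the
CD² value exactly, so the package reports its own computed value and the
tests assert agreement with the circulated value only to the precision
the pair of published numbers supports (5e−6).

## Design construction

New tables are constructed in two phases.  Good-lattice-point phase:
columns u_ij = ((i·h_j − 1) mod n) + 1 for a subset of the generators h
coprime to n; all generator subsets are scanned when their count fits the
search budget (default 2000), otherwise a seeded random subset sample of
that size; ties prefer the lexicographically smallest generator tuple.
Refinement phase: steepest-descent pairwise level swaps within columns,
started from the best lattice table and from a small number of seeded
random U-type tables (default 16 restarts), keeping the overall CD²
minimizer.  The refinement matters: lattice columns are linear modulo n,
and at n = 5, s = 2 the global CD² minimizer over all U-type tables is
not linear — plain generator search stops about 14% short of the global
minimum, while swap descent with restarts reaches it (the basin of the
global optimum covers roughly half of random starts at that size, so 16
restarts fail with probability ~3·10⁻⁶).  Construction is deterministic
given (n, s, budget, seed, restarts).

## Allocation

Factor j receives design column j.  A q-level column is collapsed to a
q′-level factor (q′ ∈ {2, 3}) by pseudo-level ℓ = ceil(u·q′/q), which for
any permutation column keeps the pseudo-level counts within one of each
other; pseudo-level ℓ then indexes the factor's sorted actual values.
The packaged 17-run plan of the motivating study is shipped verbatim
rather than derived, because it is the anchor for the packaged response
table and cannot be derived from the packaged design by any monotone
per-column collapsing.

## Execution and replication

Each (run, replicate) cell gets the seed
`SeedSequence(master_seed, spawn_key=(run_id, replicate))`, so seeds are
stable under adding runs or replicates elsewhere in the plan.  Objectives
implement `evaluate(settings, replicate, seed)` and must be deterministic
in those arguments.  Failures fail fast by default; an opt-in skip policy
records NaN cells and flags them in the table metadata.  Replicate means
are kept at full precision; CSV display rounds to 2 decimals.  Printed
response tables are accepted if their stated means are within one display
ulp (0.01) of the recomputed replicate means, because such tables are
sometimes truncated rather than rounded — the packaged response table
itself truncates 2 of its 17 printed means.

## The response-surface surrogate

Factors are affinely coded to [−1, +1] (smallest level → −1, largest →
+1; an unevenly spaced middle level keeps its affine image, e.g. 16 in
{8, 16, 32} codes to −1/3).  The candidate dictionary is the polynomial
family: intercept; Xᵢ; Xᵢ²; Xᵢ³; all XᵢXⱼ (i < j).  Structural pruning
removes terms that are exactly collinear on the factor's support — Xᵢ²
and Xᵢ³ for 2-level factors, Xᵢ³ for 3-level factors (any function of 3
points lies in span{1, x, x²}) — leaving, for the default four 3-level +
four 2-level factors, 41 candidates for 17 runs.

Selection is hierarchical forward stepwise: the path grows greedily by
residual sum-of-squares reduction, considering linear terms first, then
pure quadratics, then interactions, skipping any candidate that would
make the selected columns rank-deficient, up to max_terms (default
n − 2 coefficients including the intercept) or an exact fit.  The fitted
model is the prefix of the path that minimizes the selection criterion.
Hierarchy is essential at this run count: the 17-run plan aliases
two-factor interactions heavily with pure quadratics, and unrestricted
greedy selection reliably absorbs quadratic curvature into spurious
interactions and never assembles a true quadratic model.

The default criterion is Mallows' Cp, RSS/σ̂² + 2k, with σ̂² the
pure-error variance of a run mean estimated from the replicates (mean
within-run variance divided by the replicate count) — the standard use of
replication in a designed experiment.  Without replicate information the
default is BIC.  AIC and AICc are available but AICc is a poor default
here: with n runs and up to n − 2 coefficients its small-sample
correction term 2p(p+1)/(n−p−1) diverges exactly in the regime the design
is built to exploit, so it can never accept a near-saturated model
regardless of signal strength.  Coefficients of the selected terms are
ordinary least squares (statsmodels OLS backs the final fit and the
summary table).  Prediction expands a candidate's coded settings over the
retained dictionary; recommendation enumerates the full level grid
(3⁴·2⁴ = 1296 combinations for the default factors) in lexicographic
order and keeps the first strict maximum, so ties resolve to the
lexicographically smallest settings vector.  A minimize flag inverts the
direction.  Fitting the packaged plan and responses recommends
(3, 4, 1, 0, 3, 32, 2, 0) at a predicted 84.3%; the study that produced
those responses published a different combination from its own (not fully
specified) regression, so the package logs its recommendation alongside
rather than asserting agreement.

## The synthetic benchmark surface

`make_synthetic_surface` builds the test objective

Y(x) = base − curvature·Σₖ zₖ² + interaction_strength·Σₖ<ₗ zₖzₗ + N(0, noise_sd²),

where zₖ = (xₖ − optₖ)/(maxₖ − minₖ) is the per-factor span-standardized
offset from a planted optimum.  Defaults: base 85 (a typical accuracy
percentage), interaction 0, noise 0, curvature 8.  The curvature default
is a detectability choice, not an imitation of any particular dataset: at
curvature 8 the cheapest possible mistake (a 3-level factor one step off
an interior optimum, z = ½) costs 2 percentage points, more than three
times the standard error of a 3-replicate mean at noise_sd = 1, so the
planted optimum is identifiable by design.  Under these defaults the
end-to-end loop (run 17×3 on the packaged plan → fit → recommend, optimum
drawn uniformly over the level grid) recovers the planted optimum in
20/20 noiseless repetitions and 37/50 (74%) at noise_sd = 1.

What the benchmark does not show: real tuning surfaces of this kind are
much shallower.  The packaged response table has a run-mean standard
deviation of only 1.7 percentage points — corresponding to curvature
near 1.5 — and at that effect size exact recovery of all eight
coordinates from 17 noisy runs is mostly beyond reach (single-step
penalties fall below the replicate-mean noise).  Passing the synthetic
benchmark therefore validates the machinery — seeding, aggregation,
coding, selection, grid search — not a claim that 17 runs suffice to pin
the true optimum of an arbitrarily flat real surface.  The synthetic
surface is also exactly quadratic with at most pairwise interactions;
real accuracy surfaces need not be.

## Architecture arithmetic

The feasibility objective and the optional trainer share one shape model:
input 50×50×3 → conv1(k=A, filters=B, stride=C, pad=D) → ReLU → 2×2/2 max
pool → conv2(E, F, G, H) → ReLU → 2×2/2 max pool → conv3(1×1, 120, stride
1) → fully connected 84 → 2 outputs.  Spatial sizes follow
os = floor((w − k + 2p)/s) + 1; pooling uses the same rule with k = s =
2, p = 0 (i.e. floor(w/2), defined for odd inputs); same-padding for odd
kernels is zp = (k − 1)/2, satisfying os(w, k, zp(k), 1) = w.  A
combination is feasible iff every propagated size stays positive; at the
50-pixel input all 1296 default-grid combinations are feasible (the
harshest chain, two 7×7 kernels at stride 2 without padding, still ends
at 1 pixel), and the enumeration reports counts plus the infeasible list
for smaller inputs.  The final fully-connected layer has 2 units because
the task is binary benign/malignant classification.  Real training
(`train_evaluate`) is deliberately only an interface: it validates a
benign/malignant image directory and otherwise raises — image data are
never simulated.  The bundled dataset manifest reproduces the benchmark
collection's counts (2480 benign + 5429 malignant = 7909 across four
magnifications); a 70/30 split takes floor(0.7·total) = 5536 training and
2373 validation images.

## Numerical choices and degenerate inputs

- Discrepancy equality in tests: 1e−12 against the direct oracles; 5e−7
  against values printed to six decimals.
- RSS is floored at 1e−12 inside selection criteria so an exact fit does
  not produce log(0); the pure-error variance in Cp is floored the same
  way, which makes noiseless replicated fits select the first exact-fit
  prefix.
- Strict-improvement comparisons (1e−12 margins in selection, exact
  strict inequality in grid argmax) make every tie deterministic:
  first-entered term, lexicographically smallest settings.
- Constant responses yield the intercept-only model; a factor constant
  across the plan is rejected as a degenerate design; design tables with
  non-permutation columns, plans with off-level cells, and response
  tables with means inconsistent with replicates are all rejected on
  construction.
- Display rounding is always 2 decimals; computation is double precision
  throughout.

## Problem sizes

The test suite and acceptance script run at the study's own scale: the
17×8 design, 17-run × 3-replicate experiments, 41-term selection, and the
1296-point grid; the recovery benchmarks use 20 noiseless and 50 noisy
seeded repetitions, and construction oracles enumerate all 5-run 2-column
tables exhaustively.  The full suite completes in a few seconds on one
CPU.
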