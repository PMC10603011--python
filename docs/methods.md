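# Methods

## Model and assumptions

A community is a relative-abundance vector p = (p₁, …, p_n): non-negative
fractions summing to 1, sorted non-increasingly for all rank-conditional
statements. Shannon entropy H(p) = −Σ pᵢ ln pᵢ is computed in nats with
−0 ln 0 = 0. Abundances are treated as parametric: no sampling variance
is modeled, and richness n is whatever the chosen policy says it is
(see below), not an estimate of true community richness. Entropy
estimation from finite samples (coverage corrections and the like) and
Rényi/Hill-number generalizations are out of scope.

The central objects are the closed-form extremal communities subject to
a fixed rank-i abundance p_i:

* maximum entropy — spread the unconstrained mass as evenly as the
  ordering constraint allows. For i = 1 that is (p₁, (1−p₁)/(n−1) ×(n−1)).
  For i ≥ 2 there are two branches meeting at p_i = 1/n: when p_i ≥ 1/n,
  the top i entries sit at p_i and the remaining n−i share the rest; when
  p_i < 1/n, the bottom n−i+1 entries sit at p_i and the top i−1 share
  the rest. Both branches give ln n at p_i = 1/n.
* minimum entropy — concentrate mass on as few taxa as possible. For
  i = 1: ⌈1/p₁⌉−1 copies of p₁, one remainder, zeros. For i ≥ 2: ranks
  2..i at p_i, everything else in the top taxon, zeros after rank i.
  The minimum never depends on n.

The bounds are the entropies of these vectors; the implementation
evaluates the closed forms directly and separately constructs the
vectors, and the test suite asserts the two routes agree to 1e-12.

## Parameters that matter

* **i** (rank, 1-based): which abundance conditions the bounds. i = 1
  has a distinct feasible interval ([1/n, 1] instead of [0, 1/i]) and
  its own formulas.
* **n** (richness): only the upper bound uses it. The richness policy
  for normalization is explicit because cohort analyses legitimately use
  three conventions: `nonzero` (default — each sample's count of
  positive taxa; the natural per-sample choice), `length` (table width,
  counting zero-count taxa), and `fixed:N` (one cohort-wide N, e.g. the
  maximum or median observed richness; samples with more than N positive
  taxa are first truncated to their N most abundant and renormalized).
  Which convention is right depends on the question; results can differ
  materially, so none is silently assumed.
* **Degeneracy cutoff** (1e-12 nats): |H_max − H_min| below this marks a
  normalization query degenerate (p_i = 1/i pins the whole vector and the
  normalizing denominator vanishes). Degenerate samples are flagged, not
  dropped, so exclusion is an explicit aggregation-time decision.

## Numerical choices

* **Sum-to-1 tolerance** 1e-8 on vector construction; an opt-in
  `renormalize` rescales when the sum is within 1e-3 of 1 (renormalized
  and truncated data land epsilon off). Negative entries within 1e-12 of
  zero are clamped; anything more negative errors.
* **Ceiling snap**: H_min for i = 1 contains ⌈1/p₁⌉, discontinuous at
  exact reciprocals. 1/p₁ is snapped to the nearest integer when within
  1e-9 (relative) before the ceiling, so p₁ = 0.2 yields 5, not 6.
* **Feasibility clamp**: queries violating the feasible interval by at
  most 1e-9 are clamped to the boundary; larger violations raise.
  p_i = 0 for i ≥ 2 uses the continuous limits of the extremal
  constructions (minimizer (1, 0, …), maximizer uniform on i−1 taxa);
  p₁ = 0 is rejected as infeasible rather than extrapolated. The
  degenerate n = i case defines the (n−i)-taxon term as 0.
* **Normalized entropy** is clamped to [0, 1] and snapped to an exact
  0 or 1 when within 1e-12 — the same resolution as the degeneracy
  cutoff — so extremal vectors normalize to exact endpoints despite
  one-ulp float differences between, e.g., 1/60 and 0.15/9.
* **Curve grids** are uniform over the feasible interval plus every
  reciprocal breakpoint 1/k (k ≤ n) in its interior, inserted once: the
  i = 1 lower bound is continuous at its kinks (both pieces give ln k at
  p₁ = 1/k), so duplicated left/right samples add nothing and the grid
  stays strictly increasing. Default resolution 512.
* **Curve identities** (upper bound given p_{n−1} vs lower bound given
  p₁ on [1/n, 1/(n−1)]; for n = 3 additionally upper given p₂ vs lower
  given p₃ on [0, 1/3]) are verified numerically on 1000-point grids
  with a 1e-12 gap criterion, not re-derived symbolically: the closed
  forms reduce to the same expression, so exact-grid agreement is the
  expected outcome and a cheap regression guard.
* **Ties** in ranking are broken by stable sort on input position. The
  value at rank i is tie-break-invariant; only the permutation isn't.

## Synthetic data and the grid oracle

The generators emulate the abundance-profile shapes that span the
feasible (p_i, H) region: symmetric Dirichlet draws (near-uniform at
high concentration, long-tailed at low), normalized geometric series
(classic rank-abundance decay), and single-dominant communities (a fixed
mass on taxon 1, the remainder split evenly or Dirichlet). Defaults are
concentration 1.0, ratio 0.5 and dominant mass 0.85 — the last matching
the worked example's strongly dominated community. All randomness flows
through one explicitly seeded generator per call.

What the generators do *not* emulate: sampling noise on counts,
taxon-taxon correlations, or any ecological dynamics. Passing tests
therefore demonstrate the mathematics of the bounds on realistic
abundance *shapes*, not robustness to the measurement process that
produces real OTU tables.

The grid oracle is the independent check on the closed forms: it
enumerates every length-n non-increasing integer composition of a grid
denominator m (deduplicating permutations by construction), computes
each vector's entropy, and buckets extrema by (rank, grid value). On
small instances (n ≤ 8, m ≤ 120; the standard sweep uses n ≤ 6, m = 60,
about 20 000 partitions) the enumerated extrema must never exceed the
closed-form bounds, and must attain them whenever the theoretical
extremal vector itself lies on the grid — off-grid optima make exact
attainment impossible by construction, so elsewhere only one-sided
dominance is asserted, and the enumerated-vs-closed-form gap must shrink
as m doubles.

## Problem sizes

The default test suite and the acceptance script use the sizes above
(identity grids of 1000 points, oracle sweep n ≤ 6 at m = 60, a 10 000
draw Dirichlet ensemble with n ∈ {2, …, 50} and concentrations in
{0.1, 0.5, 1, 5}); the whole suite runs in a few seconds on one core,
so these sizes are comfortable rather than binding.

## Known limitations

* Bounds conditional on a single rank only; jointly fixing two
  abundances is not supported.
* The richness policies expose, but do not resolve, the ambiguity of
  whether zero-count taxa in a master table count toward richness.
* Pielou's J′ appears as a courtesy column in summaries only; no other
  classical evenness index is implemented.
* BIOM/HDF5 table formats and group-comparison statistics are out of
  scope; summaries are tidy TSV intended for downstream tools.
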