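# Methods

## Model and test

Outcomes follow a random-intercept linear mixed model

    Y_ijk = μ₀ + u_j + μ·1{i=2} + ε_ijk,
    u_j ~ N(0, τ²),  ε_ijk ~ N(0, σ²),  independent,

for arms i ∈ {1,2}, centres j = 1..c and subjects k = 1..n_ij. The
covariance of the stacked outcomes is block diagonal with exchangeable
blocks σ²I + τ²J per centre. The intraclass correlation is
ρ = τ²/(τ²+σ²). The treatment effect is estimated by the difference of
overall arm means μ̂ = Ȳ₂·· − Ȳ₁·· (each subject weighted equally),
which remains unbiased even when a centre recruited for one arm only.
Its variance is

    Var(μ̂) = σ²·N/(N₁N₂) + τ²·Σ_j (n₁j/N₁ − n₂j/N₂)²,

verified in the tests against the explicit quadratic form w'Σw. The
null hypothesis μ = 0 is tested with T = μ̂/√(est. Var), referred to the
standard normal; rejection requires |T| to strictly exceed q_{1−α/2}.
No t or Satterthwaite correction is applied: the normal reference is the
approximation the planning formulas themselves rest on, adequate for the
sample sizes (hundreds) these designs produce.

Variance components are estimated by closed-form quadratic forms, not
REML/ML: σ̂² pools the unbiased within-cell sample variances over
arm-centre cells; τ̂² averages, over arms, the sample variance of the
centre means around the arm mean. The test plugs the *estimated*
components into the variance formula, matching what an analyst without
knowledge of the truth would do. Degenerate cells are handled by
exclusion: cells with fewer than two subjects do not enter σ̂² (the
divisor is the eligible-cell count) and empty cells do not enter τ̂²
(per-arm divisors use the non-empty centre counts). This keeps both
estimators defined under multinomial centre sizes, where empty and
single-subject cells occur routinely; both forms are non-negative by
construction, so no truncation is needed.

## Imbalance of incomplete blocks

Within a centre, permuted blocks of length b realise the k:1 ratio
exactly in every complete block, so the centre's squared imbalance
Δ² = (n₁j/k − n₂j)² is produced entirely by the final block of
r = n_j mod b subjects. That final block is the leading prefix of a
uniformly permuted complete block, hence the arm-1 count j among its r
subjects is hypergeometric (population b, kb/(k+1) arm-1 labels, draw
r), and Δ² = (j/k − (r−j))² with support in [0, m*], m* = b²/(k+1)².
The implementation evaluates this law exactly via `scipy.stats.hypergeom`;
a brute-force enumeration of all C(b, b/(k+1)) block tuples is kept as an
independent test oracle (capped at b ≤ 20, where enumeration is cheap).
Support points whose Δ² coincide are merged with tolerance 1e-9 —
relevant for k > 1, where Δ² values are non-integer rationals held in
floating point.

The conditional expectation is the plain mean E(Δ²|r) = Σ_ℓ p(ℓ|r)·ℓ.
For k = 1 it has the closed form r(b−r)/(b−1), and its average over
r = 1..b is (b+1)/6; both are asserted in the tests up to b = 40.

## Sample-size formulas

Setting (q_{1−α/2}+q_{1−β})² = μ²/Var(μ̂) with the per-centre imbalance
replaced by its expectation gives a quadratic in N whose positive root is

    N = A·( σ²(k+1)²/(2k) + √( σ⁴(k+1)⁴/(4k²) + τ²(k+1)²μ²·S/q² ) ),

with A = (q/μ)², q = q_{1−α/2}+q_{1−β} and S = Σ_j E(Δ²|r_j). The four
named methods differ only in S: zero (lower boundary), c·E(Δ²|r₁) with a
self-consistent r₁ (equal centres), c·(b+1)/6-style uniform average
(unequal centres), and c·E(Δ²|b/(k+1)) (upper boundary). All raw sizes
are rounded **up** to the next integer and are not forced to multiples of
k+1; the ordering lower ≤ unequal ≤ upper holds on the raw values and is
property-tested.

The equal-centres search evaluates N(r₁) for every r₁ ∈ 1..b and keeps
the candidate minimising |((N(r₁)/c) mod b) − r₁|, using the unrounded
N and real-valued modulus, with ties broken toward the smallest N. For
the reference grid (μ=1, σ=4, ρ=0.5) this reproduces the published
c = 23 sizes for every block length; for several c = 46 and c = 92 cells
no reading of the self-consistency rule we tried (integer vs real
modulus, either tie rule, floor vs ceiling) reproduces the published
values, so those cells are not asserted anywhere. The unequal-centres
and upper-boundary columns reproduce in full.

One printed form of the conditional expectation carries a 1/m*
normalising prefactor; with that prefactor none of the multi-centre
grid values can be reproduced, while the plain mean reproduces all
unequal-centres and upper-boundary cells exactly. The package therefore
uses the plain mean throughout.

## Simulator

The generator mirrors the planning assumptions: subjects are spread over
centres either evenly (remainder to the first N mod c centres) or by a
multinomial draw — equal probabilities 1/c ("unequal 1") or normalised
iid Uniform(0,1) weights ("unequal 2"). Multinomial draws may leave
centres empty; they are retained so c stays fixed, and the estimators'
exclusion rules absorb them. Each centre receives its own randomisation
stream, spawned from the master generator (numpy `SeedSequence` children),
so per-centre lists are independent as stratified randomisation implies;
trial replicates in the power engine are likewise spawned, making grids
reproducible and order-independent. μ₀ defaults to 0 since it cancels
from every statistic of interest. The degenerate settings σ² = 0 and
μ = 0 are accepted by the simulator — they enable noise-free exactness
tests and type-I-error runs — while the sample-size formulas reject them.

What the generator does *not* emulate: non-normal outcomes, staggered
recruitment, dropout, control-group contamination, treatment-by-centre
interaction, or variable block lengths. Passing tests therefore show the
method behaves as designed under its own model, not robustness to these
departures.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | two-sided type-I error rate |
| 1−β | 0.8 | target power |
| k | 1 | allocation ratio k:1 (imbalance effects are strongest at k=1) |
| b | 6 | block length, a common practical choice |
| n_sim | 10,000 | Monte-Carlo replicates for production power estimates |
| seed | 42 | CLI default; every stochastic API takes an explicit seed |

Normal quantiles are used throughout; with α = 0.05 and power 0.8,
q² ≈ 7.8489 and the reference single-stratum size for μ=1, σ²=16 is 503.

## Problem sizes used in the checked runs

The test suite and `scripts/acceptance.py` run reduced-replicate
simulations — 2,000 replicates for type-I error, the upper-boundary
power and the long-block power-loss demonstration, 4,000 for the
nominal-band power check, and 2,000 trials for estimator-recovery — with
all stochastic assertions stated as 3 Monte-Carlo-standard-error bands
(or the explicit band [0.78, 0.84] for nominal power). These sizes give
standard errors below 0.01 on a rejection proportion, ample for the
bands asserted, while keeping a full run on a single CPU in well under a
minute. Production analyses should use n_sim = 10,000.

## Known limitations

- The equal-centres self-consistency rule can have near-ties in its
  distance criterion; the smallest-N tie-break is a convention.
- The moment estimator τ̂² absorbs part of the within-centre sampling
  noise of the centre means (upward bias of order σ²/n̄_ij); at the cell
  sizes these designs produce the effect on the test is negligible, and
  the calibration simulations confirm nominal behaviour.
- Power estimates for k > 1 are supported by the engine but not
  calibrated here; expected imbalance, and hence the penalty, shrinks
  as k grows.
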