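# Methods

## Model chain

`granutab` treats tableting as four sequential stages, each with a
reduced-order model, and couples every stage to two upstream granule
attributes: the ribbon relative density ρ_ribbon ∈ (ρ_c,rib, 1) and the
granule size distribution.

**Die filling.** The tablet weight is W = φ ρ_t ρ_ribbon V_fill. V_fill is
the die volume at the dosing position; for the doubly convex tooling the
fill-state volume carries half the two-cap term of the compacted-state
volumes (V_fill = πD²t_fill/4 + (πh/12)(3D²/4 + h²) against
πD²t/4 + (πh/6)(3D²/4+h²) for the pre-compression, in-die and out-of-die
states). The two coefficients are implemented exactly in these forms
because the shipped reference parameters were estimated against them; the
geometric asymmetry (one cup exposed at fill, two after compaction) is the
plausible reading. The filling efficacy φ is a packing fraction of the
granule mixture, φ(X,Y) = p₄(q₂X+1)/(q₁XY+q₂X+1) on the unit square of
X = (1−α)(1−μ₁³/μ₂³) and Y = α. The constraint p₂ = q₂p₄ forces both
unimodal limits (α→0, equal mode sizes) to the same packing fraction p₄,
and q₁ < 0 makes bimodality always help packing (φ ≥ p₄). Reports of this
surface conventionally quote |q₁|; the package stores the signed value
(q₁ = −6.08 in the reference set) since the negative sign is what produces
the packing maximum near small-mode fraction α ≈ 0.7. A hard-sphere
bimodal packing relation (`brouwers_packing`, with random packing fraction
φ_rp and packing-mode constant C) is included purely as a qualitative
reference oracle for this surface.

**Compaction.** A Kawakita-type force model restated in terms of the
critical (jamming) in-die density ρ_c:
F = πD²(ρ_in-die−ρ_c)/(4b(ρ_in-die(a−1)+ρ_c)). a is the total
compressibility, b (1/MPa; conventionally reported in 1/GPa and stored
that way in the reference set, converted internally) the pressure
parameter. Feasibility requires ρ_in-die > ρ_c and ρ_in-die(a−1)+ρ_c > 0;
violations raise, or are rejected with infinite SSE during fitting.

**Unloading.** ε = ε₀((ρ_in-die−ρ_c,ε)/(1−ρ_c,ε))ⁿ with onset density
ρ_c,ε and nonlinearity exponent n; ρ_tablet = ρ_in-die(1−ε). Below the
onset the recovery is taken as zero (the fractional power of a negative
bracket has no physical reading).

**Strength.** σ_t = σ₀[1 − ((1−ρ_tablet)/(1−ρ_c,σ)) e^(ρ_tablet−ρ_c,σ)].
The exponential is grouped inside the bracket: that is the only grouping
for which σ_t vanishes at the coherence threshold ρ_c,σ and equals σ₀ at
zero porosity, the two boundary facts the model is built on.

## Coupling by constrained rational surfaces

Raw upstream variables are normalized by X = ((x−lb)/(ub−x))^r, mapping
[lb, ub) onto [0, ∞) with a shape exponent r ∈ (0, 10]. Bounds are
physical: ribbon density lives in (ρ_c,rib, 1) with ρ_c,rib = 0.566 (the
smallest density at which a ribbon forms); mean granule size in (0, D/6)
(the die-filling rule of thumb that granules should be at least six times
smaller than the die); the packing fraction in (φ_min, φ_max) =
(0.367, 0.631) when it serves as the strength model's second covariate Z.

Each coupled model parameter is a rational surface
f(X,Y) = (p₁XY+p₂X+p₃Y+p₄)/(q₁XY+q₂X+q₃Y+1). The corner limits are
interpretable — f(0,0)=p₄, f(∞,∞)=p₁/q₁, f(0,∞)=p₃/q₃, f(∞,0)=p₂/q₂ — and
are implemented by explicit limit algebra rather than floating-point
overflow, with a cascade for coefficient sets whose leading corner terms
vanish (the constant variant has the same finite value on every edge).
Nine constrained variants (progressively zeroing {p₂,q₂}, {p₃,q₃}, both,
or everything but p₄, each with exponents free or fixed at 1) give
parameter counts 9, 7, 7, 5, 7, 5, 5, 3, 1. A tablet attribute needs a
*pair* of surfaces (e.g. a and ρ_c); the library holds 25 pairs out of the
81 combinations: matched pairs (v,v) for v = 1..8, (v,9) for v = 1..8, and
(9,w) for w = 1..9. Exponents are shared between the two members of a pair
and are fixed at 1 only when both members fix them — the only bookkeeping
under which the published parameter counts (9 for the force pair (7,7)
with b; 7 for the recovery pair (4,9) with n; 16 for the strength pair
(1,1)) are all reproduced.

## Estimation and model selection

Fitting is at condition level: tablet records are averaged per tableting
condition (n = number of conditions, 24 in the reference campaign) after
deriving per-tablet quantities — out-of-die density from weight and tablet
volume, tensile strength from hardness through the convex-tablet (Pitt)
relation, in-die density from weight and the main-compression volume.
Tablet-level fitting (n = 2400) would weight every condition by its
tablet count and let within-condition noise dominate SSE; condition means
match the design intent of one SSE term per press setting and are the
package default.

Per attribute, the observable and predictor are: weight — W from the
packing surface; force — F from in-die density (computed from measured
weight); recovery — out-of-die density predicted through the in-die chain;
strength — σ_t from the *measured* out-of-die density. The weight model is
fitted first since its φ bounds feed the strength covariate Z.

The constraint sets are: force — all free coefficients positive,
r ∈ (0,10], plus the two force-positivity predicates evaluated at every
data condition; recovery — order constraints 0 < pᵢ < qᵢ (with q₄ ≡ 1)
keeping ε₀ ∈ (0,1), and ρ_c,ε ∈ (ρ̄_c, 1); strength — positivity,
r ∈ (0,10], and ρ_c,σ above the recovery onset at every condition;
weight — p₄ > 0, q₁ < 0. ρ̄_c, the lower bound of the compaction critical
density, defaults to 0.33 — the corner value ρ_c(0,0) of the reference
compaction surface. This matters: the recovery onset is estimated from
data far above it (ρ_in-die ≈ 0.73–0.95), so it is weakly identified and
trades off against the exponent n; the constraint anchors it to the
physically consistent range.

Data-dependent feasibility is enforced by rejection (infinite SSE), so the
search stages stay interchangeable and no stage biases the estimate toward
an initial guess. The three stages are: (1) a restarted
differential-evolution global search over the box bounds (3 restarts,
population multiplier 20, 400 generations, Sobol initialization);
(2) bounded trust-region least squares from the stage-1 best, using smooth
square-root penalty residuals near the feasibility boundaries so the
solver can approach them without the rejection discontinuity; (3) a
multi-start polish (15 starts, Gaussian perturbations at 30% of the box
span) of the same local solver, gated by the hard rejection objective.
All stages are deterministic for a fixed seed. These budgets are defaults
in `FitBudget`, chosen so that a 9-parameter force fit converges to
machine-zero SSE on noiseless synthetic data across arbitrary seeds in
roughly 20 s; the 16-parameter strength pair is the hardest problem and
lands within a fraction of a percent of the generating surface values.

Model selection minimizes AIC = n ln(SSE/n) + 2N_p over the library; ties
break toward fewer parameters, then lexicographic pair id. The ranking is
invariant to a uniform rescaling of observations and predictions (the
rescaling adds the same n ln c² to every AIC), so SSE units never affect
which model wins.

## Uncertainty propagation

Measured tablet weight is the dominant stochastic input: it is modeled as
Normal with mean from the die-filling model and relative standard
deviation 1.6% (the reported campaign-average weight RSD; configurable).
Holding the main-compression thickness fixed — the press setting — each
weight draw maps to an in-die density and then through force, recovery and
strength. This is the only reading under which weight noise reaches all
downstream attributes. Sampling is plain Normal with a rejection guard:
draws violating a feasibility condition (negative weight, jamming,
sub-threshold tablets) are dropped and counted; at the default RSD the
rejection fraction is far below 1e−6. The default sample count is 10,000.
Standard deviations are reported as exact zeros when the RSD is zero (the
distribution is a point mass; naive accumulation would report float
epsilon).

## Synthetic campaigns

No tablet-level dataset is public, so testing runs on synthetic campaigns
generated from the shipped reference parameters. The generator emulates
the reference study's design: 6 granule batches (ribbon density 0.613 to
0.803, bimodal Weibull GSDs), 4 press conditions per batch inside the
published per-batch dosing-position and compression-thickness ranges, 100
tablets per condition. The exact 24 experimental setpoints are not
published; the generator targets four evenly spaced in-die densities per
batch within the window that is reachable inside the printed setpoint
rectangle under the reference weight model, capped at 0.95 and floored so
the predicted out-of-die density clears the strength threshold with
margin. This makes every generated condition feasible for all four
attributes — a stand-in for the study's own trial-and-error setpoint
selection, not a reconstruction of it.

Per tablet, weight is drawn at 1.6% RSD and pushed through the ROM chain;
force, out-of-die density and strength carry additional independent
multiplicative observation noise (2% default — an artifact choice, the
source study reports only the weight RSD). The overall thickness is
back-computed from the out-of-die density, and the hardness from the
strength through the inverse convex-tablet relation, so files mimic raw
press/tester records. Campaigns are bit-exactly regenerable from (seed,
parameters, noise spec).

What passing recovery tests show: with noiseless data the estimation
pipeline returns the generating surfaces essentially exactly (surface
values at all six batches within 1%, typically to machine precision), and
at the reference noise level within 5%. What they do not show: robustness
to model misspecification, to correlated or heteroscedastic measurement
error, to press transients, or to granule batches outside the reference
density/size ranges — real campaigns have all of these.

## Numerical choices and edge cases

- Units: mm, mm³, mg, g/cc, N (hardness), kN (punch force), MPa; sizes in
  μm; mg/mm³ ≡ g/cc numerically so density ratios need no conversion.
- The two Weibull-mean values printed for the 30-bar reference batches are
  inconsistent with their own (λ, k) parameters; means are therefore
  always recomputed from the parameters and the printed values kept as
  metadata only.
- Normalization raises distinct errors below the lower bound (domain
  error) and at/above the upper bound (overflow signal); surfaces can be
  evaluated *at* the infinite limit explicitly.
- SSE = 0 maps to AIC = −∞ with a warning (a perfect fit wins any
  ranking).
- R² is computed about the observed mean; zero total variance is an error
  rather than a silent NaN.
- Selection over sub-libraries is supported and used in tests at reduced
  optimizer budgets; the mechanics (sorting, tie-breaks, rescale
  invariance) are independent of budget.

## Known limitations

- The ejection stage carries no model (none is defined for it); press
  dynamics, tooling wear, lubrication and strain-rate effects are out of
  scope.
- The recovery onset density and exponent are jointly weakly identified
  from high-density campaigns; estimates of ρ_c,ε inherit the constraint
  anchor ρ̄_c.
- The strength pair (1,1) has 16 parameters against 24 conditions;
  individual coefficients are not identifiable (nor meant to be) — only
  the surface values over the sampled covariate range are.
- The reference parameters are for one formulation (10% APAP / 90% MCC)
  and one tooling; other elasto-plastic profiles need refitted or
  different stage models.
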