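# Methods

`climniche` re-implements, as a tested library, an inference chain that asks
whether the climatic niches of lineages with different nesting habits (here:
ground-nesting vs. arboreal-nesting ants) evolve under different dynamics.
The chain has four scientific stages — occurrence summarization, canopy
habitat coding, constrained discrete ancestral-state reconstruction, and
state-dependent Ornstein–Uhlenbeck (OU) model comparison with parametric
bootstrap — plus a synthetic-data layer that supplies every input with known
truth so that each stage can be verified end to end without any download.

## Occurrence cleaning and species summaries

Records carry species, coordinates, a reported country, a biome and realm
label, and 36 environmental variables (19 bioclim layers, net primary
productivity, potential evapotranspiration, elevation, 14 topsoil
variables).  Cleaning:

1. **Coordinate validation and repair.** Candidate variants are tried in a
   fixed order — as given, latitude sign flip, longitude sign flip, both
   flips, then the same four after swapping latitude and longitude.  The
   first variant lying on land and within a tolerance (default 1.0 degree,
   configurable) of the reported country is accepted; otherwise the record
   is rejected with a reason code (`off-land`, `wrong-country`,
   `unknown-country`).  The fixed trial order makes repair deterministic.
2. **Deduplication.** One record per distinct (species, latitude, longitude)
   triple, first kept.  Species with a single record are retained.
3. **Completeness.** Records missing any required variable are dropped (the
   count is logged).
4. **Summaries.** Per-species medians of each variable; the bioclim layers
   stored in tenths of a degree (BIO1, BIO2, BIO5–BIO11 except the index
   BIO3 and the ×100 standard deviation BIO4; the set is configurable) are
   divided by 10 *before* the median, which is equivalent to converting
   afterwards since scaling commutes with the median.  An even record count
   uses the midpoint of the central pair.  Biome and realm occupancy
   proportions are tabulated over the same unique records.

## Canopy coding

Each biome is mapped to a canopy class (closed = forested, open =
non-forested) by an editable YAML config.  Two schemes ship: `primary`
(Mediterranean forests, woodlands & scrub closed) and `mediterranean_open`
(the robustness variant treating that biome as open).  A species is flagged
as occupying a canopy class when *strictly more than one third* of its
unique records fall in that class; the two flags combine to the composite
states closed / both / open.  Because the classes partition the biomes, the
(0,0) combination is impossible.  "Both" is treated as a real intermediate
state of the transition model (the prohibition below is only meaningful that
way); an ambiguity encoding ("closed&open" tip sets) is also supported by
the Mk machinery.

## Constrained Mk model and marginal ancestral states

The canopy character evolves under a 3-state continuous-time Markov model
with all-rates-different parameterization and structural zeros forbidding
direct closed↔open transitions (4 free rates; the prohibited cells are
exactly zero at every parameter value).  The likelihood is the standard
pruning recursion with per-node rescaling; branch kernels are matrix
exponentials computed by scaling-and-squaring, batched over branches.  Root
handling follows the FitzJohn–Maddison–Otto ("maddfitz") weighting: each
root state is weighted by its own conditional likelihood.  Rates are
optimized on the log scale within [1e-9, 100] events/Ma by bounded
quasi-Newton from 10 seeded log-uniform restarts (defaults; both
configurable).

Marginal reconstructions combine the downward partials with an upward pass.
The root weights are computed once from the full-data root conditionals and
held fixed while node states are constrained — the marginal at node *v* is
`P(state | data)` under the prior implied by those frozen weights, and the
root's own marginal is therefore proportional to the squared root
conditionals.  The same definition is used by the exhaustive-enumeration
oracle in the test suite, which sums over all internal-state assignments
with per-branch matrix exponentials.

## State-dependent OU models

A regime painting assigns one selective regime per branch; by default a
branch takes the state of its rootward (parental) node, with a tipward
option for terminal branches.  Regimes here come from a binary nesting
character (ground vs arboreal), whose node states are taken from a
binary-Mk marginal reconstruction or supplied directly.

Seven models are fit per climatic variable: BM1, BMS (regime-specific
Brownian rates), OU1, and OUM / OUMV / OUMA / OUMVA (regime-specific optima
θ, optionally regime-specific diffusion σ² [V] and/or pull α [A]).  The tip
distribution is the exact multivariate Gaussian of the piecewise-OU process:
per branch segment of duration *t* in regime *k*, the mean decays toward
θ_k by `e^(-α_k t)` and the variance propagates as
`v' = v e^(-2α_k t) + σ²_k (1 - e^(-2α_k t)) / (2α_k)`; tip covariance is
the MRCA variance times the decay products down both paths.  Segments with
`α t < 1e-8` switch to the Brownian limit — the same rule the forward
simulator uses, so analytic moments and simulation agree to machine
precision in the BM limit.

**Estimation.** θ0 and the θs enter the tip mean linearly and are profiled
out by GLS at each likelihood evaluation; the overall σ² scale is profiled
in closed form.  The numerical search therefore runs over at most the log
pulls and log σ² ratios (0–3 dimensions), via bounded Brent (1-D) or
Nelder–Mead with bounds, multi-started from a half-depth-half-life heuristic
plus seeded log-uniform draws.  α is bounded in [1e-6, 50] /Ma.  Free
parameter counts for AICc count every estimated quantity including θ0:
BM1 2, BMS 1+k, OU1 4, OUM 3+k, OUMV 2+2k, OUMA 2+2k, OUMVA 1+3k.

**Root-state identifiability.** On an ultrametric tree every tip shares the
depth *T*, so for shared-α models (OU1, OUM, OUMV) the θ0 design column
`e^(-αT)·1` is an exact linear combination of the θ columns: θ0 is
structurally confounded with a uniform shift of the optima, and a "full"
Hessian would have an exact zero eigenvalue.  The package resolves the alias
on ultrametric input by the stationary-start convention — θ0 is tied to the
optimum of the root's regime and reported as such (`theta0_aliased=True`) —
and computes the curvature diagnostic over the remaining identifiable
parameters.  With regime-specific α (OUMA, OUMVA) the decay varies across
tips and θ0 is estimated freely — unless it is *effectively* unidentifiable
(every tip's root weight `e^(-α·path)` below 1e-2, contributing less than
1% of a trait unit per unit θ0), in which case the same stationary-start
fold applies; without it, the θ0 direction's true curvature sits below
finite-difference noise and the diagnostic would reject sound fits
essentially at random.  AICc parameter counts are left unchanged by the
alias.

**Diagnostics.** At the optimum the Hessian of −lnL over the model's
(identifiable) parameter vector is computed by central differences (default
relative step 5e-3, large enough that differencing noise does not swamp
genuinely small curvatures); a fit passes iff all eigenvalues are strictly
positive and no pull sits on its optimization bound.  Failing fits stay in
the comparison table but are excluded from Akaike weights and from
best-model selection.  Derived quantities are the phylogenetic half-life
ln(2)/α and stationary variance σ²/(2α) per regime (infinite under BM).

## Parametric bootstrap

The best-fit model is refit to (default) 50 datasets simulated at its ML
estimates with the exact per-branch OU transition.  Refits warm-start from
the original optimum; a replicate failing the curvature diagnostic gets one
retry from fresh heuristic/random starts before being dropped (dropped
counts are reported; more than 50% failures abort).  Intervals are 2.5/97.5
percentile over surviving replicates, for every parameter and derived
quantity; the observed estimate is flagged as inside/outside its own CI,
and a between-regime difference is called significant when the two 95%
intervals are disjoint (closed intervals; a shared endpoint is not
significant).  Percentile was preferred over BCa, which is unreliable at 50
replicates.

## Synthetic data

*Trees* grow by a forward birth–death simulation (exponential waiting times;
the present is set just before the next unrealized event so pendant branches
are positive; extinct side-branches pruned; whole-clade extinction retried
up to 1000 times).  *Discrete characters* evolve by sampling the exact
kernel `expm(Q t)` per branch.  *Traits* evolve by the exact one-step OU
transition per branch (no Euler discretization), so closed-form checks are
exact.  *Occurrences* are drawn on a toy world of six rectangular countries
(latitudes 2–28, longitudes 35–95) tiled by biome patches with realm labels
and smooth deterministic climate fields (temperature fields generated in
tenths of a degree).  Corruption is applied per record at configurable
rates: latitude/longitude swap, latitude sign flip, or displacement into the
ocean; the geometry of the land block guarantees that any swap or sign flip
of a land point leaves the land, so those two corruptions are exactly
repairable and offshore points are exactly rejectable — recovery rate 1.0
under swap-only corruption is a designed property, not an accident.  All
generators are seeded and bit-reproducible.

What the toy world does *not* emulate: irregular coastlines and country
borders, spatial autocorrelation structure of real climate rasters,
sampling effort biases, taxonomic noise.  Passing tests therefore certify
the *logic* of cleaning, coding and inference, not robustness to real-world
GIS artifacts.

## Verification experiments and problem sizes

The heavy acceptance-level experiment simulates 20 datasets under OUMVA on
400-tip birth–death trees (speciation 1.0, extinction 0.5 /Ma; crown depths
around 10 Ma), nesting regimes from a 0.2 /Ma binary character painted from
true node states, optima 20 vs 25 (≈5.6 ground-regime stationary SDs
apart), pulls 0.5 vs 1.0 /Ma, diffusions 0.8 vs 0.4.  It scores the median
relative error of the recovered optima, the AICc rank of the generating
model among all seven, and the fraction of datasets whose 50-replicate
bootstrap CIs cover both true optima.  These conditions were chosen once as
a strong-signal regime in which all OUMVA parameters are identifiable
(deeper trees keep θ0 informative and the pull estimates nearly unbiased);
under weak pulls or shallow trees the percentile intervals inherit the
well-known upward bias of ML pull estimates and undercover.

Moment exactness is checked against 50,000-replicate forward simulation for
all seven models on random ≤8-tip instances.  Because thousands of Gaussian
comparisons are made at a 3-SE band, the check bounds the random exceedance
fraction at 1% and requires nothing beyond 5 SE, rather than asserting
every single entry within 3 SE (which a correct implementation would fail
with probability near one).

## Numerical choices and degenerate inputs

- Covariance matrices get a jitter of 1e-10 × mean diagonal before Cholesky;
  failure after jitter is a hard error naming the offending eigenvalue.
- Likelihood is computed through triangular solves; no explicit inverses.
- Zero-length branches are legal everywhere (identity kernels; zero added
  variance).  Polytomies and duplicate tip labels are rejected on input.
- Invariant characters drive the identifiable Mk rates to the lower bound
  and the maddfitz likelihood to ~0; this is reported, not an error.
- Ties at the exact 1/3 canopy threshold resolve to "not occupying" (strict
  inequality).
- All stochastic stages take explicit integer seeds; rerunning a pipeline
  configuration reproduces byte-identical manifests (relative paths, sorted
  keys, no timestamps).

## Known limitations

- The dense-covariance OU likelihood is O(n³) per evaluation; adequate to a
  few thousand tips, not for much larger trees.
- No measurement-error term in the OU models; no hidden-rate Mk models; no
  stochastic character mapping; regimes cannot change within a branch.
- θ0 on ultrametric trees is reported under the stationary-start alias for
  shared-α models (see above); comparing θ0 across models should respect
  the `theta0_aliased` flag.
- Percentile bootstrap CIs are mildly anticonservative: in the recovery
  experiment the per-regime optimum CIs cover their truths roughly 85–95%
  of the time each, but the joint event (both regimes simultaneously) lands
  nearer 75–85%, with misses typically a hundredth of a trait unit beyond
  an interval edge.  This is the known behaviour of percentile intervals
  with ML plug-in parameters (no bias correction at 50 replicates), not an
  implementation artifact — conditional-bias checks show the optimum
  estimator is unbiased given the tree.
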