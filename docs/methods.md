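# Methods

This note documents the models implemented in `conflictsex`, the defaults of
the synthetic-season generator, and the numerical and design choices a
maintainer or reviewer would want spelled out. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Data model and time

The unit of analysis is the **flower**, not the plant: andromonoecy is a
*modular* heteromorphism, and comparing male with bisexual flowers requires
per-flower fitness components. A `FlowerRecord` carries sex class, pistil and
stamen counts (initial and post-manipulation effective), phenology intervals,
morphology (tepal length in mm, stalk height in cm) and seed count.

Time is discretized to integer day indices from the season start. All phases
are half-open intervals `[start, end)`, and *every* overlap question
(candidate-sire filtering, mating, availability) is evaluated on the
census-day grid — by default every 3.5 days, which on an integer grid yields
the alternating 3/4-day visit pattern of a real field census. Consequences:
a flower whose phase falls entirely between census days is invisible to
mating and availability, exactly as it would be to a census-based study.

Bisexual flowers are strictly protogynous here: the female phase starts at
opening; anthers open `female phase + slope × pistils/100` days after
opening, so the male-phase onset delay increases with female allocation
(default slope 0.58 d per 100 pistils). Days between female-phase end and
anther opening are a real state of the flower ("interphase" in
`censuses.csv`); they count toward neither sexual function. Flowering
duration is the union length of the two phase intervals.

## 2. Synthetic-season generator

The generator's defaults are the study conditions the analysis assumes; they
are not tuning knobs. Where the source system fixes a value we use it;
where it does not, the value below was chosen once as field-realistic and is
documented here.

| parameter | default | rationale |
|---|---|---|
| individuals | 150 | population size of the fenced plot |
| flowers/individual | 1 + Poisson(0.15) | mostly single-flowered; ~170 flowers total |
| proportion male flowers | 0.26 | ≈46 male / 175 flowers |
| male opening offset | −3 d | male flowers flower earlier |
| female phase | N(5, 2.1) d, ≥1 | observed mean ± sd |
| duration, bisexual / male | N(9.6, 1.5) / N(10.7, 1.5) d | observed means; sd chosen field-realistic |
| pistils | lognormal, median ≈70, σ=0.7, clipped 1–300 | "one to a few hundred" pistils, right-skewed |
| stamens | N(150, 25), clipped 20–300 | stamen number comparatively uniform |
| stamen removal | 50% from 16% of flowers; 100% from 9.6% (bisexual only) | experimental design; counts = fraction × total, rounded |
| seed set | 0.3 per receptive pistil per census day | yields ~25–30 seeds per flower, a plausible fruit set |
| selfing weight | 1.0 | own-individual pollen competes at face value |
| loci / alleles | 10 / 8, Dirichlet(1) frequencies | microsatellite panel |
| genotyping error | 0.018 | per-locus replacement rate |
| missing calls | 0.02 | sparse missingness, exercises the ≥5-loci filter |

Mating: on each census day, every not-yet-set pistil of every receptive
flower sets a seed with probability `seed_set_prob`; the sire flower is
drawn with probability proportional to effective stamen number among flowers
releasing pollen that day, with own-individual flowers' weights multiplied
by `selfing_weight`. Because within-flower phases are strictly sequential,
selfing arises through geitonogamy (other flowers of the same individual);
with mostly single-flowered individuals the realized selfing rate is low
(a few per mille under defaults). Receptive days with no pollen available
simply set no seeds.

Genotypes: adults are Hardy–Weinberg draws (one multilocus genotype per
individual; all its flowers share it); seeds inherit one uniform allele from
each parent. The observation layer replaces each single-locus genotype,
independently with probability ε, by a random Hardy–Weinberg genotype at the
population frequencies — deliberately the *same* error model the paternity
likelihood mixes in, so the likelihood is exactly matched to the generative
process. All draws flow from one seeded generator in a fixed order
(flower counts → sex → phenology → morphology → removal → mating →
genotypes), giving byte-identical outputs per seed.

What the generator does **not** emulate: spatially explicit pollinator
movement and distance-dependent pollen flow, pollen competition within
pistils, plastic sex expression across seasons, weather-driven phenology
shifts beyond the opening-day spread, and linkage or null alleles in the
marker panel. Tests that pass on this generator therefore establish internal
correctness and statistical calibration under the stated model — not that
any particular field estimate is right.

## 3. Phenology

Pistil availability per stamen is computed per census day under three
scenarios: (1) effective (post-removal) stamens, (2) stamens as produced,
(3) as (2) but excluding unisexual male flowers from the sire pool. A flower
spanning *k* census days presents `count/k` organs at each (equal
presentation), which makes per-flower contributions conserve exactly.
Days with zero mature stamens have *undefined* availability, encoded as NaN,
never as 0 — downstream plots and summaries must break there.

The male-onset delay (anther day − opening day, unmanipulated bisexual
flowers only) is regressed on pistils/100 in a random-intercept mixed model
with the opening day as the grouping factor (absorbing shared weather
effects). The fit is a direct Nelder–Mead optimization of the profiled
Gaussian likelihood with Sherman–Morrison block algebra; REML is the default
(see §5), the slope is reported per 100 pistils and its SE comes from the
GLS information at the fitted variances. Flowering durations are compared
with a Welch unequal-variance t-test.

## 4. Paternity

The LOD score of candidate *c* for seed *o* with mother *m* is
`Σ_loci ln [P(o | m, c) / P(o | m, random sire)]` with the error model mixed
into the offspring transition probability:
`P_obs = (1−ε)·P_mendel + ε·P_HW(o)`. Missing calls contribute probability 1
(a candidate untyped at a locus contributes 0 to its LOD); seeds typed at
fewer than 5 loci are dropped. With ε > 0 every LOD is finite; a zero null
likelihood (possible only at ε = 0) signals a Mendelian-impossible
mother–offspring pair and raises an error rather than silently excluding.
This replacement-error model is simpler than Cervus's allele-level model;
that divergence is intentional and documented (it inverts the simulator's
error process exactly).

Candidates for a family are flowers that retained at least one stamen and
whose pollen presentation shared ≥1 census day with the mother's receptive
phase. Own-individual flowers stay in the list, so selfing is detected
genetically (sire individual = mother individual), at the individual level,
while fitness credit stays at the flower level.

The confidence threshold Δ\* is calibrated once per analysis against the
population-wide stamen-bearing candidate pool (as in standard parentage
software): seeds of known sires are simulated from the pool (mothers from
Hardy–Weinberg at the panel frequencies, offspring observed through the ε
model), each scored against all candidates, and Δ\* is the smallest
threshold at which the fraction of correct best-candidates among
above-threshold cases reaches the requested confidence (default 80%,
n_sim = 1000). A seed is assigned iff its best LOD is finite, strictly
unique, and Δ ≥ Δ\*. The family selfing rate divides assigned-self seeds by
*all* sampled seeds (unassigned seeds stay in the denominator). Siring
credit is `family seed count × (seeds assigned to sire / seeds sampled)`,
so credit can never exceed the family size and the unassigned fraction is
credited to no one.

Allele frequencies are counting estimates over non-missing adult calls.
Rarely, a seed carries an allele unobserved among adults (in a small sample
the error process can miscall every adult carrier); such alleles enter the
panel with a half-count pseudo-frequency so the likelihood stays defined.

## 5. Fitness and selection

**Female fitness** is `W_f = N(1 − s·δ)`: outcrossed seeds at full value,
selfed seeds devalued by the inbreeding depression δ. The alternative
literal reading `N·s·(1−δ)` would give a fully outcrossing flower zero
fitness and is rejected; this is the one deliberately interpretive step in
the fitness construction and is therefore flagged prominently here. δ is an
input (default 0.93); the equilibrium estimator
`δ = 1 − 2F(1−s)/[s(1−F)]` (adult inbreeding coefficient F, population
selfing rate s) is provided separately and clamped to [0,1] with a warning.
Per-flower selfing rates feed the discount; flowers without a genotyped
family receive the population mean rate.

The analysis set is bisexual flowers of single-flowered individuals with all
five traits measured; stamen-manipulated flowers are *included*, using
effective stamen counts — the manipulation exists precisely to widen that
trait axis. Traits (pistil number, effective stamen number, flowering date =
opening day, tepal length, stalk height) are z-scored with the sample
(ddof = 1) SD. Each fitness component is divided by its mean over this set,
so both functions have mean relative fitness 1.

**Sex-specific model.** Stacked female/male relative fitness per flower;
fixed effects are function-specific intercepts and function-specific linear
and quadratic terms for the five traits (22 parameters; correlational γ_ij
terms are omitted, matching the reported table layout); a flower-level
random intercept τ² and separate residual variances σ²_F, σ²_M. The
per-flower covariance is a common 2×2 matrix, so the likelihood is evaluated
by whitening with its Cholesky factor; the three log-variances are optimized
by Nelder–Mead with fixed effects profiled out by GLS.

*REML is the default criterion*, a deliberate design choice: with 22 fixed
effects on 2n ≈ 114 observations, plain-ML variance estimates are biased by
(N−p)/N ≈ 0.8 and the interaction tests would over-reject. The same
likelihood with `reml=False` is available. Starting values exploit the
identical-regressor (Zellner) property — per-function OLS plus the residual
covariance — so the optimizer starts essentially at the optimum and
converges in a few dozen evaluations. Wald t statistics use
df = N − p; interactions are β_F − β_M contrasts from the full GLS
covariance. γ is twice the fitted quadratic coefficient (and its SE twice
the coefficient SE), the standard correction for the ½γz² surface
parameterization. A variance component driven to ~0 triggers a boundary
warning and is reported at the boundary; non-convergence raises.

**Combined model.** OLS of `relW_female + relW_male` (each component
relativized by its own mean first, then summed) on the same linear and
quadratic terms, with the same γ doubling.

**Indices.** SAS = |G_F − G_M|; SA = G_F·G_M / √((G_F²+G_M²)/2), computed
for linear and quadratic gradients alike and rounded half-even to two
decimals in formatted output. SA is computed with the larger magnitude
factored out so sub-normal gradients cannot underflow to NaN; SA(0,0) is
defined as 0 with a warning.

**Regime classification** examines w(z) = βz + (γ/2)z² on the observed
standardized range at α = 0.05 (raw p-values, no multiplicity correction,
matching reported practice): neither term significant → none; significant
γ < 0 with interior stationary point → stabilizing (optimum at −β/γ);
significant γ > 0 with interior stationary point → disruptive (reported
optimum at the better endpoint); otherwise directional toward the endpoint
with the higher fitted fitness. A quadratic on an interval cannot have two
maxima *and* two minima, so "interior minimum" is the operative disruptive
criterion. Inputs flagged significant with β = γ = 0 raise a contradiction
error.

## 6. Numerical choices and degenerate inputs

- Variance parameters are optimized on the log scale, clipped to
  e^(−15) … e^(15); hitting the lower clip is reported as a boundary fit.
- Nelder–Mead tolerances: xatol 1e-8/1e-9, fatol 1e-10/1e-11 (delay model /
  gradient model). The fixed effects at the optimum are an exact GLS solve
  given the variances, so fixed-effect accuracy is limited by linear algebra,
  not by the optimizer (verified against a dense explicit-covariance GLS
  solve to well below 1e-6).
- LOD ties (|ΔLOD| ≤ 1e-9) leave a seed unassigned — two flowers of the same
  individual always tie, so geitonogamous sires are identified to individual
  but not flower, and remain unassigned at flower level.
- Singular designs (constant trait, constant pistil count), empty inclusion
  sets, zero-mean fitness and all-missing loci raise typed errors
  (`EstimationError`, `ValueError`) naming the offending quantity; a census
  day with receptive pistils but no pollen is logged, not raised.
- Half-open boundaries: a male phase `[0,5)` and female phase `[5,9)` never
  overlap, including on a census day at 5.

## 7. Problem sizes used in the automated checks

The acceptance-style tests run the whole machinery at the study's scale:
full seasons of ~150 individuals for paternity recovery and conservation
checks; 50 replicate datasets (n = 200 flowers) for gradient-recovery bias;
1000 replicate no-conflict datasets at n = 57 flowers (the size of the
analysis set) for interaction-test calibration; Δ\*-calibration simulations
of 1000–2000 seeds. These sizes give Monte-Carlo error comfortably inside
the asserted bands while keeping the suite quick on a single CPU.

## 8. Known limitations

- The paternity error model is locus-level replacement, not an allele-level
  dropout/miscall model; with data genotyped under a very different error
  process the Δ\* calibration inherits that mismatch.
- Δ\* is calibrated against the global candidate pool, not per family;
  families with very small filtered candidate lists are assigned slightly
  conservatively.
- Female fitness counts seeds only; seed dispersal and establishment (where
  stalk height plausibly acts) are outside the model, as is lifetime fitness
  across seasons.
- The equilibrium δ estimator assumes inbreeding equilibrium and a single
  population-wide selfing rate; it is an auxiliary tool, not part of the
  main pipeline's fitted quantities.
- Selection on male flowers' own traits is not estimated (they have no seed
  families); male flowers enter as sires and in trait-distribution overlays
  only.
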