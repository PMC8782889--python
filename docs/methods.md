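# Methods

## The quantities

For each mixture plot-year the package computes the additive partition of
the net biodiversity effect,

    NE = Y_O − Y_E = CE + SE
    CE = N · mean(ΔRY_i) · mean(M_i)
    SE = N · cov(ΔRY_i, M_i)          (covariance with divisor N)

with N the number of sown species, M_i the pure-stand yield of species i
averaged across the site's blocks for that year, ΔRY_i = Y_i/M_i − RY_E,i,
Y_O the summed observed mixture species yields and Y_E = Σ RY_E,i·M_i; and
the per-species corrected relative yields RY_C = RY_O/RY_E with
RY_O = Y_i / (pure-stand yield of i in the same block).

Two related but distinct relative yields appear, deliberately:

* inside CE/SE, ΔRY is taken against the cross-block mean M_i.  Together
  with the divisor-N covariance this makes NE = CE + SE an *exact algebraic
  identity* (Σ a_i b_i = N·mean(a)·mean(b) + N·cov(a,b)), which the test
  suite enforces to 1e−9 relative on every computed row;
* the species-level RY_O/RY_C reported in the species table use the
  *within-block* pure stand as the reference, so that multiplicative block
  effects cancel.  Field texts commonly describe RY_O this way; using it
  inside the partition would break the identity whenever a block deviates
  from the cross-block mean, so the two usages are kept separate and both
  are emitted.

Baselines: under N0 all references are unfertilized pure stands; under N1
the grass and chicory references come from fertilized pure stands.  The
design contains no fertilized legume stands, so the clover reference under
N1 remains the unfertilized clover pure stand of the same population; the
output provenance carries this flag, and clover RY_C rows are omitted under
N1 by default (they would duplicate the N0 values) unless requested.
Clover references are always population-matched: a mixture sown with
population T3 is compared against T3's own pure stand, never a
population-averaged one.  The duplicated ryegrass pure stands are averaged
within block and fertilization level *before* any reference is built.

Degenerate references (missing or zero pure-stand yield) leave the affected
plot-year flagged with an explanatory string and NaN results — flagged, not
imputed and not dropped, so that row counts are preserved and the reason is
auditable.  Non-sown ("weed") biomass is carried through the data model but
never enters any of the above quantities, which are defined on sown species
only.

## The synthetic experiment

The generator reproduces the field trial's factor structure exactly: per
site (R, D), 4 blocks × 38 plots — 8 white-clover populations × {pure
stand, clover–grass TL, clover–chicory TC, clover–grass–chicory TLC},
2 duplicate ryegrass pure-stand plots at each of N0/N1 and one chicory
plot at each level — 152 plots per site, 5 years × 4 harvests, with plot
order randomized within block under the seed.

Expectations (t DM ha⁻¹ a⁻¹):

    pure stand:  E[Y_i] = μ_s · g_i · (1 + a_p if clover)
                        · (1 + β if N1 non-legume)
                        · (1 − d_y if N0 non-legume) · drought_{i,y}
    mixture:     E[Y_i] = RY_E,i · Y_i^pure(N0, block level) · r_i(p, y)

so the *true* N0-baseline RY_C of species i equals r_i by construction, and
the true N1-baseline RY_C of non-legumes is r_i·(1−d_y)/(1+β) up to noise
(plus a small Jensen term from the noisy cross-block mean in CE/SE).
Block effects are multiplicative lognormal (mean 1, log-SD σ_block) and
shared by *all* plots of a block, mirroring why relative yields are taken
within blocks — they cancel there.  Residual noise is lognormal with CV
σ_res per plot-year (a Gaussian alternative sits behind the `noise` switch,
clipped at zero).  Annual totals are split over the four harvests by fixed
proportions (0.30/0.30/0.25/0.15) — annual accumulation makes the split
immaterial to every effect, it exists to exercise the aggregation code —
and a constant non-sown fraction w is added to the harvested totals.

Defaults and why: site productivities μ = (10.0, 8.5) and species
multipliers g = (0.8, 0.55, 0.7) for clover/grass/chicory put unfertilized
pure stands near 8, 5.5 and 7 t DM ha⁻¹ — productive temperate forage
levels, with the unfertilized grass stand weakest (no nitrogen source) and
chicory intermediate (deep roots, less N-limited).  β = 0.8: 240 kg N ha⁻¹
raises non-legume pure stands by ~80%.  d_y rising to 0.20 by year 5:
progressive nitrogen depletion of unfertilized non-legume references under
repeated cutting.  r_grass = 1.35, r_chicory = 1.0, r_clover = 0.85:
grass profits most from growing next to clover, chicory is near-neutral,
clover tends to be competitively displaced.  σ_block = σ_res = 0.10 and
w = 0.05 are typical magnitudes for cut-plot forage trials.  The ratios r_i
accept scalars or arrays over (population, year); a dependence on mixture
type or site is not exposed — no scenario here needs it.

The true ratios are parameterized directly rather than derived from a
mechanistic nitrogen-cycling model, so recovery targets are exact; the
price is that r_i is phenomenological.  The generator also does not emulate
several features of real data: species-specific residual noise within a
plot (one multiplier is shared by all species of a plot-year), harvest-level
composition shifts, spatial autocorrelation beyond the block effect, weather
other than the per-year drought multipliers, or measurement error in the
manual separation.  Passing tests therefore demonstrate correctness of the
estimators and workflow under a controlled data-generating process, not
robustness to every field-data pathology.

### Scenario presets

* **null** — all ratios 1, no fertilization response, no noise, no weeds:
  every NE/CE/SE is exactly 0 and every RY_C exactly 1.
* **population-facilitation** — facilitation shares f_p rise from 0.25 to
  1.0 across the eight populations and r_grass,p = 1 + f_p·β: populations
  deliver increasing nitrogen to their grass companion, so complementarity
  under N0 is ordered by f_p.  Also the "strong population effect" scenario
  for power checks.
* **facilitation-matched** — the nitrogen-mediation mechanism in its pure
  form: every companion boost is fully N-mediated and exactly equivalent to
  fertilization (f_p = 1, r_grass = r_chicory = 1 + β, r_clover = 1), while
  populations differ in pure-stand vigour (a_p from −25% to +25%, the span
  plausible for diverse breeding material).  Under N0 the positive mean ΔRY
  propagates the vigour differences into CE; under N1 the mean ΔRY
  collapses to ~0, so CE and its population differences vanish.  This is
  the only physically consistent way to realize "referencing against
  fertilized stands removes the facilitation signal": with real yields on
  both sides, RY_C under N1 is mechanically RY_C(N0)·P_N0/P_N1, so a
  population-specific boost carried by the ratios themselves can only
  shrink by the factor 1/(1+β).
* **temporal-depletion** — d_y = (0, .10, .20, .20, .20) with
  r_grass,y = 1.25/(1−d_y): the unfertilized references run down while
  absolute mixture yields hold steady, so grass RY_C (N0) rises over years
  1–3 and levels off; drought multipliers and reduced r_clover cut clover
  performance in years 4–5.

## Inference

Each response (NE, CE, SE per baseline; RY_C per species and baseline) is
modelled with population, year (categorical, 5 levels), mixture type and
site plus all interactions as fixed effects and plot-nested-in-block random
intercepts, via statsmodels' MixedLM.  RY_C responses are square-root
transformed (they are non-negative and right-skewed); the transform is
refused for negative inputs rather than silently shifted.  Residuals are
homoscedastic by default; RY_C is scale-free and the partition components
share one yield unit, so no per-stratum weighting is applied (none of the
synthetic scenarios generates heteroscedastic strata; a weighting knob was
considered and left out as untestable here).

Model simplification is *backward* elimination on AICc (all-subsets search
would also be defensible; backward is what the selection path documents):
at each step every droppable term — one not nested in a retained
higher-order term, so marginality is preserved on every path — is removed
in turn, candidates are refitted by **maximum likelihood** (AICc across
different fixed structures is only valid under ML), and the removal that
most lowers AICc is accepted, ties preferring the higher-order term.  The
random structure is never simplified.  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)
with k counting fixed-effect coefficients plus the three variance
parameters and n the number of observations.  The final model is refitted
by REML.

Retained terms are tested with sequential (type-I) Wald chi-square tests in
the canonical order (population, year, mixtype, site, then interactions):
the design and response are whitened by the inverse Cholesky factor of the
fitted covariance (block + plot + residual components) and each term's chi-
square is the drop in whitened residual sum of squares as its columns
enter.  Statistics are reported as F = χ²/df — the printing convention of
the mixed-model ecosystem this workflow mirrors — with denominator degrees
of freedom by the containment rule: terms constant within plots are tested
against the plot stratum (n_plots − (n_blocks−1) − p_between), terms varying
within plots against the residual stratum (n − n_plots − p_within).  The
test suite cross-checks log-likelihood, variance components, F, df and ddf
against R's nlme on identical data.  Terms not retained are printed as "–".
The significance level is 0.05 throughout.

## Numerical and scaling choices

* Identity and recovery tolerances: the partition identity is checked at
  1e−9 relative (it holds to ~1e−13; the slack is accumulated rounding over
  nansum reductions), exact-recovery checks at 1e−9, oracle comparisons at
  1e−12.
* Fraction-sum tolerance on harvest records defaults to 0.01 (manual
  separation of 250 g subsamples rounds); configurable.
* Missing harvests: strict by default (a plot-year must have all four
  cuts); a permissive mode sums what exists and warns.
* Tables are written with `%.17g` floats and read with the round-trip
  parser, so annual/effects tables survive CSV round trips bit-exactly.
* Simulation-based checks use 100 replicate studies for parameter recovery,
  attenuation and inference power; the power/selection replicates run on a
  one-site, three-year slice of the design (288 effect rows per replicate),
  which keeps one full sweep near three minutes on a single CPU while
  leaving the population contrast amply powered.  The temporal-trend check
  pools 20 replicates.
* Mixed-model fits use L-BFGS with a 200-iteration cap; non-convergence or
  non-finite likelihoods raise a clear error naming the attempted formula,
  and failed elimination candidates are skipped with a warning rather than
  aborting the search.

## Known limitations

* The sequential tests are Wald-type with plug-in variance components;
  denominator df are containment approximations, not Kenward–Roger.
* The generator's N1-baseline truth is derived (r·(1−d_y)/(1+β)), not an
  independent dial — a consequence of insisting on physically consistent
  yields (see the facilitation-matched preset note above).
* Flagged (incomputable) plot-years are excluded from model fits; with many
  missing references the factorial balance that the containment df assume
  would erode.
* AICc counts variance parameters as 3 regardless of boundary estimates
  (a variance component estimated at 0 still counts), matching common
  information-criterion practice but debatable near boundaries.
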