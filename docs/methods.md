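# Methods

## The standard-curve model

Population-based cancer registries can be reduced to two numbers per sex:
the median age of the resident population, *x*, and the median age at
lung-cancer onset, *y*, both in years. Across registries these points
scatter around a straight line — older populations get lung cancer later —
and the scatter absorbs the between-population variation in smoking,
radon, occupation, deprivation and the other onset-shifting risk factors.
The package fits this "standard curve" by Bayesian simple linear
regression, for registries *i = 1 … n* of one sex:

    y_i ~ Normal(α + β x_i, 1/τ)
    α ~ Normal(0, precision 1e-6)
    β ~ Normal(0, precision 1e-6)
    τ ~ Gamma(shape 0.5, rate 0.01)

Sexes are modelled completely separately (their curves differ materially;
female slopes run much steeper than male ones).

A small area is then scored by how far its observed onset median sits from
the curve's expectation at its own *x*:

* **residual** = y_obs − E[α + βx] in years, negative = earlier onset than
  expected — the "pollution signature" when a shared local exposure is the
  plausible cause;
* a 95% equal-tailed credibility interval of the residual;
* **PP** = P(y_rep ≤ y_obs | x), the lower-tail posterior probability that
  a replicate observation falls at or below the observed median. PP near 0
  flags improbably early onset, PP near 1 improbably late onset.

Decisions are two-sided with a Bonferroni-corrected threshold
t = α / m, where m counts the **eligible** study areas (more than one
incident case and a computable onset median). With α = 0.05, m = 40 gives
t = 0.00125 and m = 35 gives t ≈ 0.00143; the comparison is inclusive
(PP exactly at t counts as significant). m is always computed from the
data, never hard-coded. Ineligible areas are reported as "no data".

Residuals are mapped into five display bands (years): ≥ +2 postponement;
(−2, +2) neutral; (−4, −2], (−6, −4], ≤ −6 increasing anticipation. Bands
are half-open, closed on the early side, so every residual belongs to
exactly one band.

### Parameter-level vs predictive-level uncertainty

Two uncertainty propagation modes are computed for every area:

* **parameter** mode draws y_rep = α_d + β_d x — only the uncertainty of
  the line itself. It answers "is this area's median off the *line*?" and
  is always at least as extreme as the predictive mode.
* **predictive** mode (the default for the headline pp/CI columns) draws
  y_rep = α_d + β_d x + ε_d with ε_d ~ Normal(0, 1/τ_d) — the area is
  judged as a *new observation* against the full dispersion of reference
  registries, which is what lets the registry scatter stand in for
  unmeasured confounding. Both are emitted in reports so the choice is
  auditable.

## Inference

The model is conditionally conjugate, so the sampler is a block Gibbs
sampler written with numpy: (α, β) jointly from their bivariate-normal
full conditional given τ, then τ from its Gamma full conditional given the
residual sum of squares. Chains start overdispersed around the
least-squares solution. The default run length (3 chains, 100,000 burn-in
+ 100,000 retained draws) matches the original analysis; tests and
simulations use 2–3 chains with a few hundred burn-in and 1,200–5,000
retained draws, which this two-parameter model mixes through easily
(split-R̂ < 1.01, bulk ESS in the thousands). Split-R̂/ESS come from
ArviZ. Fits are bit-reproducible given the seed.

Numerical choices worth knowing:

* x is **not** centred by default, so the intercept is on the raw scale of
  the reported regression equations; `center=True` fits on centred x and
  maps back.
* Predictive intervals use equal-tailed Monte-Carlo quantiles with one
  ε draw per retained posterior draw (retained with the curve, so bands
  are deterministic functions of a fitted curve).
* Predictive-mode PP is Rao-Blackwellized: PP = mean over draws of
  Φ((y_obs − α_d − β_d x)√τ_d). This is the same estimand as counting
  indicator draws but resolves the 1e-3-scale tails demanded by
  Bonferroni thresholds at desk-scale draw counts. Parameter-mode PP is
  the empirical fraction of line draws at or below y_obs.
* Note the stated priors are *not* jointly normal-inverse-gamma (the
  coefficient priors do not scale with τ); at n = 36 this shifts
  coefficient posterior SDs by ~3% relative to the NIG closed form. The
  test-suite oracle is therefore an exact quadrature of the actual prior
  model, not the NIG formula.

## Grouped medians

Registry inputs are age-binned in quinquennia (0–4, …, 80–84, 85+).
Medians are estimated by linear interpolation within the bin containing
the N/2 point: median = L + ((N/2 − CF)/f)·h. This equals the exact median
of the density that spreads each bin's count uniformly over the bin (the
test oracle solves the piecewise-linear CDF by root finding). When N/2
falls exactly on a bin edge the formula is continuous and returns the
edge. A median falling in the open 85+ bin has no upper edge and is
reported as undefined rather than extrapolated — such units become
ineligible. The N/2 continuum convention (not (N+1)/2) is used for both
population and case medians, one code path.

## The synthetic-data generator

Real study data of this kind are access-restricted, so the generator
emulates the study design and is first-class, tested code:

* **Reference registries** (default 36, the reference-population count):
  x ~ Uniform(40, 50) years — typical Italian municipal population
  medians — and y = α + βx + Normal(0, σ). Defaults α = 56 years,
  β = 0.4, σ = 1.5 years, chosen to resemble the male reference fit;
  registry case/population totals are drawn at realistic magnitudes.
* **Study areas** (default 41, the section count): each draws x, a target
  median y* = line + shift (shift < 0 injects an early-onset exposure),
  then simulates n_cases individual onset ages ~ Normal(y*, sd_onset) and
  reports their *sample median*. sd_onset defaults to 9 years, a plausible
  spread of lung-cancer onset ages within an area. Case counts default to
  a right-skewed 0–300 distribution like real census sections; areas with
  0–1 cases exercise the eligibility rules.
* **Null study areas** (`generate_null_study_pairs`): onset medians drawn
  directly from the reference law y ~ Normal(line, σ²). This is the null
  under which PP is uniform and flag rates are calibrated; it is the right
  generator for calibration checks, while the individual-age route is the
  right one for power and pipeline checks (see limitations).
* `binned_counts_for_median` inverts the grouped-median formula (half the
  mass in the target's bin, the remainder split between the neighbouring
  bins), so the binned-input route can be tested end-to-end against the
  pair route to 1e-6. Counts are real-valued; a target in the lower half
  of the lowest bin or in the open bin is not representable and raises.

All generators are deterministic given the scenario seed and emit their
truth tables.

## What the checks show — and measured behaviour

All quantitative guarantees are measured on synthetic scenarios at the
design sizes above, with desk-scale chains (the two-parameter conjugate
model makes long chains unnecessary; the acceptance script finishes in
about two minutes on one CPU):

* Gibbs posterior means/SDs of α, β agree with the deterministic
  quadrature posterior to a few tenths of a percent.
* The 95% predictive band covers ~94.5% of fresh null registries
  marginally over fits. The ~0.5 pp shortfall is the familiar small-n
  effect of vague-prior predictive intervals at n = 36; it also makes the
  uncorrected per-tail null flag rate run slightly above nominal
  (~0.052–0.055 vs 0.05).
* Under the model null, PP is indistinguishable from Uniform(0,1)
  (Kolmogorov–Smirnov at ~2,000 simulated areas).
* An injected −8-year area with 30 cases among 40 nulls is flagged under
  the Bonferroni threshold with probability ~0.92. Detection probability
  is estimated by solving each fitted curve's exact flag boundary and
  integrating out the area's 30-case median sampling noise — the same
  marginal flag rate as rerunning the binary pipeline, with much smaller
  Monte-Carlo error.

## Known limitations

* Sparse-area onset medians carry sampling noise (sd ≈ 1.25·sd_onset/√n
  years) that the regression's dispersion term does not represent; for
  30-case areas this inflates the realized per-tail flag rate under the
  individual-age null to ~7% at nominal 5%. The method inherits this from
  its design — the reference registries are large, the study areas are
  not. Interpret borderline flags in very sparse areas accordingly.
* The generator does not simulate spatially correlated exposure surfaces,
  demographic structure beyond the medians, or covariate confounding;
  passing checks show the statistical machinery is calibrated under its
  own assumptions, not that those assumptions hold in any particular
  registry.
* No spatial smoothing, FDR alternatives, or robust/hierarchical
  extensions; sensitivity to the reference set is explored by rerunning
  with a different reference CSV, not by a special code path.
* Medians in the open 85+ bin are undefined by design; units whose case
  median lands there are excluded rather than extrapolated.
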