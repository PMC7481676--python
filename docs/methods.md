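# Methods

This note documents the statistical model the package implements, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Model structure

The joint posterior ties three observation layers to one latent density
surface, separately for each month *m* and age class *a* (adult, juvenile):

**1. REST passage counts.** Each camera watches a fixed focal area — an
equilateral triangle of side `focal_side_m` (default 1.9 m, area
(√3/4)·side² ≈ 1.56 m²) — inside which every passage is assumed detected.
The REST identity states that, for randomly moving animals, expected passage
count equals density × area × (active time / mean staying time).  With
density log-linear in landscape principal-component scores,

    mu_{i,m,a} = exp(alpha_{0,m,a} + Σ_{e=1..4} alpha_{e,m,a}·PC_{e,i})
                 × 1e-6 × A[m²] × T_{i,m}·p_{m,a} / E[stay]_{m,a}

where T is deployment seconds in the month and p the daily activity
proportion.  Counts are negative binomial with mean mu and gamma shape
k_{m,a} (variance mu + mu²/k), absorbing camera-level heterogeneity beyond
the habitat model.  A camera-month with zero deployment contributes no
likelihood term.

**Unit convention.** exp(linear predictor) is density in animals per km²;
the factor 1e-6 converts it to per-m² inside the count expectation.  This is
the only convention compatible with a Uniform(−3, 3) prior on alpha and
densities of order 1–25 animals/km² (exp(±3) ≈ 0.05–20): under a per-m²
reading the intercept of any realistic density would sit near −11.5, outside
its own prior.  All reported densities are per km².

**2. Staying times.** Measured staying times (seconds per passage) follow a
parametric family — exponential, gamma, lognormal or Weibull, each optionally
extended with a lognormal camera-station random effect (multiplicative scale
exp(u_j), u_j ~ N(0, τ²), τ ~ half-Normal(1)).  Candidates are fitted by MCMC
with Normal(0, 10) priors on unconstrained (log-scale) parameters and scored
by WAIC = −2(lppd − p_WAIC), with p_WAIC the summed pointwise posterior
variance of the log-likelihood; the minimum-WAIC model wins, ties broken
toward fewer parameters.  In the fitting pipeline the sweep runs once per age
class on pooled data (a single family is selected for all months, matching
how such selections are reported in practice); the selected family's
*per-month* parameters are then sampled inside the joint model, so
staying-time uncertainty propagates into density (config `stay_mode: joint`;
`plugin` fixes the posterior-mean staying time instead).  Censoring at the
video length is off by default: staying times are treated as fully observed
measurements across consecutive recordings.

**3. Daily activity proportion.** The REST denominator assumes every
individual is active at the peak of the circadian rhythm, so the active
fraction of the day is p = (1/24h)/max_t f(t) with f the circular density of
detection times.  f is a von Mises kernel density on a 512-point grid.  The
kernel concentration is the standard maximum-likelihood plug-in
ν = (3n κ̂² I₂(2κ̂) / (4√π I₁(κ̂)²))^{2/5} multiplied by an adjustment of 1.5 —
the undersmoothing factor used in the activity-level literature, because the
target is the density *peak*, which the L2-optimal bandwidth systematically
flattens (measured on simulated von Mises data: without the adjustment the
estimated proportion is biased up ~20% at n ≈ 50; with it the mean log-error
is ≈ 0 from n ≈ 200).  Estimates are computed per month × age class, pooling
symmetrically over adjacent months below `activity_min_detections` (default
10).  Each passage contributes its entry timestamp once; staying duration
does not weight the density.  The proportion enters the joint model as a
plug-in point estimate (its sampling noise, sd ≈ 4–6% of log density at
500–2000 detections, is the dominant non-count error at large camera
numbers — see Limitations).

**4. Up-scaling and catch-effort.** Landscape PCA is fitted once on the
camera-site compositions (six land-use percentages standardized to mean 0,
sd 1; axes signed so each axis's largest-magnitude loading is positive) and
treated as fixed.  Grid cells are projected with the *camera-site* means and
sds, which keeps the cell covariates on the scale the coefficients were
estimated on.  Cell density is exp(alpha·[1, PC_c]); unit density is the
forest-area-weighted mean over the unit's cells (forest area = broadleaf +
conifer + bamboo fraction × 1 km²), summed over the age classes modelled
that month.  Monthly catches per unit and trap type are
Poisson(c_{m,t} × traps × D_{u,m}); catchability c is shared across units
per (month, trap type), the identifiable default when one value per month
and type is the quantity of interest.  Harvest does not feed back into
density (no removal dynamics): months are estimated independently.

## Priors and sampling

alpha ~ Uniform(−3, 3), enforced as a hard constraint; catchability ~
Uniform(0, 1); dispersion via a half-Cauchy(scale 5) prior on 1/√k;
Normal(0, 10) on unconstrained staying-time parameters.  The sampler is a
blocked adaptive random-walk Metropolis (Metropolis-within-Gibbs): months
factorize, and each month contributes an alpha block (5-d), a dispersion
block (1-d) and a staying-time block (2-d) per age class, plus a
2-d catchability block when harvest data exist.  Proposal scales follow
Robbins–Monro adaptation toward 0.234 acceptance (0.44 for 1-d blocks) and
proposal covariances track the running empirical block covariance; adaptation
continues through the whole run with a diminishing rate (t^−0.6), which is
ergodic and keeps mixing good even with short burn-ins.  Chains start from
moment-based values (REST point estimate for the intercept, data moments for
staying-time parameters, catch/(traps×density) for catchability) with small
jitter on chains 2+.  Defaults follow the study design: 50 000 iterations,
10 000 burn-in, thinning 20, 3 chains (2000 kept draws per chain);
convergence is declared at split-chain Rhat < 1.1 for every parameter, and
the CLI `fit` command exits non-zero otherwise.

Numerical guards: any parameter point where the staying-time mean, the count
mean or the Poisson rate is non-finite or non-positive has log-posterior −∞;
Poisson terms use log(max(λ, 1e-300)) with λ = 0 ∧ y = 0 contributing 0;
the von Mises KDE uses exponent-scaled Bessel functions and caps the kernel
concentration at 1000 (point-mass samples), where the 512-point grid still
integrates the density to 1 within 1e-6.

## The synthetic-data generator

`boarest.simulate` draws complete studies from exactly the model above —
that is by design: it provides ground truth for end-to-end recovery tests,
not an independent ecological world.  Defaults mirror the motivating study's
scale (180 cameras, 897 one-km² cells, 33 management units, 12 months; a
"small" preset 30/100/6/3 keeps tests fast):

* compositions from a two-component Dirichlet mixture (55% forest-dominated,
  45% mosaic sites), giving realistic correlations among the six classes;
  cells are striped row-major into contiguous units;
* adult log-density intercept 2.0 ± 0.3 seasonal sine (≈ 5–10 animals/km²,
  matching densities reported for managed boar populations), juveniles 1.2,
  slopes (−0.3, −0.2, +0.4, +0.15) on PC1–PC4 (negative on the forest and
  conifer gradients, positive on abandoned-field and bamboo gradients);
  NB dispersion k = 1, a typical overdispersion for camera counts;
* lognormal staying times (meanlog 1.8, sdlog 0.7 → mean ≈ 7.7 s for adults);
* von Mises activity rhythms (adults: peak 22:00, κ = 1.2 → 42% of the day;
  juveniles: peak 14:00, κ = 0.8 → 52%);
* catchabilities 0.02 (box) and 0.012 (snare) per trap-month per animal/km²
  (ratio 1.67, echoing the reported box/snare contrast), trap counts negative
  binomial around 20 (box) and 15 (snare) per unit-month;
* juvenile data only in a configurable subset of months (default the first
  half), mimicking the seasonal availability of juvenile observations.

What it does **not** emulate: animal movement and home ranges (counts are
conditionally independent given habitat — no spatial autocorrelation between
nearby cameras), imperfect detection inside the focal area, trap
interference or saturation, observation error in land-use maps, and any
mismatch between the parametric staying-time family and reality.  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation in field data.

## Validation experiments (`boarest.experiments`)

Problem sizes are chosen so each experiment runs in well under a minute on
one CPU.

* **Joint recovery** (small preset, MCMC 5000/1000/5 × 3 chains): 95% CI
  coverage of all 20 habitat coefficients and all 6 catchabilities, max Rhat.
* **Density accuracy at high effort**: REST-only fits at 1200 cameras ×
  6 months; median across months of the relative error of the site-averaged
  posterior-median density.  Per-month error sd is ≈ 5–6% (activity plug-in
  + intercept posterior width), so the median over 6 months keeps the
  sampling distribution of the statistic comfortably under 10%.
* **Posterior contraction**: 60 camera stations, then every station
  duplicated so the doubled data set contains the baseline data plus an
  independent replicate — exactly twice the count information, expected
  sd ratio √2.  Doubling *deployment time* would not double information:
  under NB heterogeneity the per-camera information saturates at k, which is
  why effort is doubled in cameras, not hours.
* **WAIC selection**: 20 replicate lognormal (μ=1, σ=0.8, n=500) data sets;
  fraction on which the four-family sweep selects the lognormal.

## Limitations

* The activity proportion is a plug-in: its nonparametric error (rate n^−2/5)
  does not propagate into credible intervals and becomes the accuracy floor
  of density estimates once camera effort is large.
* Catchability and density enter the harvest mean as a product; harvest data
  alone cannot separate them.  Identification comes entirely from the camera
  layer, so biases in the REST density map directly into catchability.
* The Uniform(−3, 3) prior on alpha truncates: populations denser than
  ≈ 20/km² at average habitat (or steeper habitat contrasts) hit the bound;
  the config can widen it, with a warning that this departs from the
  reference design.
* Months are independent; no demographic coupling (births, recruitment,
  removal feedback) is modelled, so seasonal density trajectories are
  descriptive, not mechanistic.
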