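# boarest

Joint Bayesian estimation of **seasonal population density, habitat
preference and trap catchability** of a wild mammal population (the motivating
system is wild boar, *Sus scrofa*, in a mosaic rural landscape) from two data
sources with complementary spatial resolution:

* **camera-trap passage data**, analysed with the REST model (random
  encounter and staying time) — no individual recognition required; and
* **municipal harvest records** (monthly counts of active box/snare traps and
  trapped animals per management unit), analysed with a catch-effort model.

## The model

For camera *i*, month *m* and age class *a* (adult/juvenile), the REST model
relates the number of passages through a fixed focal area (an equilateral
triangle of side 1.9 m, area (√3/4)·1.9² ≈ 1.56 m²) to local density:

```
D_{i,m,a} = (N_{i,m,a} / A) · (E[staying time]_{m,a} / active time_{i,m,a})
```

where *active time* is the camera's deployment time multiplied by the **daily
activity proportion** — the fraction of the 24 h day the population is active,
estimated from the circadian distribution of detection times by a von Mises
kernel density: `p = (1/24h) / max_t f(t)`.  Staying times are fitted with
exponential/gamma/lognormal/Weibull candidates (optionally with a
camera-station random effect) and the family is selected by WAIC.

Habitat enters through a log-linear model on principal-component scores of the
surrounding land-use composition (6 classes within a 500 m buffer, PCA axes
1–4):

```
D_{i,m,a} = exp( α_{0,m,a} + Σ_e α_{e,m,a} · PC_{e,i} ),   α ~ Uniform(−3, 3)
```

with densities in animals/km².  Passage counts are negative binomial around
the implied expectation (gamma-Poisson heterogeneity, shape *k*).  The same
coefficients predict density in every 1 km² grid cell; management-unit density
is the **forest-area-weighted mean** of its cells.  Monthly unit catches are

```
y_{u,m,t} ~ Poisson( c_{m,t} · traps_{u,m,t} · D_{u,m} ),   c ~ Uniform(0, 1)
```

which identifies the **catchability** `c` of each trap type per month.  All
parameters are sampled jointly by a blocked adaptive Metropolis sampler
(default 50 000 iterations, 10 000 burn-in, thinning 20, 3 chains → 2000 kept
draws per chain), with convergence checked by split-chain Rhat < 1.1.

A full generative simulator (`boarest.simulate`) draws every input table from
this model with known ground truth, so estimation can be validated end to end
without field data.

## Worked example

```
$ boarest simulate --preset small --out study/ --seed 1
wrote synthetic study (small) to study

$ cat > cfg.yaml <<EOF
months: ["2018-06", "2018-07", "2018-08"]
juvenile_months: ["2018-06"]
stay_families: [lognormal]
stay_random_effects: false
mcmc: {iterations: 5000, burn_in: 1000, thin: 5, chains: 3, seed: 1}
EOF

$ boarest fit --config cfg.yaml --data study/ --out fit/
fit complete: 38 parameters, max Rhat 1.023

$ boarest summarize --draws fit/ | head -6
                                    mean     sd    q2.5     q25  median     q75   q97.5   rhat
parameter
alpha0[2018-06,adult]             1.8797 0.3684  1.1391  1.6345  1.8823  2.1196  2.5704 1.0078
alpha1[2018-06,adult]            -0.5660 0.1886 -0.9626 -0.6900 -0.5593 -0.4382 -0.2161 1.0030
alpha2[2018-06,adult]            -0.2858 0.3127 -0.9036 -0.4987 -0.2763 -0.0752  0.2973 1.0021
alpha3[2018-06,adult]             0.0958 0.6153 -1.0721 -0.3274  0.0647  0.4978  1.3577 1.0057
```

`alpha0[2018-06,adult] ≈ 1.88` is log density at average landscape
composition, i.e. a posterior median of e^1.88 ≈ 6.6 adults/km²; the
simulator's generating value (recorded in `study/truth.yaml`) is α₀ = 2.0,
≈ 7.4/km², inside the 95% interval.  Negative `alpha1` means density
decreases along PC1.  The fit
directory also contains `density_area.csv` / `density_units.csv` (posterior
density summaries per month, age and management unit, with 50% and 95%
credible intervals), `catchability_summary.csv`, `rhat.csv` and `draws.csv`;
`fit` exits non-zero if any Rhat ≥ 1.1 unless `--allow-nonconverged` is given.

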