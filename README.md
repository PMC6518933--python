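# pondscape

Longitudinal habitat-loss biodiversity analysis for two-epoch pond
metacommunities — built for the situation where a landscape of discrete
habitats (here: shallow saline ponds) was surveyed for its invertebrate
communities twice, decades apart, and most of the habitat disappeared in
between. The package separates the boring explanation (fewer habitats ⇒
fewer species, by sampling alone) from the interesting one (the surviving
habitats themselves lost species because the habitat network thinned out).

It is aimed at spatial community ecologists with site × species incidence
tables, pond coordinates/areas, and a habitat-quality covariate per epoch.

## What it computes

* **Rarefaction null** — sample-based species accumulation (2000 random
  site permutations) by habitat count and by cumulative area, with 95%
  envelopes (exact per-k quantiles on the count axis; spline quantile
  regression at τ = 0.025/0.5/0.975 on the area axis). Expected loss when
  rarefying epoch 1 to epoch-2 habitat, against the closed form
  E[S_m] = Σ_i [1 − C(n−n_i, m)/C(n, m)].
* **Habitat number vs habitat area** — per accumulation run, an additive
  penalized-spline (GAM-style) model richness ~ s(sites) + s(area); the
  predictor whose removal costs more explained deviance wins the run.
* **Network change** — closeness (mean Euclidean distance to all other
  extant ponds, km) per epoch and its per-pond change; an increase means
  the pond became more peripheral.
* **Diversity change** — α, γ, Whittaker β = γ/ᾱ per epoch; permutation
  effect sizes D̄ (200 label permutations of pooled site rows) for Δα
  and Δβ.
* **Driver models** — binomial GLM of regional extinction on
  √occupancy, log body size and salinity preference; commonality
  partitioning of adjusted (pseudo-)R² into pure/shared fractions; local
  partition of per-pond richness change onto Δcloseness, Δconductivity,
  Δlog-area.
* **Synthetic landscapes** — a generator producing two-epoch
  metacommunities with the study's structure (116 ponds → 30 survivors,
  53 sampled, 24 shared; many-rare species pool; salinity niches;
  connectivity-dependent relaxation), so everything above runs and is
  verified without external data.

See `docs/methods.md` for the models and their assumptions.

## Worked example

The numbered scripts under `analysis/` run the full story on a synthetic
case study (seed 1) and write their tables under `results/`:

```sh
python analysis/01_generate_landscape.py
python analysis/02_rarefaction_null.py
python analysis/03_habitat_number_vs_area.py
python analysis/04_network_change.py
python analysis/05_diversity_effect_sizes.py
python analysis/06_extinction_drivers.py
```

prints, among other things:

```
epoch-1 matrix: 53 sites x 42 species (gamma = 42)
epoch-2 matrix: 30 sites x 38 species (gamma = 38)

observed net regional loss: 4 species
expected from rarefaction to 30 ponds: 4.07 (rounded 4; analytic check 4.06)

1957: habitat number wins 99.2% of 500 runs (0 ties excluded)

mean alpha: 8.51 -> 6.83 (D-bar 1.68, p = 0.020)
beta:       4.94 -> 5.56 (D-bar 0.63, p = 0.423)

local richness change at shared ponds, pure adjusted R^2:
  d_closeness     +0.308 (slope -2.019, p = 0.003)
  d_conductivity  -0.024 (slope +0.065, p = 0.689)
  d_log_area      -0.015 (slope +0.400, p = 0.504)
```

Reading this: regional richness fell from 42 to 38 species; rarefaction
says random loss of 23 ponds would cost ~4 species, so at the regional
scale this particular synthetic draw is consistent with sampling. But
locally each pond lost ~1.7 species on average (p = 0.02) while β stayed
flat, and the local losses concentrate in ponds whose closeness index
grew — the ponds that became isolated (pure R² 0.31, negative slope,
p = 0.003), not the ponds that shrank or changed salinity. That is the
connectivity-loss signature the pipeline is designed to detect, and here
it is detected because the generator put it there.

The same stages are available as a CLI (`pondscape fixtures`, `rarefy`,
`compare-predictors`, `network`, `richness-change`, `drivers`,
`full-run`) for running on your own CSV tables; column conventions are in
`docs/methods.md`.

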