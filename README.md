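# plbreed

Plackett–Luce trees and genomic prediction for decentralized (tricot)
crop variety trials.

Decentralized on-farm testing hands small randomized sets of genotypes —
here three test entries plus a check — to many farmers, who rank them
best to worst at the end of the season. `plbreed` asks the question such
programs face: does modelling those farmer rankings directly, together
with on-site climate, predict varietal performance in farmers' fields
better than a conventional *centralized* route, where genomic prediction
is trained on research-station trials and extrapolated outward?

The package provides both routes and everything around them, exercised
end to end on synthetic data with known ground truth:

* **Rankings** — grouped-ranking containers, construction of rankings
  from per-plot grain yield, comparison-graph connectivity checks, CSV
  I/O (long and wide).
* **Plackett–Luce core** — each genotype *i* has a worth αᵢ > 0, Σα = 1;
  an ordering is generated stagewise with P(next = i) = αᵢ/Σ(remaining α),
  so αᵢ is the probability of winning against the whole set and
  P(i ≻ j) = αᵢ/(αᵢ+αⱼ) is the *reliability* of *i* against a check *j*.
  Maximum-likelihood fitting (MM algorithm) and a MAP variant with a
  genomic-kinship prior on log-worths.
* **Plackett–Luce trees** — recursive covariate-threshold splits gated
  by a Bonferroni-adjusted likelihood-ratio test (α = 0.01, minimum leaf
  20% of the data), giving each environment type its own worth vector;
  JSON serialization and prediction for new covariate profiles.
* **Climate** — agroclimatic covariates (night/day temperature
  statistics, GDD, rainfall indices) per growth phase from daily
  weather, e.g. `minNT_veg`, the minimum night temperature during
  vegetative growth; sowing-window quantile midpoints.
* **Centralized benchmark** — marker QC, VanRaden kinship, station BLUPs
  from a REML mixed model, GBLUP training/prediction, broad- and
  narrow-sense heritability.
* **Selection & evaluation** — forward covariate selection with seasons
  as cross-validation blocks scored by Akaike weights; field-level
  Kendall τ accuracy, combined across seasons with √n weights.
* **Extrapolation** — apply a fitted tree across simulated seasons ×
  sowing dates, average win probabilities per location, and score the
  top-3 recommendation against the check (reliability, expected yield
  gain).
* **Synthetic data** — a generator for the whole study (markers,
  weather, latent worths with a night-temperature switch, tricot and
  station trials) so every stage is testable without any download.

## Worked example

`examples/03_benchmark_vs_decentralized.py` runs the full synthetic
experiment once (seed 1): a study with 100 station genotypes, 15 + check
on farms, 360 farmer fields over three seasons, and a strong worth
reversal at a vegetative night temperature of 11.5 °C:

```
     method trait   season   n   tau
  benchmark    GY combined 360 0.308
  benchmark    OA combined 360 0.353
3d-breeding    OA combined 360 0.377
3d-breeding    GY combined 360 0.359

covariates selected for OA: ['minNT_veg', 'maxNT_rep']
```

Each `tau` is the mean field-level Kendall τ between predicted and
observed rankings; `combined` rows weight the seasons by √n. The
decentralized model recovers the night-temperature covariate by blocked
cross-validation, splits near the true 11.5 °C threshold
(`examples/02_grow_pltree.py` prints the tree), and beats the
station-trained benchmark on both farmer appreciation (OA) and grain
yield (GY) — the benchmark carries a single warm-station ranking into
cold fields where the true ordering has flipped. Other examples cover
worth fitting on a toy set, station heritability, and season
extrapolation with reliability versus the check.

A thin CLI wraps the same pipeline:

```bash
plbreed report --seed 1 --outdir out/   # comparison table + artifacts
```

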