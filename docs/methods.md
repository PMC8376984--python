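# Methods

`plbreed` implements and compares two routes to predicting crop-variety
performance in farmers' fields: a *centralized* genomic-prediction
benchmark trained on research-station trials, and a *decentralized*
approach that models farmer rankings from tricot trials with
Plackett–Luce trees over agroclimatic covariates. Everything is
exercised end to end on synthetic data with known ground truth; this
note records the models, the generator, the numerical choices, and what
the tests do and do not demonstrate.

## The Plackett–Luce model

Each genotype *i* carries a positive worth αᵢ. A farmer's best-to-worst
ordering of their block is modelled stagewise: the next-best entry is
chosen among the remaining ones with probability αᵢ / Σⱼ αⱼ (Luce's
axiom: the preference between two entries does not depend on which
others are present). Under the Σα = 1 gauge, αᵢ is the probability that
*i* wins against all others in the set, and the *reliability* of *i*
against a check *j* is αᵢ/(αᵢ+αⱼ).

**Fitting.** `fit_pl` maximizes the likelihood with Hunter's
minorize–maximize iteration (monotone in the likelihood; update
αᵢ ← Wᵢ/Cᵢ with Wᵢ the win count and Cᵢ the summed inverse set-worths of
the sets containing *i*). The MLE exists iff the pairwise win/loss
digraph is strongly connected; `fit_pl` verifies this and raises an
error naming the components otherwise. Convergence: max absolute change
of the normalized worths below `tol` (default 1e-10, `max_iter` 5000;
non-convergence is flagged and the best iterate returned).

**Genomic prior.** `fit_pl_genomic` is a MAP fit: mean-centred
log-worths λ receive a N(0, `prior_scale`·K + 1e-8·I) prior, K being the
additive relationship matrix, and −log posterior is minimized by
L-BFGS. The prior makes the fit identifiable on disconnected comparison
graphs and produces worths for genotypes that were never ranked (shrunk
toward their genomic relatives). `prior_scale` defaults to 1.0 — on the
log-worth scale this matches the typical genetic spread of the
generator; there is no published value for it, and sensitivity to it is
mild because it only shrinks, never reorders strongly supported
contrasts.

## Plackett–Luce trees

`grow_tree` recursively splits the records on numeric covariate
thresholds (candidates are the midpoints of consecutive unique values;
`x ≤ t` goes left). A split must (a) leave at least `min_size` (default
20%) of the *total* records in each child, and (b) pass a
likelihood-ratio test: the statistic is 2·gain with df = (number of
items in the node − 1), and the χ² tail probability is
Bonferroni-multiplied by the number of candidate thresholds and the
number of covariates searched before comparison with `alpha` (default
0.01). The LR construction is this package's choice of instability
test — it is exactly computable from the fits the tree already produces
and the Bonferroni factor counteracts threshold-search optimism; it is
*not* the M-fluctuation test used by psychotree-style software, so trees
can differ from that family in borderline cases.

Two numerical details matter at realistic sizes:

* **Smoothed split-search fits.** Candidate children in a tricot design
  (4-entry blocks out of dozens of genotypes) frequently have win graphs
  that are not strongly connected. Split-search fits therefore add a
  small pseudo-count (`smoothing`, default 0.5) of wins/losses against a
  ghost opponent of average worth, keeping every candidate gain defined.
  Gains are data log-likelihoods evaluated at the smoothed estimates, so
  they are slightly conservative.
* **Leaf estimates.** Without a kinship matrix, leaves are pure MLE fits
  and splits whose children would be non-identifiable are rejected. With
  a kinship matrix, leaves are genomic MAP fits over all kinship
  genotypes and such splits are allowed.

`max_candidates` (default 16 in the pipeline) thins candidate thresholds
to a quantile-spaced subset — a determinism-preserving speed knob whose
resolution (range/`max_candidates`) is far below every tolerance used in
the tests. Trees serialize to JSON (splits, thresholds, leaf worths) for
reproducible prediction.

## Covariate selection

`forward_select` performs greedy forward selection with seasons as
cross-validation blocks: each candidate extension is scored by
leave-one-season-out holdout deviance (−2 × held-out log-likelihood of
the tree grown on the training seasons), candidates and the incumbent
are compared via Akaike weights with AIC = mean holdout deviance +
2 × penalty, and a step is accepted only on strict weight improvement.
The penalty is (mean leaf count across block trees) × (n_items − 1); the
complexity term is not published, and this choice makes the criterion
explicitly tree-size-aware on top of the cross-validation. Season
deviances enter unweighted; √n weighting is reserved for the accuracy
metric where it is stated. Ties between candidates resolve by covariate
name order, so the whole trail is deterministic.

## Climate covariates

`compute_indices` derives, per growth phase (vegetative [planting,
flowering), reproductive [flowering, maturity), grain filling [maturity,
harvest), full cycle), 14 indices: min/max/mean night temperature
(statistics of daily tmin, the climatrends convention), min/max/mean day
temperature (daily tmax), mean diurnal range, growing degree days
(Σ max(0, (tmax+tmin)/2 − base), base 0 °C by default, configurable),
rain total, rainy days (≥ 1 mm), longest dry and wet runs, and max 1-day
and 5-day totals — 56 covariates in total. Windows are half-open, so a
day equal to the flowering date belongs to the reproductive phase only.
The published analysis used a larger (unpublished) index list; covariate
*count* parity is explicitly not a goal. Sowing windows are the
midpoints of k equiprobable quantile intervals of observed planting
dates (probabilities (2j−1)/2k, linear interpolation).

## Centralized benchmark

Markers are QC'd (SNPs/samples with > 80% missing or > 50%
heterozygosity dropped, remaining gaps mean-imputed) and converted to a
VanRaden method-1 relationship matrix K = ZZᵀ/2Σp(1−p). Station plot
data are reduced to genotype BLUPs with a deliberately simplified mixed
model — environment (location × season) fixed; genotype,
replicate-within-environment and block random — fitted by profile REML
on Henderson's mixed-model equations (the original study's alpha-lattice
spatial model is not reproducible from its main text). GBLUP
(y = μ + u + e, u ~ N(0, σ²ᵤK)) uses the same REML machinery through the
substitution u = L a with K = LLᵀ, and predicts targets as
û = K₍t,train₎(K₍train₎ + λI)⁻¹(y − μ) at λ = σ²ₑ/σ²ᵤ. Heritability on
the trial-mean basis is H² = σ²g/(σ²g + σ²gl/l + σ²e/(l·r)); the narrow
sense substitutes the genomic variance in the numerator (and its own
denominator), so h² ≤ H² whenever the genomic variance is smaller.
Training on rank-transformed phenotypes is available as a flag.
Accuracy against farm observations is the field-level Kendall τ (tau-a
over the 4 entries), averaged within season and combined across seasons
with √n weights.

## The synthetic scenario

The generator emulates the *structure* of a decentralized durum-wheat
study, not its measured effect sizes (which are free parameters). The
standard scenario, fixed once and used by the test-suite and
`scripts/acceptance.py`:

| parameter | value | why |
|---|---|---|
| station genotypes / SNPs | 100 / 300 | enough for a well-conditioned kinship at desk scale |
| on-farm genotypes | 15 + 1 check | keeps the rankings-per-genotype ratio (~24) close to the full study's (~28) |
| farm fields | 360 (80/160/120 per season) | 4 plots each → 1,440 farm plots |
| stations | 2 × 2 seasons × 2 reps | 400 plots per station field here; the full layout (400 genotypes → 800/3,200) is exercised in the count fixtures |
| worth model | base sd 0.75, shift sd 2.0 (log-worth scale) | strong genotype-by-environment switch: cold and warm orderings are nearly uncorrelated |
| switch | minNT_veg > 11.5 °C (strict) | single night-temperature threshold; boundary fields take base worths |
| sites | stations 16.0 ± 0.1 °C level, warm farms 16.5 ± 0.3, cold farms 10.5 ± 0.8; cold fraction 0.5 (exact count) | computed minNT_veg straddles 11.5 °C and cold farms sit below every station |
| yield link | GY = 2.5 + 0.35·(centred log-worth) + N(0, 0.4), truncated at 0 | scale-stable ranking signal in t/ha |
| station OA | round(3 + 1.2·z + N(0, 0.7)) clipped to 1..5, 15 + 15 raters per location in the first season | integer scores, no half values, gender-tagged |

Rankings are drawn by Gumbel-argmax over entry log-worths, which is
exactly the sequential Luce process. Tricot blocks are allocated by a
balanced greedy rule (each field gets the three least-used test
genotypes, random tie-break), so assignment frequencies stay within the
documented 1.5 max/min ratio. All generators take explicit integer
seeds; a scenario is a pure function of (config, seed).

**What the generator does not emulate:** spatial field structure and
neighbour effects, management variation, rater-specific biases and
gender differences on farms, missing data and attrition, multi-trait
correlations, and real weather autocorrelation beyond a sinusoidal
seasonal cycle plus i.i.d. noise. Passing tests show the estimators
recover the structure they assume; they do not certify performance on
real trial data, where the published analysis found far lower absolute
accuracies (τ ≈ 0.1–0.3).

## Problem sizes in the test-suite

Recovery and headline experiments run at the standard scenario or
smaller (threshold recovery: 1,000 rankings of 10 items, 20 seeds;
forward selection: 180 rankings, 1 signal + 4 independent noise
covariates, 20 seeds; GBLUP ratio recovery: n = 200, 20 seeds; headline
comparison: 20 seeds with and 20 without the worth switch). These sizes
are the package's choice of desk-scale experiment; the full 1,165-field
/ 3,200-plot layout is generated only where the check is a count.

## Known limitations

* The split significance test is an LR surrogate for the unpublished
  original instability test; α-level behaviour is verified by simulation
  under the null, but the tree topology is not guaranteed to match other
  PL-tree software.
* The station model ignores incomplete-block efficiency and spatial
  trends beyond a random block effect.
* The genomic prior enters as a log-worth covariance; other readings of
  "SNP data as a prior" (e.g. pseudo-rankings) would differ and are
  isolated behind `fit_pl_genomic`.
* Ties in rankings are not modelled; measured-yield ties are broken
  lexicographically and flagged so callers can drop or jitter them.
* Extrapolation assumes fixed phase durations from each simulated sowing
  date; per-scenario phenology is not modelled.
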