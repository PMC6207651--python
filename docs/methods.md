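# Methods

## The scientific problem

In fragmented tropical forests, tree diversity erodes near edges. One
candidate mechanism is the weakening of conspecific negative density
dependence (CNDD): specialized insect herbivores and fungal pathogens kill
seeds and seedlings of locally abundant species disproportionately, which
prevents dominant species from monopolizing recruitment and so maintains
diversity (the Janzen–Connell mechanism). This package implements, as a
tested pipeline on synthetic data, the analysis of a field experiment that
crosses distance-to-edge with enemy exclusion: stations in four edge-distance
bands (E0 = 0–5 m, E1 = 20–30 m, E2 = 50–60 m, E3 = 90–100 m), each holding
two 1-m² seed traps and five 1-m² seedling plots assigned to untreated
control, water-sprayed control, fungicide, insecticide, or both pesticides.

Two analyses share the data:

1. **Diversity contrasts.** Hill-number diversity of seedling recruits per
   plot (rarefied richness, inverse Simpson, exponentiated Shannon) is
   modelled with a Gaussian linear mixed model: edge band × treatment fixed
   effects, the station's seed diversity as an additive covariate, and a
   station random intercept. Pairwise cell contrasts use Wald z statistics
   with a configurable familywise correction.
2. **CNDD estimation.** Per species and station, recruits relate to seed
   density by the power law `R = a · S^b`. `b = 1` means recruitment
   proportional to seed arrival (no density dependence); `b < 1` means the
   per-seed transition probability declines with conspecific density
   (CNDD). A hierarchical Bayesian negative-binomial model estimates a mean
   slope per edge × treatment cell.

## The CNDD model

For plot observation *n* (species *s*, station *j*, cell *c*):

```
R_n ~ NegBin(mean = exp(α + a_s + g_j + (β_c + u_s)·z_k),  size = φ)
```

where `z_k` is the latent log seed density of the station × species pair
*k*, `β_c` the cell-level slope, `u_s ~ N(0, τ)` a species slope deviation
shared across cells (a config switch allows cell-specific deviations),
`a_s ~ N(0, σ_sp)` and `g_j ~ N(0, σ_st)` species and station intercepts.

### Measurement error

Seeds are counted in traps adjacent to, not inside, the seedling plots, so
true seed density is observed with error; regressing on the noisy counts
attenuates `b` toward zero and manufactures spurious CNDD. The latent
density therefore carries two Gaussian factors on the log scale:

* **Trap evidence.** The two trap counts give sample mean `m` and sample
  variance `v`; the matched log-normal (mean exactly `m`, variance exactly
  `v' = max(v, 0.25)`) is `σ² = ln(1 + v'/m²)`, `μ = ln m − σ²/2`. When
  both traps are empty but seedlings occurred, the seedling count stands in
  for both moments — a deliberately conservative imputation that biases
  *against* detecting CNDD. Pairs with neither seeds nor seedlings carry no
  information and are dropped.
* **Population layer.** `z_k ~ N(ν_s, ω)` with species means `ν_s` and a
  shared between-station log-density SD `ω`, both estimated. This makes the
  construction a structural errors-in-variables model: noisy observations
  are shrunk toward the species' typical density. The layer is essential —
  a latent variable whose prior is centered on the noisy observation itself
  reproduces the naive slope almost exactly (we verified this by
  simulation), because classical attenuation can only be undone by a model
  of where true densities live.

The `fit_naive_model` variant fixes `z` at `ln(max(m, 0.5))` with no latent
layer; it exists as the comparison arm for quantifying attenuation.

### Priors and sampler

Priors are weakly informative and centered on "no CNDD": `β_c ~ N(1, 1)`,
intercept `α ~ N(−1, 1.5)` (log scale, centered covariate), half-normal(1)
for `τ, σ_sp, σ_st`, half-normal(2) for `ω`, `φ ~ Gamma(2, rate 0.2)`.

The posterior is sampled with a purpose-built adaptive
Metropolis-within-Gibbs scheme. Every block (latent `z`, species and
station intercepts, slope deviations, cell slopes) is conditionally
independent across its elements, so each block is updated with a vectorized
elementwise random-walk Metropolis step; `ν_s` has a conjugate Gibbs
update. Proposal scales adapt per coordinate during warmup toward 0.44
acceptance and are frozen afterwards. Two numerical choices matter:

* the log-density covariate is centered globally for `β` and per species
  for `u_s`, which removes the slope–intercept correlations that otherwise
  cripple random-walk mixing (slopes are invariant to centering);
* negative-binomial likelihood differences for blocks that do not touch `φ`
  reduce to `r·lm − (r+φ)·logaddexp(ln φ, lm)`, so a block update costs one
  `logaddexp` per observation.

Defaults are 4 chains × 2,000 iterations (1,000 warmup). Convergence is
assessed with split R-hat (flagged above 1.01) and bulk ESS via arviz;
non-converged fits are flagged but summaries are still emitted. The
community slope reported per cell is `β_c + mean_s(u_s)`, the identified
combination. There is no divergence diagnostic because the sampler is not
gradient-based; acceptance rates are reported instead.

### Species filters

Following the experimental protocol, CNDD uses species that occur (as seeds
or seedlings) in ≥ 10 stations, vary ≥ 3-fold between the largest and
smallest positive station seed densities, and have ≥ 5 seedlings in total.
"Seed density" for the fold rule is the trap-pair mean per station
(configurable to the station sum); stations with zero seeds are excluded
from the ratio. Water and untreated control plots enter the CNDD model as
separate observations of the same "control" cell, sharing the station's
latent density (configurable).

## Diversity analysis choices

* Indices are computed per seedling plot and per station seed pool (the two
  traps summed, since they sample the same station). Rarefaction uses 2
  individuals for seedlings and 5 for seeds.
* Plots with zero recruits have undefined diversity and are excluded from
  the LMM with a logged count (zero is not a diversity value);
  single-individual assemblages score 1; rarefaction with fewer individuals
  than the subsample size returns missing rather than extrapolating.
* Untreated and water controls are averaged per station into one Control
  value before modelling (the experiment found no difference between them).
* Contrasts: Wald z on cell differences, Tukey-style studentized-range
  adjustment within each family (the treatments of one edge band, or the
  edge bands of one treatment), configurable to `none`. Groupings are
  reported as compact letter displays.
* If the random-intercept fit is singular the model falls back to a
  fixed-intercept OLS with a warning. Several optimizers are tried first
  (lbfgs, bfgs, powell) because the default optimizer alone fails on data
  with modest station variance.

## The synthetic-data generator

The generator reproduces the field design exactly (15 locations × 3
stations in each of E0–E2, 15 E3 stations attached to 5 locations, 2 traps
and 5 plots per station; 150 stations in total, with an override to thin to
the 146 the field campaign realized) and the statistical structure the
analyses assume:

* ranked log-series relative abundances (`p_s ∝ θ^s/s`, θ = 0.95 over 40
  species) — a standard shape for tropical tree communities; a log-normal
  alternative is available;
* total seed rain 200 seeds m⁻² station⁻¹ (within the range reported for
  wet tropical forests over a comparable census), split by relative
  abundance; per-station latent densities log-normal around the species
  mean (mean-preserving) with log-SD 0.8;
* traps count the latent density with independent Poisson noise — the
  minimal counting model, and the source of the attenuation the correction
  targets;
* recruitment per plot is NegBin(`a·λ^b`, φ) with a = 0.25 shared across
  species, φ = 5, and species slope deviations of SD 0.1 around the cell
  slope `b`.

The interior-CNDD scenario (`e3_control_cndd_scenario`) sets `b = 0.9`
everywhere except `b = 0.4` in the E3 control and water cells, magnitudes
consistent with community-level seed-to-seedling slope estimates (roughly
0.4–1). Under it, enemy exclusion raises the dominance of abundant species
only in the interior, which is the signature the diversity pipeline should
detect.

What the generator does **not** emulate: spatial coordinates and dispersal
(stations are exchangeable), seasonality, seed predation before trap
censusing, taxonomic mismatch between seed and seedling morphospecies, and
any real station-level habitat effects (station intercepts in the fitted
models are therefore superfluous on synthetic data, which the tests
tolerate). Passing tests show the estimators are calibrated for data whose
error structure matches these assumptions, not that field data meet them.

## Test problem sizes

The simulation studies in the test suite run at sizes chosen to keep the
default `pytest` run inside a few minutes while retaining statistical
meaning; thresholds are binomial bounds at the nominal rates, computed at
the reduced replicate counts:

* null calibration: 25 datasets × 4 edge × treatment cells (b = 1
  everywhere), 2 chains × 2,000 iterations;
* slope recovery: 20 datasets of 60 stations × 20 species at b = 0.7;
* attenuation: 12 paired corrected/naive fits at b = 1;
* diversity power: 40 replicates of the full 150-station design under the
  interior-CNDD scenario.

Observed behavior at these sizes: corrected-slope bias ≈ 0 (|bias| < 0.1
asserted), naive slopes attenuated by ≈ 0.1–0.15, credible-interval
coverage ≈ 90–95%, and the fungicide-vs-control contrast flagged at E3 and
not nearer the edge in well over 80% of replicates.

## Known limitations

* The Metropolis-within-Gibbs sampler needs longer chains than a
  gradient-based sampler would for the same ESS; R-hat above 1.01 on short
  exploratory runs is common and is flagged rather than hidden.
* The moment-matched trap evidence treats the two-trap sample variance as
  informative; with only two traps it is extremely noisy, which the
  variance floor (0.25, below one-seed resolution) regularizes.
* Dropping station × species pairs with neither seeds nor seedlings
  truncates the lowest-density pairs and can flatten slopes slightly
  (≈ 0.03 at the default community); the effect is second-order relative
  to the measurement-error correction.
* Species whose latent densities fall mostly below one seed per trap mix
  information-poor evidence with the imputation rule; the species filters
  remove the worst cases but the community slope remains a filtered-species
  quantity.
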