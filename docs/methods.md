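# Methods

This package estimates, for each tree species in a mapped forest plot, a
colonization ability and a competitive ability, and tests whether the two
trade off across species.

## Model assumptions

**Seed shadow.** Seed deposition around a mother tree is the product of a
size-specific annual fecundity and a radially symmetric dispersal kernel.
Fecundity is `F = beta * BA(dbh)`, with `BA = pi (dbh/2)^2` the basal area
in cm^2 and `beta` a size-independent parameter (seeds cm^-2 yr^-1). Only
stems at or above the species' reproductive threshold `dbh_r` produce
seeds. The expected count in trap `k` over `T` years is

    lambda_k = T * area_k * sum_i beta * BA(dbh_i) * P(d_ik)

summing over conspecific reproductive stems, and observed counts are
independent Poisson draws. This assumes no masting, no seed predation
before trapping, isotropic dispersal, and that all conspecific sources are
mapped (edge effects from unmapped off-plot sources are ignored).

**Kernel families.** Four two-parameter-or-fewer families, all densities
per unit area at distance `r`:

| family | density P(r) | parameters (units) | radial CDF |
|---|---|---|---|
| negative exponential | `exp(-r/b) / (2 pi b^2)` | scale `b` (m) | `1 - (1 + r/b) exp(-r/b)` |
| two-dimensional t | `p / (pi u) (1 + r^2/u)^-(p+1)` | `u` (m^2), shape `p` | `1 - (1 + r^2/u)^-p` |
| lognormal | `exp(-(ln(r/a))^2 / (2 b^2)) / ((2 pi)^{3/2} b r^2)` | median `a` (m), shape `b` | lognormal CDF in `ln r` |
| Weibull | `(c / (2 pi a^c)) r^{c-2} exp(-(r/a)^c)` | scale `a` (m), shape `c` | `1 - exp(-(r/a)^c)` |

The lognormal density vanishes at the origin and the Weibull density
diverges there for `c < 2`; both are handled exactly because every
integral is taken through the closed-form radial CDF, never the raw
density.

**Estimation.** `beta` enters every trap mean linearly, so for fixed
kernel parameters its maximizing value is `beta_hat = N_total / sum_k c_k`
(`c_k` = unit-beta mean). The numerical search therefore runs only over
the one or two log kernel parameters (Nelder-Mead from a deterministic
multi-start grid spanning the observed trap-to-tree distance quantiles);
the profiled optimum is the joint MLE. Families are compared by
`AIC = 2k - 2 logLik`; exact ties go to fewer parameters, then to a fixed
family order, so selection is deterministic.

**Colonization ability.** `p_G` is the probability that one seed lands in
a 10 x 10 m gap. Seed arrivals are independent, so the expected number of
years until first arrival at `F` seeds per year is `t = 1 / (p_G F)`, and
colonization ability is `1/t = p_G F`. The mother stands at the plot
center and `p_G` is averaged over 1000 uniformly random gap placements
inside the plot. The placement set is *fixed* (one seed, shared by point
estimates, bootstrap replicates and the synthetic ground truth): the
placement distribution of `p_G` is heavily skewed, and comparing values
computed on different placement sets introduces a systematic bias of order
20%. With the shared set, `p_G` is a single deterministic estimand.
Long-distance dispersal (LDD) is the kernel mass beyond 50 m,
`1 - C(50)`.

**Gap integral.** The 2-D integral of the kernel over a rectangle reduces
to one dimension in polar coordinates: each ray from the mother crosses
the rectangle in one interval `[r0(theta), r1(theta)]` (slab method), so
`p_G = (1/2pi) int [C(r1) - C(r0)] d theta`. The integrand is smooth
between the four corner angles; the batch path applies 48-point
Gauss-Legendre quadrature per segment (agrees with adaptive quadrature to
near machine precision), and the single-gap path uses adaptive quadrature
with a seeded Monte Carlo fallback that warns when used.

**Competition.** For focal tree `i`, the neighborhood crowding index is

    NC_i = ln( sum_j BA_j * exp(-0.2 d_ij) )

over neighbors of any species with strictly larger DBH within 15 m. Focals
with no such neighbor have undefined NC and are excluded; fits use only
focals more than 15 m from every plot edge. Survival over the census
interval is a per-species logistic regression on initial DBH and NC.
Competitive ability is the survival odds ratio `SOR = s/(1-s) =
exp(intercept + b_dbh * dbh + b_nc * nc*)` evaluated at `nc*`, the 97.5th
percentile of NC pooled over every stem in the plot. Survival is never
extrapolated beyond a species' maximum observed DBH.

**Uncertainty.** Two resampling schemes mirror the data structure: seed
traps are resampled with replacement and the seed-shadow model refit
(propagating into `beta`, kernel parameters, `1/t`, LDD); occupied
20 x 20 m quadrats are resampled with replacement and the survival model
refit (preserving spatial correlation; `nc*` held at its full-data value).
Intervals are 95% percentile intervals. If more than 20% of replicates
fail, the bootstrap errors out rather than returning a biased interval.

**Trade-off test.** For each of `n_draw` draws, one replicate per species
is sampled independently from each quantity's bootstrap distribution and
the cross-species Pearson (or Spearman) correlation computed; the CI is
the 2.5/97.5 percentile interval of the draw correlations, and the point
estimate correlates the per-species replicate means. A significant
negative correlation between `1/t` and SOR is the trade-off criterion.

## Parameters and defaults

| parameter | default | units / meaning |
|---|---|---|
| plot | 500 x 400 | m (20 ha) |
| trap area | 0.5 | m^2 |
| traps | 149 | transect layout over 5 trails |
| census window | 10 | years of seed rain |
| gap size | 10 x 10 | m |
| gap placements | 1000 | fixed seed 0 |
| LDD threshold | 50 | m |
| crowding radius | 15 | m |
| distance decay | 0.2 | per m |
| edge buffer | 15 | m |
| crowding percentile | 97.5 | % |
| quadrat | 20 x 20 | m |
| inclusion filter | >= 250 seeds in >= 20 traps | API default |
| bootstrap / draws | 1000 / 1000 | replicates |
| reference sizes | 5, 10, 20 | cm DBH |

## What the synthetic data emulate — and what they do not

The generator produces a 13-species community (3 understory, 3 midstory,
7 canopy growth forms) on the 20-ha plot: Thomas-process clustered stem
maps, lognormal DBH truncated at the 1 cm census threshold, transect trap
layout, Poisson seed rain that is the exact generative twin of the fitted
likelihood, and Bernoulli survival from the logistic model (optionally
with a quadrat-level random effect). A target cross-species correlation
between true `1/t` and true SOR can be planted exactly (solved over a
latent Gaussian mixing weight); the natural-scale Pearson correlation of
two lognormal margins is bounded away from -1, so the planting log-SDs
default to 0.35, which keeps targets down to about -0.85 attainable.

Deliberately not emulated: topography and habitat covariates, seed
predation, masting, anisotropic dispersal, off-plot seed sources, and
interannual variation. Stem density defaults to 400 stems per species
(desk-scale runtime) instead of census density (~5500); the CLI flag
`--paper-scale` restores full density. At desk scale the inclusion filter
is applied proportionally (>= 50 seeds in >= 10 traps) in the bundled
analysis scripts.

## Numerical choices

- All randomness descends from one master seed via hierarchical
  `SeedSequence` spawning; every pipeline output is bitwise reproducible.
- Log-parameterized optimization enforces positivity; a large finite
  sentinel (1e12) replaces infinite NLLs so Nelder-Mead never sees NaN.
- Bootstrap refits warm-start at the full-data estimate.
- SOR is computed as `exp(linear predictor)`, avoiding overflow of
  `s/(1-s)` as `s -> 1`.
- Logistic fits use IRLS (statsmodels GLM); separation or non-convergence
  falls back to an L2-penalized fit flagged `penalized=True`.
- PCA standardizes traits (unit variance, `ddof=1`) and uses SVD; the
  dominant loading of each component is made positive for sign stability.

## Limitations

- The paired-bootstrap CI for the cross-species correlation reflects
  *within-species* estimation uncertainty only. Its frequentist behavior
  as a test of the cross-species null depends on the ratio of estimation
  noise to the between-species spread of true abilities: when per-species
  estimates are very precise the interval narrows toward the single
  realized correlation and the test can over-reject; when estimation noise
  is comparable to the spread (as at field-census precision in our
  calibration) the size is near nominal and power against a strong planted
  trade-off is high. At the reduced desk-scale precision, power degrades
  before size does.
- `1/t` inherits the single-mother, plot-center idealization; it is a
  comparative index, not a demographic forecast.
- The crowding index fixes the 0.2 m^-1 decay and 15 m radius rather than
  estimating them.
- Percentile bootstrap intervals can undercover for strongly skewed
  estimators at small replicate counts.
- Kernel selection by AIC among four families does not quantify kernel
  *shape* uncertainty beyond the bootstrap of the selected family.
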