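# Methods

## Scope and model

`reefseed` implements a first-order larval budget for a broadcast-spawning
coral population on a reef shore with two habitats (a shallow back reef and
a fore/outer reef).  "First-order" means the calculation chains measured
mean values through stated assumptions without claiming inferential power:
it can show that self-seeding is *feasible* (production exceeds
requirement), never that it occurred.

The chain per habitat and year:

1. **Density.**  Recruits: mean tile count per site × depth × deployment
   period, the two period means summed into an annual density per tile
   scoring area (225 cm²), then averaged across sites within depth, then
   across depths.  Juveniles (≤ 4 cm) and all colonies: mean quadrat counts
   per 0.25 m², depth means within sites, then site means.  The alternative
   `pooled` weighting (total count / total samplers) is provided because
   site-mean arithmetic and pooled arithmetic differ whenever sites
   contribute unequal effort; `simple` is the default and both agree exactly
   under equal effort.
2. **Abundance.**  `abundance = density / sampler_area × habitat hard-bottom
   area`.  All areas are converted to cm² at ingest (1 km² = 10¹⁰ cm²);
   a single internal unit system prevents km²/m² slips, and a test asserts
   the cm² and m² pathways agree to 1 part in 10⁹.
3. **Reproduction.**  Colonies at or above the maturity threshold
   (inclusive, default ≥ 14 cm diameter — the maturation size of congeneric
   Pacific spawners) are mature; the representative mature colony has the
   mean mature diameter.  Tissue area follows the wax-dipping calibration
   `A = 2.493 · d^2.312` (r² = 0.986).  Annual eggs = abundance ×
   proportion mature × A(d̄) × pooled fecundity; zygotes = eggs × mean
   fertilization success.  An `integrate` option sums tissue area over the
   full measured size list instead of using the mean diameter; because the
   power law is convex this always yields at least as many eggs, and it is
   offered for sensitivity analysis only.
4. **Assessment.**  Required larvae = observed recruits / (1 − loss
   fraction).  The loss fraction is an assumption, not an estimate, so the
   report sweeps a grid (default 0.9, 0.99, 0.999) in addition to the
   headline 0.999 scenario.  Sufficiency > 1 means the shore produced more
   larvae than needed.  Recruit→juvenile survival is reported unclamped;
   values above 1 are flagged implausible.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| tile scoring area | 225 | cm² | lower tile surface, where >90 % of recruits settle |
| quadrat area | 0.25 | m² | 0.5 × 0.5 m frame |
| points per image | 200 | — | random-point cover scoring |
| grid cells | 25 | — | dominance scoring, 4 % cover resolution |
| back-reef hard bottom | 4.58 | km² | satellite-derived |
| outer-reef hard bottom | 3.15 | km² | to 17 m depth |
| maturity threshold | 14 | cm | inclusive (≥) |
| polyp density | 66 | polyps cm⁻² | converts per-polyp fecundities |
| fecundity | 6,327 ± 1,882 | eggs cm⁻² yr⁻¹ | pooled from three studies (7,300 cm⁻²; 63 and 114 polyp⁻¹) |
| fertilization | 0.15 ± 0.21 | fraction | pooled across two spawning-coral studies |
| allometry a, b | 2.493, 2.312 | cm², — | log-log OLS calibration |
| larval loss | 0.999 | fraction | assumption; swept over a grid |
| MC draws | 20,000 | — | per habitat-year chain |

Every one of these is a config default, never a literal buried in an
operation, so users can substitute local values.

## Statistical conventions

* Cover SE uses the sample SD (n − 1) over per-image covers divided by √n;
  a single-image group reports SE 0 and is logged.  A category unscored on
  an image is 0 % cover there, not missing — both scoring schemes are
  exhaustive per image.
* Fecundity pooling converts per-polyp values with the polyp density, then
  takes mean and sample SD (n − 1) over converted values.  One study gives
  an undefined (NaN) SD, flagged rather than zeroed.
* The allometry fit regresses log area on log diameter by OLS
  (statsmodels); the coefficient is the back-transformed intercept and the
  95 % interval on the exponent comes from the fit.  No small-sample
  back-transform bias correction is applied: the calibration is used at the
  mean mature diameter, well inside the fitted range.
* Monte Carlo draws are independent normals for fecundity and fertilization
  at their pooled means/SDs.  **Negative draws are kept by default.**  The
  fertilization distribution (CV = 1.4) puts ~24 % of its mass below zero,
  so truncating at zero would shift the mean upward by tens of percent and
  decouple the Monte Carlo mean from the deterministic product of means.
  Untruncated, E[XY] = E[X]·E[Y] holds exactly and the two routes check one
  another; truncation remains available and is reported when on.  A
  consequence worth stating: individual draws can be negative, and the draw
  SD is large (CV ≈ 1.5) — the chain mean is well constrained, its spread
  is not.
* Skewness and kurtosis use 1/n central moments, with kurtosis on the
  Pearson convention (normal = 3).  Normality uses a one-sample
  Kolmogorov–Smirnov statistic against a normal with the sample's own mean
  and SD (ddof = 1); the p-value comes from the asymptotic Kolmogorov
  distribution and is flagged approximate because the parameters are
  estimated from the same sample (no Lilliefors correction is applied).
* Seeding: a single master generator (`numpy` PCG64) draws one sub-seed per
  habitat-year chain in sorted key order, so results are independent of
  dict iteration and bit-reproducible for a fixed seed.

## The published Moorea inputs

`reefseed.moorea` stores the printed densities, maturity summaries and
study tables and recomputes the budget from them.  Three bookkeeping rules:

* January-2015 back-reef surveys are labelled year 2014, as the source
  pairs them with the April/May 2014 outer-reef census.
* Where a printed shore-wide abundance disagrees with its own printed
  density by more than 2 % (the density having been printed at coarser
  precision, or the arithmetic being internally inconsistent), the printed
  abundance is treated as data and used with a `printed_abundance_used`
  flag.  Four entries are affected (outer-reef 2010 recruits, 2010
  juveniles, 2010 colonies, 2014 colonies); all self-consistent chains are
  recomputed from densities.
* The two 2010 maturity proportions as printed (21 % outer, 50 % back)
  reproduce neither habitat's printed egg/zygote totals, while the swapped
  assignment reproduces both habitats' zygote totals and the outer-reef egg
  total.  `maturity_2010="transposed"` (default) uses the swapped
  proportions; `"as_printed"` is available, and the package takes no
  position beyond the default.  The printed back-reef 2010 egg total is
  inconsistent with its own printed zygote product under either variant and
  is not used as a check anywhere.

The printed Monte Carlo spreads (SD, skewness ≈ 0.6, kurtosis ≈ 3.5–3.8)
imply a coefficient of variation near 0.25, which is unreachable from the
stated input CVs (0.30 for fecundity, 1.4 for fertilization force a chain
CV above 1).  These diagnostics are therefore computed and reported but
never asserted against the printed values; the Monte Carlo *mean* is the
reproducible quantity.

## Synthetic data

The generator (`reefseed.simulate`) draws tile and quadrat counts from
Poisson laws at the true densities (a negative-binomial overdispersion hook
exists, off by default), juvenile counts as binomial thinnings of the
same-quadrat colony count (so nesting holds exactly while both margins stay
Poisson), point/grid scores as multinomials over true cover fractions with
an `other` remainder, colony diameters as lognormals (mature fraction has a
closed-form tail), and allometry pairs as the power law times multiplicative
lognormal noise.  Default efforts mirror field practice: 15 tiles per
site-depth, 40 quadrats, 40 images, and a 50-pair calibration.

What it does **not** emulate: spatial autocorrelation among samplers,
site-level heterogeneity beyond independent replication, temporal
correlation between years, tile-vs-natural-substrate settlement bias,
detection error in photoquadrats, and taxonomic misassignment.  Passing
recovery tests therefore demonstrates correctness of the estimators under
their own sampling assumptions, not robustness of field inference.

## Problem sizes and tolerances

Unit and property tests run at small n (hundreds of samplers, 10³–10⁵
diagnostic draws); the budget and its Monte Carlo run at the full 20,000
draws everywhere, including the acceptance script, since the whole pipeline
completes in seconds.  Recovery assertions use 3-standard-error bands from
the known sampling laws; exact algebraic identities are asserted at
relative 10⁻⁹–10⁻¹²; comparisons against printed values use 0.5–1 %
bands reflecting the 2–3 significant figures of the printed inputs.

## Known limitations

* The representative-colony approximation ignores the size spread above the
  maturity threshold; with a convex allometry it underestimates egg output
  (the `integrate` option bounds the effect).
* Settlement tiles index relative, not absolute, recruitment; scaling tile
  densities to whole habitats inherits that bias in an unknown direction.
* Fecundity and fertilization come from other regions and taxa; they are
  the weakest inputs, which is exactly why they carry the Monte Carlo.
* The budget treats habitats as closed at the shore scale and years as
  independent; no transport, retention or phenology is modelled.
* Brooding congeners are outside the model; the maturity threshold and
  allometry are for spawners.
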