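# Methods notes

## Assignment model

The model treats each grid cell c as a candidate foraging origin for a
female with epidermis values x = (δ¹³C, δ¹⁵N) and scores it with a
bivariate normal likelihood f(x; μ(c), Σ(c)). The mean vector comes
from the two isoscapes; the covariance combines among-turtle tissue
variation (constant across cells) with the squared kriging standard
error (cell-specific). Summing the two variance sources assumes the
processes are independent — there is no reason tissue physiology should
covary with interpolation error. The kriging model estimates no
cross-element covariance, so the off-diagonal carries the tissue-based
covariance alone, reconstructed as c̄ = r̄·√(v̄_C·v̄_N) because the
per-area statistics that get averaged are correlations, not raw
covariances. Averaging across the six broad calibration areas is
unweighted; a sample-size-weighted mean is available via
`pooled_tissue_covariance(..., weighted=True)`.

Surfaces are max-normalized rather than sum-normalized: the value at a
cell is relative evidence against the best cell, and ties at 1 are
expected wherever the isoscapes predict identical values. The prior
over cells is implicitly flat; no latitude-dependent cell-area
weighting is applied before summing, and cohort sums are therefore
evidence indices ("probable number of females using the cell"), not
counts.

Densities are computed in log space and exponentiated after
subtracting the per-surface maximum, so cells hundreds of SDs from the
observation cannot underflow the normalization. Σ(c) is positive
definite by construction while |r̄| < 1 (kriging only inflates the
diagonal); a diagonal ridge of 1e-8 is kept as a guard and warns if it
ever fires.

## Isoscape fitting

The interpolator is ordinary kriging with an exponential (default),
spherical, or Gaussian variogram fit to the binned empirical
semivariogram by weighted least squares with Cressie weights
N(h)/γ(h)². Distances are great-circle separations expressed in
degrees of arc — the study spans ~30° of latitude, so planar degrees
would stretch northern lags. Duplicate calibration coordinates are
averaged before fitting (the kriging system is singular otherwise).
Prediction variance is the standard OK form λᵀγ₀ + μ, clipped at zero;
the unbiasedness constraint (weights summing to 1) is asserted inside
the solver on every cell.

The empirical-Bayesian kriging used in the original ArcGIS workflow is
proprietary; ordinary kriging supplies the same two products the
assignment model consumes (a mean raster and an error raster), so
isoscape-dependent results are expected to match that workflow
approximately, not bit-exactly. Because OK assumes a constant mean, it
smooths across calibration-coverage gaps; measured against the
synthetic truth this leaves ~0.2‰ mean bias near the edges of the
calibration areas, the main driver of the residual hotspot-attribution
bias discussed below. Universal kriging with spatial covariates would
reduce it but is deliberately out of scope.

Variogram parameters from a single ~200-point sample carry large
sampling error (quartiles roughly ±50% on the range in simulation);
the recovery test therefore judges the estimator by its median over 60
independent realizations.

## Rank tests

Friedman uses the tie-corrected statistic
(k−1)·Σⱼ(Rⱼ − b(k+1)/2)²/(A − C), which reduces to the familiar
12/(bk(k+1))·ΣRⱼ² − 3b(k+1) without ties; it is cross-checked against
scipy and against exhaustive within-block permutation on small tables.
The post hoc is Conover's Friedman-type test (t with (b−1)(k−1) df on
within-block rank sums), the canonical companion to a Friedman
omnibus; no installed package provides it, so it is implemented here
and verified against an independently coded textbook evaluation. When
rankings are perfectly consistent across blocks the Conover scale
collapses to zero; tied rank sums then get p = 1 and distinct ones
p = 0 (the limit of the t statistic). BH adjustment (statsmodels) is
applied to the k(k−1)/2 upper-triangle p-values. Letters are assigned
by insert-and-absorb, which here guarantees two treatments share a
letter iff their adjusted p ≥ α; ties are broken by the fixed hotspot
order, so output is deterministic.

## Synthetic study design

The generator emulates the structure of the field study at the scale
the analysis needs, not its oceanography. Choices, made once:

- **Grid** 0.5° cells over 18–46°N, 98–60°W, all-ocean mask by default
  (the pipeline supports masks; the synthetic study does not need one).
  0.5° keeps the full nine-season analysis under ~10 s on one CPU.
- **Truth fields** are linear trends plus a smooth Gaussian-process
  anomaly (amplitude 0.6‰, length 6°), sampled exactly on a coarse
  knot lattice and bicubically interpolated. δ¹³C is mostly
  latitudinal (−0.35‰/°), δ¹⁵N mostly longitudinal (+0.28‰/°): two
  near-orthogonal gradients make dual-isotope assignment informative
  in both axes, as real marine isoscapes are (neritic/oceanic and
  latitudinal contrasts), and place adjacent hotspot centroids ≥ ~2
  tissue-SD apart in isotope space — the "well-separated gradients"
  regime the recovery tests presuppose.
- **Tissue noise** v_C = 0.30, v_N = 0.25 (SD ≈ 0.5–0.55‰), r = 0.2 —
  mid-range for within-area among-turtle variation in marine turtle
  tissues.
- **Design sizes** mirror the sampling design: 227 calibration animals
  across six areas; cohorts of 63, 71, 58, 70, 73, 103, 98, 73, 140
  females for 2007–2015 (749 total) with 56, 47, 33, 52, 50, 55, 83,
  73, 64 recorded nests (513).
- **Mixtures** encode the qualitative story: a stable ~0.30 share for
  the rookery-adjacent E FL hotspot, southern pulses in 2007/2014,
  northern pulses in 2009/2012.
- **Reproduction**: clutch ~ round(Normal(113, 20)) truncated at 1;
  hatched ~ Binomial(clutch, p_h) with p_h from 0.55 (N Hatteras) to
  0.80 (Bahamas); dead/live-in-nest are small binomial counts (0.7% /
  0.3% of hatched), so realized emergence rates sit within ~0.01 of
  p_h.
- All randomness flows from one seed through named SeedSequence
  spawns, so every output is byte-reproducible; latent hotspot labels
  go to a sidecar file the pipeline never reads.

What the generator does **not** emulate: bathymetry/ocean masks,
non-Gaussian or spatially correlated tissue residuals, tissue-type
mixtures (synthetic animals are all epidermis; conversion is exercised
by unit tests), remigration dynamics, and any climate driver of the
mixtures. Passing recovery tests therefore show the pipeline's
statistical machinery is sound under its own assumptions — not that
real-ocean assignments reach the same accuracy.

## Known limitations

- Hotspot attribution from max-normalized surfaces is a soft
  (confusion-prone) measurement: on the default scenario, per-year
  mixture proportions are recovered to ~±0.1 per hotspot (worst case),
  with per-hotspot emergence probabilities within ±0.05 and the
  calibration median posterior ≈ 0.93. The residual attribution bias
  traces to OK smoothing at calibration-coverage edges (above).
- Hotspot membership is cell-center-in-polygon; at 0.5° resolution a
  polygon boundary shift of one cell can move a few percent of an
  index sum.
- The emergence-success surface is defined as the ratio of the
  emergent- to the egg-weighted index — the only construction bounded
  by the contributing nests' rates — since a ratio of sums is a
  probability-weighted mean of per-nest emergence success.
- "Overall" tables are the mean of the nine annual (normalized)
  columns, not a pooled re-computation.
- Tissue-conversion coefficients are analyst inputs; the shipped YAML
  holds synthetic placeholders.
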