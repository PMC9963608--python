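# Methods

## The model

The pipeline estimates a township-level annual PM2.5 field from
sparse station measurements and turns it into a composite health
score.  Its stages and the assumptions they rest on:

**Buffer covariates.**  A covariate's value at a point is its mean
(continuous surfaces) or class proportion (categorical land cover)
over grid cells whose centres fall within a closed disc of radius r.
Membership is decided purely by cell-centre inclusion — no partial-
cell area weighting — which makes every aggregate bit-reproducible
and convergent as the grid is refined.  Cells beyond the grid edge
are ignored (the divisor shrinks), so edge stations see a truncated
disc rather than imputed values.  The default radius ladder doubles
from 250 m to 16 000 m.

**Stepwise LUR.**  Forward entry picks, among all (covariate, radius)
candidates, the one with the largest absolute partial correlation
given the current model, and admits it if its partial-F p-value is
below `p_enter` (default 0.05); backward removal drops terms whose
p-value rises above `p_remove` (default 0.10), largest first.  At
most one radius per covariate may be in the model at a time — the
standard guard against the near-perfect collinearity of neighbouring
radii.  Because that same collinearity lets a greedy first entry lock
in a slightly wrong radius, an exchange phase re-examines each
selected covariate after every entry and swaps its radius for
whichever alternative most reduces the residual sum of squares; under
a numerically perfect fit (SSE ≤ 1e-10·SST) entry stops and redundant
terms are pruned if their removal keeps the fit perfect.  Ties at
entry break lexicographically on (covariate, radius).  The fitted
model is accepted only if R² > 0.90, mirroring standard practice of
rejecting weak LUR fits before inversion.

**Diagnostics.**  Per-term t-tests (flag at p > 0.05), variance-
inflation factors computed by auxiliary regressions (flag at
VIF > 10; a single-predictor model has VIF 1 by definition),
Durbin–Watson on residuals in station order with an acceptance band
of [1.5, 2.5], and Shapiro–Wilk residual normality.  When residuals
are numerically zero the normality test is meaningless and is
reported as missing rather than as a p-value.

**Inversion and zonal means.**  The accepted model is evaluated at
every grid cell, with buffers around each cell centre exactly as
around stations; negative predictions are physically impossible and
are clipped to zero with a logged count.  Township values are means
over cells whose centres fall inside the polygon; a township too
small to contain any cell centre is an error, not a silent zero.

**Composite index.**  With the annual limit 35 µg/m³ as threshold,
the exposure–response degree uses the *relative* margin
(35 − c)/35 on the clean side and the capped relative excess
min(c − 35, 35)/35 on the polluted side, each multiplied by the
standardized population density and by the single criterion-level
exposure weight w_e = 0.4.  This keeps |erd| ≤ w_e, makes erd exactly
zero at the limit from both sides, and keeps the three components of
the composite commensurate.  An alternative reading in which both
exposure indicator weights multiply the product is available as
`erd_weighting="indicator_product"`.  The composite applies no second
criterion multiplier to rv and ra: indicator weights already sum to
their criterion weight, and double-weighting would break the intended
0.4/0.2/0.4 balance.  On the polluted branch vulnerability switches
sign (ahp = erd − rv + ra): vulnerable populations aggravate, and
adaptability mitigates, the damage of above-limit exposure.

**Zoning.**  Seven half-open intervals [0,5), [5,10), [10,15),
[15,18.6), [18.6,21.5), [21.5,35), [35,∞).  The interior B-class
boundaries 18.6 and 21.5 are frozen published constants (originally
derived by natural breaks on the source study's own data) and are
deliberately not recomputed from whatever data the pipeline is run
on; the generic Fisher–Jenks engine is available separately.

**AHP weights.**  Principal-eigenvector method on a positive
reciprocal judgment matrix (order 2–10), CI = (λmax − n)/(n − 1),
CR = CI/RI with Saaty's random-index table {3: 0.58, 4: 0.90,
5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}; CR is defined
as zero for n ≤ 2.  The gate is strict (CR < 0.1).  The eigenvector
method (rather than the geometric-mean shortcut) was chosen as the
classical formulation; tests cross-check it against an independent
power-iteration solver.

**Spatial autocorrelation.**  Queen contiguity: units are adjacent
iff their polygon boundaries share at least one point; a configurable
snap distance (default 0 — exact sharing) accommodates imperfectly
digitised polygons.  Weights are row-standardized, so global
I = z·Wz/z·z and local Iᵢ = zᵢ·lagᵢ·n/Σz², and the mean of local
statistics equals the global one (an identity the tests check to
1e-10).  The global test permutes values over locations and is
two-sided around E[I] = −1/(n−1); the local test uses conditional
permutation (unit i held fixed, neighbours drawn from the rest
without replacement) and is one-sided toward the observed statistic,
following common LISA practice.  Both default to 999 permutations;
pseudo p-values carry the +1 correction and are bounded below by
1/(permutations+1).  Units without neighbours (islands) have an
undefined lag and are excluded from both statistics with a warning.
No multiple-comparison correction is applied to LISA p-values by
default, matching common mapping practice; users can filter the
returned p-values themselves.

**Class intervals.**  Natural breaks is the exact Fisher–Jenks
dynamic program (O(k·n²) with prefix sums) minimising total
within-class sum of squared deviations; ties resolve toward the
earliest feasible split, making the output deterministic.  Tests
verify optimality against exhaustive enumeration for n ≤ 14, k ≤ 4.
Quantile breaks use the inclusive linear-interpolation quantile
convention.

**Descriptive statistics.**  SD is the n−1 sample standard deviation;
skewness is the adjusted (sample-corrected) moment coefficient;
kurtosis is the plain moment ratio m₄/m₂² (so a Gaussian reference is
3, and the two-point ±1 sample gives exactly 1).  The plain
convention was chosen because the summary tables this format mirrors
report kurtosis values straddling 3 rather than 0.

## The synthetic region

The generator emulates the *structure* of the real inputs — a
~417-unit township lattice (default 12×35 = 420 square cells of 4 km)
partitioned into three contiguous city blocks proportioned
191:51:175, 34 stations, five covariate surfaces at 1 km resolution,
and ten per-unit attributes — with a fully known generating process:

- Covariate surfaces are moving-average-smoothed white noise scaled
  to physical ranges (elevation 0–1200 m, rainfall 1000–2000 mm, wind
  1–6 m/s, population a cubed smoothed field up to 4·10⁴ persons/km²);
  land cover is thresholded smoothed noise (forest/built/water/other),
  with built cells tied to high population.  Smoothing, not an
  explicit Gaussian process, supplies the spatial autocorrelation —
  a deliberate dependency-light choice.
- Station PM2.5 is an exact linear function of disc-buffered
  covariates (defaults: elevation −0.0015, population +1e-4, forest
  proportion −2.5, all at radius 1000 m, base 19.35 µg/m³) plus
  i.i.d. Gaussian noise, clipped at zero.  Because stations sit on
  cell centres and the true surface uses the same buffer operator as
  the LUR stage, a noiseless fit on the true terms reproduces both
  coefficients and surface exactly — the oracle the recovery tests
  use.  The default noise SD (0.25 µg/m³) is calibrated so the true
  model explains about 93 % of across-station variance, the fit
  quality the R² > 0.90 acceptance gate presumes.
- Indicator attributes are monotone transforms of latent Gaussians
  mixed with the PM2.5 rank, so their Spearman correlations have, in
  expectation, the field-typical signs (all positive except forest
  share) and rough magnitudes; a scale knob can force independence.
  Subgroup densities are shares of the total, so female + under-14 +
  over-65 can never exceed it, and a small fraction of units is
  uninhabited.  Forest share per unit is derived from the land-cover
  surface, so its negative association emerges mechanistically from
  the negative forest coefficient in the concentration model.

What the generator does **not** emulate: real administrative polygon
shapes (units are squares; irregular-polygon handling is exercised by
hand-built fixtures), coastline/topography coupling, measurement
error structure of real monitors, population rasters downscaled by
age and sex, or any real spatial units.  Passing tests therefore
demonstrate that the *procedures* are implemented correctly and
recover known ground truth under realistic signal-to-noise, not that
any particular real-world estimate is reproduced.

## Problem sizes and runtime

Tests run the default 420-unit region for end-to-end checks and a
6×12-unit region (24–30 stations) for replicated studies: 12 seeds
for exact noiseless recovery, 100 seeds for the noisy gate-pass rate,
400 replicates (199 permutations each) for the permutation test's
type-I error on a 10×10 lattice, and 500 replicates for the
Durbin–Watson null band.  These sizes keep the whole suite under
about a minute while leaving Monte-Carlo error well inside the
asserted tolerances.  The acceptance script runs the full default
pipeline once (999 permutations) plus a 20-seed gate-rate study.

## Known limitations

- Stepwise selection with exchange is a heuristic; it is exact in the
  noiseless limit (verified) but under heavy noise can settle on a
  neighbouring radius or an extra weak term, which is why acceptance
  is framed as a gate-pass *rate* rather than exact support recovery.
- The buffer operator ignores partial cell coverage; with very small
  radii relative to the cell size the disc degenerates to the single
  containing cell.
- Kinmen-style detached units become islands under queen contiguity
  and drop out of Moran statistics (with a warning) rather than being
  bridged.
- The erd formula's published form is ambiguous about where the
  weight enters; both defensible readings are implemented, and the
  criterion-level reading is the default (see above).  Results using
  the other switch are not directly comparable in scale.
- Only annual-mean exposure is scored; instantaneous or
  time-integrated exposure taxonomies are out of scope.
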