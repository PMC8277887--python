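# Methods

## The frustum-stack cell model

A flattened cell is reconstructed from two orthogonal projections. The
frontal view — the widest face — supplies the outline area `A_f` (µm²),
perimeter `P_f` (µm) and the bounding extents `L >= W` (µm). The apical
view supplies the thickness `T` (µm) and the profile of slice widths
`W_0..W_n` at `n + 1` equally spaced stations spanning the full thickness.

Every cross-section parallel to the frontal plane is assumed to be a
scaled copy of the frontal outline. At station `j` the scale factor is
`f_j = W_j / W`, so the section has area `A_j = A_f f_j²` and perimeter
`P_j = P_f f_j`. Consecutive sections bound a frustum of thickness
`t = T / n` with

- volume `V_i = t/3 (A_i + A_{i+1} + sqrt(A_i A_{i+1}))`,
- slant height `s_i = sqrt(t² + ((W_i − W_{i+1})/2)²)`,
- lateral area `S_i = s_i (P_i + P_{i+1}) / 2`.

The cell volume is the frustum sum; the surface adds the flat areas of the
two outermost sections (zero when the profile tapers to points, twice the
smallest slice area for symmetric truncated profiles). The width profile is
sampled over the full thickness, symmetric about the frontal plane, which
is assumed to coincide with the widest section.

**Accuracy.** The quadratic-in-`f` section areas make the volume exact in
the limit for any solid whose sections are similar copies of the frontal
outline; sphere volume error falls monotonically with `n` and is ~1.5e-6 at
`n = 2000`. The lateral term is a conical-band approximation whose slant
uses only the width-direction offset. It converges to the true surface for
solids of revolution about the thickness axis (spheres, oblate spheroids,
lobed discs — the geometry of the flattened, lobed cells this model was
built for). For strongly elongated frontal outlines it is biased: for a
(2, 1, 0.5) triaxial ellipsoid the converged stack surface is 13.37 versus
15.87 by surface quadrature, about 16 % low. Users with elongated cells
should treat `S` as a width-convention surface, not a differential-geometry
one. The default `n = 1000` slabs puts discretization error far below
measurement error (sphere error at `n = 1000` is < 1e-5).

## Shape indices

With `V` and `S` reconstructed and the three axes `L, W, T` measured:

- circularity `alpha = 4 pi A_f / P_f²` (1 for a circle, falls with
  elongation and lobulation). Values > 1 are geometrically impossible and
  are returned unclamped with a warning, since they indicate inconsistent
  area/perimeter measurements.
- the equal-volume, same-proportion ellipsoid: shrink factor
  `k = (3V / (4 pi L W T))^(1/3)`, semi-axes `(kL, kW, kT)`, surface by the
  Knud Thomsen approximation
  `S_ell = 4 pi ((a^p b^p + a^p c^p + b^p c^p)/3)^(1/p)`, `p = 1.6075`
  (exact for spheres, within 1.1 % of spheroid closed forms for axis
  ratios up to 5; `p` is exposed as a module constant).
- degree of fractalization `beta = S / S_ell` — surface gained by
  lobulation at fixed proportions;
- degree of flattening `gamma = S_ell / S_sphere` with
  `S_sphere = (36 pi)^(1/3) V^(2/3)` — surface gained by departing from a
  sphere while staying smooth;
- overall surface gain `delta = beta * gamma = S / S_sphere`. The product
  identity is exact by construction; tests assert it to machine precision.

## Mask measurements

Masks are binarized rasters; foreground pixel centers define the region
(half-pixel convention), so a solid `w x h` rectangle measures exactly
`w x h` pixels. Area is a pixel count. The perimeter is the polygon length
of the 0.5-level contour of the indicator field smoothed with a sigma = 1 px
Gaussian: the raw marching-squares contour of binary data overestimates a
disc's perimeter by ~5 %, the smoothed sub-pixel contour is within 0.5 %.
This differs slightly from Fiji's perimeter dialect; the difference is a
systematic sub-percent offset, irrelevant for log-log scaling but worth
remembering when comparing absolute circularities. `L`, `W`, `T` are
extents along the region's principal axes (the minor axis is taken as the
perpendicular of the major one, so isotropic regions are handled), making
measurements equivariant under rotation and reflection. The width profile
counts pixels in unit-thickness bands perpendicular to the thickness axis —
exact for aligned prisms, within a pixel of analytic chords for discs —
and interpolates at the requested stations.

Only one apical outline per species is typically photographed; the
pipeline therefore rescales the apical profile by its own maximum and
multiplies by the frontal width, and species values average the per-cell
`V` and `S` (means of reconstructions, not reconstructions of means).

## Growth rates

For each replicate, a cubic smoothing spline is fitted to
`ln(abundance)` versus time (days); `mumax` (1/day) is the maximum of the
spline's first derivative on a dense uniform grid (default 400 points)
over the observed range, and the species rate is the arithmetic mean over
replicates. The smoothing penalty is chosen by generalized
cross-validation (scipy's `make_smoothing_spline`) unless supplied. Zero
counts are rejected rather than offset — with a 100 cells/mL inoculum a
zero is a counting artifact, and a pseudo-count would bias early slopes.

**Known bias.** The maximum of a noisily estimated derivative is biased
upward. Under the package's reference conditions (logistic growth,
mu = 0.25/day, 9 samples over 35 days, lognormal counting noise
sigma = 0.1) the four-replicate mean overestimates mu by ~12 % on average
(simulation over 500 experiments; an R `smooth.spline` cross-check gives
the same figure, so this is inherent to the spline-GCV estimator, not to
this implementation). `t_at_max` is reported so users can flag maxima at
the schedule boundary. Time-axis rescaling maps exactly onto the fit only
when the penalty is rescaled as `lam / c³`; GCV re-selection reproduces it
to a couple of percent.

Serial medium replacement (e.g. 10 % every 4 days) multiplies the observed
concentration by `1 − fraction` per event. `dilution_correct` rescales each
observation by `1/(1 − fraction)^k`, `k` = events strictly before the
observation (an event on the sampling day happens after the sample). The
pipeline default applies **no** correction; note that an uncorrected 10 %/4
d protocol depresses the log-slope by 0.026/day, which matters for slow
growers.

## SMA allometry

Scaling relations `Y = Y0 M^b` are fitted on log10-log10 axes by
standardized major axis regression: `b = sign(r) sd(y)/sd(x)` through the
centroid. The 95 % CI uses `B = F(0.95; 1, n−2)(1 − r²)/(n − 2)` and
bounds `b (sqrt(B+1) ± sqrt(B))`. Two distinct tests are exposed: the
correlation against zero (the p-value reported alongside each fit) and the
one-sample slope test against a reference `b0` (correlation between
`y − b0 x` and `y + b0 x`, t on `n − 2` df) used for comparing slopes with
−1/4 (quarter-power growth scaling) or 2/3 (Euclidean surface scaling).
Residual-trait correlations are reported unadjusted for multiple testing —
mirroring common practice in the scaling literature, and a documented
caveat. SMA residuals, unlike OLS residuals, are not orthogonal to the
predictor; interpret residual correlations accordingly.

The implementation is validated against a brute-force oracle that
minimises the SMA loss (the summed triangle areas between points and line,
`sum(res²)/(2|b|)` at the optimal intercept) on a dense slope grid, plus
the exact symmetry `slope(y~x) = 1/slope(x~y)`.

## Synthetic data

The generator families and their defaults encode the study conditions the
pipeline is meant to analyse:

- **Shapes.** Spheres and ellipsoids carry closed-form (or, for triaxial
  surfaces, converged-quadrature) oracles. The lobed flattened cell —
  outline `rho(theta) = r0(1 + eps cos m theta)`, elliptic thickness
  profile with thickness-to-width ratio `flat` — is the stand-in for
  deeply lobed desmid morphology: `A_f = pi r0²(1 + eps²/2)` and
  `V = (2/3) A_f T` are closed forms, the perimeter is a line integral and
  the surface a two-resolution-converged quadrature (relative change
  < 1e-4). Lobe count must be even so both principal extents equal
  `2 r0 (1 + eps)`. Single-frequency lobes do not imitate real semicell
  hierarchies; they reproduce the *scaling-relevant* features (perimeter
  gain, surface gain, flattening) with known truth.
- **Growth.** Logistic trajectories (`K = 1e5` cells/mL, `N0 = 100`
  cells/mL, 0–35 days sampled every 4 days, four replicates) with optional
  per-event 10 % dilution and multiplicative lognormal counting noise
  (sigma = 0.1 by default), matching a 12-well hemocytometer protocol.
- **Traits.** Log10 trait pairs with x uniform over a two-decade span and
  independent normal errors on both axes with `sd_y/sd_x = |b|`. This
  error structure — not perpendicular scatter — is the one under which the
  SMA estimator is consistent (perpendicular scatter makes the *major
  axis* consistent instead and would bias SMA by ~+0.09 at `b = −0.25`,
  r² ≈ 0.47). It also makes the slope test exactly t-distributed under the
  null, so calibration checks are sharp. `scatter_sd = 0.11` reproduces the
  r² ≈ 0.4 regime typical of growth-mass scaling across ~24 species.

What passing tests show: the chain recovers known geometry, rates and
exponents under these idealized conditions. What they do not show:
robustness to segmentation error, non-similar cross-sections,
non-logistic growth, or non-lognormal counting error in real cultures.

## Numerical choices

- Width-profile scale factors may exceed 1 by up to 1 % (views come from
  different cells) and are clipped to 1; larger excesses raise.
- Boundary widths at the outermost stations use clamped interpolation of
  the band profile, so truncated profiles keep their cap area.
- The species-level SMA table uses the six canonical pairs
  (µmax~mass, µmax~volume, µmax~surface, mass~volume, surface~volume,
  surface~mass); the residual table correlates µmax~mass residuals with
  alpha, beta, gamma, delta, density and surface.
- All stochastic components take explicit seeds; pipeline runs are
  byte-reproducible (tested).
- Problem sizes used in the validation suite — 2000 slabs for convergence
  checks, 20-sphere scaling series, 500-seed recovery and 1000-seed
  calibration studies — were chosen so Monte-Carlo error is well below the
  asserted tolerances while the whole suite stays interactive (~1 min).

## Limitations

- The lateral-surface bias for elongated frontal outlines (above).
- The µmax estimator's noise-dependent upward bias (above); comparisons
  *between* species measured under the same protocol are unaffected to
  first order.
- Thickness imputation from a single apical outline assumes one
  width:thickness ratio per species.
- No phylogenetic correction: species are treated as independent points.
  For clades where scaling residuals carry phylogenetic signal the SMA
  slopes are unchanged but the CIs are optimistic.
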