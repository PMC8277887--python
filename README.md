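# cellscale

Cell morphometry and allometric scaling for unicellular algae.

Large flattened, deeply lobed cells — desmids such as *Micrasterias* are
the motivating case — sit at the boundary between unicellular and
multicellular body plans, and their population growth rate µmax is
expected to scale with body size as a power law `Y = Y0 M^b`. Testing
whether `b` follows quarter-power ("Kleiber") scaling, and whether cell
fractality and flattening inflate the surface-to-volume exponent above the
Euclidean 2/3, requires three things this package provides as one tested
chain:

1. **3-D morphometry from two projections.** The cell is modelled as a
   stack of frustum slabs: the frontal view gives the widest outline
   (area `A_f`, perimeter `P_f`), the apical view gives the thickness `T`
   and a width profile; each cross-section is a scaled copy of the frontal
   outline, so volume and surface follow from the frustum sums
   `V_i = t/3 (A_i + A_{i+1} + sqrt(A_i A_{i+1}))`,
   `S_i = s_i (P_i + P_{i+1})/2`. Shape is summarised by circularity
   `alpha = 4 pi A_f / P_f²`, degree of fractalization `beta = S/S_ell`,
   degree of flattening `gamma = S_ell/S_sphere` and overall surface gain
   `delta = beta gamma = S/S_sphere`, where `S_ell` is the Knud Thomsen
   surface of the equal-volume, same-proportion ellipsoid.
2. **Growth rates.** µmax per replicate as the maximum first derivative
   of a GCV-smoothed cubic spline of `ln N(t)`, averaged across replicates.
3. **Allometry.** Standardized major axis (SMA) regression on
   log10-log10 axes — slope `sign(r) sd(y)/sd(x)` with the standard 95 %
   CI and one-sample slope tests against reference exponents such as −1/4
   and 2/3 — plus residual-trait correlations.

Because the original culture measurements are not published as data, a
first-class synthetic module generates every input with known ground
truth: spheres/ellipsoids/lobed flattened cells with analytic or
quadrature oracles, logistic count series with lognormal counting noise,
and trait tables with a known SMA slope.

## Worked example

```python
import numpy as np
from cellscale import (make_lobed_cell, stack_cell, cell_shape_indices,
                       simulate_allometric_traits, sma_fit, sma_slope_test)

# a lobed, flattened cell: outline r(theta) = 50 (1 + 0.3 cos 8 theta) µm,
# thickness 40% of width
cell = make_lobed_cell(r0=50.0, m=8, eps=0.3, flat=0.4, n=1000)
geom = stack_cell(cell.views)
idx = cell_shape_indices(cell.views, geom)
print(f"V = {geom.V:.0f} um^3   (oracle {cell.oracle_V:.0f})")
print(f"S = {geom.S:.0f} um^2")
print(f"alpha = {idx.alpha:.3f}  beta = {idx.beta:.3f}  "
      f"gamma = {idx.gamma:.3f}  delta = {idx.delta:.3f}")

# a 24-species trait table simulated at the quarter-power slope
traits = simulate_allometric_traits(24, -0.25, 0.0, (-1.0, 1.0), 0.11, seed=1)
fit = sma_fit(traits["x"], traits["y"])
print(f"SMA slope = {fit.slope:.3f}  CI [{fit.ci_lo:.3f}, {fit.ci_hi:.3f}]  "
      f"r2 = {fit.r2:.2f}")
print(f"p(slope = -1/4) = {sma_slope_test(fit, -0.25):.2f}")
```

prints

```
V = 284522 um^3   (oracle 284524)
S = 49311 um^2
alpha = 0.291  beta = 2.004  gamma = 1.176  delta = 2.357
SMA slope = -0.259  CI [-0.357, -0.187]  r2 = 0.45
p(slope = -1/4) = 0.83
```

The reconstructed volume matches the generator's closed form to 5 digits;
the deep lobes double the surface over the smooth ellipsoid
(`beta ≈ 2.0`) while flattening adds another ~18 % (`gamma ≈ 1.18`), and
the outline's circularity is far below a circle's 1. The SMA fit recovers
the simulated −0.25 exponent within its CI, and the slope test rightly
fails to reject it (p = 0.83).

The same stages are scriptable from the shell — `cellscale measure`
(masks → geometry), `cellscale growth` (counts CSV → µmax),
`cellscale scale` (trait CSV → SMA table), `cellscale simulate`
(synthetic inputs), `cellscale run` (full pipeline from a YAML config).

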