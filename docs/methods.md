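# Methods

## Model and assumptions

The package targets shallow (≲1 m), clear (low-turbidity) streams with a
vegetated bed photographed or measured at nadir.  Under those conditions
the at-sensor radiance is dominated by bottom-reflected light, and the
water column acts as a wavelength-selective exponential attenuator:

```
L(λ, d) = g(λ) · [ R_b(λ) · e^(−K(λ)·d) + R_c(λ) · (1 − e^(−K(λ)·d)) ]
```

with submergence depth `d` (cm), bottom (canopy) reflectance `R_b`,
water-column volume reflectance `R_c`, effective attenuation `K` (per cm,
two-way path and scattering losses lumped in), and a per-band gain `g`
that collapses downwelling irradiance, interface transmission,
atmospheric transmittance and camera exposure.  With `R_c = 0` (the
shallow-clear-water assumption; no numeric value for `R_c` is available
for these streams, so 0 is the default) the log of any band ratio is
**exactly** linear in depth:

```
ln L₁ − ln L₂ = ln(R_b1/R_b2) + ln(g₁/g₂) + (K₂ − K₁)·d
```

This identity is the analytic oracle for the whole chain: OBRA slopes
must equal attenuation differences, single-band fits must recover
`(ln g·R̄_b, −K̄)`, and fit→invert must round-trip depths exactly on
noiseless scenes.

Depth-model regression runs in the direction `predictor = a + b·d` and is
inverted algebraically (`d = (p − a)/b`), matching the published form of
such models; regressing `d` on the predictor would give different
coefficients under noise and is deliberately not used.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| attenuation preset `water_like` | ~0.002 /cm (green) → ~0.09 /cm (1000 nm) | clear-water absorption magnitudes per cm; steep rise past 700 nm, local dip near 790 nm where water absorption briefly slackens |
| bottom preset `vegetation` | green peak 550 nm, chlorophyll minimum ~672 nm, red-edge plateau ≈0.45 | canopy archetype; guarantees `r_b(850) > r_b(675)` |
| `noise_sd` | 0.1 | sd of multiplicative log-normal DN noise (per pixel / wavelength); log-normal preserves the log-linearity of the model in expectation |
| `gain` | `"auto"` (70% of full scale at depth 0) | emulates per-filter-shot exposure of a camera; `gain_scale` applies a common illumination change |
| `depth_range_cm` | (5, 60) | sampled submergence range of a shallow vegetated channel |
| `pixel_size_m` | 0.0024 | nominal ground resolution of pole-mounted imagery |
| polygon diameter | 0.185 m | circular depth-sample footprint (~4700 pixels at 2.4 mm) |
| statistic | `max` | canopy DN statistic: gaps and shading make means under-represent top-of-canopy reflectance; the per-polygon maximum tracks it |
| hold-out fraction | 0.15 | validation split |
| mean-filter window | 5 (4 supported) | sources disagree between 4×4 and 5×5; default 5 centers cleanly, even windows anchor top-left (the output pixel is the window's top-left corner); the discrepancy is recorded, not resolved |
| hillshade | azimuth 315°, altitude 45° | conventional cartographic defaults (Horn gradients) |

## What the generator emulates — and what it does not

Scenes have a parabolic cross-channel depth profile (optionally any
injected raster), full or patchy canopy cover over a darker substrate,
per-band top-hat integration of the forward model between the filters'
50% transmission cuts (only those cuts are tabulated for the filters, so
band-effective `K̄` and `R̄_b` are in-band means), 8-bit quantization,
saturated salt-noise glint (glint is treated as "highest DN to exclude",
not modelled physically), and an additive radial flare
(sinusoid + linear vignetting trend) on selected NIR bands.  Sample
polygons are placed stratified over the depth range, away from the
extreme banks, mirroring a field campaign that marks vegetation at
regular depth intervals towards mid-channel.

Not emulated: volume scattering and BRDF, wave-surface optics, water-surface
reflections of bank vegetation, shading from banks, plant motion between
filter shots (available only as an explicit band-shift experiment in the
tests), and any particular real stream's spectra.  A green test therefore
establishes internal consistency of the estimators with the stated
optical model — not field accuracy under adjacency, shading or
misregistration effects, which field studies report as the dominant
residual errors.

## Numerical choices

- **OBRA**: vectorised moment-based OLS over all pairs when all values
  are positive; pairwise-complete exclusion (never offsets) otherwise;
  cells with <3 valid samples or zero variance are NaN-flagged, not zero.
  Significance is a two-sided t-test on the slope.  `best_ratio` breaks
  exact R² ties by larger |slope|, then smaller wavelengths, and orients
  the pair so the slope is nonnegative.
- **Flare mask**: 90 concentric circles from the flare center to the
  farthest corner, nearest-radius binning, per-circle minimum, 5-point
  centered moving average with shrinking edge windows, linear
  interpolation in radius (flat beyond the outermost circle), normalised
  to min 0 so only radial *structure* is subtracted (absolute subtraction
  demonstrably degrades depth relationships); empty circles are merged
  with neighbours.  Negative corrected DN are clipped at 0.
- **Warping**: polynomial transforms are fitted by least squares in both
  directions; nearest-neighbour lookup under the inverse mapping never
  interpolates DN.
- **Mean filter**: symmetric (edge-inclusive) reflection padding, which
  conserves the global mean exactly for odd windows; nodata pixels are
  ignored in the window average and the valid footprint never grows.
- **Degenerate inputs**: zero depth variance, nonpositive predictors,
  all-glint polygons, rank-deficient tie-point sets and non-invertible
  (b = 0) models all raise informative errors rather than propagating
  NaNs silently.
- The sub-400 nm spectroradiometer edge is excluded from the default
  survey grid (400–1000 nm): that UV edge is noisy in practice and would
  otherwise be selected as the low-attenuation band by construction.

## Known limitations

- The polygon-maximum statistic couples to extreme-value noise: its
  expectation is offset by roughly `σ·√(2 ln N)` (≈0.37 in ln-DN for
  σ = 0.1, N ≈ 1000 pixels), which is absorbed into the model intercept.
  Hold-out validation (same statistic) is unaffected, but per-pixel DEMs
  inherit the offset as a near-constant depth bias of order
  `σ·√(2 ln N)/|b|` — the dominant term in the ~10%-of-range DEM error
  the acceptance pipeline reports.
- Within a polygon the depth varies with the local bed slope; the maximum
  DN tracks the shallowest edge rather than the center depth, inflating
  fitted |slope| by a few percent on steep banks.
- Single-band models shift by `Δln(gain)/|b|` under illumination changes;
  only ratio models are gain-invariant.  Both behaviours are asserted in
  the tests.
- The flare mask estimates structure from scene minima and will absorb
  any genuinely radial scene signal (e.g. a radially symmetric depth
  pattern); it is safe only where the darkest element on each circle is
  depth-stationary.
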