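# Methods and design notes

## The problem

Prairie restoration experiments manipulate seeding diversity and
management (prescribed burning vs annual haying) in blocked designs, and
ask whether those choices propagate to productivity, canopy water, albedo
and surface temperature — the terms of the surface energy balance.
Airborne VNIR imaging spectroscopy and broadband thermal imaging sample
whole plots at the meter scale; quadrat surveys supply species-level
diversity at known coordinates. This package implements the full chain
from at-sensor imagery and cover tables to the diversity–energy-balance
regressions, together with a synthetic scene generator against which every
stage can be validated by parameter recovery.

## Single-channel LST retrieval

With one broad 7.5–14 μm channel, the at-sensor radiance of a surface at
temperature `T_s` and emissivity `ε` is

    L_sensor = τ (ε B(T_s) + (1 − ε) L↓) + L↑

where `B(T)` is the response-weighted band integral of the spectral
Planck function and (τ, L↓, L↑) are band-effective atmospheric
transmittance, downwelling and upwelling radiances. A single channel can
identify only band-effective quantities, so all radiances here are
band-mean spectral radiances (W m⁻² sr⁻¹ μm⁻¹) against a normalized
response; the default response is a flat boxcar over 7.5–14 μm sampled at
0.01 μm (the instrument class specifies the interval, not a shape; any
response can be supplied).

**Tarp emissivity.** For each calibration tarp, a contact thermocouple
gives the true temperature and a handheld infrared thermometer the
radiometric one; by the Stefan–Boltzmann law ε = (T_IRT/T_TC)⁴. Values
above 1 (measurement noise) are clipped with a warning.

**Atmospheric solve.** Substituting u = τ, v = τL↓, w = L↑ makes the
radiative-transfer equation linear per tarp:
`L_i = ε_i B(T_i) u + (1 − ε_i) v + w`. Three tarps of contrasting
emissivity and temperature give a 3×3 linear system solved exactly;
condition numbers above 1e10 raise a degeneracy error naming the most
similar tarp pair, and solutions violating 0 < τ ≤ 1, L↓ ≥ 0, L↑ ≥ 0 are
rejected as unphysical. The tarp ground temperature entering the solve is
the thermocouple reading (the radiometric reading enters only through the
emissivity ratio).

**Emissivity separation.** Per-pixel emissivity follows the NDVI-threshold
model: ε = ε_s below NDVI_s, ε = ε_v above NDVI_v, and linear interpolation
via the vegetation fraction P_v = (NDVI − NDVI_s)/(NDVI_v − NDVI_s)
between. Defaults ε_s = 0.95 (dry sandy soil), ε_v = 0.985 (dense
vegetation), NDVI_s = 0.2, NDVI_v = 0.5; the thresholds are conventional
for this method family and configurable. The formula is a single clipped
expression, so it is continuous at both thresholds by construction.

**Grid transfer.** The 1-m NDVI map moves to the thermal grid by
nearest-center lookup (each thermal pixel takes the closest VNIR pixel's
NDVI; exact ties resolve to the lower row-major index). Truth fields in
the simulator move to the thermal grid by area-weighted box averaging in
radiance space: radiance mixes linearly over area, temperature does not,
so the simulator averages ε·B(T) and re-inverts rather than averaging T.

**Planck inversion.** `B(T)` is strictly increasing, so inversion is a
bracketed root find on [250, 370] K (scalar path: Brent, tolerance 1e-4 K;
exact quadrature). Array paths use a cubic spline of `B(T)` tabulated at
0.02 K — indistinguishable from quadrature at ~1e-12 relative (validated
against a brute-force fine-grid trapezoid oracle in the tests) — with
Newton refinement from a table-lookup start. Radiances outside the
attainable band are flagged missing and counted.

**Noise.** The thermal camera's stated accuracy (±1.5 K) is expressed as a
radiance sigma via dB/dT at a 300 K reference. Retrieval noise amplifies
by 1/(τ·ε) ≈ 1.12 at the default atmosphere, so a 1.5 K-equivalent sensor
noise propagates to ≈1.6–1.7 K RMSE on retrieved temperature with
negligible bias (the inversion's curvature contributes < 0.02 K); the
Monte-Carlo acceptance test verifies both.

## VNIR calibration and indices

The full radiative transfer of the VNIR path is out of scope; calibration
is an empirical line per band — the least-squares line through the three
tarps' (ground reflectance, at-sensor radiance) points, requiring positive
gain and at least two spectrally distinct tarps. On the simulator's linear
forward model the fit is exact; on real data the per-band residual is kept
as a diagnostic. Calibrated reflectance is clamped to [0, 1.5] with a
logged count (bright targets legitimately exceed 1 under noise; hard
failure would be wrong).

Bands are selected by nearest center with ties toward the shorter
wavelength — at 2.3 nm sampling, interpolation would change indices far
below their noise level. NDVI uses 680/800 nm, WBI 900/970 nm, and albedo
is the unweighted mean over band centers in [450, 900] nm (whether a
bandwidth-weighted mean was intended is ambiguous; unweighted is the
simpler reading and is flagged in configuration). Every index map records
the band centers actually used.

## Survey metrics

Rows within 5 m of the plot boundary are dropped before analysis (edge
effects from mowing and vehicle traffic); the buffer is configurable and
zero disables the filter. Richness counts species with cover > 0 — no
trace-cover floor. Shannon indices use natural log (the vegan convention;
no base is standard in the field reports) over relative covers among
vegetation rows; litter and bare-soil rows are ground cover, never
community members. Functional Shannon aggregates covers to C3 / C4 / forb
before applying the same formula, so it is bounded above by the species
index.

Plot-level communities are mean covers across retained locations,
normalized to relative cover (rows sum to 1). The rare-species filter
removes species whose **maximum** relative cover across plots is below 5%;
an across-plot **mean** rule is available behind a switch, since published
descriptions of the "< 5% coverage from all plots" convention admit both
readings. Bray–Curtis distances use the standard abundance form via
scipy; pairs of all-zero rows are undefined and flagged missing. Box-plot
summaries use linearly interpolated quartiles and 1.5·IQR whiskers.

## Linkage statistics

The regression unit is the sampling location, matching the point clouds of
the field study design (plot-level aggregation is a trivial groupby away);
fits are unweighted OLS. Each response is fitted overall, by management,
and by seeding. ANCOVA is two-stage: an F-test of all interaction terms
in `y ~ x * group` tests slope heterogeneity; the additive refit
`y ~ x + group` against `y ~ x` tests intercept differences. Both
p-values are always reported. Significance codes: ns (P ≥ 0.05),
\* (0.01 ≤ P < 0.05), ** (0.001 ≤ P < 0.01), *** (P < 0.001); the single
star is included for completeness even though some published tables omit
that stratum.

## The synthetic scene

The generator encodes the mechanism the analysis is meant to detect, with
one latent "restoration success" field L(x, y) ∈ [0, 1] driving
everything:

* **Treatment means** — control 0.25, mid 0.55, high 0.65, +0.12 under
  burning — plus block (sd 0.05) and plot (sd 0.05) random effects and
  spatially correlated noise (Gaussian-smoothed white noise, sd 0.12,
  8 m correlation length; the field data imply spatial structure but do
  not constrain it).
* **Cover**: green = 0.15 + 0.70·L; litter takes 55% (hayed) or 16%
  (burned) of the remainder; bare soil the rest. Fractions sum to 1 by
  construction.
* **Water content** w = 0.10 + 0.80·L; **temperature**
  T = 318 − 12·green − 6·w + correlated noise (sd 0.4 K) — evaporative
  cooling and thermal mass make vegetated, wet pixels cooler.
* **Reflectance**: cover-weighted mixture of parametric endmembers —
  logistic red edge (inflection 715 nm) with a 550 nm green peak and a
  970 nm Gaussian water absorption scaled by w for green vegetation;
  gently sloped featureless spectra for litter and soil, chosen so green >
  litter > soil in VNIR albedo and both non-green endmembers sit below the
  NDVI soil threshold. Parametric curves keep the package download-free.
* **Emissivity** is assigned from the scene's own noise-free NDVI through
  the same threshold model used in retrieval, so truth and retrieval are
  commensurable at the thermal scale.
* **Species tables**: a brome-like C3 dominant declines with L while
  seeded C4 grasses and forbs rise with it; the mid-diversity mix excludes
  the tall competitive C4 grasses; burning suppresses C3 and boosts forbs.
  Covers are gamma draws (shape 3) around these means, rescaled to the
  local green cover, with a 0.5% detection floor. Because locations read
  the same latent field as the pixels, field diversity and image indices
  genuinely covary.
* **Tarps**: white/silver/black with VNIR reflectance 0.80/0.45/0.05,
  thermal emissivity 0.88/0.93/0.97 and thermocouple temperatures
  318/322/330 K (sunlit tarps run hot, darker ones hotter) — free
  parameters of the simulator chosen to yield a well-conditioned solve;
  published experiments of this type do not report them.
* **Atmosphere**: τ = 0.92, L↓ = 5.0, L↑ = 0.8 W m⁻² sr⁻¹ μm⁻¹ —
  representative of a clear mid-summer 1.5-km path in the 7.5–14 μm
  window. The VNIR forward model is per-band linear (gain sloping
  1.6 → 1.0, Rayleigh-like offset decaying from 0.06), a deliberate match
  to the empirical-line correction's model class.

Plot geometry: 80 m × 50 m (0.40 ha) rectangles — the stated subplot array
(2 × 3 at 30 m spacing) and 5 m edge margins cannot coexist in a square of
that area, and the rectangle holds both exactly. Default scene 600 × 400 m
(1 m VNIR pixels, 261 bands at 2.3 nm; thermal 1.4 m). `SceneConfig.compact()`
keeps the identical metric layout and effect sizes at 2 m / 2.8 m pixels
and 9.2 nm bands; Monte-Carlo studies (the 100-seed sign-recovery check,
the 200-rep noise study on a 50 × 50 px scene) use that scale so the full
suite completes in minutes.

### What the simulator does not emulate

No BRDF or illumination geometry, no georectification beyond the local
metric grid, no radiative-transfer atmosphere (the VNIR path is linear by
construction, so the empirical line is exact there in a way it is not on
real data), no species spatial autocorrelation beyond the latent field,
and no observer error in cover estimation. Passing tests demonstrate the
pipeline's internal consistency and statistical calibration — not that
real atmospheric correction residuals or taxonomic error would leave the
field relationships intact.

## Numerical choices

* Radiance units are W m⁻² sr⁻¹ μm⁻¹ everywhere; conversion only at I/O.
* Pixel centers at half-integer multiples of the GSD; origin at the scene's
  lower-left corner, row 0 at the north edge.
* Box-average resampling normalizes weights over the overlapping span, so
  destination pixels partially outside the source keep correct means.
* All randomness derives from one root seed through named SeedSequence
  branches (layout 0, truth 11, cover 23, VNIR 31, thermal 47), so stages
  are individually reproducible and bit-identical across reruns.
* Empirical-line fits use `np.polyfit` per band; degenerate (constant
  reflectance) bands raise an error naming the band.
* OLS and ANCOVA go through statsmodels; nested-model F-tests use
  `compare_f_test`.

## Known limitations

* The empirical line shares the three tarps with the thermal solve; on
  real data, tarp non-uniformity or sub-pixel misregistration would
  correlate the two stages' errors. The simulator's tarp radiances are
  analytic means, standing in for the 81-pixel averages a 9 m tarp allows.
* Band-effective (τ, L↓, L↑) are only as transferable as the scene is
  homogeneous in column water vapor; a single channel cannot do better.
* The NDVI-threshold emissivity model saturates outside [NDVI_s, NDVI_v];
  senescent litter with soil-like NDVI but vegetation-like emissivity
  will bias its pixels warm by ~0.5 K per 0.01 emissivity error.
* Location-level regressions ignore spatial autocorrelation within plots;
  p-values are anti-conservative to that extent, exactly as in the plain
  OLS/ANCOVA convention they reproduce.
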