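# Methods

This note describes the models and numerical choices behind `pansharp`:
what the four fusion algorithms compute, how the six quality indices and
the Borda ranking are defined, what the synthetic scene generator does
and does not emulate, and the design decisions taken where the published
descriptions of these methods leave room.

## Problem setting

Very-high-resolution optical satellites deliver a multispectral image
(MS, here 8 bands on the WorldView-2 layout, 1.84 m) and a panchromatic
band (PAN, 450–800 nm, 0.46 m), a resolution ratio of r = 4.
Pansharpening injects the PAN's spatial detail into the MS bands to
produce an 8-band product at the PAN grid. Two error modes compete:
spectral distortion (band ratios drift, colours shift) and spatial
distortion (detail is missing or invented). The toolkit implements four
injection schemes spanning that trade-off, six indices that measure both
error modes, band-subset analysis (the PAN covers bands 2–6 only; bands
1, 7, 8 lie outside its span), block quality maps, and Borda-count
aggregation of the index rankings.

All algorithms take the MS already expanded to the PAN grid (bicubic by
default) and assume co-registered inputs; no registration is performed.

## Fusion algorithms

**FIHS.** Intensity I = unweighted mean of the injected bands (all 8 by
default; configurable). The PAN is moment-matched to I and the
difference PAN_m − I added to every injected band. The matching step is
not part of the classic description but without it the injected detail
carries the PAN's radiometry and biases every band; the same matching is
applied wherever PAN detail meets MS radiometry below.

**HCS.** Each pixel's band vector is read in hyperspherical
coordinates: radius = Euclidean norm, n−1 angles. The radius is
replaced by the PAN moment-matched to the radius plane; the angles are
untouched, so per-pixel band ratios — and hence the spectral angle — are
preserved exactly. This is the direct-substitution form; the smoothed
variant of the original formulation is out of scope.

**MTF-GLP-HPM.** PAN_low is the PAN filtered by a Gaussian matched to
the sensor MTF, decimated by r and re-expanded (one generalized-pyramid
stage with scale factor 4). High-pass modulation then sets
FUS_i = MS_i · PAN / PAN_low, preserving band ratios. Pixels where
PAN_low < ε (ε = 10⁻⁶ × the global PAN mean) pass the MS through
unchanged. MTF gains default to 0.35 for the band filters and are
per-band configurable; the values are nominal literature figures, not
calibrated to a specific sensor.

**WAT⊗FRAC.** The PAN (matched to band i) is decomposed with the
à trous wavelet transform (levels = log₂ r = 2) and the detail planes
are injected with a per-pixel weight α_i(x, y):
FUS_i = MS_i + α_i · Σ_k W_k. α_i is the band's fractal dimension map
normalized from the surface-dimension range [2, 3] to [0, 1]: rough,
textured covers receive the full detail, smooth covers (calm water,
homogeneous soil) receive little, which suppresses the salt-and-pepper
effect over homogeneous areas. One α map per band is applied identically
at every level (the published description does not distinguish levels).
Window-size guidance: 7 for heterogeneous shrubland, 27 for smooth
coastal scenes, 15 for mixed scenes.

Negative fused values are clipped to 0; there is no upper clip.

### Shared machinery

*À trous transform.* Separable B3-spline kernel [1, 4, 6, 4, 1]/16 with
2^(k−1)−1 zeros inserted at level k, reflect boundary. The transform is
additive by construction, so residual + Σ details reproduces the input
to machine precision — tested at 1e-9 relative.

*MTF-matched Gaussian.* Specified by its gain at the Nyquist frequency
of the r-times-decimated grid (f = 1/2r cycles/sample). The kernel
width is solved numerically (Brent root-finding on the discrete kernel's
frequency response) rather than from the continuous closed form
σ = (r/π)√(−2 ln g): for r = 1 the closed form yields σ < 1 sample,
where a sampled Gaussian's response deviates grossly from the continuous
one. The numeric solve meets the requested gain to machine precision at
every ratio. DC gain is always 1.

*Histogram matching* is moment matching: source rescaled to the
reference's mean and standard deviation. A zero-variance source is only
accepted against a zero-variance reference (output constant at the
reference level); tolerance for "zero" is 1e-12 relative, so bicubic
interpolation dust on constant planes does not trip the check.

*Fractal dimension map.* Sliding-window differential box counting. For
a window of w samples the covered extent is w−1 pixel spacings; boxes of
side ε = s−1 (filter sizes s = 2 … (w+1)/2, at most 5 scales) have
height ε·G/(w−1), G being the window's gray range. The per-cell count
is (local range)/(box height) + 1, averaged over the window with a
uniform filter and multiplied by the ((w−1)/ε)² grid size; the dimension
is the least-squares slope of log N against log((w−1)/ε), clipped to
[2, 3]. Flat or smooth-gradient surfaces give exactly 2 (the +1 term
dominates and the range scales linearly with ε); white noise pushes the
slope toward 3. Scaling box height with ε rather than with the filter
size s matters: a size-s filter spans s−1 spacings, and mixing the two
conventions biases smooth surfaces below dimension 2.

## Quality indices

With MS_i the reference band (original MS bicubically upsampled to the
PAN grid by default; a compare-at-MS mode degrades the fused product by
block means instead), FUS_i the fused band, and h/l the PAN/MS
resolution ratio (0.46/1.84 = 0.25):

- **SAM** — mean over pixels of the angle between reference and fused
  band vectors, in degrees; zero-norm pixels are skipped.
- **Spectral ERGAS** — 100·(h/l)·√(mean_i (rmse_i / mean(MS_i))²).
- **Spatial ERGAS** — same form with the PAN as the per-band reference;
  by default the PAN is moment-matched to each fused band first
  (removing radiometric offsets), a raw mode uses it unchanged.
- **FC** — per band, Pearson correlation of blockwise (8×8) DCT
  coefficients between fused band and PAN, pooled over all AC
  coefficients of all blocks (DC excluded, so constant offsets are
  invisible); mean over bands.
- **Zhou** — per band, Pearson correlation of 3×3 Laplacian high-pass
  planes (centre +8, neighbours −1) of fused band and PAN; mean over
  bands.
- **Q / Q8** — per band, the universal image quality index
  4·σ_xy·x̄·ȳ / ((σ_x²+σ_y²)(x̄²+ȳ²)), computed globally or as a mean
  over blocks; the scalar index is the mean over bands. The printed
  8-band formula sums band terms; reported values lie in [0, 1], which
  implies the mean — we normalize by the band count. The
  quaternion-style Q4 construction is deliberately not used. Degenerate
  0/0 blocks (both planes constant) score 1 if identical, else 0.

Block quality maps evaluate Q per band on non-overlapping blocks
(default 64 pixels, reflect-padded at the margins), giving a
⌈H/64⌉ × ⌈W/64⌉ grid per band; values are clamped to [0, 1] for
rendering only.

Band subsets: `in_pan` keeps the bands whose wavelength span lies wholly
inside the PAN span (bands 2–6), `out_pan` the rest (1, 7, 8).
Containment, not mere overlap, is the criterion — band 7 (770–895 nm)
overlaps the 450–800 nm span by 30 nm but is an out-of-PAN band.

## Borda ranking

Each index ranks the N candidate algorithms; the best earns N points,
the worst 1 (this weighting, rather than N−1…0, is what the published
rank columns are consistent with). Groupings sum member-index points:
spectral = {SAM, spectral ERGAS}, spatial = {FC, Zhou}, global = all
six. The spatial pair omits spatial ERGAS because the published spatial
rank columns are arithmetically consistent only with the {FC, Zhou}
pair; the three-index grouping is available by passing an explicit
grouping. Ties within an index are resolved by policy — `high` (all
tied items take the best contested rank's points, the default), `low`,
or `average` — and ties in aggregate scores are always reported jointly.
Under the default policy the mixed-scene benchmark yields a joint global
top (WAT⊗FRAC with MTF-GLP-HPM, both 18); under `low` WAT⊗FRAC is
strictly first. The published global columns for that scene resolve
different ties differently and cannot be reproduced by any single
policy; the package therefore asserts only who reaches the top rank.

## Synthetic scenes

Real scenes of the target ecosystems are commercial imagery, so the
generator paints reflectance-like truth at the PAN grid from 8-band
material signatures (vegetation peaking in the NIR, water decaying to
near-zero NIR, bright dune sand, dark wet shore sand, buildings, roads)
and three archetypes:

- **shrubland** — bare soil densely covered by small elliptical shrub
  patches (2–10 PAN pixels across, ~40% cover), each with its own
  brightness, with patch density following a smooth field so vegetation
  clusters at the landscape scale;
- **coastal** — ≥ 60% water with a smooth depth-driven shallow-to-deep
  gradient, a wet-sand shore strip and a few shore shrubs;
- **mixed** — a lagoon, an urban district of axis-aligned buildings on a
  road grid, and a dune field.

A spectrally neutral multiplicative texture (material-dependent
amplitude: rough soil/shrub 0.16, smooth sand 0.04–0.05, water
0.02–0.03) and a smooth illumination field provide the fine detail the
PAN sees. Degradation is Wald-style: per-band MTF blur (gain 0.35 at
the decimated grid's Nyquist), r× decimation, additive Gaussian noise
(sd = 1% of the band mean by default); the PAN is the overlap-weighted
sum of truth bands 2–6 blurred by the PAN MTF (gain 0.15). Everything
is a pure function of the seed.

What the generator does **not** emulate: radiative transfer, bathymetric
optics, BRDF, sensor geometry, non-Gaussian sensor noise, registration
error, or the within-material spectral variability of real land covers.
Consequences for interpretation: passing tests show the algorithms and
indices behave correctly and that the constructed contrasts (in-PAN vs
out-of-PAN band quality, scene-complexity ordering) are recovered; they
do not certify index *values* on real imagery. One structural
difference deserves note: on these scenes the upsampled MS bands are
very smooth, so the fractal weights are small and WAT⊗FRAC injects
conservatively — spectrally safest, spatially the most timid — whereas
on real textured imagery its weights are larger. Relatedly, the
component-substitution methods (HCS, HPM) show the classic NIR
spectral distortion here in exaggerated form, because the synthetic
vegetation's NIR pattern is strongly anti-correlated with the PAN.

## Numerical choices and degenerate inputs

- Upsampling: `scipy.ndimage.zoom` with spline order 0/1/3,
  `grid_mode=True`, reflect boundary. On the block-centre grid this
  preserves the global band mean under block-mean decimation to machine
  precision and preserves constants exactly; interpolation overshoot is
  clipped at 0.
- Decimation in the synthetic degradation samples the central polyphase
  ([r/2::r]) after the MTF blur.
- Division guards: HPM (ε above), HCS zero-radius pixels output 0, SAM
  skips zero-norm pixels, Pearson correlations raise on zero-variance
  planes, ERGAS raises on zero-mean reference bands.
- Problem sizes in the test-suite and acceptance runs are 16–64 MS
  pixels per side (64–256 at the PAN grid) — large enough for stable
  statistics on every index while keeping runs fast; the pipeline
  handles 512-pixel MS scenes in a few minutes.

## Known limitations

- FIHS intensity weights for 8-band sensors and the HCS
  intensity-matching details are not pinned down in the method
  literature; both are configurable and the defaults (unweighted mean;
  moment matching) are stated choices, not claims about the original
  implementations.
- The moment-matching variant of histogram matching is linear; full CDF
  matching is not implemented.
- Quality maps are returned as arrays/JSON; no PNG rendering is built
  in (any plotting library can consume `QualityMap.clamped()`).
- TIFF I/O carries no georeferencing tags; co-registration is assumed,
  not checked.
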