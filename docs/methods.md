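# Methods

## The normalised-distance transform

The coordinate assigns each quantified pixel `u = layer_base + f`, where
`layer_base` is 0 (basal), 1 (spinous/granular) or 2 (transitional) and
`f = d_in / (d_in + d_out)` is the fractional position between the
layer's bounding polylines, with `d_in`/`d_out` the minimum Euclidean
point-to-polyline distances (2D, in-plane pixels) to the deeper and the
more superficial boundary. "Linear interpolation between boundaries"
admits several concrete formulas; this one was chosen because it anchors
both boundaries exactly (f = 0 on the inner, f = 1 on the outer) and is
invariant to a uniform scaling of the layer thickness, which is the point
of the coordinate. One unit per layer (u ∈ [0, 3]) rather than a global
[0, 1] keeps layer boundaries at fixed coordinates independent of the
layers' relative thicknesses; a `rescale_unit` flag divides by 3 for
consumers that want [0, 1].

Conventions that had to be fixed somewhere and are this package's own:

* Coordinates are 0-based (x = column, y = row), origin top-left, row
  index increasing with tissue depth.
* A point exactly on a boundary belongs to the layer above (closer to the
  surface), except the dermal–basal interface b₀, which belongs to BASAL;
  b₃ itself is still TRANSITIONAL and carries the top anchor u = 3.
* Distances are 2D Euclidean within the imaging plane. The transform is
  applied per z-slice; z position never enters u. z is collapsed by
  policy: `per_slice` (default), `middle_slice`, or `z_mean`; mean
  normalisation happens after the collapse.
* Dermis and cornified/exterior pixels are excluded from quantification
  (stratum-corneum autofluorescence, non-specific signal); the exclusion
  report counts them by reason, they are never silently dropped.

Boundaries are operator-supplied inputs, validated before use: each
polyline must span the full column range, and after per-column resampling
the rows must satisfy row(b₀) > row(b₁) > row(b₂) > row(b₃) at every
column; violations are reported with the offending columns. Automatic
boundary detection is deliberately out of scope.

### Numerics

The scalar distance uses exact point-to-segment minimisation (shapely).
The raster path densifies each polyline at ~1 px arc-length spacing,
proposes a nearest vertex with a KD-tree, and minimises the exact segment
distance over a ±4-segment window around the proposal — exact for the
single-valued, per-column-resampled boundaries used here (verified
against the scalar path to 1e-9 in tests). If both bounding distances
vanish (touching boundaries) the transform raises rather than guessing.

## Profiles

Intensities are mean-normalised per (target, patient, stack) over
quantified pixels only — the only scope computable without cross-file
bookkeeping; the factor is recorded in the profile header. Smoothing is
LOESS: tricube-weighted local *linear* regression over the span-fraction
nearest neighbours, no robustness iterations, evaluated on a fixed grid
(default 151 nodes on [0, 3]; span default 0.3, exposed as a parameter
and recorded in output metadata). The implementation delegates to
statsmodels `lowess` (it = 0, `xvals=grid`); tests cross-check it against
a brute-force tricube weighted-least-squares oracle. Local linear
smoothing reproduces constants and straight lines exactly but has
curvature bias at sharp kinks — at a piecewise-linear peak the fitted
maximum is attenuated by a few per cent at span 0.3 — which is why the
recovery guarantees are stated as RMSE over the profile, not pointwise.

Comparison re-evaluates both profiles (linear interpolation) on the
intersection of their grid ranges and reports RMSE and Pearson r;
pooling returns the node-wise mean and a min–max envelope. When either
profile is exactly constant, r is defined as 1 if both are constant and
0 otherwise.

## Synthetic tissue

The generator stands in for the deposited patient imagery; its defaults
mirror the documented acquisition: 1,024 × 1,024 px frames at
160 nm/pixel, 8-bit uncompressed TIFF, 4× frame averaging, detector
gain/offset using the full dynamic range, a ~10 µm z-interval. The slice
spacing within that interval is not documented anywhere; this package
uses 4 slices × 2.5 µm. Tissue defaults: basal 15 µm, spinous+granular
36 µm, transitional 14 µm, cornified 13 µm (a ~78 µm epidermis, typical
of interfollicular skin at these magnifications); dermal-interface
undulation 8 µm amplitude, 55 µm wavelength, plus smooth low-frequency
noise at 10 % of the amplitude (rete-ridge-like protrusions), decaying to
half/quarter amplitude at the suprabasal boundaries and flat at the
surface. A three-"patient" preset scales all thicknesses by {0.6, 1.0,
1.6}, mimicking the very-thin to very-thick spread seen across real
donors.

Morphology is schematic: each quantified layer is tiled by a seeded
anisotropic Voronoi tessellation (cells ~11 µm, roughly isotropic in
basal/spinous, ≥ 3:1 flattened in the transitional layer), membranes are
the thickened inter-cell boundaries, nuclei are ellipses of radius 3.2 µm
(flattened in the transitional layer) clipped to cell interiors. The
cornified layer is anuclear with a bright constant "autofluorescence"
(120 detector units) unrelated to the target profile, so exclusion logic
is exercised. The imposed intensity is
`intensity_profiles[compartment](true_depth)`; the default target profile
is piecewise linear — 30 at u = 0, 55 at u = 1, peak 100 at u = 2,
declining to 50 at u = 3 — i.e. a strong rise over the spinous/granular
layers, qualitatively like an activated kinase, on detector-unit scale.

Noise: each of n frames is `Poisson(I·gain_p)/gain_p + N(0, σ_read)`
(defaults gain_p = 2 photons per detector unit, σ_read = 8), frames are
averaged, then an affine digitiser maps the 0.1–99.9 percentiles of the
averaged stack onto the quantisation range and rounds to `bit_depth`
bits. At the default settings single-frame noise is ~10 % of the imposed
intensity range, halved by 4× averaging. The variance guarantee
(averaging n frames divides pixel variance by n) is measured on the
pre-quantisation averaged image: the per-stack percentile gain would
rescale each replicate differently, and the claim concerns the noise
model, not the digitiser. A ×10 "gain" applied to the averaged analogue
image before quantisation is exactly cancelled by the percentile mapping,
which is the mechanism behind the gain-invariance of mean-normalised
profiles.

The truth channel's `true_depth` uses the same fractional-distance
formula as the production transform but is evaluated against the
*continuous* generating curves sampled at 0.25 px, so it does not inherit
the per-column polyline discretisation; the genuinely independent oracle
is the closed form for straight horizontal boundaries, which the
transform must match to 1e-9. Determinism: all randomness flows through
`numpy.random.default_rng` seeded from the caller; identical (spec, seed)
give bit-identical stacks and truth.

### What the generator does not emulate

No optical point-spread function, fluorophore spectra, tissue tilt
relative to the imaging plane, z-varying structure (slices share one
tissue realisation and differ only in noise), or histologically realistic
cell packing. Passing recovery tests therefore demonstrates correctness
of the coordinate transform, normalisation and smoothing under realistic
geometry, sampling and noise — not robustness to optical blur, staining
artefacts or segmentation error in operator-drawn boundaries.

## Problem sizes

Unit and acceptance tests run the pipeline on reduced frames (256–384
columns, 640–1,500 rows — enough for several hundred cells per tissue and
10⁴–10⁵ quantified pixels) with 8–15 % random pixel sampling for the
LOESS stages; the full 1,024 × 1,024 default preset is exercised once to
verify the acquisition geometry. The Monte-Carlo noise check uses 10,000
replicates of a 16-pixel flat patch. These sizes give comfortable margins
on every stated tolerance (e.g. thickness-invariance RMSE ~0.006 against
a bound of 0.1) while keeping the whole suite around a minute.

## Known limitations

* Boundary polylines must be single-valued per column; strongly
  re-entrant dermal protrusions (overhangs) cannot be represented.
* Whole-cell masks are treated as 2D per-slice labellings; per-cell
  statistics collapse z by `middle_slice` (default) or `z_mean`.
* The settings-file dialect is this package's own KEY\<TAB\>VALUE format;
  vendor exports need a user-supplied adapter, and anyone importing the
  originally deposited processed tables must map their columns onto the
  documented TSV layout.
* LOESS grid nodes outside the sampled u-range are extrapolated by the
  local fit of the nearest window; profiles from very sparse sampling
  should be inspected before comparison.
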