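# stratiquant

Layer-normalised depth profiling of immunofluorescence image stacks of
stratified epidermis.

## The problem

In human interfollicular epidermis, keratinocytes proliferate in the basal
layer and terminally differentiate as they move toward the skin surface
over roughly two weeks. A cell's depth in the tissue is therefore a proxy
for its differentiation stage, and confocal immunofluorescence of skin
cross-sections can read out how a signalling protein (e.g. the Raf → MEK →
ERK cascade components and their phosphorylated forms) changes along that
gradient. Two obstacles stand between a raw image stack and a comparable
expression-vs-differentiation curve:

1. **Tissue geometry varies.** Epidermal and per-layer thickness differ
   between donors and within a section, so raw depth in micrometres is not
   comparable across samples.
2. **Detector units vary.** Gain and offset are tuned per acquisition to
   fill the dynamic range, so raw intensities are not comparable either.

`stratiquant` addresses both with the *normalised distance* coordinate and
mean-normalised LOESS profiles. It is aimed at researchers quantifying
expression gradients in stratified epithelia who have image stacks plus
operator-drawn tissue-layer boundaries.

## The method

The quantified epidermis is delimited by four non-crossing boundary
polylines, deep to superficial: dermal–basal interface *b₀*, basal →
spinous/granular *b₁*, spinous/granular → transitional *b₂*, and the
transitional surface *b₃* (spinous and granular are merged — they cannot
be separated without extra histological markers). A pixel *p* in the layer
bounded by (*b_in*, *b_out*) gets the coordinate

```
u = layer_base + d(p, b_in) / (d(p, b_in) + d(p, b_out))
```

with `layer_base` ∈ {0, 1, 2} for basal, spinous/granular and transitional,
and `d` the Euclidean point-to-polyline distance. Each layer occupies one
unit of `u` ∈ [0, 3] regardless of its absolute thickness, which removes
thickness variation while keeping the phenotypically distinct layers
segregated at fixed coordinates. Dermis and cornified/exterior pixels are
excluded (autofluorescence and non-specific signal) with reason codes.

Sampled intensities are divided by their per-stack mean (making profiles
unitless, mean 1) and smoothed against `u` by LOESS — tricube-weighted
local linear regression over the span-fraction nearest neighbours
(default span 0.3) — on a fixed 151-node grid, so profiles from different
samples can be compared node by node (RMSE, Pearson r) and pooled
(node-wise mean with a min–max envelope).

Because the original patient imagery lives in an external repository, the
package ships a synthetic-tissue generator
(`stratiquant.synthetic`) that emulates the acquisition — layered
epidermis with membrane/cytoplasm/nucleus compartments, flattened
transitional cells, an undulating dermal interface, shot + read noise
under 4× frame averaging, 8-bit quantisation — together with a ground
truth channel (per-pixel compartment, true depth, the imposed intensity
function) against which the whole pipeline is tested.

## Worked example

```python
import numpy as np
from stratiquant import synthetic as syn, transform as tr, profiles as pr

# a reduced-frame synthetic acquisition with ground truth
spec = syn.SyntheticTissueSpec(frame_width_px=256, frame_height_px=768)
stack, truth = syn.generate_stack(spec, seed=7)
print("stack:", stack.voxels.shape, stack.voxels.dtype)

# sample 15 % of pixels on the middle slice and transform to u
mask = tr.random_sampling_mask(stack.frame_shape, 0.15, seed=3)
points = tr.transform_stack(stack, truth.boundaries, mask,
                            tr.TransformConfig(z_policy="middle_slice"))
print("sampled points:", len(points))
print("exclusions:", tr.exclusion_report(truth.boundaries, mask))

# mean-normalise and LOESS-smooth
profile = pr.profile_from_points(points, span=0.3)
print(f"normalisation factor: {profile.normalisation_factor:.2f}")
peak = profile.grid[np.argmax(profile.fitted)]
print(f"profile peak at u = {peak:.2f}, value {profile.fitted.max():.3f}")
```

prints

```
stack: (4, 768, 256) uint8
sampled points: 16121
exclusions: {'dermis': 9832, 'cornified_exterior': 3613, 'quantified': 16121}
normalisation factor: 125.25
profile peak at u = 1.98, value 1.364
```

The generator's default target profile peaks at the spinous/granular →
transitional boundary (u = 2); the pipeline recovers that peak at
u = 1.98 with mean-normalised amplitude 1.364 — intensities ~36 % above
the stack mean. The normalisation factor (125.25 detector units) is the
pre-normalisation mean; 16,121 of the 29,566 sampled pixels fall in
quantified layers, the rest are excluded as dermis or cornified/exterior.

The same pipeline is available from the shell:

```
stratiquant simulate  --outdir sim --seed 7 --frame-width 256 --frame-height 768
stratiquant transform --stack sim/default/stack.tif \
                      --boundaries sim/default/boundaries.tsv \
                      --z-policy middle_slice --out sampled.tsv
stratiquant profile   --sampled sampled.tsv --span 0.3 --out profile.tsv
stratiquant compare   --profiles p1.tsv --profiles p2.tsv --out report.json
```

Every command writes a `provenance.json` (config, versions, seed) beside
its outputs; runs are byte-reproducible from it.

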