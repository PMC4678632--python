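"""Synthetic confocal-like image stacks of layered epidermis with ground truth.

Real cryosectioned-skin image data live in an external repository and are
not needed to exercise the pipeline: this module generates image stacks
that emulate the acquisition — a cross-section of interfollicular
epidermis spanning dermis, basal, merged spinous/granular, transitional
and cornified compartments, imaged as a short z-stack with frame
averaging, shot noise and read noise, quantised to a fixed bit depth —
together with a truth channel (per-pixel compartment, per-pixel true
normalised depth, the imposed intensity function) that recovery tests can
compare against.

The default preset mirrors the acquisition geometry of the source dataset:
1,024 × 1,024 px frames at 160 nm/pixel, a z-interval of ~10 µm, 4× frame
averaging, 8-bit uncompressed TIFF, detector gain/offset set so the
dynamic range is used with minimal underflow and saturation.

Morphology is schematic, not histological: each quantified layer is tiled
with membrane-delimited cells with nuclei via a seeded anisotropic
Voronoi tessellation (roughly isotropic cells in the basal and
spinous/granular layers; flattened, >= 3:1 aspect, in the transitional
layer, mimicking the keratinocyte flattening that follows
caspase-14-mediated filaggrin release).  The cornified layer is anuclear
and carries an optional bright "autofluorescence" intensity independent
of the target profile, so that stratum-corneum exclusion logic is
exercised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries
from skimage.morphology import binary_dilation, disk

from .segmentation import LayerBoundarySet, LayerLabel, validate_boundaries
from .transform import normalised_distance_raster

LAYER_ORDER = ("basal", "spinous_granular", "transitional", "cornified")

#: compartment codes in the truth raster
COMPARTMENTS = ("exterior", "dermis", "nucleus", "cytoplasm", "membrane", "cornified")
COMPARTMENT_CODE = {name: i for i, name in enumerate(COMPARTMENTS)}


def default_target_profile(u):
    """Default imposed depth profile g(u): low basal, peak at u = 2, declining.

    Piecewise linear in the normalised coordinate, qualitatively like an
    activated kinase that rises over the spinous/granular layers and falls
    in the transitional layer.  Detector units, peak 100.
    """
    u = np.asarray(u, dtype=float)
    return np.interp(u, [0.0, 1.0, 2.0, 3.0], [30.0, 55.0, 100.0, 50.0])


def _default_intensity_profiles() -> dict[str, Callable]:
    g = default_target_profile
    return {
        "cytoplasm": g,
        "nucleus": lambda u: 0.6 * g(u),
        "membrane": lambda u: 1.15 * g(u),
        "dermis": lambda u: np.full_like(np.asarray(u, float), 8.0),
        "cornified": lambda u: np.full_like(np.asarray(u, float), 120.0),
        "exterior": lambda u: np.full_like(np.asarray(u, float), 2.0),
    }


@dataclass
class SyntheticTissueSpec:
    """Parameters of one synthetic tissue + acquisition.

    Geometry defaults reproduce the source acquisition (1,024 × 1,024 px at
    160 nm/pixel, ~10 µm z-interval, 4× frame averaging, 8 bit); tissue
    defaults give an epidermis of ~78 µm total thickness with an undulating
    dermal–basal interface.
    """

    frame_width_px: int = 1024
    frame_height_px: int = 1024
    n_slices: int = 4
    pixel_size_nm: float = 160.0
    z_step_um: float = 2.5
    layer_thicknesses_um: dict[str, float] = field(
        default_factory=lambda: {
            "basal": 15.0,
            "spinous_granular": 36.0,
            "transitional": 14.0,
            "cornified": 13.0,
        }
    )
    undulation_amplitude_um: float = 8.0
    undulation_wavelength_um: float = 55.0
    nucleus_radius_um: float = 3.2
    membrane_width_px: int = 2
    cell_diameter_um: float = 11.0
    transitional_aspect: float = 3.5  # width:height of flattened cells
    intensity_profiles: dict[str, Callable] = field(
        default_factory=_default_intensity_profiles
    )
    photon_gain: float = 2.0  # photons per detector unit
    read_noise_sd: float = 8.0  # detector units, single frame
    noise_enabled: bool = True
    n_frames_averaged: int = 4
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in LAYER_ORDER:
            t = self.layer_thicknesses_um.get(name)
            if t is None or t <= 0:
                raise ValueError(f"layer thickness for {name!r} must be strictly positive")
        if self.undulation_amplitude_um < 0:
            raise ValueError("undulation amplitude must be nonnegative")
        if self.undulation_amplitude_um >= self.layer_thicknesses_um["basal"]:
            raise ValueError(
                "undulation amplitude "
                f"({self.undulation_amplitude_um} um) must be smaller than the basal "
                f"thickness ({self.layer_thicknesses_um['basal']} um); boundaries would cross"
            )
        if self.undulation_wavelength_um <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("wavelength and pixel size must be positive")
        if self.z_step_um <= 0 or self.photon_gain <= 0:
            raise ValueError("z step and photon gain must be positive")
        if self.read_noise_sd < 0 or self.n_frames_averaged < 1:
            raise ValueError("read noise must be nonnegative, frame count >= 1")
        if self.membrane_width_px < 1:
            raise ValueError("membrane width must be a positive pixel count")
        missing = set(COMPARTMENTS) - set(self.intensity_profiles)
        if missing:
            raise ValueError(f"intensity_profiles missing compartments: {sorted(missing)}")

    @property
    def px_per_um(self) -> float:
        return 1000.0 / self.pixel_size_nm

    def scaled(self, thickness_multiplier: float, **overrides) -> "SyntheticTissueSpec":
        """Copy of the spec with all layer thicknesses scaled by one factor."""
        thick = {k: v * thickness_multiplier for k, v in self.layer_thicknesses_um.items()}
        return dataclasses.replace(self, layer_thicknesses_um=thick, **overrides)


@dataclass
class GroundTruth:
    """Truth channel of one synthetic tissue.

    ``true_depth`` holds the layer-normalised coordinate u of every pixel in
    the quantified epidermis and NaN elsewhere (dermis, cornified,
    exterior).  ``cell_labels`` (0 = not a cell interior) supports per-cell
    extraction tests.
    """

    compartment_labels: np.ndarray  # uint8 codes, see COMPARTMENT_CODE
    true_depth: np.ndarray  # float, NaN outside quantified epidermis
    boundaries: LayerBoundarySet
    intensity_function: dict[str, Callable]
    cell_labels: np.ndarray | None = None

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.compartment_labels == COMPARTMENT_CODE[name]


def generate_boundaries(spec: SyntheticTissueSpec, seed: int) -> LayerBoundarySet:
    """Generate the four layer boundaries for one tissue.

    The dermal–basal interface undulates as a seeded sinusoid (the stated
    amplitude and wavelength) plus smooth low-frequency noise at 10 % of the
    amplitude, emulating rete-ridge-like dermal protrusions; the undulation
    decays toward the surface (suprabasal boundaries follow the interface at
    half and quarter amplitude, and the cornified surface is flat).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    W, H = spec.frame_width_px, spec.frame_height_px
    ppu = spec.px_per_um
    x = np.arange(W, dtype=float)
    thick_px = {k: v * ppu for k, v in spec.layer_thicknesses_um.items()}
    total_quant = thick_px["basal"] + thick_px["spinous_granular"] + thick_px["transitional"]

    amp = spec.undulation_amplitude_um * ppu
    wav = spec.undulation_wavelength_um * ppu
    phase = rng.uniform(0, 2 * np.pi)
    # smooth extra roughness: 3 random long-wavelength harmonics, sd ~ amp/10
    harmonics = [
        (0.1 * amp / np.sqrt(3), rng.uniform(1.5 * wav, 4 * wav), rng.uniform(0, 2 * np.pi))
        for _ in range(3)
    ]

    def und_fn(xq):
        xq = np.asarray(xq, dtype=float)
        out = amp * np.sin(2 * np.pi * xq / wav + phase)
        if amp > 0:
            for a_h, w_h, p_h in harmonics:
                out = out + a_h * np.sin(2 * np.pi * xq / w_h + p_h)
        return out

    und = und_fn(x)

    r3_base = 0.12 * H  # cornified surface position; margin leaves room above
    r3 = np.full(W, r3_base)
    r2 = r3 + thick_px["transitional"] + 0.25 * und
    r1 = r2 + thick_px["spinous_granular"] + 0.25 * und
    r0 = r1 + thick_px["basal"] + 0.5 * und
    if r0.max() >= H:
        raise ValueError(
            "tissue does not fit in the frame: dermal boundary reaches row "
            f"{r0.max():.0f} of {H}"
        )
    polys = [np.column_stack([x, r]) for r in (r0, r1, r2, r3)]
    b = validate_boundaries(LayerBoundarySet(polys, frame_shape=(H, W)))

    # attach the continuous generating curves so the truth channel can be
    # evaluated at sub-pixel resolution, independent of the per-column
    # resampling the production transform uses
    base0 = float(r3_base)
    t_tr = thick_px["transitional"]
    t_sp = thick_px["spinous_granular"]
    t_ba = thick_px["basal"]
    b.analytic_rows = [
        lambda xq: base0 + t_tr + t_sp + t_ba + und_fn(xq),
        lambda xq: base0 + t_tr + t_sp + 0.5 * und_fn(xq),
        lambda xq: base0 + t_tr + 0.25 * und_fn(xq),
        lambda xq: np.full_like(np.asarray(xq, dtype=float), base0),
    ]
    return b


def _tile_layer(
    rng: np.random.Generator,
    b: LayerBoundarySet,
    layer_mask: np.ndarray,
    inner_idx: int,
    outer_idx: int,
    cell_w_px: float,
    cell_h_px: float,
    next_id: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Anisotropic Voronoi tessellation of one layer band.

    Returns (label raster over the layer, centre array (n, 2) of (x, y),
    next free id).  Cell centres sit on a jittered grid in (column,
    fractional-depth) space so cell size follows the local layer thickness.
    """
    H, W = layer_mask.shape
    r_in = b.rows[inner_idx]
    r_out = b.rows[outer_idx]
    mean_thick = float(np.mean(r_in - r_out))
    n_cols = max(1, int(round(W / cell_w_px)))
    n_rows_cells = max(1, int(round(mean_thick / cell_h_px)))
    cx = (np.arange(n_cols) + 0.5) * (W / n_cols)
    cf = (np.arange(n_rows_cells) + 0.5) / n_rows_cells
    gx, gf = np.meshgrid(cx, cf)
    gx = gx.ravel() + rng.uniform(-0.3, 0.3, gx.size) * (W / n_cols)
    gf = gf.ravel() + rng.uniform(-0.3, 0.3, gf.size) / n_rows_cells
    gx = np.clip(gx, 0, W - 1)
    gf = np.clip(gf, 0.02, 0.98)
    gy = np.interp(gx, np.arange(W), r_in) * (1 - gf) + np.interp(
        gx, np.arange(W), r_out
    ) * gf
    centres = np.column_stack([gx, gy])

    yy, xx = np.nonzero(layer_mask)
    tree = cKDTree(np.column_stack([centres[:, 0] / cell_w_px, centres[:, 1] / cell_h_px]))
    _, idx = tree.query(np.column_stack([xx / cell_w_px, yy / cell_h_px]), k=1)
    labels = np.zeros((H, W), dtype=np.int32)
    labels[yy, xx] = idx + next_id
    return labels, centres, next_id + len(centres)


def render_tissue(
    boundaries: LayerBoundarySet, spec: SyntheticTissueSpec, seed: int
) -> GroundTruth:
    """Rasterise compartments and true depth for one tissue.

    Quantified layers are tiled with cells; every intracellular pixel is
    nucleus, membrane or cytoplasm.  ``true_depth`` is the layer index plus
    the fractional distance between the pixel's bounding polylines — the
    same interpolation formula the production transform applies, evaluated
    from the generating boundaries.
    """
    rng = np.random.default_rng(seed)
    b = boundaries if boundaries.validated else validate_boundaries(boundaries)
    H, W = b.frame_shape
    ppu = spec.px_per_um
    yy = np.arange(H, dtype=float)[:, None]
    r0, r1, r2, r3 = (b.rows[i][None, :] for i in range(4))

    dermis = yy > r0
    basal = (yy > r1) & ~dermis
    spinous = (yy > r2) & (yy <= r1)
    transitional = (yy >= r3) & (yy <= r2)
    corn_thick = spec.layer_thicknesses_um["cornified"] * ppu
    cornified = (yy >= r3 - corn_thick) & (yy < r3)
    exterior = yy < r3 - corn_thick
    epidermal = basal | spinous | transitional

    comp = np.zeros((H, W), dtype=np.uint8)
    comp[exterior] = COMPARTMENT_CODE["exterior"]
    comp[dermis] = COMPARTMENT_CODE["dermis"]
    comp[cornified] = COMPARTMENT_CODE["cornified"]

    # cell tessellation per quantified layer
    cw = spec.cell_diameter_um * ppu
    cells = np.zeros((H, W), dtype=np.int32)
    centres_all = []
    flat = []  # per-centre flattened flag
    nid = 1
    for mask, (i_in, i_out), aspect in (
        (basal, (0, 1), 1.0),
        (spinous, (1, 2), 1.0),
        (transitional, (2, 3), spec.transitional_aspect),
    ):
        if not mask.any():
            continue
        cw_l = cw * np.sqrt(aspect)
        ch_l = cw / np.sqrt(aspect)
        lab, cen, nid = _tile_layer(rng, b, mask, i_in, i_out, cw_l, ch_l, nid)
        cells = np.where(mask, lab, cells)
        centres_all.append(cen)
        flat.extend([aspect > 1.0] * len(cen))

    # membrane: thick inter-cell boundaries within the epidermis
    membrane = find_boundaries(cells, mode="thick") & epidermal
    if spec.membrane_width_px > 2:
        membrane = binary_dilation(membrane, disk((spec.membrane_width_px - 1) // 2))
        membrane &= epidermal

    comp[epidermal] = COMPARTMENT_CODE["cytoplasm"]
    comp[membrane] = COMPARTMENT_CODE["membrane"]

    # nuclei: one ellipse per cell centre, clipped to the cell interior
    if spec.nucleus_radius_um > 0 and centres_all:
        centres = np.vstack(centres_all)
        r_px = spec.nucleus_radius_um * ppu
        nuc = np.zeros((H, W), dtype=bool)
        for (cx, cy), is_flat in zip(centres, flat):
            if is_flat:
                rx, ry = r_px * 1.7, max(1.0, r_px / 2.2)
            else:
                rx = ry = r_px
            x0, x1 = int(max(0, cx - rx - 1)), int(min(W, cx + rx + 2))
            y0, y1 = int(max(0, cy - ry - 1)), int(min(H, cy + ry + 2))
            if x0 >= x1 or y0 >= y1:
                continue
            sy, sx = np.ogrid[y0:y1, x0:x1]
            nuc[y0:y1, x0:x1] |= ((sx - cx) / rx) ** 2 + ((sy - cy) / ry) ** 2 <= 1.0
        nuc &= epidermal & ~membrane
        comp[nuc] = COMPARTMENT_CODE["nucleus"]

    depth = _truth_depth_raster(b)
    # membrane pixels are not cell interior
    cell_interior = np.where(epidermal & ~membrane, cells, 0).astype(np.int32)

    return GroundTruth(
        compartment_labels=comp,
        true_depth=depth,
        boundaries=b,
        intensity_function=dict(spec.intensity_profiles),
        cell_labels=cell_interior,
    )


def _truth_depth_raster(b: LayerBoundarySet) -> np.ndarray:
    """True depth from the continuous generating curves, if available.

    When the boundary set carries its analytic generating curves
    (``analytic_rows``), distances are measured against those curves
    sampled at 0.25 px, so the truth channel does not inherit the
    per-column polyline discretisation of the production transform.  For
    boundary sets without analytic curves the polyline raster is used.
    """
    from .segmentation import assign_layer_raster, polyline_distances as _pd
    from .transform import LAYER_BOUNDS

    analytic = getattr(b, "analytic_rows", None)
    if analytic is None:
        return normalised_distance_raster(b)
    H, W = b.frame_shape
    xf = np.arange(0.0, W - 1 + 1e-9, 0.25)
    polys = [np.column_stack([xf, fn(xf)]) for fn in analytic]
    layers = assign_layer_raster(b)
    yy, xx = np.indices((H, W))
    u = np.full((H, W), np.nan)
    for layer, (base, i_in, i_out) in LAYER_BOUNDS.items():
        m = layers == layer
        if not m.any():
            continue
        d_in = _pd(xx[m], yy[m], polys[i_in])
        d_out = _pd(xx[m], yy[m], polys[i_out])
        tot = d_in + d_out
        frac = np.divide(d_in, tot, out=np.zeros_like(d_in), where=tot > 0)
        u[m] = base + frac
    return u


def clean_image(truth: GroundTruth, spec: SyntheticTissueSpec) -> np.ndarray:
    """Noise-free intensity frame: profiles evaluated at the true depth."""
    comp = truth.compartment_labels
    u = np.where(np.isfinite(truth.true_depth), truth.true_depth, 0.0)
    out = np.zeros(comp.shape, dtype=float)
    for name, func in spec.intensity_profiles.items():
        m = comp == COMPARTMENT_CODE[name]
        if m.any():
            out[m] = np.asarray(func(u[m]), dtype=float)
    return out


def simulate_frames(
    clean: np.ndarray, spec: SyntheticTissueSpec, seed: int
) -> np.ndarray:
    """Frame-averaged analogue image: shot + read noise, before quantisation.

    Each of ``n_frames_averaged`` independent frames is
    ``Poisson(I * photon_gain) / photon_gain + N(0, read_noise_sd)``; the
    frames are averaged.  With the noise flag off the clean image is
    returned unchanged.  Deterministic for a fixed seed.
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0) or not np.all(np.isfinite(clean)):
        raise ValueError("clean image must be finite and nonnegative")
    if not spec.noise_enabled:
        return clean.copy()
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(clean)
    for _ in range(spec.n_frames_averaged):
        frame = rng.poisson(clean * spec.photon_gain).astype(float) / spec.photon_gain
        if spec.read_noise_sd > 0:
            frame += rng.normal(0.0, spec.read_noise_sd, size=clean.shape)
        acc += frame
    return acc / spec.n_frames_averaged


def quantise_stack(
    analogue: np.ndarray, spec: SyntheticTissueSpec, gain_scale: float = 1.0
) -> tuple[np.ndarray, float, float]:
    """Digitise an analogue image: affine gain/offset then integer rounding.

    The affine map sends the 0.1–99.9 intensity percentiles onto the full
    quantisation range (detector gain and offset adjusted to use the
    dynamic range while minimising underflow and saturation), then clips
    and rounds to ``bit_depth`` bits.  ``gain_scale`` models an extra
    detector-gain factor applied before digitisation.  Returns
    (quantised array, gain, offset) with quantised = clip(round(gain * x +
    offset)).
    """
    x = np.asarray(analogue, dtype=float) * gain_scale
    maxq = 2**spec.bit_depth - 1
    lo, hi = np.percentile(x, [0.1, 99.9])
    if hi <= lo:
        gain, offset = 0.0, maxq / 2.0
    else:
        gain = maxq / (hi - lo)
        offset = -lo * gain
    q = np.clip(np.rint(gain * x + offset), 0, maxq)
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    return q.astype(dtype), float(gain), float(offset)


def apply_noise(clean_image_arr: np.ndarray, spec: SyntheticTissueSpec, seed: int,
                gain_scale: float = 1.0):
    """Full acquisition of a z-stack from one clean frame (or stack).

    Accepts a 2D clean frame (replicated over ``n_slices`` with independent
    noise per slice) or a 3D clean stack.  Returns an
    :class:`~stratiquant.image_io.ImageStack`.
    """
    from .image_io import ImageStack

    clean = np.asarray(clean_image_arr, dtype=float)
    if np.any(clean < 0) or not np.all(np.isfinite(clean)):
        raise ValueError("clean image must be finite and nonnegative")
    if clean.ndim == 2:
        planes = [clean] * spec.n_slices
    elif clean.ndim == 3:
        planes = list(clean)
    else:
        raise ValueError("clean image must be 2D or 3D")
    rng = np.random.default_rng(seed)
    analogue = np.stack(
        [
            simulate_frames(p, spec, int(rng.integers(0, 2**31 - 1)))
            for p in planes
        ]
    )
    q, gain, offset = quantise_stack(analogue, spec, gain_scale=gain_scale)
    return ImageStack(
        voxels=q,
        pixel_size_nm=spec.pixel_size_nm,
        z_step_um=spec.z_step_um,
        bit_depth=spec.bit_depth,
        channel_name="synthetic",
        gain=gain,
        offset=offset,
    )


def generate_stack(spec: SyntheticTissueSpec, seed: int):
    """Generate one full synthetic acquisition: (ImageStack, GroundTruth).

    Sub-seeds for boundary generation, tissue rendering and noise are
    derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    b = generate_boundaries(spec, seeds[0])
    truth = render_tissue(b, spec, seeds[1])
    clean = clean_image(truth, spec)
    stack = apply_noise(clean, spec, seeds[2])
    return stack, truth


def acquisition_metadata(spec: SyntheticTissueSpec, stack=None):
    """Microscope-settings record for a synthetic acquisition.

    Mirrors the documented acquisition: 63× oil objective, NA 1.32, the
    spec's pixel pitch, frame averaging and z-interval; gain/offset from
    the digitiser if a stack is supplied.
    """
    from .image_io import AcquisitionMetadata

    return AcquisitionMetadata(
        objective_magnification=63.0,
        numerical_aperture=1.32,
        gain=getattr(stack, "gain", 1.0) if stack is not None else 1.0,
        offset=getattr(stack, "offset", 0.0) if stack is not None else 0.0,
        frame_averaging=spec.n_frames_averaged,
        pixel_size_nm=spec.pixel_size_nm,
        z_interval_um=spec.n_slices * spec.z_step_um,
        extras={"immersion": "oil", "channel": "synthetic"},
    )


#: thickness multipliers of the three-patient preset (middle = reference;
#: one very thick, one very thin tissue, as seen across real donors)
PATIENT_THICKNESS_MULTIPLIERS = {"pat1": 1.0, "pat2": 1.6, "pat3": 0.6}


def three_patient_specs(
    base: SyntheticTissueSpec | None = None,
) -> dict[str, SyntheticTissueSpec]:
    """Replicate tissues with thickness multipliers {0.6, 1.0, 1.6}."""
    base = base or SyntheticTissueSpec()
    return {
        name: base.scaled(mult)
        for name, mult in PATIENT_THICKNESS_MULTIPLIERS.items()
    }
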