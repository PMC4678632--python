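"""The layer-normalised "normalised distance" coordinate transform.

Sampled pixels are mapped from 2D image coordinates to a one-dimensional
coordinate ``u`` along the keratinocyte differentiation gradient.  Each of
the three quantified layers occupies one unit:

* BASAL → ``u`` in [0, 1),
* SPINOUS_GRANULAR → ``u`` in [1, 2),
* TRANSITIONAL → ``u`` in [2, 3].

Within a layer the fractional position is obtained by linear interpolation
between the two bounding polylines::

    frac = d_inner / (d_inner + d_outer)

where ``d_inner`` is the Euclidean distance to the deeper boundary and
``d_outer`` to the more superficial one.  This form anchors both boundaries
(0 on the inner, 1 on the outer) and is invariant to a uniform scaling of
the layer thickness — the point of the coordinate: it removes the
inter-patient and intra-sample variation in absolute layer thickness while
keeping phenotypically distinct layers segregated at fixed coordinates.

Dermal and cornified/exterior pixels carry autofluorescence and
non-specific signal and are excluded from quantification; they are reported
with reason codes rather than silently dropped.

Distances are measured in 2D Euclidean pixel units within the imaging
plane; the z position of a slice does not enter ``u``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import (
    LayerBoundarySet,
    LayerLabel,
    QUANTIFIED_LAYERS,
    distance_to_boundary,
    polyline_distances,
)

#: value of ``u`` recorded for excluded points
EXCLUDED = float("nan")

#: layer → (base coordinate, inner boundary index, outer boundary index)
LAYER_BOUNDS = {
    LayerLabel.BASAL: (0.0, 0, 1),
    LayerLabel.SPINOUS_GRANULAR: (1.0, 1, 2),
    LayerLabel.TRANSITIONAL: (2.0, 2, 3),
}


@dataclass
class SampledPoint:
    """One measured pixel with its normalised-distance coordinate."""

    x_px: int
    y_px: int
    z_index: int
    intensity: float
    layer: LayerLabel
    u: float

    @property
    def excluded(self) -> bool:
        return not np.isfinite(self.u)


@dataclass
class TransformConfig:
    """Options of the normalised-distance transform.

    z_policy
        ``per_slice`` emits every slice, ``middle_slice`` only the central
        one, ``z_mean`` averages intensities over z before sampling.
    rescale_unit
        If true, divide ``u`` by 3 so the coordinate spans [0, 1].
    """

    z_policy: str = "per_slice"
    rescale_unit: bool = False
    excluded_labels: tuple[LayerLabel, ...] = (
        LayerLabel.DERMIS,
        LayerLabel.CORNIFIED_EXTERIOR,
    )
    layer_breakpoints: dict = field(default_factory=lambda: dict(LAYER_BOUNDS))


def fractional_position(
    point: tuple[float, float],
    inner_boundary: np.ndarray,
    outer_boundary: np.ndarray,
) -> float:
    """Relative position of a point between two boundary polylines.

    Returns ``d_inner / (d_inner + d_outer)``: 0 on the inner (deeper)
    boundary, 1 on the outer.  Raises if both distances vanish (degenerate
    geometry: the boundaries touch at the point).
    """
    d_in = distance_to_boundary(point, inner_boundary)
    d_out = distance_to_boundary(point, outer_boundary)
    total = d_in + d_out
    if total == 0.0:
        raise ValueError(
            f"degenerate geometry at {point}: both bounding boundaries at distance 0"
        )
    return d_in / total


def normalised_distance(
    point: tuple[float, float],
    b: LayerBoundarySet,
    cfg: TransformConfig | None = None,
) -> float:
    """Normalised-distance coordinate of a single point, or NaN if excluded.

    ``u = layer_base + fractional_position`` with ``layer_base`` in
    {0, 1, 2}; dermis and cornified/exterior points return the excluded
    sentinel (NaN).
    """
    from .segmentation import assign_layer

    cfg = cfg or TransformConfig()
    layer = assign_layer(point, b)
    if layer in cfg.excluded_labels:
        return EXCLUDED
    base, i_in, i_out = LAYER_BOUNDS[layer]
    u = base + fractional_position(point, b.boundaries[i_in], b.boundaries[i_out])
    return u / 3.0 if cfg.rescale_unit else u


def normalised_distance_raster(b: LayerBoundarySet) -> np.ndarray:
    """``u`` for every frame pixel; NaN outside the quantified epidermis.

    Vectorised over the whole frame; distances computed with the exact
    KD-tree-assisted polyline distance.  Polylines are taken from the
    validated per-column resampling so the raster is consistent with
    per-pixel layer assignment.
    """
    from .segmentation import assign_layer_raster

    if not b.validated:
        raise ValueError("boundary set has not been validated")
    n_rows, n_cols = b.frame_shape
    layers = assign_layer_raster(b)
    yy, xx = np.indices((n_rows, n_cols))
    u = np.full((n_rows, n_cols), np.nan)
    cols = np.arange(n_cols, dtype=float)
    polys = [np.column_stack([cols, b.rows[i]]) for i in range(4)]
    for layer, (base, i_in, i_out) in LAYER_BOUNDS.items():
        m = layers == layer
        if not m.any():
            continue
        d_in = polyline_distances(xx[m], yy[m], polys[i_in])
        d_out = polyline_distances(xx[m], yy[m], polys[i_out])
        tot = d_in + d_out
        frac = np.divide(d_in, tot, out=np.zeros_like(d_in), where=tot > 0)
        u[m] = base + frac
    return u


def transform_stack(
    stack,
    b: LayerBoundarySet,
    sampling_mask: np.ndarray | None = None,
    cfg: TransformConfig | None = None,
) -> list[SampledPoint]:
    """Sample a stack and attach the normalised-distance coordinate.

    Parameters
    ----------
    stack
        :class:`~stratiquant.image_io.ImageStack`.
    b
        Validated :class:`LayerBoundarySet` matching the frame shape.
    sampling_mask
        Optional binary raster selecting pixels; ``None`` samples every
        pixel.  Pixels falling in excluded layers produce no output record
        (they are excluded by tissue segmentation) but are counted.
    cfg
        Transform options; see :class:`TransformConfig`.

    Returns
    -------
    list of SampledPoint, deterministic row-major order (then z).
    """
    cfg = cfg or TransformConfig()
    voxels = np.asarray(stack.voxels)
    nz, n_rows, n_cols = voxels.shape
    if b.frame_shape != (n_rows, n_cols):
        raise ValueError(
            f"boundary frame shape {b.frame_shape} != stack frame ({n_rows}, {n_cols})"
        )
    if sampling_mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    else:
        mask = np.asarray(sampling_mask).astype(bool)
        if mask.shape != (n_rows, n_cols):
            raise ValueError("sampling mask shape does not match stack frame")
    if not mask.any():
        warnings.warn("sampling mask is empty; no points sampled", stacklevel=2)
        return []

    u_raster = normalised_distance_raster(b)
    if cfg.rescale_unit:
        u_raster = u_raster / 3.0
    from .segmentation import assign_layer_raster

    layer_raster = assign_layer_raster(b)
    keep = mask & np.isfinite(u_raster)
    if not keep.any():
        warnings.warn("all sampled pixels fall in excluded layers", stacklevel=2)
        return []
    ys, xs = np.nonzero(keep)  # row-major order

    if cfg.z_policy == "middle_slice":
        planes = [(nz // 2, voxels[nz // 2])]
    elif cfg.z_policy == "z_mean":
        planes = [(-1, voxels.astype(float).mean(axis=0))]
    elif cfg.z_policy == "per_slice":
        planes = list(enumerate(voxels))
    else:
        raise ValueError(f"unknown z_policy {cfg.z_policy!r}")

    points: list[SampledPoint] = []
    for z, img in planes:
        vals = np.asarray(img, dtype=float)[ys, xs]
        for x, y, v in zip(xs, ys, vals):
            points.append(
                SampledPoint(
                    x_px=int(x),
                    y_px=int(y),
                    z_index=int(z),
                    intensity=float(v),
                    layer=layer_raster[y, x],
                    u=float(u_raster[y, x]),
                )
            )
    return points


def exclusion_report(
    b: LayerBoundarySet, sampling_mask: np.ndarray | None = None
) -> dict[str, int]:
    """Count sampled pixels per exclusion reason (never silently dropped)."""
    from .segmentation import assign_layer_raster

    layers = assign_layer_raster(b)
    if sampling_mask is not None:
        sel = np.asarray(sampling_mask).astype(bool)
    else:
        sel = np.ones(b.frame_shape, dtype=bool)
    return {
        "dermis": int(((layers == LayerLabel.DERMIS) & sel).sum()),
        "cornified_exterior": int(
            ((layers == LayerLabel.CORNIFIED_EXTERIOR) & sel).sum()
        ),
        "quantified": int(
            sum(((layers == lab) & sel).sum() for lab in QUANTIFIED_LAYERS)
        ),
    }


def random_sampling_mask(
    frame_shape: tuple[int, int], fraction: float, seed: int
) -> np.ndarray:
    """Uniform random binary sampling mask covering ``fraction`` of pixels."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    return rng.random(frame_shape) < fraction
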