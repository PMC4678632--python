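"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* **Image stacks** — multipage uncompressed grayscale TIFF (8- or 16-bit),
  one page per z-slice; calibration (pixel pitch, z-step, bit depth,
  channel name) stored in the TIFF ImageDescription tag as JSON so the
  write→read round trip is lossless.
* **Microscope settings** — plain-text ``KEY<TAB>VALUE`` lines, one per
  line.  This dialect is this package's own (vendor exports would need an
  adapter); unknown keys are preserved in a pass-through map.
* **Sampled data** — TSV with one header row, either the *xy* format
  (``target patient x_px y_px z_index intensity layer``) or the
  *normalised* format with the extra ``u`` column.  Reals are serialised
  with 6 significant digits (8-bit source data cannot exceed that
  precision meaningfully).
* **Boundary polylines** — TSV of ``boundary_index  vertex_index  x_px  y_px``.
* **Masks** — integer TIFF; 0 is background, positive values are cell ids
  for labelled masks.
* **Profiles** — TSV of ``u  fitted`` with a ``#``-prefixed header block
  carrying span, point count and normalisation factor.

Coordinates are 0-based ``(x = column, y = row)``, origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import LayerBoundarySet, LayerLabel


class FormatError(ValueError):
    """Raised when an on-disk file violates its documented format."""


@dataclass
class ImageStack:
    """A calibrated 3D image stack (slice, row, column)."""

    voxels: np.ndarray
    pixel_size_nm: float
    z_step_um: float
    bit_depth: int = 8
    channel_name: str = ""
    gain: float | None = None
    offset: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("stack must be 3D (slice, row, column)")
        if np.issubdtype(self.voxels.dtype, np.integer):
            top = 2**self.bit_depth - 1
            if self.voxels.min() < 0 or self.voxels.max() > top:
                raise ValueError(f"integer voxel values must lie in [0, {top}]")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class AcquisitionMetadata:
    """Microscope settings parsed from a sidecar text file."""

    objective_magnification: float
    numerical_aperture: float
    gain: float
    offset: float
    frame_averaging: int
    pixel_size_nm: float
    z_interval_um: float
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture <= 2:
            raise ValueError("numerical aperture must lie in (0, 2]")
        if self.frame_averaging < 1:
            raise ValueError("frame averaging must be >= 1")


# ---------------------------------------------------------------- stacks

def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multipage uncompressed TIFF with JSON calibration."""
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "z_step_um": stack.z_step_um,
        "bit_depth": stack.bit_depth,
        "channel_name": stack.channel_name,
        "gain": stack.gain,
        "offset": stack.offset,
    }
    tifffile.imwrite(
        str(path),
        stack.voxels,
        compression=None,
        photometric="minisblack",
        description=json.dumps(meta),
        metadata=None,
    )


def read_stack(path) -> ImageStack:
    """Read a multipage TIFF stack written by :func:`write_stack`."""
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            pages = tf.pages
            arrays = []
            for i, page in enumerate(pages):
                if page.compression not in (1, tifffile.COMPRESSION.NONE):
                    raise FormatError(f"{path}: page {i} is compressed; only uncompressed TIFF is supported")
                arrays.append(page.asarray())
            desc = tf.pages[0].description or "{}"
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises assorted errors on corrupt input
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise FormatError(f"{path}: pages have differing shapes {sorted(shapes)}")
    voxels = np.stack(arrays)
    if voxels.ndim == 2:
        voxels = voxels[None]
    try:
        meta = json.loads(desc)
        if not isinstance(meta, dict):
            meta = {}
    except json.JSONDecodeError:
        meta = {}
    return ImageStack(
        voxels=voxels,
        pixel_size_nm=float(meta.get("pixel_size_nm", 0.0) or 0.0),
        z_step_um=float(meta.get("z_step_um", 0.0) or 0.0),
        bit_depth=int(meta.get("bit_depth", 8 * voxels.dtype.itemsize)),
        channel_name=str(meta.get("channel_name", "")),
        gain=meta.get("gain"),
        offset=meta.get("offset"),
    )


# ---------------------------------------------------------------- settings

_MANDATORY_SETTINGS = {
    "objective_magnification": float,
    "numerical_aperture": float,
    "gain": float,
    "offset": float,
    "frame_averaging": int,
    "pixel_size_nm": float,
    "z_interval_um": float,
}


def write_settings(meta: AcquisitionMetadata, path) -> None:
    """Write microscope settings in the KEY<TAB>VALUE dialect."""
    lines = []
    for key in _MANDATORY_SETTINGS:
        lines.append(f"{key}\t{getattr(meta, key):g}")
    for key, value in meta.extras.items():
        lines.append(f"{key}\t{value}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_settings(path) -> AcquisitionMetadata:
    """Parse a settings text file; unknown keys land in ``extras``."""
    path = Path(path)
    fields: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" not in line:
            raise FormatError(f"{path}:{ln}: expected KEY<TAB>VALUE, got {line!r}")
        key, value = line.split("\t", 1)
        fields[key.strip()] = value.strip()
    kwargs = {}
    for key, conv in _MANDATORY_SETTINGS.items():
        if key not in fields:
            raise FormatError(f"{path}: missing mandatory settings key {key!r}")
        try:
            kwargs[key] = conv(float(fields.pop(key)))
        except ValueError as exc:
            raise FormatError(f"{path}: key {key!r} is not numeric") from exc
    return AcquisitionMetadata(**kwargs, extras=fields)


# ---------------------------------------------------------------- sampled data

SAMPLED_COLUMNS_XY = ["target", "patient", "x_px", "y_px", "z_index", "intensity", "layer"]
SAMPLED_COLUMNS_NORMALISED = SAMPLED_COLUMNS_XY + ["u"]


def _fmt_real(x: float) -> str:
    return f"{x:.6g}"


def write_sampled(table: pd.DataFrame, path, format: str = "normalised") -> None:
    """Write a sampled-record table as TSV.

    ``format='xy'`` writes the coordinate format (no ``u`` column, which is
    dropped if present); ``format='normalised'`` requires ``u``.
    """
    if format == "xy":
        cols = SAMPLED_COLUMNS_XY
    elif format == "normalised":
        if "u" not in table.columns:
            raise ValueError("normalised format requires the u column")
        cols = SAMPLED_COLUMNS_NORMALISED
    else:
        raise ValueError(f"unknown sampled format {format!r}")
    missing = [c for c in cols if c != "u" and c not in table.columns]
    if missing:
        raise ValueError(f"sampled table missing columns: {missing}")
    out = table.loc[:, cols].copy()
    out["layer"] = out["layer"].map(
        lambda v: v.value if isinstance(v, LayerLabel) else str(v)
    )
    for col in ("intensity", "u"):
        if col in out.columns:
            out[col] = out[col].map(_fmt_real)
    out.to_csv(path, sep="\t", index=False)


def read_sampled(path) -> pd.DataFrame:
    """Read a sampled-record TSV (either format); layer parsed to LayerLabel."""
    df = pd.read_csv(path, sep="\t")
    expected = set(SAMPLED_COLUMNS_XY)
    if not expected.issubset(df.columns):
        raise FormatError(
            f"{path}: missing sampled columns {sorted(expected - set(df.columns))}"
        )
    if len(df):
        df["layer"] = df["layer"].map(LayerLabel)
    else:
        df["layer"] = df["layer"].astype(object)
    for col in ("x_px", "y_px", "z_index"):
        df[col] = df[col].astype(int)
    return df


def points_to_table(points, target: str = "", patient: str = "") -> pd.DataFrame:
    """Convert a list of :class:`~stratiquant.transform.SampledPoint` to a table."""
    return pd.DataFrame(
        {
            "target": target,
            "patient": patient,
            "x_px": [p.x_px for p in points],
            "y_px": [p.y_px for p in points],
            "z_index": [p.z_index for p in points],
            "intensity": [p.intensity for p in points],
            "layer": [p.layer for p in points],
            "u": [p.u for p in points],
        }
    )


# ---------------------------------------------------------------- boundaries

def write_boundaries(b: LayerBoundarySet, path) -> None:
    """Write boundary polylines as TSV (boundary_index, vertex_index, x, y)."""
    rows = []
    for bi, poly in enumerate(b.boundaries):
        for vi, (x, y) in enumerate(poly):
            rows.append((bi, vi, _fmt_real(x), _fmt_real(y)))
    pd.DataFrame(rows, columns=["boundary_index", "vertex_index", "x_px", "y_px"]).to_csv(
        path, sep="\t", index=False
    )


def read_boundaries(path, frame_shape: tuple[int, int]) -> LayerBoundarySet:
    """Read a boundary TSV back into an (unvalidated) LayerBoundarySet."""
    df = pd.read_csv(path, sep="\t")
    needed = {"boundary_index", "vertex_index", "x_px", "y_px"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: missing boundary columns {sorted(needed - set(df.columns))}")
    polys = []
    for bi in range(4):
        sub = df[df["boundary_index"] == bi].sort_values("vertex_index")
        if sub.empty:
            raise FormatError(f"{path}: boundary {bi} has no vertices")
        polys.append(sub[["x_px", "y_px"]].to_numpy(dtype=float))
    return LayerBoundarySet(polys, frame_shape=frame_shape)


# ---------------------------------------------------------------- masks

def write_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = mask.astype(np.uint8)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be boolean or integer valued")
    tifffile.imwrite(str(path), mask, compression=None, metadata=None)


def read_mask(path) -> np.ndarray:
    """Read a binary or labelled mask TIFF; 0 = background."""
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: mask pixel type {arr.dtype} is not integer")
    return arr


# ---------------------------------------------------------------- profiles

def write_profile(profile, path) -> None:
    """Write a smoothed profile as TSV with a ``#`` header block."""
    header = (
        f"# span\t{_fmt_real(profile.span)}\n"
        f"# n_points\t{profile.n_points}\n"
        f"# normalisation_factor\t{_fmt_real(profile.normalisation_factor)}\n"
    )
    body = pd.DataFrame({"u": profile.grid, "fitted": profile.fitted})
    with open(path, "w") as fh:
        fh.write(header)
        body.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_profile(path):
    """Read a profile TSV written by :func:`write_profile`."""
    from .profiles import SmoothedProfile

    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, value = line[1:].strip().split("\t", 1)
                meta[key] = value
            else:
                rows.append(line)
    if not rows:
        raise FormatError(f"{path}: profile file has no data rows")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t")
    return SmoothedProfile(
        grid=df["u"].to_numpy(),
        fitted=df["fitted"].to_numpy(),
        span=float(meta.get("span", "nan")),
        n_points=int(meta.get("n_points", "0")),
        normalisation_factor=float(meta.get("normalisation_factor", "nan")),
    )
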