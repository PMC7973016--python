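"""Movie, map and metric I/O for optical-mapping analysis.

Conventions used throughout the package:

* Movies are 3D arrays indexed ``[frame, row, col]`` (time first).
* 2D maps are indexed ``[row, col]``, origin at the top-left, 0-based.
* The tissue mask is a boolean ``[row, col]`` array, ``True`` = tissue.

Supported on-disk formats are multi-page TIFF stacks and raw binary files,
each accompanied by a YAML sidecar header declaring dtype, shape, frame
rate and pixel pitch.  Scalar maps round-trip through CSV or ``.npy``;
PNG renders use a fixed colour convention (binary dispersion maps: green
below threshold, yellow above, black outside the mask).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

logger = logging.getLogger("apdisp")

CHAMBERS = ("atrium", "ventricle", "unknown")

#: fixed colours for binary dispersion renders (RGB)
BINARY_COLORS = {
    "below": (0, 170, 0),     # green: dispersion <= threshold
    "above": (255, 215, 0),   # yellow: dispersion > threshold
    "background": (0, 0, 0),  # outside mask / invalid
}


class FormatError(ValueError):
    """File is unreadable or its size is inconsistent with its header."""


class MetadataError(ValueError):
    """Header metadata contradicts the stored array."""


@dataclass
class AcquisitionMeta:
    """Acquisition metadata for one optical-mapping movie.

    Defaults mirror a MiCAM-style CMOS acquisition: 1,000 frames/s at
    100 x 100 pixels with 0.095 mm pixel pitch.
    """

    frame_rate_hz: float = 1000.0
    pixel_pitch_mm: float = 0.095
    n_frames: int = 0
    height: int = 100
    width: int = 100
    subject_label: str = ""
    chamber: str = "unknown"

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise MetadataError("frame_rate_hz must be positive")
        if self.pixel_pitch_mm <= 0:
            raise MetadataError("pixel_pitch_mm must be positive")
        if self.chamber not in CHAMBERS:
            raise MetadataError(f"chamber must be one of {CHAMBERS}")

    @property
    def dt_ms(self) -> float:
        """Frame interval in milliseconds."""
        return 1000.0 / self.frame_rate_hz

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VoltageMovie:
    """A calibrated voltage-fluorescence recording.

    ``data`` is ``[frame, row, col]`` in arbitrary fluorescence units;
    ``mask`` marks tissue pixels.  Pixels whose signal is unusable (flat
    traces after preprocessing) are removed from the mask rather than
    tracked separately.
    """

    data: np.ndarray
    meta: AcquisitionMeta
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise MetadataError("movie data must be 3D [frame, row, col]")
        t, h, w = self.data.shape
        if (self.meta.n_frames, self.meta.height, self.meta.width) != (t, h, w):
            raise MetadataError(
                f"header shape {(self.meta.n_frames, self.meta.height, self.meta.width)} "
                f"does not match array shape {(t, h, w)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("movie contains non-finite values")
        if self.mask is None:
            self.mask = np.ones((h, w), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (h, w):
            raise MetadataError("mask shape must match frame shape")
        if not self.mask.any():
            raise MetadataError("mask contains no tissue pixels")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.meta.frame_rate_hz

    def times_ms(self) -> np.ndarray:
        """Frame times in ms from recording start."""
        return np.arange(self.n_frames) * self.meta.dt_ms


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _meta_from_header(header: dict) -> AcquisitionMeta:
    fields = {k: header[k] for k in
              ("frame_rate_hz", "pixel_pitch_mm", "n_frames", "height", "width")
              if k in header}
    for opt in ("subject_label", "chamber"):
        if opt in header:
            fields[opt] = header[opt]
    return AcquisitionMeta(**fields)


def read_movie(path, format: str = "tiff_stack", sidecar=None, mask=None) -> VoltageMovie:
    """Read a movie from a TIFF stack or raw binary + YAML header.

    The YAML sidecar (``<file>.<ext>.yaml`` unless given explicitly) declares
    ``frame_rate_hz`` and ``pixel_pitch_mm``; for raw binary it must also
    declare ``dtype`` and the shape (``n_frames``, ``height``, ``width``).
    ``mask`` may be a boolean array or a path to a PNG/CSV mask (any value
    > 0 is tissue); if absent the mask defaults to all-true.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    header: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            header = yaml.safe_load(fh) or {}

    if format == "tiff_stack":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    elif format == "raw_binary":
        for key in ("dtype", "n_frames", "height", "width"):
            if key not in header:
                raise MetadataError(f"raw binary header missing '{key}'")
        dtype = np.dtype(header["dtype"])
        shape = (int(header["n_frames"]), int(header["height"]), int(header["width"]))
        expected = dtype.itemsize * int(np.prod(shape))
        actual = path.stat().st_size
        if actual != expected:
            raise MetadataError(
                f"file is {actual} bytes but header implies {expected}")
        data = np.fromfile(path, dtype=dtype).reshape(shape)
    else:
        raise ValueError(f"unknown movie format: {format}")

    header.setdefault("n_frames", data.shape[0])
    header.setdefault("height", data.shape[1])
    header.setdefault("width", data.shape[2])
    if (int(header["n_frames"]), int(header["height"]), int(header["width"])) != data.shape:
        raise MetadataError(
            f"header shape {(header['n_frames'], header['height'], header['width'])} "
            f"does not match movie shape {data.shape}")
    meta = _meta_from_header(header)

    if isinstance(mask, (str, Path)):
        mask = read_mask(mask)
    return VoltageMovie(data=np.asarray(data, dtype=float), meta=meta, mask=mask)


def write_movie(movie: VoltageMovie, path, format: str = "tiff_stack") -> None:
    """Write a movie plus its YAML sidecar header (lossless float64)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tiff_stack":
        tifffile.imwrite(path, movie.data)
    elif format == "raw_binary":
        movie.data.tofile(path)
    else:
        raise ValueError(f"unknown movie format: {format}")
    header = movie.meta.to_dict()
    header["dtype"] = str(movie.data.dtype)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=True)


def read_mask(path) -> np.ndarray:
    """Load a tissue mask from PNG (0/255) or CSV of 0/1; binarized at > 0."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
    else:
        arr = np.loadtxt(path, delimiter=",")
    return np.asarray(arr) > 0


def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)
    else:
        np.savetxt(path, mask.astype(int), fmt="%d", delimiter=",")


# ---------------------------------------------------------------------------
# scalar / boolean maps
# ---------------------------------------------------------------------------

def write_map(map2d: np.ndarray, path, format: str = "csv",
              valid: np.ndarray | None = None,
              threshold_binary: bool | None = None) -> None:
    """Write a 2D scalar or boolean map.

    csv and npy are lossless (invalid pixels stored as NaN in csv/npy for
    float maps).  PNG uses a fixed colour scale: binary maps render
    green (below) / yellow (above) / black (background); continuous maps
    use the viridis colormap over the valid range.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    map2d = np.asarray(map2d)
    is_binary = map2d.dtype == bool if threshold_binary is None else threshold_binary

    if format == "csv":
        out = map2d.astype(float).copy()
        if valid is not None:
            out[~valid] = np.nan
        np.savetxt(path, out, fmt="%.17g", delimiter=",")
    elif format == "npy":
        out = map2d.astype(float).copy()
        if valid is not None:
            out[~valid] = np.nan
        np.save(path, out)
    elif format == "png":
        h, w = map2d.shape
        rgb = np.zeros((h, w, 3), dtype=np.uint8)
        rgb[:] = BINARY_COLORS["background"]
        vmask = np.ones((h, w), dtype=bool) if valid is None else valid.astype(bool)
        vmask = vmask & np.isfinite(map2d.astype(float))
        if is_binary:
            above = map2d.astype(bool)
            rgb[vmask & ~above] = BINARY_COLORS["below"]
            rgb[vmask & above] = BINARY_COLORS["above"]
        else:
            import matplotlib.cm as cm
            vals = map2d.astype(float)
            if vmask.any():
                lo, hi = np.nanmin(vals[vmask]), np.nanmax(vals[vmask])
                span = hi - lo if hi > lo else 1.0
                norm = np.clip((vals - lo) / span, 0, 1)
                colored = (cm.viridis(norm)[..., :3] * 255).astype(np.uint8)
                rgb[vmask] = colored[vmask]
        Image.fromarray(rgb, mode="RGB").save(path)
    else:
        raise ValueError(f"unknown map format: {format}")


def read_map(path, format: str = "csv") -> np.ndarray:
    """Read a 2D map written by :func:`write_map` (csv or npy)."""
    path = Path(path)
    if format == "csv":
        return np.atleast_2d(np.loadtxt(path, delimiter=","))
    if format == "npy":
        return np.load(path)
    raise ValueError(f"unknown map format: {format}")


# ---------------------------------------------------------------------------
# tidy metrics tables
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["subject_label", "chamber", "metric", "value"]


def write_metrics(records: list[dict], path, append: bool = False) -> None:
    """Write per-subject metric records as a tidy one-row-per-metric CSV.

    Each record needs ``subject_label``, ``chamber``, ``metric`` and
    ``value``.  Duplicate (subject, metric) pairs are kept and logged;
    append mode preserves column order.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    for rec in records:
        missing = [c for c in METRIC_COLUMNS if c not in rec]
        if missing:
            raise ValueError(f"metric record missing fields {missing}: {rec}")
        extra = [c for c in rec if c not in METRIC_COLUMNS]
        if extra:
            raise ValueError(f"unexpected fields {extra} collide with schema")
    df = pd.DataFrame(records, columns=METRIC_COLUMNS)
    dup = df.duplicated(subset=["subject_label", "metric"], keep=False)
    if dup.any():
        logger.warning("duplicate metric rows kept: %s",
                       df.loc[dup, ["subject_label", "metric"]].to_dict("records"))
    if append and path.exists():
        prev = pd.read_csv(path)
        if list(prev.columns) != METRIC_COLUMNS:
            raise ValueError(f"existing file {path} has incompatible columns")
        df = pd.concat([prev, df], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path)
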