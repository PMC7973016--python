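"""Windowed APD-dispersion maps, binarization, area fraction and islands.

Dispersion is the population standard deviation of APD across the
pixels of a sliding centered window (default 10 x 10); the alternative
``max_minus_min`` statistic implements the high-APD-gradient definition
(largest difference between a long and a neighboring short APD within
the window).  Maps are binarized with a strict ``> threshold`` rule
(default 10 ms) and quantified as the percent of computable tissue
above threshold; supra-threshold islands are extracted as 8-connected
components with shape descriptors.

Window convention: an even window is centered with the extra row and
column on the bottom/right, so a width-10 window at pixel (i, j) spans
rows i-4..i+5 and columns j-4..j+5.  Pixels whose window holds fewer
than 50% valid neighbors (relative to the full window area) are marked
invalid, which suppresses edge artifacts at the tissue border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from skimage.measure import label, regionprops

from .signal import APDMap

STATISTICS = ("std", "max_minus_min")

#: shape-classification conventions (the source taxonomy names the shapes
#: without metrics): serpiginous if elongated or strongly non-convex
SERPIGINOUS_ELONGATION = 3.0
SERPIGINOUS_SOLIDITY = 0.6


@dataclass
class DispersionMap:
    """Windowed APD dispersion (ms) with the window/statistic that made it."""

    values: np.ndarray
    window_px: int
    statistic: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.window_px < 2:
            raise ValueError("window_px must be >= 2")
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("dispersion values must be >= 0")


@dataclass
class BinaryDispersionMap:
    """Thresholded dispersion map: True where dispersion > threshold."""

    above: np.ndarray
    threshold_ms: float
    source_statistic: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.above = np.asarray(self.above, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(self.above & ~self.valid):
            raise ValueError("above pixels must lie inside the valid region")


@dataclass
class Island:
    """One 8-connected supra-threshold component."""

    id: int
    pixel_count: int
    area_mm2: float
    centroid: tuple[float, float]
    elongation: float
    solidity: float
    shape_label: str


@dataclass
class IslandSet:
    islands: list[Island] = dc_field(default_factory=list)
    labels: np.ndarray = dc_field(default_factory=lambda: np.zeros((0, 0), dtype=int))

    def __len__(self) -> int:
        return len(self.islands)

    def centroids(self) -> np.ndarray:
        if not self.islands:
            return np.empty((0, 2))
        return np.array([isl.centroid for isl in self.islands])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": i.id, "pixel_count": i.pixel_count, "area_mm2": i.area_mm2,
              "centroid_row": i.centroid[0], "centroid_col": i.centroid[1],
              "elongation": i.elongation, "solidity": i.solidity,
              "shape_label": i.shape_label} for i in self.islands],
            columns=["id", "pixel_count", "area_mm2", "centroid_row",
                     "centroid_col", "elongation", "solidity", "shape_label"])


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def _window_views(arr: np.ndarray, valid: np.ndarray, window_px: int,
                  fill: float = 0.0):
    """Sliding (H, W, w, w) views of arr (filled) and validity, centered
    with the bottom/right convention for even windows."""
    lo = (window_px - 1) // 2
    hi = window_px // 2
    filled = np.where(valid, arr, fill)
    pad_a = np.pad(filled, ((lo, hi), (lo, hi)), constant_values=fill)
    pad_v = np.pad(valid, ((lo, hi), (lo, hi)), constant_values=False)
    return (sliding_window_view(pad_a, (window_px, window_px)),
            sliding_window_view(pad_v, (window_px, window_px)))


def dispersion_map(apd: APDMap, window_px: int = 10,
                   statistic: str = "std") -> DispersionMap:
    """Sliding-window dispersion of an APD map.

    ``std`` is the population (divide-by-n) standard deviation of the
    valid APDs in each window; ``max_minus_min`` is their range.  A
    pixel is valid only when at least 50% of its full window area holds
    valid APDs.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    h, w = apd.values.shape
    if window_px > min(h, w):
        raise ValueError(f"window {window_px} exceeds map size {(h, w)}")
    if window_px < 2:
        raise ValueError("window_px must be >= 2")

    aw, vw = _window_views(apd.values, apd.valid, window_px)
    n = vw.sum(axis=(2, 3)).astype(float)
    min_valid = 0.5 * window_px * window_px
    ok = n >= min_valid

    with np.errstate(invalid="ignore", divide="ignore"):
        if statistic == "std":
            s1 = (aw * vw).sum(axis=(2, 3))
            s2 = (aw * aw * vw).sum(axis=(2, 3))
            mean = s1 / n
            var = np.maximum(s2 / n - mean * mean, 0.0)
            vals = np.sqrt(var)
        else:
            big = np.where(vw, aw, -np.inf).max(axis=(2, 3))
            small = np.where(vw, aw, np.inf).min(axis=(2, 3))
            vals = big - small
    vals = np.where(ok, vals, np.nan)
    return DispersionMap(values=vals, window_px=window_px,
                         statistic=statistic, valid=ok)


def gradient_map(apd: APDMap, window_px: int = 10) -> DispersionMap:
    """High-APD-gradient map: windowed (max - min) of valid APDs."""
    return dispersion_map(apd, window_px=window_px, statistic="max_minus_min")


# ---------------------------------------------------------------------------
# binarization and quantification
# ---------------------------------------------------------------------------

def binarize(dmap: DispersionMap, threshold_ms: float = 10.0) -> BinaryDispersionMap:
    """Strict threshold: True exactly where dispersion > threshold."""
    if threshold_ms < 0:
        raise ValueError("threshold must be >= 0")
    with np.errstate(invalid="ignore"):
        above = dmap.valid & (dmap.values > threshold_ms)
    return BinaryDispersionMap(above=above, threshold_ms=threshold_ms,
                               source_statistic=dmap.statistic, valid=dmap.valid)


def area_fraction(bmap: BinaryDispersionMap, mask: np.ndarray | None = None) -> float:
    """Percent of computable tissue with dispersion above threshold.

    The denominator is the tissue mask restricted to pixels where the
    dispersion statistic was computable.
    """
    denom = bmap.valid if mask is None else (np.asarray(mask, dtype=bool) & bmap.valid)
    n = int(denom.sum())
    if n == 0:
        raise ValueError("mask holds no computable pixels")
    return 100.0 * int((bmap.above & denom).sum()) / n


def extract_islands(bmap: BinaryDispersionMap, pixel_pitch_mm: float) -> IslandSet:
    """8-connected supra-threshold components with shape descriptors.

    ``elongation`` is the major/minor axis ratio of the second-moment
    ellipse; islands with elongation > 3 or solidity < 0.6 are labelled
    serpiginous, otherwise ovoid.
    """
    labels = label(bmap.above, connectivity=2)
    islands = []
    for rp in regionprops(labels):
        minor = rp.axis_minor_length
        elong = rp.axis_major_length / minor if minor > 0 else np.inf
        sol = rp.solidity
        shape = ("serpiginous"
                 if (elong > SERPIGINOUS_ELONGATION or sol < SERPIGINOUS_SOLIDITY)
                 else "ovoid")
        islands.append(Island(
            id=int(rp.label), pixel_count=int(rp.area),
            area_mm2=float(rp.area) * pixel_pitch_mm ** 2,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            elongation=float(elong), solidity=float(sol), shape_label=shape))
    return IslandSet(islands=islands, labels=labels)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_stats(values, null_value: float = 0.0) -> dict:
    """Mean, SEM and a two-sided one-sample t-test against ``null_value``.

    With zero variance the test is degenerate: t = 0 and p = 1 when the
    common value equals the null, otherwise t = +/-inf and p = 0 (with a
    warning either way).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("group statistics need at least 2 subjects")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    if sem == 0.0:
        warnings.warn("zero within-group variance: t-test degenerate", stacklevel=2)
        if mean == null_value:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean - null_value)) * np.inf, 0.0
    else:
        res = stats.ttest_1samp(values, popmean=null_value)
        t, p = float(res.statistic), float(res.pvalue)
    return {"n": int(n), "mean": mean, "sem": sem, "t": t, "df": int(n - 1),
            "p": p, "significant": bool(p < 0.05)}
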