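"""Spatial statistics operationalizing the uniform/random/clustered taxonomy.

Three complementary statistics are computed on the high-dispersion
islands and map:

* quadrat variance-to-mean ratio (VMR, index of dispersion) of island
  centroid counts in grid cells — ~1 under complete spatial randomness
  (CSR), > 1 clustered, < 1 regular;
* Clark-Evans nearest-neighbor index R — observed over expected mean
  nearest-neighbor distance; < 1 clustered, > 1 regular;
* Moran's I spatial autocorrelation of the continuous dispersion map
  under rook or queen contiguity weights.

The rule-based classifier labels a pattern clustered when the VMR is
significantly above 1 (one-sided chi-square at level alpha) and R < 1,
uniform when the VMR is significantly below 1 and R > 1, random when
the CSR null is not rejected, and indeterminate when the two statistics
conflict or there are too few islands.  The taxonomy itself is verbal
in origin; every threshold here is an explicit, configurable convention
of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .dispersion import DispersionMap

LABELS = ("uniform", "random", "clustered", "indeterminate")
MIN_POINTS = 5

#: Clark-Evans nearest-neighbor SE constant: sqrt((4 - pi) / (4 * pi))
_CE_SE = 0.26136


@dataclass
class PatternReport:
    """Spatial statistics and the resulting pattern label."""

    vmr: float
    vmr_chi2: float
    vmr_p: float
    n_quadrats: int
    clark_evans_r: float
    ce_z: float
    morans_i: float
    label: str
    n_islands: int
    quadrat_size_px: int
    alpha: float


# ---------------------------------------------------------------------------
# quadrat index of dispersion
# ---------------------------------------------------------------------------

def quadrat_vmr(centroids: np.ndarray, region: np.ndarray | None = None,
                quadrat_size_px: int = 20):
    """Variance-to-mean ratio of quadrat counts.

    The region (a boolean mask, or the points' bounding box when absent)
    is tiled with ``quadrat_size_px`` squares from the top-left; quadrats
    with less than 50% of their area inside the region are dropped, and
    points falling in dropped quadrats are ignored.  VMR uses the
    population variance of the counts; the test statistic is the exact
    Pearson index of dispersion ``sum((x - mean)^2) / mean`` (equal to
    ``VMR * n_quadrats``), whose expectation under complete spatial
    randomness with the total count fixed is exactly ``n_quadrats - 1``;
    it is referred to a chi-square with ``n_quadrats - 1`` df
    (two-sided p).

    Returns ``(vmr, chi2, p, n_quadrats)``; all NaN (an indeterminate
    signal, not an exception) with fewer than 5 points.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    q = int(quadrat_size_px)
    if q < 1:
        raise ValueError("quadrat size must be >= 1")
    if region is not None:
        region = np.asarray(region, dtype=bool)
        h, w = region.shape
        r0 = c0 = 0.0
    else:
        if pts.shape[0] == 0:
            return np.nan, np.nan, np.nan, 0
        r0, c0 = pts.min(axis=0)
        h = float(np.ceil(pts[:, 0].max() - r0)) + 1
        w = float(np.ceil(pts[:, 1].max() - c0)) + 1

    n_rows = int(np.ceil(h / q))
    n_cols = int(np.ceil(w / q))
    counts = []
    for bi in range(n_rows):
        for bj in range(n_cols):
            rlo, rhi = r0 + bi * q, r0 + (bi + 1) * q
            clo, chi = c0 + bj * q, c0 + (bj + 1) * q
            if region is not None:
                cell = region[int(rlo):int(min(rhi, h)), int(clo):int(min(chi, w))]
                if cell.sum() < 0.5 * q * q:
                    continue
            else:
                # bounding-box region: drop quadrats mostly outside the box
                inside = (min(rhi, r0 + h) - rlo) * (min(chi, c0 + w) - clo)
                if inside < 0.5 * q * q:
                    continue
            in_cell = ((pts[:, 0] >= rlo) & (pts[:, 0] < rhi)
                       & (pts[:, 1] >= clo) & (pts[:, 1] < chi))
            counts.append(int(in_cell.sum()))
    counts = np.asarray(counts, dtype=float)
    n_quadrats = counts.size
    if pts.shape[0] < MIN_POINTS or n_quadrats < 2 or counts.sum() == 0:
        return np.nan, np.nan, np.nan, int(n_quadrats)
    mean = counts.mean()
    vmr = counts.var() / mean                     # population variance
    chi2 = vmr * n_quadrats                       # Pearson index of dispersion
    df = n_quadrats - 1
    p = 2.0 * min(stats.chi2.cdf(chi2, df), stats.chi2.sf(chi2, df))
    return float(vmr), float(chi2), float(min(p, 1.0)), int(n_quadrats)


# ---------------------------------------------------------------------------
# Clark-Evans nearest-neighbor index
# ---------------------------------------------------------------------------

def clark_evans(centroids: np.ndarray, region_area: float | None = None,
                edge_correction: str = "none",
                region_shape: tuple[int, int] | None = None):
    """Clark-Evans aggregation index R and its normal-approximation z.

    ``R = mean observed NN distance / (0.5 / sqrt(density))`` with
    density = n / region area (bounding-box area when not given).
    ``edge_correction='guard'`` drops points closer to the region
    boundary than the expected NN distance from the numerator (their
    neighbors still count), reducing the positive bias of border points.

    Returns ``(R, z)``; NaN with fewer than 5 points.
    """
    if edge_correction not in ("none", "guard"):
        raise ValueError("edge_correction must be 'none' or 'guard'")
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n < MIN_POINTS:
        return np.nan, np.nan
    if region_shape is not None:
        bounds_lo = np.array([0.0, 0.0])
        bounds_hi = np.array(region_shape, dtype=float)
    else:
        bounds_lo = pts.min(axis=0)
        bounds_hi = pts.max(axis=0)
    if region_area is None:
        span = np.maximum(bounds_hi - bounds_lo, 1e-12)
        region_area = float(span[0] * span[1])
    density = n / region_area
    expected = 0.5 / np.sqrt(density)

    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    nn = dists[:, 1]

    if edge_correction == "guard":
        d_edge = np.minimum(pts - bounds_lo, bounds_hi - pts).min(axis=1)
        keep = d_edge >= expected
        if keep.sum() >= MIN_POINTS:
            nn = nn[keep]
    m = nn.size
    observed = float(nn.mean())
    r = observed / expected
    se = _CE_SE / np.sqrt(m * density)
    z = (observed - expected) / se
    return float(r), float(z)


# ---------------------------------------------------------------------------
# Moran's I on the continuous map
# ---------------------------------------------------------------------------

_ROOK = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN = _ROOK + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def morans_i(dmap, weights: str = "rook") -> float:
    """Moran's I of a dispersion map under grid-contiguity weights.

    Accepts a :class:`~apdisp.dispersion.DispersionMap` or a plain 2D
    array (all-finite pixels valid).  Returns NaN for a zero-variance
    map or fewer than 9 valid pixels (an indeterminate signal).
    """
    if weights == "rook":
        offsets = _ROOK
    elif weights == "queen":
        offsets = _QUEEN
    else:
        raise ValueError("weights must be 'rook' or 'queen'")
    if isinstance(dmap, DispersionMap):
        vals, valid = dmap.values, dmap.valid
    else:
        vals = np.asarray(dmap, dtype=float)
        valid = np.isfinite(vals)
    n = int(valid.sum())
    if n < 9:
        return np.nan
    z = np.where(valid, vals - vals[valid].mean(), 0.0)
    denom = float((z[valid] ** 2).sum())
    if denom == 0.0:
        return np.nan

    num = 0.0
    wsum = 0.0
    for di, dj in offsets:
        zi = z
        vi = valid
        zj = np.roll(np.roll(z, di, axis=0), dj, axis=1)
        vj = np.roll(np.roll(valid, di, axis=0), dj, axis=1)
        # forbid wrap-around pairs
        edge = np.ones_like(valid)
        if di == 1:
            edge[0, :] = False
        elif di == -1:
            edge[-1, :] = False
        if dj == 1:
            edge[:, 0] = False
        elif dj == -1:
            edge[:, -1] = False
        pair = vi & vj & edge
        num += float((zi * zj)[pair].sum())
        wsum += float(pair.sum())
    if wsum == 0.0:
        return np.nan
    return (n / wsum) * (num / denom)


# ---------------------------------------------------------------------------
# rule-based classification
# ---------------------------------------------------------------------------

def classify_pattern(centroids: np.ndarray, region: np.ndarray | None = None,
                     dmap=None, alpha: float = 0.05,
                     quadrat_size_px: int = 20,
                     edge_correction: str = "none",
                     weights: str = "rook") -> PatternReport:
    """Label an island point pattern uniform / random / clustered.

    Decision rule (all inputs recorded in the report): clustered when
    the one-sided chi-square on the quadrat VMR rejects upward at
    ``alpha`` and R < 1; uniform when it rejects downward and R > 1;
    random when neither direction rejects; indeterminate when the VMR
    and Clark-Evans signals conflict or fewer than 5 islands exist.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n_islands = pts.shape[0]
    region_shape = region.shape if region is not None else None
    region_area = float(region.sum()) if region is not None else None
    vmr, chi2, p_two, n_quadrats = quadrat_vmr(pts, region, quadrat_size_px)
    r, z = clark_evans(pts, region_area=region_area,
                       edge_correction=edge_correction,
                       region_shape=region_shape)
    mi = morans_i(dmap, weights=weights) if dmap is not None else np.nan

    if n_islands < MIN_POINTS or not np.isfinite(vmr) or not np.isfinite(r):
        lab = "indeterminate"
    else:
        df = n_quadrats - 1
        p_up = float(stats.chi2.sf(chi2, df))    # evidence of clustering
        p_down = float(stats.chi2.cdf(chi2, df))  # evidence of regularity
        if p_up < alpha:
            lab = "clustered" if r < 1.0 else "indeterminate"
        elif p_down < alpha:
            lab = "uniform" if r > 1.0 else "indeterminate"
        else:
            lab = "random"
    return PatternReport(vmr=float(vmr), vmr_chi2=float(chi2), vmr_p=float(p_two),
                         n_quadrats=int(n_quadrats), clark_evans_r=float(r),
                         ce_z=float(z), morans_i=float(mi), label=lab,
                         n_islands=int(n_islands),
                         quadrat_size_px=int(quadrat_size_px), alpha=float(alpha))
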