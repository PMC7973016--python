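"""Per-pixel signal conditioning, activation detection and APD mapping.

The action potential duration at repolarization level L (APD_L) is
measured from the 50%-amplitude upstroke crossing to the first downward
crossing of ``1 - L/100`` of that beat's baseline-to-peak amplitude,
with linear interpolation between frames for sub-frame resolution.
Amplitude is referenced per beat (local baseline to local peak) so the
measurement is invariant to affine rescaling of the raw trace and
tolerant of residual drift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.ndimage import uniform_filter, uniform_filter1d

from .io import AcquisitionMeta, VoltageMovie

logger = logging.getLogger("apdisp")

REFRACTORY_MS = 30.0      # lockout after each detected activation
UPSTROKE_LEVEL = 0.5      # activation fiducial: fraction of beat amplitude
BASELINE_LOOKBACK_MS = 20.0


@dataclass
class SignalConfig:
    """Signal-conditioning and APD-measurement parameters.

    ``repolarization_level_pct`` defaults to 90 (APD90, the usual
    optical-mapping convention); 50–90 are all meaningful and APD maps
    depend on the choice.  Filters of width <= 1 sample are no-ops.
    """

    spatial_filter_px: int = 3
    temporal_filter_ms: float = 5.0
    repolarization_level_pct: float = 90.0
    detrend: bool = True
    beat_policy: str = "median_over_beats"   # or "single_beat_index"
    beat_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.repolarization_level_pct < 100.0:
            raise ValueError("repolarization level must be in (0, 100)")
        if self.spatial_filter_px < 1 or self.spatial_filter_px % 2 == 0:
            raise ValueError("spatial filter width must be an odd integer >= 1")
        if self.temporal_filter_ms < 0:
            raise ValueError("temporal filter width must be >= 0")
        if self.beat_policy not in ("median_over_beats", "single_beat_index"):
            raise ValueError("unknown beat policy")


@dataclass
class APDMap:
    """Per-pixel APD (ms) at a stated repolarization level."""

    values: np.ndarray
    level_pct: float
    valid: np.ndarray
    meta: AcquisitionMeta
    n_beats_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")
        if np.any(self.values[self.valid] <= 0):
            raise ValueError("valid APD values must be positive")


@dataclass
class ActivationMap:
    """Local activation time per pixel (ms from beat onset), one beat."""

    times_ms: np.ndarray
    valid: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.times_ms)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(~np.isfinite(self.times_ms[self.valid])):
            raise ValueError("activation times must be finite where valid")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _baseline_detrend(data: np.ndarray) -> np.ndarray:
    """Remove a per-pixel linear trend fitted to below-median samples.

    Restricting the fit to each pixel's lower half keeps the large
    action-potential deflections from tilting the estimated baseline —
    an ordinary least-squares line through a short paced recording is
    dominated by the AP humps and distorts the repolarization tail.
    """
    t = np.arange(data.shape[0], dtype=float)[:, None, None]
    med = np.median(data, axis=0)
    w = (data <= med[None]).astype(float)
    n = w.sum(axis=0)
    tw = (w * t).sum(axis=0) / n
    vw = (w * data).sum(axis=0) / n
    tc = t - tw[None]
    num = (w * tc * (data - vw[None])).sum(axis=0)
    den = (w * tc * tc).sum(axis=0)
    slope = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return data - slope[None] * tc - vw[None]


def preprocess(movie: VoltageMovie, config: SignalConfig | None = None) -> VoltageMovie:
    """Condition a movie: detrend, temporal/spatial smoothing, normalize.

    Order: per-pixel linear detrend (if enabled), temporal moving
    average, spatial mean filter restricted to the mask, then per-pixel
    amplitude normalization to [0, 1] over the whole recording.  Pixels
    with (near-)flat traces are dropped from the mask rather than raising.
    """
    config = config or SignalConfig()
    data = movie.data.astype(float, copy=True)
    mask = movie.mask.copy()

    if config.detrend:
        data = _baseline_detrend(data)

    width = int(round(config.temporal_filter_ms * movie.meta.frame_rate_hz / 1000.0))
    if width > 1:
        data = uniform_filter1d(data, size=width, axis=0, mode="nearest")

    k = config.spatial_filter_px
    if k > 1:
        weight = mask.astype(float)[None]
        num = uniform_filter(data * weight, size=(1, k, k), mode="constant")
        den = uniform_filter(np.broadcast_to(weight, data.shape).copy(),
                             size=(1, k, k), mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            data = np.where(den > 0, num / den, 0.0)

    lo = data.min(axis=0)
    hi = data.max(axis=0)
    span = hi - lo
    flat = span <= 1e-12 * np.maximum(1.0, np.abs(hi))
    if np.any(flat & mask):
        logger.info("preprocess: %d flat pixels marked invalid", int((flat & mask).sum()))
    mask &= ~flat
    safe = np.where(span > 0, span, 1.0)
    data = (data - lo[None]) / safe[None]
    data[:, flat] = 0.0
    return VoltageMovie(data=data, meta=movie.meta, mask=mask)


# ---------------------------------------------------------------------------
# activation detection and APD measurement on single traces
# ---------------------------------------------------------------------------

def detect_beats(trace: np.ndarray, frame_rate_hz: float) -> list[int]:
    """Indices of upward 0.5-amplitude crossings with a 30 ms lockout.

    Expects a normalized trace in [0, 1].  Returns the sample index just
    before each accepted crossing, strictly increasing.
    """
    trace = np.asarray(trace, dtype=float)
    up = np.nonzero((trace[:-1] < UPSTROKE_LEVEL) & (trace[1:] >= UPSTROKE_LEVEL))[0]
    if up.size == 0:
        return []
    lockout = REFRACTORY_MS * frame_rate_hz / 1000.0
    accepted = [int(up[0])]
    for i in up[1:]:
        if i - accepted[-1] >= lockout:
            accepted.append(int(i))
    return accepted


def _interp_crossing(t0: float, v0: float, v1: float, level: float) -> float:
    """Sub-frame crossing position between samples t0 and t0+1."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0)


def compute_apd(trace: np.ndarray, activation_index: int, level_pct: float,
                frame_rate_hz: float, next_activation_index: int | None = None
                ) -> float:
    """APD_L (ms) for one beat, or NaN when repolarization is not reached.

    Amplitude is referenced to this beat: baseline = minimum over the
    20 ms preceding the upstroke, peak = maximum before the next beat.
    The activation fiducial is the interpolated 50%-amplitude upstroke
    crossing; APD ends at the first interpolated downward crossing of
    ``baseline + (1 - L/100) * amplitude`` after the peak.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    dt_ms = 1000.0 / frame_rate_hz
    i0 = int(activation_index)
    end = n if next_activation_index is None else int(next_activation_index)
    look = max(1, int(round(BASELINE_LOOKBACK_MS / dt_ms)))
    baseline = trace[max(0, i0 - look):i0 + 1].min()
    seg = trace[i0:end]
    if seg.size < 2:
        return np.nan
    peak_rel = int(np.argmax(seg))
    peak = seg[peak_rel]
    amp = peak - baseline
    if amp <= 0:
        return np.nan

    up_level = baseline + UPSTROKE_LEVEL * amp
    # refine the activation time around the detected index
    t_act = None
    for i in range(max(0, i0 - 2), min(n - 1, i0 + 3)):
        if trace[i] < up_level <= trace[i + 1]:
            t_act = _interp_crossing(i, trace[i], trace[i + 1], up_level)
            break
    if t_act is None:
        t_act = float(i0)

    rep_level = baseline + (1.0 - level_pct / 100.0) * amp
    below = np.nonzero(seg[peak_rel + 1:] < rep_level)[0]
    if below.size == 0:
        return np.nan  # repolarization not reached before the next beat
    j = peak_rel + 1 + below[0]           # first sample below the level
    t_rep = _interp_crossing(i0 + j - 1, seg[j - 1], seg[j], rep_level)
    apd = (t_rep - t_act) * dt_ms
    return apd if apd > 0 else np.nan


# ---------------------------------------------------------------------------
# whole-movie APD and activation maps
# ---------------------------------------------------------------------------

def compute_apd_map(movie: VoltageMovie, config: SignalConfig | None = None,
                    preprocessed: bool = False) -> APDMap:
    """Per-pixel APD map aggregated over beats.

    Runs :func:`preprocess` first unless ``preprocessed=True``.  The
    default beat policy takes the median APD across all complete beats;
    pixels where detection or repolarization fails are flagged invalid.
    """
    config = config or SignalConfig()
    if not preprocessed:
        movie = preprocess(movie, config)
    data, mask = movie.data, movie.mask
    fs = movie.meta.frame_rate_hz
    h, w = mask.shape
    values = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    n_beats_seen = 0

    rows, cols = np.nonzero(mask)
    for i, j in zip(rows, cols):
        trace = data[:, i, j]
        beats = detect_beats(trace, fs)
        if not beats:
            continue
        bounds = beats[1:] + [None]
        apds = [compute_apd(trace, b, config.repolarization_level_pct, fs, nb)
                for b, nb in zip(beats, bounds)]
        apds = [a for a in apds if np.isfinite(a)]
        if not apds:
            continue
        if config.beat_policy == "single_beat_index":
            if config.beat_index >= len(apds):
                continue
            values[i, j] = apds[config.beat_index]
            used = 1
        else:
            values[i, j] = float(np.median(apds))
            used = len(apds)
        valid[i, j] = values[i, j] > 0
        n_beats_seen = max(n_beats_seen, used)

    if not valid.any():
        warnings.warn("no pixel yielded a complete beat", stacklevel=2)
    return APDMap(values=values, level_pct=config.repolarization_level_pct,
                  valid=valid & mask, meta=movie.meta, n_beats_used=n_beats_seen)


def compute_activation_map(movie: VoltageMovie, config: SignalConfig | None = None,
                           beat_index: int = 0, preprocessed: bool = False
                           ) -> ActivationMap:
    """Interpolated activation time (ms) of one beat per pixel."""
    config = config or SignalConfig()
    if not preprocessed:
        movie = preprocess(movie, config)
    data, mask = movie.data, movie.mask
    fs = movie.meta.frame_rate_hz
    dt_ms = 1000.0 / fs
    h, w = mask.shape
    times = np.full((h, w), np.nan)
    rows, cols = np.nonzero(mask)
    for i, j in zip(rows, cols):
        trace = data[:, i, j]
        beats = detect_beats(trace, fs)
        if beat_index >= len(beats):
            continue
        b = beats[beat_index]
        times[i, j] = _interp_crossing(b, trace[b], trace[b + 1], UPSTROKE_LEVEL) * dt_ms
    return ActivationMap(times_ms=times)


def estimate_cv_map(activation: ActivationMap, pixel_pitch_mm: float,
                    window_px: int = 5, residual_tol_ms: float = 2.0,
                    min_slowness_ms_per_px: float = 1e-6) -> np.ndarray:
    """Local conduction speed (mm/ms) from a windowed plane fit.

    Fits ``t(row, col)`` with a least-squares plane over each centered
    ``window_px`` window of valid activation times; speed is the inverse
    gradient magnitude.  Pixels are NaN where the window is not fully
    valid, the fit residual exceeds ``residual_tol_ms`` (RMS), or the
    gradient is degenerate (simultaneous activation).
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 3")
    t = activation.times_ms
    ok = activation.valid
    h, w = t.shape
    half = window_px // 2
    dy, dx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    speed = np.full((h, w), np.nan)
    for i in range(half, h - half):
        for j in range(half, w - half):
            vw = ok[i - half:i + half + 1, j - half:j + half + 1]
            if not vw.all():
                continue
            tw = t[i - half:i + half + 1, j - half:j + half + 1]
            tc = tw - tw.mean()
            gx = (dx * tc).sum() / (dx * dx).sum()
            gy = (dy * tc).sum() / (dy * dy).sum()
            resid = tc - gx * dx - gy * dy
            if np.sqrt((resid ** 2).mean()) > residual_tol_ms:
                continue
            slow = np.hypot(gx, gy)          # ms per pixel
            if slow < min_slowness_ms_per_px:
                continue                      # zero gradient: speed undefined
            speed[i, j] = pixel_pitch_mm / slow
    return speed
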