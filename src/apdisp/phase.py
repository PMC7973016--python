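"""Dominant-frequency maps, phase maps and phase-singularity analysis.

Phase is extracted per pixel as the analytic-signal angle (Hilbert
transform of the mean-subtracted, detrended trace).  Phase
singularities — the organizational centers of reentry — are detected by
topological charge: the wrapped phase differences around each 2 x 2
pixel plaquette sum to +/- 2 pi exactly when the loop encloses a
singularity, the sign giving the chirality.  Per-frame detections are
aggregated into a singularity-point-density (SPD) map (visits per pixel
neighborhood per second), and the highest-SPD region can be compared
against a neighboring window of the APD map.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import detrend as sp_detrend, hilbert, periodogram

from .io import VoltageMovie
from .signal import APDMap


@dataclass
class DFMap:
    """Per-pixel dominant frequency (Hz) within a band."""

    freq_hz: np.ndarray
    power_fraction: np.ndarray
    band_hz: tuple[float, float]
    valid: np.ndarray

    def __post_init__(self) -> None:
        ok = self.valid
        f = self.freq_hz[ok]
        if f.size and (f.min() < self.band_hz[0] or f.max() > self.band_hz[1]):
            raise ValueError("dominant frequencies must lie within the band")
        pf = self.power_fraction[ok]
        if pf.size and (pf.min() < 0 or pf.max() > 1 + 1e-12):
            raise ValueError("power fraction must lie in [0, 1]")


@dataclass
class PhaseMovie:
    """Instantaneous phase in (-pi, pi] per pixel and frame."""

    phase: np.ndarray
    method: str = "hilbert_on_detrended"
    valid: np.ndarray = dc_field(default=None)  # type: ignore[assignment]
    frame_rate_hz: float = 1000.0
    #: frames trimmed from the start of the source movie
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.phase.shape[1:], dtype=bool)


@dataclass
class SingularitySet:
    """Per-frame singularity detections plus the aggregated SPD map.

    ``per_frame[k]`` is a list of ``(row, col, charge)`` with charge in
    {+1, -1}; positions are plaquette centers (half-integer grid).
    ``spd_map`` counts singularity visits within a smoothing window per
    pixel, divided by the recording duration (units: 1/s).
    """

    per_frame: list
    spd_map: np.ndarray
    window_px: int
    duration_s: float

    def total_count(self) -> int:
        return sum(len(f) for f in self.per_frame)

    def net_charge(self, frame: int) -> int:
        return sum(ch for _, _, ch in self.per_frame[frame])


# ---------------------------------------------------------------------------
# dominant frequency
# ---------------------------------------------------------------------------

def dominant_frequency_map(movie: VoltageMovie, band_hz=(1.0, 40.0)) -> DFMap:
    """Per-pixel dominant frequency from a Hann-window periodogram.

    The trace is linearly detrended first; DF is the frequency of
    maximum power within ``band_hz`` and ``power_fraction`` the share of
    band power concentrated in that peak.  Pixels with no power in the
    band (flat traces) are invalid.
    """
    fs = movie.meta.frame_rate_hz
    lo, hi = band_hz
    if hi > fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
    if movie.duration_s < 2.0 / max(lo, 1e-9) and movie.duration_s < 2.0:
        raise ValueError("recording too short for the requested band resolution")
    flat = movie.data.std(axis=0) <= 1e-10 * np.maximum(
        1.0, np.abs(movie.data).max(axis=0))
    freqs, pxx = periodogram(movie.data, fs=fs, window="hann",
                             detrend="linear", axis=0)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError("no periodogram bins inside the band")
    fband = freqs[sel]
    pband = pxx[sel]
    total = pband.sum(axis=0)
    peak_idx = pband.argmax(axis=0)
    peak_pow = np.take_along_axis(pband, peak_idx[None], axis=0)[0]
    valid = movie.mask & (total > 0) & ~flat
    freq = np.where(valid, fband[peak_idx], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        pf = np.where(valid, peak_pow / np.where(total > 0, total, 1.0), np.nan)
    return DFMap(freq_hz=freq, power_fraction=pf, band_hz=(lo, hi), valid=valid)


# ---------------------------------------------------------------------------
# phase
# ---------------------------------------------------------------------------

def phase_movie(movie: VoltageMovie, edge_trim_frames: int | None = None) -> PhaseMovie:
    """Analytic-signal phase of each pixel's mean-subtracted trace.

    The Hilbert transform is unreliable near the ends of a finite record
    (over a zone that scales with the dominant oscillation period), so
    ``edge_trim_frames`` (default: 5% of the recording, at least 2) are
    dropped from each end; ``PhaseMovie.frame_offset`` records the shift
    relative to the movie's frame numbering.
    """
    data = sp_detrend(movie.data, axis=0, type="linear")
    flat = data.std(axis=0) <= 1e-12
    trim = edge_trim_frames if edge_trim_frames is not None else max(2, data.shape[0] // 20)
    analytic = hilbert(data, axis=0)
    if trim > 0 and data.shape[0] > 2 * trim + 1:
        analytic = analytic[trim:-trim]
    else:
        trim = 0
    phase = np.angle(analytic)
    valid = movie.mask & ~flat
    return PhaseMovie(phase=phase, valid=valid,
                      frame_rate_hz=movie.meta.frame_rate_hz,
                      frame_offset=trim)


def _wrap(dp: np.ndarray) -> np.ndarray:
    return (dp + np.pi) % (2 * np.pi) - np.pi


def detect_singularities(pmovie: PhaseMovie, spd_window_px: int = 10) -> SingularitySet:
    """Topological-charge singularity detection on 2 x 2 plaquettes.

    For each frame and each plaquette the wrapped phase differences are
    summed counterclockwise around the loop; a sum of +/- 2 pi marks a
    singularity at the plaquette center with that sign as its charge.
    """
    phase = pmovie.phase
    n_frames, h, w = phase.shape
    vplaq = (pmovie.valid[:-1, :-1] & pmovie.valid[:-1, 1:]
             & pmovie.valid[1:, :-1] & pmovie.valid[1:, 1:])
    per_frame = []
    counts = np.zeros((h, w))
    for k in range(n_frames):
        p = phase[k]
        d1 = _wrap(p[:-1, 1:] - p[:-1, :-1])   # top edge, left -> right
        d2 = _wrap(p[1:, 1:] - p[:-1, 1:])     # right edge, top -> bottom
        d3 = _wrap(p[1:, :-1] - p[1:, 1:])     # bottom edge, right -> left
        d4 = _wrap(p[:-1, :-1] - p[1:, :-1])   # left edge, bottom -> top
        winding = (d1 + d2 + d3 + d4) / (2 * np.pi)
        hits = vplaq & (np.abs(winding) > 0.5)
        rows, cols = np.nonzero(hits)
        frame_list = []
        for i, j in zip(rows, cols):
            charge = int(np.sign(winding[i, j]))
            frame_list.append((i + 0.5, j + 0.5, charge))
            counts[i, j] += 1.0
        per_frame.append(frame_list)
    duration_s = n_frames / pmovie.frame_rate_hz
    k = int(spd_window_px)
    visits = uniform_filter(counts, size=k, mode="constant") * (k * k)
    spd_map = visits / max(duration_s, 1e-12)
    return SingularitySet(per_frame=per_frame, spd_map=spd_map,
                          window_px=k, duration_s=duration_s)


# ---------------------------------------------------------------------------
# highest-SPD-region vs neighbor comparison
# ---------------------------------------------------------------------------

def _window_stats(apd: APDMap, r0: int, c0: int, w: int) -> dict:
    vals = apd.values[r0:r0 + w, c0:c0 + w]
    ok = apd.valid[r0:r0 + w, c0:c0 + w]
    v = vals[ok]
    return {"mean_apd_ms": float(v.mean()), "max_apd_ms": float(v.max()),
            "std_apd_ms": float(v.std())}


def compare_spd_region(apd: APDMap, spd: SingularitySet,
                       window_px: int = 10) -> dict:
    """APD statistics of the highest-SPD window vs its nearest neighbor.

    Region A is the ``window_px`` square centered on the SPD-map maximum
    (clipped to the grid); region B is the nearest fully-valid,
    non-overlapping window of the same size, ties broken in
    row-then-column order.  Returns average, maximum and std of APD in
    both regions and their A - B differences.
    """
    h, w = apd.values.shape
    win = int(window_px)
    if win > min(h, w) // 2:
        raise ValueError("window too large for the map")
    peak = np.unravel_index(int(np.nanargmax(spd.spd_map)), spd.spd_map.shape)
    lo = (win - 1) // 2
    a_r = int(np.clip(peak[0] - lo, 0, h - win))
    a_c = int(np.clip(peak[1] - lo, 0, w - win))

    # candidate B windows: fully valid, non-overlapping with A
    best = None
    a_center = (a_r + (win - 1) / 2.0, a_c + (win - 1) / 2.0)
    for r in range(0, h - win + 1):
        overlap_r = (r < a_r + win) and (a_r < r + win)
        for c in range(0, w - win + 1):
            overlap_c = (c < a_c + win) and (a_c < c + win)
            if overlap_r and overlap_c:
                continue
            if not apd.valid[r:r + win, c:c + win].all():
                continue
            center = (r + (win - 1) / 2.0, c + (win - 1) / 2.0)
            d = np.hypot(center[0] - a_center[0], center[1] - a_center[1])
            key = (d, r, c)
            if best is None or key < best[0]:
                best = (key, r, c)
    if best is None:
        raise ValueError("no fully-valid non-overlapping neighbor window")
    b_r, b_c = best[1], best[2]

    if not apd.valid[a_r:a_r + win, a_c:a_c + win].any():
        raise ValueError("highest-SPD window holds no valid APD pixels")
    stats_a = _window_stats(apd, a_r, a_c, win)
    stats_b = _window_stats(apd, b_r, b_c, win)
    return {
        "region_a_origin": (a_r, a_c), "region_b_origin": (b_r, b_c),
        "region_a": stats_a, "region_b": stats_b,
        "difference": {k: stats_a[k] - stats_b[k] for k in stats_a},
    }
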