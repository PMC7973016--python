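"""Synthetic optical-mapping data with exact ground truth.

This module generates the inputs every downstream stage is tested
against: per-pixel APD fields in the three theoretical dispersion
patterns (uniform / random / clustered islands of prolonged APD),
paced voltage movies built from an analytic action-potential template,
and reentrant spiral-wave movies with known phase-singularity cores.

The action-potential template is a piecewise-smooth waveform (tanh
upstroke, short plateau, raised-cosine repolarization) parameterized
directly by the APD at the readout repolarization level, so the
duration each pixel should report is known exactly — no ionic model is
involved.  Islands are painted as discs (ovoid) or dilated
self-avoiding random walks (serpiginous); island centers are placed by
the standard point-process archetypes: jittered lattice (uniform),
homogeneous Poisson (random), Matern cluster process (clustered).

Everything is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.morphology import dilation, disk

from .io import AcquisitionMeta, VoltageMovie

PATTERNS = ("uniform", "random", "clustered", "constant")
SHAPES = ("ovoid", "serpiginous")


class InfeasibleFieldError(ValueError):
    """Requested islands would cover more than 90% of the grid."""


class FusionError(ValueError):
    """Pacing cycle length too short for the APD field (beats would fuse)."""


@dataclass
class IslandParams:
    """Geometry of the high-APD islands painted onto the baseline field.

    Island radius and APD elevation are synthetic conventions (the
    arrhythmic hearts motivating these patterns were not morphometrically
    quantified); the defaults put the supra-threshold dispersion area in
    the ~10% regime typical of fibrillation-prone tissue.
    """

    count: int = 25
    radius_px: float = 6.0
    elevation_ms: float = 25.0
    shape: str = "ovoid"
    #: Matern cluster process parameters (clustered pattern only)
    n_parents: int = 5
    cluster_radius_px: float = 10.0
    #: bias parent centers toward the tissue border (clustered pattern)
    edge_bias: bool = False
    #: lattice jitter as a fraction of lattice spacing (uniform pattern)
    jitter_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}")
        if self.count < 0:
            raise ValueError("island count must be >= 0")


@dataclass
class APDField:
    """Ground-truth per-pixel APD (ms) with its generating pattern."""

    values: np.ndarray
    pattern: str
    baseline_apd_ms: float
    island_params: IslandParams | None
    seed: int
    centers: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("APD values must be positive")
        if self.pattern == "constant" and np.ptp(self.values) != 0:
            raise ValueError("constant pattern requires zero spatial variance")


@dataclass
class GroundTruth:
    """Simulation truth carried alongside a synthetic movie."""

    apd_field: APDField
    activation_field: np.ndarray            # per-pixel activation delay, ms
    true_area_fraction_pct: float           # oracle windowed-std fraction
    singularity_locations: list             # per frame: list of (row, col)
    singularity_charges: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_area_fraction_pct <= 100.0:
            raise ValueError("area fraction must be in [0, 100]")


# ---------------------------------------------------------------------------
# island center placement
# ---------------------------------------------------------------------------

def _uniform_centers(rng, count, shape, jitter_frac):
    h, w = shape
    m = math.ceil(math.sqrt(count))
    sr, sc = h / m, w / m
    rows = (np.arange(m) + 0.5) * sr
    cols = (np.arange(m) + 0.5) * sc
    grid = np.array([(r, c) for r in rows for c in cols])
    grid = grid[rng.permutation(len(grid))[:count]]
    jitter = rng.uniform(-1, 1, size=grid.shape) * [jitter_frac * sr, jitter_frac * sc]
    return np.clip(grid + jitter, 0, [h - 1, w - 1])


def _random_centers(rng, count, shape):
    h, w = shape
    return np.column_stack([rng.uniform(0, h, count), rng.uniform(0, w, count)])


def _clustered_centers(rng, params: IslandParams, shape):
    """Matern cluster process: Poisson parents, offspring in a disc."""
    h, w = shape
    n_parents = max(1, params.n_parents)
    if params.edge_bias:
        # parents in a border band one cluster-radius wide
        band = max(params.cluster_radius_px, 2.0)
        parents = []
        while len(parents) < n_parents:
            p = rng.uniform(0, [h, w])
            d_edge = min(p[0], h - p[0], p[1], w - p[1])
            if d_edge <= band:
                parents.append(p)
        parents = np.array(parents)
    else:
        parents = np.column_stack(
            [rng.uniform(0, h, n_parents), rng.uniform(0, w, n_parents)])
    idx = rng.integers(0, n_parents, params.count)
    theta = rng.uniform(0, 2 * np.pi, params.count)
    rad = params.cluster_radius_px * np.sqrt(rng.uniform(0, 1, params.count))
    offs = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    pts = parents[idx] + offs
    return np.clip(pts, 0, [h - 1, w - 1])


# ---------------------------------------------------------------------------
# island painting
# ---------------------------------------------------------------------------

def _paint_disc(canvas, center, radius):
    h, w = canvas.shape
    rr, cc = np.ogrid[:h, :w]
    canvas |= (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _paint_serpiginous(canvas, center, radius, rng):
    """Dilated self-avoiding random walk: a wavy, snake-like island."""
    h, w = canvas.shape
    n_steps = max(4, int(round(4 * radius)))
    pos = np.round(np.asarray(center)).astype(int)
    visited = {tuple(pos)}
    path = [tuple(pos)]
    moves = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])
    for _ in range(n_steps):
        order = rng.permutation(4)
        for k in order:
            nxt = pos + moves[k]
            if 0 <= nxt[0] < h and 0 <= nxt[1] < w and tuple(nxt) not in visited:
                pos = nxt
                visited.add(tuple(pos))
                path.append(tuple(pos))
                break
        else:
            break  # walk trapped; keep what we have
    track = np.zeros_like(canvas)
    rows, cols = zip(*path)
    track[list(rows), list(cols)] = True
    width = max(1, int(round(radius / 2)))
    canvas |= dilation(track, disk(width)).astype(bool)


def generate_apd_field(pattern: str, grid=(100, 100), baseline_apd_ms: float = 50.0,
                       island_params: IslandParams | None = None,
                       seed: int = 0) -> APDField:
    """Generate a ground-truth APD field in one of the dispersion patterns.

    Patterns place island centers as: ``uniform`` — jittered regular
    lattice; ``random`` — homogeneous Poisson; ``clustered`` — Matern
    cluster process (with optional edge bias); ``constant`` — no islands.
    Pixels inside an island take ``baseline + elevation``; outside, the
    baseline.  Deterministic given the seed.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    h, w = grid
    rng = np.random.default_rng(seed)
    values = np.full((h, w), float(baseline_apd_ms))
    if pattern == "constant":
        return APDField(values, pattern, baseline_apd_ms, None, seed)

    params = island_params if island_params is not None else IslandParams()
    if params.radius_px >= min(h, w) / 2:
        raise ValueError("island radius must be < min(H, W) / 2")
    approx_cover = params.count * np.pi * params.radius_px ** 2 / (h * w)
    if approx_cover > 0.9:
        raise InfeasibleFieldError(
            f"requested islands would cover ~{100 * approx_cover:.0f}% of the grid")

    if pattern == "uniform":
        centers = _uniform_centers(rng, params.count, grid, params.jitter_frac)
    elif pattern == "random":
        centers = _random_centers(rng, params.count, grid)
    else:
        centers = _clustered_centers(rng, params, grid)

    canvas = np.zeros((h, w), dtype=bool)
    for c in centers:
        if params.shape == "ovoid":
            _paint_disc(canvas, c, params.radius_px)
        else:
            _paint_serpiginous(canvas, c, params.radius_px, rng)
    values[canvas] = baseline_apd_ms + params.elevation_ms
    return APDField(values, pattern, baseline_apd_ms, params, seed, centers=centers)


# ---------------------------------------------------------------------------
# generator-side oracle for the supra-threshold dispersion fraction
# ---------------------------------------------------------------------------

def oracle_area_fraction(values: np.ndarray, mask: np.ndarray | None = None,
                         window_px: int = 10, threshold_ms: float = 10.0) -> float:
    """Brute-force supra-threshold windowed-std area fraction (percent).

    Direct per-pixel double loop over centered ``window_px`` windows
    (even windows extend one extra row/column to the bottom/right),
    population std over in-mask pixels, windows with < 50% valid
    neighbors excluded.  Serves as the generator's own ground-truth
    oracle, deliberately independent of the dispersion module.
    """
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    mask = np.ones((h, w), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    lo = (window_px - 1) // 2
    hi = window_px // 2
    min_valid = 0.5 * window_px * window_px
    n_above = 0
    n_computable = 0
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            r0, r1 = max(0, i - lo), min(h, i + hi + 1)
            c0, c1 = max(0, j - lo), min(w, j + hi + 1)
            win = values[r0:r1, c0:c1][mask[r0:r1, c0:c1]]
            if win.size < min_valid:
                continue
            n_computable += 1
            if win.std() > threshold_ms:  # population std, strict >
                n_above += 1
    if n_computable == 0:
        return 0.0
    return 100.0 * n_above / n_computable


def field_with_target_fraction(target_pct: float, pattern: str = "clustered",
                               grid=(100, 100), baseline_apd_ms: float = 50.0,
                               island_params: IslandParams | None = None,
                               seed: int = 0, window_px: int = 10,
                               threshold_ms: float = 10.0,
                               max_count: int = 60) -> tuple[APDField, float]:
    """Construct a field whose oracle supra-threshold fraction is near target.

    Sweeps the island count upward (all else fixed) and returns the
    field whose oracle fraction lies closest to ``target_pct``, together
    with that oracle fraction.  Deterministic given the seed.
    """
    base = island_params if island_params is not None else IslandParams()
    best = None
    for count in range(1, max_count + 1):
        params = IslandParams(count=count, radius_px=base.radius_px,
                              elevation_ms=base.elevation_ms, shape=base.shape,
                              n_parents=base.n_parents,
                              cluster_radius_px=base.cluster_radius_px,
                              edge_bias=base.edge_bias, jitter_frac=base.jitter_frac)
        fld = generate_apd_field(pattern, grid, baseline_apd_ms, params, seed)
        frac = oracle_area_fraction(fld.values, None, window_px, threshold_ms)
        if best is None or abs(frac - target_pct) < abs(best[1] - target_pct):
            best = (fld, frac)
        if frac > target_pct + 5.0:  # fraction grows with count; stop past target
            break
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# paced-movie synthesis
# ---------------------------------------------------------------------------

UPSTROKE_TAU_MS = 0.4      # tanh upstroke time constant: 10-90% rise < 2 ms
PLATEAU_FRAC = 0.25        # plateau duration as a fraction of APD
START_PAD_MS = 10.0        # quiet interval before the first activation


def ap_template(t_ms: np.ndarray, apd_ms, level_pct: float = 90.0) -> np.ndarray:
    """Analytic action potential, time measured from the 50% upstroke point.

    tanh upstroke, plateau of ``PLATEAU_FRAC * APD``, then a raised-cosine
    repolarization whose duration is solved so the waveform crosses
    ``1 - level_pct/100`` of its amplitude exactly ``apd_ms`` after the
    upstroke midpoint.  The raised cosine reaches the resting level in
    finite time, so successive beats at a physiological cycle length do
    not contaminate each other's baseline.
    """
    thr = 1.0 - level_pct / 100.0
    apd = np.asarray(apd_ms, dtype=float)
    p = PLATEAU_FRAC * apd
    dur = np.pi * (apd - p) / np.arccos(2.0 * thr - 1.0)
    up = 0.5 * (1.0 + np.tanh(t_ms / UPSTROKE_TAU_MS))
    frac = np.clip((t_ms - p) / dur, 0.0, 1.0)
    rep = 0.5 * (1.0 + np.cos(np.pi * frac))
    return up * rep


def plane_wave_delays(shape, pixel_pitch_mm: float, angle_deg: float = 0.0,
                      speed_mm_per_ms: float = 0.3) -> np.ndarray:
    """Activation delay (ms) of a plane wave; zero at the first-activated pixel.

    ``angle_deg`` is the propagation direction measured from the +col
    axis toward +row.
    """
    h, w = shape
    th = np.deg2rad(angle_deg)
    rr, cc = np.mgrid[:h, :w]
    proj_mm = (cc * np.cos(th) + rr * np.sin(th)) * pixel_pitch_mm
    delays = proj_mm / speed_mm_per_ms
    return delays - delays.min()


def synthesize_movie(apd_field: APDField, meta: AcquisitionMeta | None = None,
                     pacing=(100.0, 10), wave=(0.0, 0.3), noise=(0.0, 0.0),
                     seed: int = 0, level_pct: float = 90.0,
                     mask: np.ndarray | None = None,
                     drift_freq_hz: float = 0.5,
                     bleach_amplitude: float = 0.0) -> tuple[VoltageMovie, GroundTruth]:
    """Synthesize a paced voltage movie over a ground-truth APD field.

    Parameters
    ----------
    pacing : (cycle_length_ms, n_beats)
    wave : (propagation angle deg, conduction speed mm/ms)
    noise : (gaussian sd, baseline drift amplitude), both relative to the
        unit action-potential amplitude; drift is a ``drift_freq_hz``
        sinusoid with a random phase per pixel, and ``bleach_amplitude``
        adds a linear photobleaching ramp over the recording.

    Returns the movie and a :class:`GroundTruth` whose area fraction is
    computed by the generator's own brute-force oracle.
    """
    cl_ms, n_beats = pacing
    values = apd_field.values
    h, w = values.shape
    if cl_ms <= values.max() + 20.0:
        raise FusionError(
            f"cycle length {cl_ms} ms must exceed max APD {values.max():.1f} ms + 20 ms")
    if n_beats < 2:
        raise ValueError("movie must contain at least 2 beats")

    delays = plane_wave_delays((h, w), 0.095 if meta is None else meta.pixel_pitch_mm,
                               angle_deg=wave[0], speed_mm_per_ms=wave[1])
    tail_ms = min(values.max() + 20.0, cl_ms)
    total_ms = START_PAD_MS + (n_beats - 1) * cl_ms + delays.max() + tail_ms
    if meta is None:
        meta = AcquisitionMeta(n_frames=int(math.ceil(total_ms)), height=h, width=w)
    else:
        need = int(math.ceil(total_ms * meta.frame_rate_hz / 1000.0))
        meta = AcquisitionMeta(frame_rate_hz=meta.frame_rate_hz,
                               pixel_pitch_mm=meta.pixel_pitch_mm,
                               n_frames=max(meta.n_frames, need) if meta.n_frames else need,
                               height=h, width=w,
                               subject_label=meta.subject_label, chamber=meta.chamber)

    t = np.arange(meta.n_frames) * meta.dt_ms
    data = np.zeros((meta.n_frames, h, w))
    for k in range(n_beats):
        t_act = START_PAD_MS + k * cl_ms + delays            # (h, w)
        data += ap_template(t[:, None, None] - t_act[None], values[None], level_pct)

    rng = np.random.default_rng(seed)
    sd, drift_amp = noise
    if drift_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=(h, w))
        data += drift_amp * np.sin(2 * np.pi * drift_freq_hz * t[:, None, None] / 1000.0
                                   + phase[None])
    if bleach_amplitude > 0:
        data -= bleach_amplitude * (t[:, None, None] / t[-1])
    if sd > 0:
        data += rng.normal(0.0, sd, size=data.shape)

    movie = VoltageMovie(data=data, meta=meta, mask=mask)
    truth = GroundTruth(
        apd_field=apd_field,
        activation_field=delays,
        true_area_fraction_pct=oracle_area_fraction(values, movie.mask),
        singularity_locations=[],
    )
    return movie, truth


# ---------------------------------------------------------------------------
# reentrant spiral movies
# ---------------------------------------------------------------------------

def generate_spiral_movie(meta: AcquisitionMeta | None = None,
                          rotation_freq_hz: float = 10.0,
                          core=(50, 50), chirality: int = 1, seed: int = 0,
                          wavelength_px: float = 60.0,
                          cores=None) -> tuple[VoltageMovie, GroundTruth]:
    """Analytic Archimedean spiral-wave movie with known singularity cores.

    The voltage is ``cos(2*pi*f*t + sum_i chi_i * theta_i + 2*pi*r1/lambda)``
    where ``theta_i`` is the polar angle about core ``i`` and ``chi_i`` its
    topological charge.  A single core gives a rotor; two cores of
    opposite charge give a figure-of-eight pattern.  Ground truth pins
    every core at every frame.
    """
    if meta is None:
        meta = AcquisitionMeta(n_frames=200)
    if rotation_freq_hz > meta.frame_rate_hz / 8.0:
        raise ValueError("rotation frequency must stay below Nyquist/4")
    if cores is None:
        cores = [(core[0], core[1], chirality)]
    h, w = meta.height, meta.width
    for r, c, chi in cores:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"core {(r, c)} outside the grid")
        if chi not in (1, -1):
            raise ValueError("chirality must be +1 or -1")

    rr, cc = np.mgrid[:h, :w]
    spatial = np.zeros((h, w))
    for r0, c0, chi in cores:
        # half-pixel offset keeps the singular point off the sample lattice
        spatial += chi * np.arctan2(rr - (r0 + 0.5), cc - (c0 + 0.5))
    r1 = np.hypot(rr - (cores[0][0] + 0.5), cc - (cores[0][1] + 0.5))
    spatial += 2 * np.pi * r1 / wavelength_px

    t = np.arange(meta.n_frames) / meta.frame_rate_hz
    data = np.cos(2 * np.pi * rotation_freq_hz * t[:, None, None] + spatial[None])

    movie = VoltageMovie(data=data, meta=meta)
    field = APDField(np.full((h, w), 50.0), "constant", 50.0, None, seed)
    truth = GroundTruth(
        apd_field=field,
        activation_field=np.zeros((h, w)),
        true_area_fraction_pct=0.0,
        singularity_locations=[[(r, c) for r, c, _ in cores]] * meta.n_frames,
        singularity_charges=[chi for _, _, chi in cores],
    )
    return movie, truth
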