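"""Shared fixtures: small synthetic movies and fields, built at test time."""

import numpy as np
import pytest

import apdisp as a

CLEAN = a.SignalConfig(spatial_filter_px=1, temporal_filter_ms=0.0, detrend=False)


@pytest.fixture(scope="session")
def constant_field():
    return a.generate_apd_field("constant", grid=(30, 30), baseline_apd_ms=50.0)


@pytest.fixture(scope="session")
def clustered_field():
    return a.generate_apd_field(
        "clustered", grid=(60, 60),
        island_params=a.IslandParams(count=8, radius_px=5.0, n_parents=2),
        seed=11)


@pytest.fixture(scope="session")
def clean_movie(clustered_field):
    """Noise-free paced movie over a clustered field (60x60, 3 beats)."""
    movie, truth = a.synthesize_movie(clustered_field, pacing=(100.0, 3), seed=0)
    return movie, truth


@pytest.fixture(scope="session")
def clean_apd_map(clean_movie):
    movie, _ = clean_movie
    return a.compute_apd_map(movie, CLEAN)


@pytest.fixture(scope="session")
def spiral_movie():
    meta = a.AcquisitionMeta(n_frames=150, height=60, width=60)
    return a.generate_spiral_movie(meta=meta, rotation_freq_hz=10.0,
                                   core=(30, 30), chirality=1)


def brute_force_window_stat(values, valid, window_px, stat="std"):
    """Independent per-pixel double-loop oracle for windowed statistics."""
    h, w = values.shape
    lo = (window_px - 1) // 2
    hi = window_px // 2
    out = np.full((h, w), np.nan)
    ok = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r0, r1 = max(0, i - lo), min(h, i + hi + 1)
            c0, c1 = max(0, j - lo), min(w, j + hi + 1)
            win = values[r0:r1, c0:c1][valid[r0:r1, c0:c1]]
            if win.size < 0.5 * window_px * window_px:
                continue
            ok[i, j] = True
            out[i, j] = win.std() if stat == "std" else win.max() - win.min()
    return out, ok
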