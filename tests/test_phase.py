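"""Dominant frequency, Hilbert phase and topological-charge detection."""

import numpy as np
import pytest

import apdisp as a
from .conftest import CLEAN


def tone_movie(freqs, amps, n_frames=2000, shape=(12, 12), fs=1000.0):
    t = np.arange(n_frames) / fs
    trace = sum(amp * np.cos(2 * np.pi * f * t) for f, amp in zip(freqs, amps))
    data = np.broadcast_to(trace[:, None, None],
                           (n_frames, *shape)).copy()
    meta = a.AcquisitionMeta(frame_rate_hz=fs, n_frames=n_frames,
                             height=shape[0], width=shape[1])
    return a.VoltageMovie(data, meta)


class TestDominantFrequency:
    def test_pure_tone_within_one_bin(self):
        movie = tone_movie([10.0], [1.0], n_frames=4000)
        dfm = a.dominant_frequency_map(movie)
        bin_hz = movie.meta.frame_rate_hz / movie.n_frames
        assert np.all(np.abs(dfm.freq_hz[dfm.valid] - 10.0) <= bin_hz)
        assert dfm.power_fraction[dfm.valid].min() > 0.5

    def test_two_tone_picks_stronger(self):
        movie = tone_movie([8.0, 16.0], [1.0, 0.3])
        dfm = a.dominant_frequency_map(movie)
        assert np.allclose(dfm.freq_hz[dfm.valid], 8.0, atol=0.5)

    def test_constant_pixel_invalid(self):
        movie = tone_movie([10.0], [1.0])
        movie.data[:, 3, 3] = 5.0
        dfm = a.dominant_frequency_map(movie)
        assert not dfm.valid[3, 3]

    def test_band_above_nyquist_rejected(self):
        movie = tone_movie([10.0], [1.0])
        with pytest.raises(ValueError):
            a.dominant_frequency_map(movie, band_hz=(1.0, 600.0))


class TestPhaseMovie:
    def test_tone_phase_slope_matches_frequency(self):
        movie = tone_movie([10.0], [1.0])
        pm = a.phase_movie(movie)
        ph = np.unwrap(pm.phase[:, 5, 5])
        slope = np.polyfit(np.arange(ph.size) / 1000.0, ph, 1)[0]
        assert abs(slope - 2 * np.pi * 10.0) / (2 * np.pi * 10.0) < 0.01

    def test_amplitude_invariance(self):
        movie = tone_movie([10.0], [1.0])
        scaled = a.VoltageMovie(movie.data * 7.3, movie.meta, movie.mask)
        p1 = a.phase_movie(movie).phase
        p2 = a.phase_movie(scaled).phase
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_spiral_phase_matches_analytic_field(self, spiral_movie):
        movie, _ = spiral_movie
        pm = a.phase_movie(movie)
        # analytic spatial phase differences are reproduced away from the core
        rr, cc = np.mgrid[:60, :60]
        spatial = (np.arctan2(rr - 30.5, cc - 30.5)
                   + 2 * np.pi * np.hypot(rr - 30.5, cc - 30.5) / 60.0)
        k = 50
        got = pm.phase[k]
        ring = (np.hypot(rr - 30.5, cc - 30.5) > 8) & (np.hypot(rr - 30.5, cc - 30.5) < 20)
        dgot = np.angle(np.exp(1j * (got - got[20, 20])))
        dref = np.angle(np.exp(1j * (spatial - spatial[20, 20])))
        err = np.angle(np.exp(1j * (dgot - dref)))[ring]
        assert np.abs(err).max() < 0.1


class TestSingularities:
    def test_single_spiral_one_per_frame_at_core(self, spiral_movie):
        movie, truth = spiral_movie
        sing = a.detect_singularities(a.phase_movie(movie))
        assert all(len(f) == 1 for f in sing.per_frame)
        charges = {f[0][2] for f in sing.per_frame}
        assert charges == {1}
        for f in sing.per_frame:
            r, c, _ = f[0]
            assert np.hypot(r - 30, c - 30) <= 1.0

    def test_opposite_chirality_flips_charge(self):
        meta = a.AcquisitionMeta(n_frames=100, height=50, width=50)
        movie, _ = a.generate_spiral_movie(meta=meta, core=(25, 25), chirality=-1)
        sing = a.detect_singularities(a.phase_movie(movie))
        assert {f[0][2] for f in sing.per_frame} == {-1}

    def test_plane_wave_has_no_singularities(self, constant_field):
        movie, _ = a.synthesize_movie(constant_field, pacing=(100.0, 3))
        sing = a.detect_singularities(a.phase_movie(movie))
        assert sing.total_count() == 0

    def test_figure_of_eight_two_singularities_net_zero(self):
        meta = a.AcquisitionMeta(n_frames=100, height=60, width=60)
        movie, _ = a.generate_spiral_movie(meta=meta,
                                           cores=[(30, 15, 1), (30, 45, -1)])
        sing = a.detect_singularities(a.phase_movie(movie))
        for k, f in enumerate(sing.per_frame):
            assert len(f) == 2
            assert sing.net_charge(k) == 0

    def test_count_invariant_to_amplitude_rescale(self, spiral_movie):
        movie, _ = spiral_movie
        scaled = a.VoltageMovie(movie.data * 0.01, movie.meta, movie.mask)
        s1 = a.detect_singularities(a.phase_movie(movie))
        s2 = a.detect_singularities(a.phase_movie(scaled))
        assert s1.total_count() == s2.total_count()

    def test_spd_map_peaks_at_core(self, spiral_movie):
        movie, _ = spiral_movie
        sing = a.detect_singularities(a.phase_movie(movie), spd_window_px=10)
        peak = np.unravel_index(np.argmax(sing.spd_map), sing.spd_map.shape)
        assert np.hypot(peak[0] - 30, peak[1] - 30) <= 6
        assert sing.spd_map.min() >= 0


class TestCompareSpdRegion:
    def test_high_dispersion_core_region_contrast(self):
        # spiral core placed inside the high-APD island neighborhood
        field = a.generate_apd_field(
            "clustered", grid=(60, 60),
            island_params=a.IslandParams(count=6, radius_px=5, n_parents=1,
                                         cluster_radius_px=8.0),
            seed=21)
        movie, _ = a.synthesize_movie(field, pacing=(100.0, 3), seed=0)
        amap = a.compute_apd_map(movie, CLEAN)
        core = tuple(int(v) for v in field.centers[0])
        meta = a.AcquisitionMeta(n_frames=80, height=60, width=60)
        spiral, _ = a.generate_spiral_movie(meta=meta, core=core)
        sing = a.detect_singularities(a.phase_movie(spiral))
        res = a.compare_spd_region(amap, sing, window_px=10)
        assert res["region_a"]["std_apd_ms"] > res["region_b"]["std_apd_ms"]

    def test_uniform_map_zero_differences(self, constant_field):
        movie, _ = a.synthesize_movie(constant_field, pacing=(100.0, 3))
        amap = a.compute_apd_map(movie, CLEAN)
        meta = a.AcquisitionMeta(n_frames=60, height=30, width=30)
        spiral, _ = a.generate_spiral_movie(meta=meta, core=(15, 15))
        sing = a.detect_singularities(a.phase_movie(spiral))
        res = a.compare_spd_region(amap, sing, window_px=10)
        for v in res["difference"].values():
            assert abs(v) < 0.5
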