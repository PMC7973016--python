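"""Generator properties: determinism, pattern geometry, template exactness."""

import numpy as np
import pytest

import apdisp as a
from apdisp.synthetic import FusionError, InfeasibleFieldError


def test_constant_field_has_zero_spatial_std():
    f = a.generate_apd_field("constant", grid=(20, 20), baseline_apd_ms=50.0)
    assert f.values.std() == 0.0
    assert f.values[0, 0] == 50.0


@pytest.mark.parametrize("pattern", ["uniform", "random", "clustered"])
def test_field_deterministic_given_seed(pattern):
    params = a.IslandParams(count=8, radius_px=4.0)
    f1 = a.generate_apd_field(pattern, grid=(50, 50), island_params=params, seed=42)
    f2 = a.generate_apd_field(pattern, grid=(50, 50), island_params=params, seed=42)
    np.testing.assert_array_equal(f1.values, f2.values)
    np.testing.assert_array_equal(f1.centers, f2.centers)
    f3 = a.generate_apd_field(pattern, grid=(50, 50), island_params=params, seed=43)
    assert not np.array_equal(f1.values, f3.values)


def test_clustered_centers_aggregated_by_nearest_neighbor_oracle():
    """Clark-Evans R of clustered centroids < 1, computed directly."""
    params = a.IslandParams(count=30, radius_px=3.0, cluster_radius_px=10.0,
                            n_parents=5)
    f = a.generate_apd_field("clustered", grid=(100, 100),
                             island_params=params, seed=5)
    pts = f.centers
    nn = np.array([np.sort(np.hypot(*(pts - p).T))[1] for p in pts])
    r = nn.mean() / (0.5 / np.sqrt(len(pts) / 10000.0))
    assert r < 1.0


def test_infeasible_island_coverage_rejected():
    with pytest.raises(InfeasibleFieldError):
        a.generate_apd_field("random", grid=(30, 30),
                             island_params=a.IslandParams(count=200, radius_px=8.0))


def test_serpiginous_islands_are_elongated_or_nonconvex():
    params = a.IslandParams(count=4, radius_px=6.0, shape="serpiginous")
    f = a.generate_apd_field("random", grid=(80, 80), island_params=params, seed=2)
    assert (f.values > f.baseline_apd_ms).sum() > 0


def test_template_crosses_level_exactly_at_apd():
    t = np.linspace(-5, 120, 20001)
    for apd, level in [(50.0, 90.0), (75.0, 90.0), (50.0, 50.0), (30.0, 80.0)]:
        v = a.ap_template(t, apd, level)
        thr = 1.0 - level / 100.0
        after_peak = t > 0.3 * apd
        crossing = t[after_peak][np.argmax(v[after_peak] < thr)]
        assert abs(crossing - apd) < 0.05, (apd, level)


def test_template_upstroke_is_sharp():
    t = np.linspace(-5, 60, 10000)
    v = a.ap_template(t, 50.0, 90.0)
    t10 = t[np.argmax(v >= 0.1)]
    t90 = t[np.argmax(v >= 0.9)]
    assert t90 - t10 <= 2.0


def test_movie_upstroke_count_matches_pacing():
    """10 Hz pacing for 1 s at 1,000 f/s gives exactly 10 upstrokes."""
    f = a.generate_apd_field("constant", grid=(10, 10), baseline_apd_ms=50.0)
    movie, _ = a.synthesize_movie(f, pacing=(100.0, 10), wave=(0.0, 1e9), seed=0)
    pre = a.preprocess(movie, a.SignalConfig(spatial_filter_px=1,
                                             temporal_filter_ms=0, detrend=False))
    for i, j in [(0, 0), (5, 5), (9, 9)]:
        assert len(a.detect_beats(pre.data[:, i, j], 1000.0)) == 10


def test_plane_wave_delay_range_matches_speed():
    """0.3 mm/ms across 100 px of 0.095 mm: 31.67 ms corner-to-corner."""
    delays = a.plane_wave_delays((100, 100), 0.095, angle_deg=0.0,
                                 speed_mm_per_ms=0.3)
    expected = 99 * 0.095 / 0.3
    assert delays.min() == 0.0
    assert np.isclose(delays.max(), expected, atol=1e-9)
    assert np.isclose(expected, 31.35, atol=0.01)
    f = a.generate_apd_field("constant", grid=(20, 20))
    _, truth = a.synthesize_movie(f, pacing=(100.0, 2), wave=(0.0, 0.3))
    assert np.isclose(truth.activation_field.max(), 19 * 0.095 / 0.3)


def test_movie_deterministic_and_noise_seeded():
    f = a.generate_apd_field("clustered", grid=(20, 20),
                             island_params=a.IslandParams(count=3, radius_px=3),
                             seed=1)
    m1, _ = a.synthesize_movie(f, pacing=(100.0, 2), noise=(0.05, 0.02), seed=9)
    m2, _ = a.synthesize_movie(f, pacing=(100.0, 2), noise=(0.05, 0.02), seed=9)
    np.testing.assert_array_equal(m1.data, m2.data)
    m3, _ = a.synthesize_movie(f, pacing=(100.0, 2), noise=(0.05, 0.02), seed=10)
    assert not np.array_equal(m1.data, m3.data)


def test_fusion_error_when_cycle_too_short():
    f = a.generate_apd_field("constant", grid=(10, 10), baseline_apd_ms=90.0)
    with pytest.raises(FusionError):
        a.synthesize_movie(f, pacing=(100.0, 3))


def test_ground_truth_fraction_matches_independent_recount(clustered_field):
    _, truth = a.synthesize_movie(clustered_field, pacing=(100.0, 2), seed=0)
    again = a.oracle_area_fraction(clustered_field.values,
                                   np.ones(clustered_field.values.shape, bool))
    assert truth.true_area_fraction_pct == again
    assert 0.0 <= truth.true_area_fraction_pct <= 100.0
    assert truth.singularity_locations == []


def test_spiral_ground_truth_and_charge_conventions():
    meta = a.AcquisitionMeta(n_frames=50, height=40, width=40)
    movie, truth = a.generate_spiral_movie(meta=meta, rotation_freq_hz=10.0,
                                           core=(20, 20), chirality=1)
    assert truth.singularity_locations[0] == [(20, 20)]
    assert len(truth.singularity_locations) == 50
    assert truth.singularity_charges == [1]


def test_figure_of_eight_brute_force_winding():
    """Two opposite-charge cores: winding +-2pi locally, 0 globally."""
    meta = a.AcquisitionMeta(n_frames=10, height=60, width=60)
    cores = [(30, 15, 1), (30, 45, -1)]
    movie, truth = a.generate_spiral_movie(meta=meta, cores=cores)
    assert truth.singularity_charges == [1, -1]

    rr, cc = np.mgrid[:60, :60]
    spatial = sum(chi * np.arctan2(rr - (r0 + 0.5), cc - (c0 + 0.5))
                  for r0, c0, chi in cores)

    def winding(loop_pts):
        ph = np.array([spatial[r, c] for r, c in loop_pts] + [spatial[loop_pts[0]]])
        d = np.diff(ph)
        d = (d + np.pi) % (2 * np.pi) - np.pi
        return d.sum() / (2 * np.pi)

    def square_loop(r0, c0, half):
        top = [(r0 - half, c) for c in range(c0 - half, c0 + half + 1)]
        right = [(r, c0 + half) for r in range(r0 - half, r0 + half + 1)]
        bottom = [(r0 + half, c) for c in range(c0 + half, c0 - half - 1, -1)]
        left = [(r, c0 - half) for r in range(r0 + half, r0 - half - 1, -1)]
        return top + right[1:] + bottom[1:] + left[1:-1]

    assert round(winding(square_loop(30, 15, 8))) == 1
    assert round(winding(square_loop(30, 45, 8))) == -1
    assert round(winding(square_loop(30, 30, 28))) == 0   # global charge zero


def test_spiral_rejects_fast_rotation_and_outside_core():
    meta = a.AcquisitionMeta(n_frames=50, height=40, width=40, frame_rate_hz=100.0)
    with pytest.raises(ValueError, match="Nyquist"):
        a.generate_spiral_movie(meta=meta, rotation_freq_hz=20.0)
    with pytest.raises(ValueError, match="outside"):
        a.generate_spiral_movie(core=(200, 200))
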