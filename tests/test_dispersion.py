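"""Dispersion maps against brute-force oracles; binarization; islands; stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apdisp as a
from .conftest import brute_force_window_stat


def apd_from_array(values, valid=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.shape, bool) if valid is None else valid
    meta = a.AcquisitionMeta(n_frames=0, height=values.shape[0],
                             width=values.shape[1])
    return a.APDMap(values=values, level_pct=90.0, valid=valid, meta=meta)


class TestDispersionMap:
    def test_constant_field_zero_dispersion(self):
        amap = apd_from_array(np.full((20, 20), 50.0))
        d = a.dispersion_map(amap, window_px=10)
        assert np.nanmax(d.values) == 0.0

    def test_half_and_half_window_population_std(self):
        """50 pixels of 20 ms + 50 of 30 ms in a 10x10 window: std = 5."""
        vals = np.full((10, 10), 20.0)
        vals[5:] = 30.0
        amap = apd_from_array(vals)
        d = a.dispersion_map(amap, window_px=10)
        assert d.values[4, 4] == pytest.approx(5.0, abs=1e-12)

    @pytest.mark.parametrize("stat", ["std", "max_minus_min"])
    def test_matches_brute_force_oracle(self, stat):
        rng = np.random.default_rng(3)
        vals = rng.uniform(30, 80, size=(30, 30))
        valid = rng.uniform(size=(30, 30)) > 0.15
        amap = apd_from_array(vals, valid)
        d = a.dispersion_map(amap, window_px=10, statistic=stat)
        ref, ok = brute_force_window_stat(vals, valid, 10, stat)
        np.testing.assert_array_equal(d.valid, ok)
        np.testing.assert_allclose(d.values[ok], ref[ok], atol=1e-10)

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(4)
        amap = apd_from_array(rng.uniform(30, 80, size=(25, 25)))
        d0 = a.dispersion_map(amap, 10)
        d_shift = a.dispersion_map(apd_from_array(amap.values + 17.0), 10)
        d_scale = a.dispersion_map(apd_from_array(amap.values * 2.0), 10)
        np.testing.assert_allclose(d_shift.values, d0.values, atol=1e-9)
        np.testing.assert_allclose(d_scale.values, 2 * d0.values, atol=1e-9)

    def test_window_larger_than_map_rejected(self):
        with pytest.raises(ValueError):
            a.dispersion_map(apd_from_array(np.full((5, 5), 50.0)), window_px=10)

    def test_low_valid_windows_marked_invalid(self):
        valid = np.zeros((20, 20), dtype=bool)
        valid[:, :3] = True  # 3 columns: every 10x10 window < 50% valid
        amap = apd_from_array(np.full((20, 20), 50.0), valid)
        d = a.dispersion_map(amap, window_px=10)
        assert not d.valid.any()


class TestGradientMap:
    def test_two_level_window_range(self):
        vals = np.full((12, 12), 40.0)
        vals[6:, 6:] = 55.0
        g = a.gradient_map(apd_from_array(vals), window_px=10)
        assert np.nanmax(g.values) == pytest.approx(15.0)

    def test_range_dominates_std_everywhere(self):
        rng = np.random.default_rng(5)
        amap = apd_from_array(rng.uniform(30, 90, size=(30, 30)))
        d = a.dispersion_map(amap, 10)
        g = a.gradient_map(amap, 10)
        both = d.valid & g.valid
        assert np.all(g.values[both] >= d.values[both] - 1e-12)


class TestBinarizeAndAreaFraction:
    def test_strict_threshold_boundary(self):
        vals = np.full((12, 12), 60.0)
        amap = apd_from_array(vals)
        d = a.dispersion_map(amap, 10)
        d.values[d.valid] = 10.0  # exactly at threshold
        b = a.binarize(d, 10.0)
        assert not b.above.any()
        d.values[d.valid] = 10.0 + 1e-9
        assert a.binarize(d, 10.0).above.sum() == d.valid.sum()

    def test_area_fraction_arithmetic(self):
        above = np.zeros((10, 10), dtype=bool)
        above.flat[:37] = True
        b = a.BinaryDispersionMap(above=above, threshold_ms=10.0,
                                  source_statistic="std",
                                  valid=np.ones((10, 10), bool))
        assert a.area_fraction(b) == pytest.approx(37.0)
        assert a.area_fraction(
            a.BinaryDispersionMap(above=np.ones((4, 4), bool), threshold_ms=0,
                                  source_statistic="std",
                                  valid=np.ones((4, 4), bool))) == 100.0

    def test_empty_mask_rejected(self):
        b = a.BinaryDispersionMap(above=np.zeros((5, 5), bool), threshold_ms=10,
                                  source_statistic="std",
                                  valid=np.ones((5, 5), bool))
        with pytest.raises(ValueError):
            a.area_fraction(b, np.zeros((5, 5), bool))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_fraction_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        amap = apd_from_array(rng.uniform(30, 80, size=(25, 25)))
        d = a.dispersion_map(amap, 10)
        fracs = [a.area_fraction(a.binarize(d, th))
                 for th in np.linspace(0, 20, 9)]
        assert all(f1 >= f2 for f1, f2 in zip(fracs, fracs[1:]))


class TestIslands:
    def test_square_island_area_in_mm2(self):
        above = np.zeros((30, 30), dtype=bool)
        above[10:20, 10:20] = True
        b = a.BinaryDispersionMap(above=above, threshold_ms=10.0,
                                  source_statistic="std",
                                  valid=np.ones((30, 30), bool))
        islands = a.extract_islands(b, 0.095)
        assert len(islands) == 1
        assert islands.islands[0].pixel_count == 100
        assert islands.islands[0].area_mm2 == pytest.approx(0.9025)

    def test_diagonal_touching_is_one_island(self):
        above = np.zeros((10, 10), dtype=bool)
        above[2:4, 2:4] = True
        above[4:6, 4:6] = True  # touches only at the (3,3)-(4,4) corner
        b = a.BinaryDispersionMap(above=above, threshold_ms=10.0,
                                  source_statistic="std",
                                  valid=np.ones((10, 10), bool))
        assert len(a.extract_islands(b, 0.095)) == 1

    def test_shape_labels_disc_vs_bar(self):
        above = np.zeros((40, 40), dtype=bool)
        rr, cc = np.ogrid[:40, :40]
        above |= (rr - 10) ** 2 + (cc - 10) ** 2 <= 36   # disc
        above[30:32, 5:35] = True                         # 2x30 bar
        b = a.BinaryDispersionMap(above=above, threshold_ms=10.0,
                                  source_statistic="std",
                                  valid=np.ones((40, 40), bool))
        islands = a.extract_islands(b, 0.095)
        labels = {i.shape_label for i in islands.islands}
        assert labels == {"ovoid", "serpiginous"}

    def test_empty_map_empty_set(self):
        b = a.BinaryDispersionMap(above=np.zeros((8, 8), bool), threshold_ms=10,
                                  source_statistic="std",
                                  valid=np.ones((8, 8), bool))
        islands = a.extract_islands(b, 0.095)
        assert len(islands) == 0
        assert islands.to_frame().empty


class TestGroupStats:
    def test_textbook_two_value_case(self):
        gs = a.group_stats([8.0, 12.0], null_value=0.0)
        assert gs["mean"] == pytest.approx(10.0)
        assert gs["sem"] == pytest.approx(2.0)
        assert gs["t"] == pytest.approx(5.0)
        assert gs["df"] == 1

    def test_all_equal_to_null_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            gs = a.group_stats([5.0, 5.0, 5.0], null_value=5.0)
        assert gs["t"] == 0.0 and gs["p"] == 1.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            a.group_stats([10.0], null_value=0.0)
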