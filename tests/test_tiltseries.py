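"""Region summation, series assembly, SMV export, dose arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoedt.frame_io import FrameStack4D, ScanGeometry, read_smv
from nanoedt.segmentation import RegionMask
from nanoedt.tiltseries import (assemble_series, compare_magnitudes,
                                exposure_budget, export_series_smv,
                                read_reflections, selected_area_dose,
                                sum_region)


def _hybrid_stack(data, tilt=0.0):
    geom = ScanGeometry(step_nm=40.0, probe_fwhm_nm=12.0, tilt_deg=tilt)
    return FrameStack4D(np.asarray(data, dtype=np.int64), geom,
                        "hybrid_counts")


def _region(mask):
    return RegionMask(np.asarray(mask, dtype=bool), 1)


class TestSumRegion:
    def test_single_pixel_region_is_that_frame(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 9, size=(3, 4, 5, 5))
        mask = np.zeros((3, 4), dtype=bool)
        mask[1, 2] = True
        np.testing.assert_array_equal(
            sum_region(_hybrid_stack(data), _region(mask)), data[1, 2])

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 9, size=(4, 4, 6, 6))
        mask = rng.random((4, 4)) > 0.4
        mask[0, 0] = True
        pattern = sum_region(_hybrid_stack(data), _region(mask))
        assert pattern.sum() == data[mask].sum()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_additivity_over_disjoint_regions(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 20, size=(5, 6, 4, 4))
        split = rng.random((5, 6)) > 0.5
        a, b = split.copy(), ~split
        a[0, 0], b[1, 1] = True, True
        b[0, 0], a[1, 1] = False, False
        union = a | b
        stack = _hybrid_stack(data)
        np.testing.assert_array_equal(
            sum_region(stack, _region(union)),
            sum_region(stack, _region(a)) + sum_region(stack, _region(b)))

    def test_raw_stack_rejected(self):
        stack = FrameStack4D(np.zeros((2, 2, 3, 3)),
                             ScanGeometry(40.0, 12.0), "raw_adu")
        with pytest.raises(ValueError, match="hybrid"):
            sum_region(stack, _region(np.ones((2, 2))))

    def test_mismatched_region_rejected(self):
        with pytest.raises(ValueError, match="scan grid"):
            sum_region(_hybrid_stack(np.zeros((2, 2, 3, 3), dtype=int)),
                       _region(np.ones((4, 4))))


class TestAssembleSeries:
    def _stacks(self, tilts):
        return [_hybrid_stack(np.ones((1, 1, 4, 4), dtype=int), tilt=t)
                for t in tilts]

    def test_81_patterns_over_pm40_at_one_degree(self):
        tilts = np.arange(-40.0, 41.0)
        series = assemble_series(self._stacks(tilts),
                                 _region(np.ones((1, 1))))
        assert len(series) == 81
        np.testing.assert_allclose(series.tilts_deg, tilts)

    def test_single_tilt(self):
        series = assemble_series(self._stacks([5.0]),
                                 _region(np.ones((1, 1))))
        assert len(series) == 1

    def test_shuffled_input_sorted_ascending(self):
        series = assemble_series(self._stacks([3.0, -7.0, 0.0]),
                                 _region(np.ones((1, 1))))
        np.testing.assert_allclose(series.tilts_deg, [-7.0, 0.0, 3.0])

    def test_duplicate_tilts_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_series(self._stacks([1.0, 1.0]),
                            _region(np.ones((1, 1))))

    def test_missing_region_leaves_logged_gap(self, caplog):
        with caplog.at_level("WARNING"):
            series = assemble_series(self._stacks([0.0, 1.0]),
                                     [_region(np.ones((1, 1))), None])
        assert len(series) == 1
        assert any("gap" in r.message for r in caplog.records)


class TestExportSMV:
    def test_parse_back_headers_match_tilts(self, tmp_path):
        tilts = [-1.0, 0.0, 2.0]
        series = assemble_series(
            [_hybrid_stack(np.full((1, 1, 4, 4), 7, dtype=int), tilt=t)
             for t in tilts], _region(np.ones((1, 1))))
        paths = export_series_smv(series, tmp_path, osc_range_deg=1.0)
        assert len(paths) == 3
        for path, tilt in zip(paths, tilts):
            data, header = read_smv(path)
            assert float(header["OSC_START"]) == tilt
            assert float(header["OSC_RANGE"]) == 1.0
            assert (data == 7).all()

    def test_empty_series_writes_nothing(self, tmp_path, caplog):
        from nanoedt.tiltseries import TiltSeries
        with caplog.at_level("WARNING"):
            assert export_series_smv(TiltSeries([]), tmp_path) == []
        assert list(tmp_path.glob("*.img")) == []


class TestExposureBudget:
    def test_paper_geometry_numbers(self):
        geom = ScanGeometry(step_nm=40.0, probe_fwhm_nm=12.0,
                            dose_e_per_A2_per_frame=1.0)
        b = exposure_budget(geom, n_tilts=81)
        assert b.step_area_nm2 == 1600.0
        assert b.probe_area_nm2 == pytest.approx(113.097, abs=0.001)
        assert b.area_ratio == pytest.approx(14.147, abs=0.001)
        assert b.nominal_series_dose_e_per_A2 == pytest.approx(81.0)

    def test_step_matching_probe_area_gives_unit_ratio(self):
        fwhm = 12.0
        step = fwhm * math.sqrt(math.pi / 4.0)
        geom = ScanGeometry(step_nm=step, probe_fwhm_nm=fwhm)
        assert exposure_budget(geom, 1).area_ratio == pytest.approx(1.0)

    def test_selected_area_dose_examples(self):
        assert selected_area_dose(0.01, 90.0, 0.3) == pytest.approx(3.0)
        assert selected_area_dose(0.0, 90.0, 0.3) == 0.0
        assert selected_area_dose(0.01, 90.0, 0.6) == pytest.approx(1.5)

    def test_zero_angular_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            selected_area_dose(0.01, 90.0, 0.0)


class TestCompareMagnitudes:
    def _set(self, intensities, sigma=0.1):
        return [((h, 0, 0), i, sigma * max(i, 1)) for h, i in
                enumerate(intensities, start=1)]

    def test_identical_sets_give_unit_slope_and_r(self):
        a = self._set([10.0, 40.0, 90.0, 160.0])
        slope, intercept, r = compare_magnitudes(a, a)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_global_intensity_scale_is_removed(self):
        a = self._set([10.0, 40.0, 90.0, 160.0])
        b = [(hkl, 2 * i, 2 * s) for hkl, i, s in a]
        slope, _, r = compare_magnitudes(a, b)
        assert slope == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_weak_reflections_filtered_by_i_over_sigma(self):
        a = self._set([10.0, 40.0, 90.0, 160.0])
        # one reflection with I/sigma = 1 must be excluded -> only 3 left
        a[0] = ((1, 0, 0), 10.0, 10.0)
        b = self._set([10.0, 40.0, 90.0, 160.0])
        slope, _, r = compare_magnitudes(a, b)
        assert r == pytest.approx(1.0)

    def test_fewer_than_three_matches_rejected(self):
        a = self._set([10.0, 40.0])
        with pytest.raises(ValueError, match="3"):
            compare_magnitudes(a, a)

    def test_gaussian_perturbation_matches_closed_form_r(self):
        """For mb = ma + eps with independent eps ~ N(0, s^2), the expected
        Pearson r is sd(ma) / sqrt(sd(ma)^2 + s^2)."""
        rng = np.random.default_rng(33)
        n = 4000
        ma = rng.uniform(5.0, 50.0, size=n)
        s = 4.0
        mb = ma + rng.normal(0.0, s, size=n)
        mb = np.clip(mb, 0.1, None)
        a = [((i, 0, 0), float(m ** 2), 0.01) for i, m in enumerate(ma)]
        b = [((i, 0, 0), float(m ** 2), 0.01) for i, m in enumerate(mb)]
        _, _, r = compare_magnitudes(a, b)
        expected = ma.std() / math.hypot(ma.std(), s)
        assert r == pytest.approx(expected, abs=0.02)

    def test_reads_whitespace_delimited_text(self, tmp_path):
        (tmp_path / "refl.txt").write_text(
            "# h k l I sigma\n1 0 0 100.0 5.0\n0 2 0 50.0 2.5\n")
        refl = read_reflections(tmp_path / "refl.txt")
        assert refl == [((1, 0, 0), 100.0, 5.0), ((0, 2, 0), 50.0, 2.5)]
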