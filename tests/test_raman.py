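import math

import numpy as np
import pandas as pd
import pytest

import osteomat as om
from osteomat.errors import BandShapeError, CoverageError, DegenerateSpectrumError
from osteomat.raman import METRIC_NAMES
from osteomat.synth import Band


def spectrum_on(w, y, **meta):
    return om.RamanSpectrum(wavenumber=np.asarray(w, float),
                            intensity=np.asarray(y, float), meta=meta)


class TestTrim:
    def test_trims_to_window(self):
        w = np.arange(300.0, 1901.0)
        s = om.trim(spectrum_on(w, np.ones_like(w)))
        assert s.wavenumber[0] >= 350.0 and s.wavenumber[-1] <= 1800.0

    def test_identity_when_already_within_range(self):
        w = np.arange(350.0, 1801.0)
        s = om.trim(spectrum_on(w, np.ones_like(w)))
        np.testing.assert_array_equal(s.wavenumber, w)

    def test_insufficient_coverage_raises(self):
        w = np.arange(400.0, 1701.0)
        with pytest.raises(CoverageError):
            om.trim(spectrum_on(w, np.ones_like(w)))


class TestRubberband:
    def test_flat_zero_spectrum_unchanged(self):
        w = np.arange(350.0, 1801.0)
        corrected, baseline = om.rubberband_baseline(spectrum_on(w, np.zeros_like(w)))
        np.testing.assert_array_equal(corrected.intensity, 0.0)
        np.testing.assert_allclose(baseline, 0.0, atol=1e-12)

    @pytest.mark.parametrize("background, tol", [
        ("flat", 0.01),     # constant offset
        ("linear", 0.02),   # a + b*nu ramp
    ])
    def test_gaussian_band_area_recovered(self, background, tol):
        w = np.arange(350.0, 1801.0)
        band = Band("gaussian", 960.0, 12.0, 100.0)
        bg = np.full_like(w, 40.0) if background == "flat" else 100.0 - 0.04 * w
        corrected, _ = om.rubberband_baseline(spectrum_on(w, band.evaluate(w) + bg))
        assert corrected.intensity.min() == 0.0
        got = om.integrate_band(corrected, 900.0, 1020.0)
        assert got == pytest.approx(band.partial_area(900.0, 1020.0), rel=tol)

    def test_endpoints_map_to_zero(self):
        s, _ = om.render_spectrum(om.SpectrumSpec(noise_sd=0.01, seed=3))
        corrected, _ = om.rubberband_baseline(om.trim(s))
        assert corrected.intensity[0] == 0.0
        assert corrected.intensity[-1] == 0.0

    def test_near_idempotence(self):
        s, _ = om.render_spectrum(om.SpectrumSpec(seed=0))
        once, _ = om.rubberband_baseline(om.trim(s))
        twice, second_base = om.rubberband_baseline(once)
        scale = once.intensity.max()
        assert np.max(np.abs(twice.intensity - once.intensity)) <= 0.01 * scale


class TestBandMeasures:
    def test_constant_band_area(self):
        w = np.arange(350.0, 1801.0)
        assert om.integrate_band(spectrum_on(w, np.ones_like(w)), 500.0, 550.0) == \
            pytest.approx(50.0)

    def test_triangle_band_area(self):
        w = np.arange(350.0, 1801.0)
        y = np.clip(20.0 - np.abs(w - 700.0), 0.0, None)  # height 20, base 40
        assert om.integrate_band(spectrum_on(w, y), 650.0, 750.0) == \
            pytest.approx(20.0 * 40.0 / 2.0, rel=1e-6)

    def test_gaussian_band_matches_erf_form(self):
        w = np.arange(350.0, 1801.0)
        band = Band("gaussian", 430.0, 12.0, 100.0)
        got = om.integrate_band(spectrum_on(w, band.evaluate(w)), 410.0, 460.0)
        assert got == pytest.approx(band.partial_area(410.0, 460.0), rel=0.005)

    def test_window_edges_interpolated(self):
        w = np.array([400.0, 410.5, 421.0])
        y = np.array([2.0, 2.0, 2.0])
        assert om.integrate_band(spectrum_on(w, y), 405.0, 415.0) == pytest.approx(20.0)

    def test_window_outside_support_raises(self):
        w = np.arange(400.0, 500.0)
        with pytest.raises(CoverageError):
            om.integrate_band(spectrum_on(w, np.ones_like(w)), 450.0, 600.0)

    def test_peak_height_at_grid_point_and_between(self):
        w = np.array([1650.0, 1655.0, 1660.0, 1665.0])
        assert om.peak_height(spectrum_on(w, [1.0, 2.0, 7.0, 1.0])) == 7.0
        w2 = np.array([1655.0, 1665.0])
        assert om.peak_height(spectrum_on(w2, [4.0, 6.0])) == pytest.approx(5.0)

    def test_fwhm_gaussian(self):
        w = np.arange(900.0, 1001.0, 0.5)
        band = Band("gaussian", 960.0, 5.0, 10.0)
        got = om.band_fwhm(spectrum_on(w, band.evaluate(w)))
        assert got == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 5.0, rel=0.01)

    def test_fwhm_lorentzian(self):
        w = np.arange(900.0, 1001.0, 0.5)
        band = Band("lorentzian", 958.0, 4.0, 10.0)
        got = om.band_fwhm(spectrum_on(w, band.evaluate(w)))
        assert got == pytest.approx(8.0, rel=0.02)

    def test_monotone_ramp_has_no_band(self):
        w = np.arange(900.0, 1001.0)
        with pytest.raises(BandShapeError):
            om.band_fwhm(spectrum_on(w, w * 0.01))


class TestComputeParams:
    def test_recovery_against_closed_form(self):
        s, truth = om.render_spectrum(om.SpectrumSpec(seed=2))
        got = om.process_spectrum(s)
        assert got.mineral_matrix == pytest.approx(truth.mineral_matrix, rel=0.02)
        assert got.gag_ratio == pytest.approx(truth.gag_ratio, rel=0.02)
        assert got.nanoporosity == pytest.approx(truth.nanoporosity, rel=0.02)
        assert got.mmc == pytest.approx(truth.mmc, rel=0.02)

    def test_intensity_scale_invariance(self):
        s, _ = om.render_spectrum(om.SpectrumSpec(noise_sd=0.01, seed=4))
        doubled = om.RamanSpectrum(s.wavenumber, 2.0 * s.intensity)
        p1 = om.process_spectrum(s).as_dict()
        p2 = om.process_spectrum(doubled).as_dict()
        for k in METRIC_NAMES:
            assert p2[k] == pytest.approx(p1[k], rel=1e-9)

    def test_zero_amide_iii_is_degenerate(self):
        w = np.arange(340.0, 1811.0)
        bands = [Band("gaussian", 960.0, 7.2, 1.0)]  # mineral only, no matrix
        y = np.sum([b.evaluate(w) for b in bands], axis=0)
        with pytest.raises(DegenerateSpectrumError):
            om.compute_params(om.trim(spectrum_on(w, y)))


class TestAggregation:
    @staticmethod
    def roi_row(subject, compartment, position, mm, quality="ok", roi_id=0):
        return dict(subject=subject, compartment=compartment, position=position,
                    roi_id=roi_id, label_quality=quality, mineral_matrix=mm)

    def test_mean_of_equivalent_rois(self):
        df = pd.DataFrame([self.roi_row("s1", "osteonal", "TA1", v, roi_id=i)
                           for i, v in enumerate([1.0, 2.0, 3.0])])
        out = om.aggregate_statistical_units(df)
        assert len(out) == 1
        assert out.loc[0, "mineral_matrix"] == pytest.approx(2.0)

    def test_flagged_rois_excluded(self):
        df = pd.DataFrame([
            self.roi_row("s1", "osteonal", "TA1", 1.0),
            self.roi_row("s1", "osteonal", "TA1", 2.0),
            self.roi_row("s1", "osteonal", "TA1", 99.0, quality="overlapping-label"),
            self.roi_row("s2", "osteonal", "TA1", 5.0, quality="single-label"),
        ])
        out = om.aggregate_statistical_units(df)
        assert len(out) == 1  # s2 has no valid ROI and yields no row
        assert out.loc[0, "mineral_matrix"] == pytest.approx(1.5)

    def test_row_count_bounded_by_positions_and_compartments(self):
        rows = []
        for comp in ("osteonal", "cancellous"):
            for roi in range(3):
                for pos in ("Os", "TA1", "TA2", "TA3", "In"):
                    rows.append(self.roi_row("s1", comp, pos, 1.0, roi_id=roi))
        out = om.aggregate_statistical_units(pd.DataFrame(rows))
        assert len(out) == 10  # 5 positions x 2 compartments

    def test_tissue_age_gradient_preserved(self):
        """MM rising from the osteoid front to interstitial bone survives the
        spectrum pipeline and ROI averaging."""
        rows = []
        scales = {"Os": 0.6, "TA1": 0.8, "TA2": 1.0, "TA3": 1.2, "In": 1.4}
        k = 0
        for pos, ms in scales.items():
            for roi in range(2):
                spec = om.SpectrumSpec(bands=om.default_bone_bands(mineral_scale=ms),
                                       noise_sd=0.01, seed=900 + k)
                s, _ = om.render_spectrum(spec)
                params = om.process_spectrum(s)
                rows.append(dict(subject="s1", compartment="osteonal", position=pos,
                                 roi_id=roi, label_quality="ok",
                                 **params.as_dict()))
                k += 1
        out = om.aggregate_statistical_units(pd.DataFrame(rows))
        mm = out.sort_values("position")["mineral_matrix"].to_numpy()
        assert np.all(np.diff(mm) > 0)


def test_manifest_pipeline_end_to_end(tmp_path):
    """Spectrum CSVs + manifest run through trim/baseline/metrics and
    aggregate into statistical units, with flagged ROIs dropped."""
    rows = []
    for i, quality in enumerate(["ok", "ok", "overlapping-label"]):
        s, _ = om.render_spectrum(om.SpectrumSpec(noise_sd=0.01, seed=50 + i))
        pd.DataFrame({"wavenumber": s.wavenumber,
                      "intensity": s.intensity}).to_csv(
            tmp_path / f"sp{i}.csv", index=False)
        rows.append(dict(file=f"sp{i}.csv", subject="s1", compartment="osteonal",
                         position="TA2", roi_id=i, label_quality=quality))
    pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
    per_roi = om.process_manifest(tmp_path / "manifest.csv")
    assert len(per_roi) == 3
    units = om.aggregate_statistical_units(per_roi)
    assert len(units) == 1
    expected = per_roi.loc[per_roi.label_quality == "ok", "mineral_matrix"].mean()
    assert units.loc[0, "mineral_matrix"] == pytest.approx(expected)
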