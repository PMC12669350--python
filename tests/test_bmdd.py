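import numpy as np
import pytest
from scipy import optimize, stats as sps

import osteomat as om
from osteomat.errors import EmptyCompartmentError, GridMismatchError
from conftest import make_ca_image


def gaussian_curve(mu, sigma, bin_width=0.17, ca_max=45.0):
    """BMDD curve obtained by discretizing a normal density (no sampling)."""
    edges = np.arange(int(np.ceil(ca_max / bin_width)) + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    freq = sps.norm.pdf(centers, mu, sigma)
    return om.BMDDCurve(bin_edges=edges, frequency=100.0 * freq / freq.sum())


@pytest.fixture(scope="module")
def straddling_cutoffs():
    return om.ReferenceCutoffs(ca_p5=20.0, ca_p95=26.0,
                               pooled=gaussian_curve(23.0, 1.0))


class TestComputeBMDD:
    def test_normalization_and_single_value(self):
        curve = om.compute_bmdd(make_ca_image(np.full((20, 20), 22.0)))
        assert curve.frequency.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.count_nonzero(curve.frequency) == 1
        assert curve.bin_centers[np.argmax(curve.frequency)] == pytest.approx(22.0, abs=0.085)

    def test_two_equal_regions_split_fifty_fifty(self):
        values = np.concatenate([np.full(200, 18.0), np.full(200, 26.0)]).reshape(20, 20)
        curve = om.compute_bmdd(make_ca_image(values))
        nonzero = curve.frequency[curve.frequency > 0]
        assert len(nonzero) == 2
        np.testing.assert_allclose(nonzero, [50.0, 50.0])

    def test_histogram_mean_matches_generating_mean(self, curve):
        spec = om.PhantomSpec(shape=(200, 200), ca_mean=21.0, ca_sd=1.5, seed=11)
        image, _ = om.render_phantom(spec, curve)
        ca = om.apply_calibration(image, curve)
        bmdd = om.compute_bmdd(ca, om.CANCELLOUS)
        ca_mean = np.sum(bmdd.frequency * bmdd.bin_centers) / 100.0
        assert ca_mean == pytest.approx(21.0, abs=0.05)

    def test_sub_threshold_pixels_excluded(self):
        values = np.full((10, 10), 22.0)
        values[0, :5] = 3.0  # void, below 5.2
        curve = om.compute_bmdd(make_ca_image(values))
        assert curve.n_pixels == 95

    def test_empty_compartment_raises(self):
        with pytest.raises(EmptyCompartmentError):
            om.compute_bmdd(make_ca_image(np.full((5, 5), 1.0)))


class TestDeriveParams:
    def test_single_bin_curve(self, straddling_cutoffs):
        curve = om.compute_bmdd(make_ca_image(np.full((20, 20), 22.0)))
        p = om.derive_params(curve, straddling_cutoffs)
        assert p.ca_mean == pytest.approx(22.0, abs=0.085)
        assert p.ca_peak == pytest.approx(p.ca_mean)
        assert p.ca_low == 0.0
        assert p.ca_high == 0.0

    def test_fwhm_of_discretized_gaussian(self, straddling_cutoffs):
        p = om.derive_params(gaussian_curve(21.0, 1.5), straddling_cutoffs)
        assert p.ca_width == pytest.approx(2.3548 * 1.5, rel=0.05)

    def test_ca_mean_matches_raw_pixel_mean_within_half_bin(self, curve):
        spec = om.PhantomSpec(shape=(150, 150), ca_mean=22.5, ca_sd=2.0, seed=13)
        image, _ = om.render_phantom(spec, curve)
        ca = om.apply_calibration(image, curve)
        raw_mean = ca.ca[ca.mineralized_mask()].mean()
        bmdd = om.compute_bmdd(ca)
        hist_mean = np.sum(bmdd.frequency * bmdd.bin_centers) / 100.0
        assert hist_mean == pytest.approx(raw_mean, abs=0.085)

    def test_peak_tie_breaks_to_lowest_calcium(self, straddling_cutoffs):
        edges = np.arange(0, 45.001, 0.17)
        freq = np.zeros(len(edges) - 1)
        freq[[100, 120]] = 50.0  # two equal maxima
        p = om.derive_params(om.BMDDCurve(edges, freq), straddling_cutoffs)
        assert p.ca_peak == pytest.approx(edges[100] + 0.085)

    def test_shift_equivariance(self, straddling_cutoffs):
        rng = np.random.default_rng(5)
        values = rng.normal(21.0, 1.5, size=(60, 60)).clip(6.0, 40.0)
        delta = 10 * 0.17  # whole number of bins keeps discretization identical
        p1 = om.derive_params(om.compute_bmdd(make_ca_image(values)), straddling_cutoffs)
        p2 = om.derive_params(om.compute_bmdd(make_ca_image(values + delta)),
                              straddling_cutoffs)
        assert p2.ca_mean - p1.ca_mean == pytest.approx(delta, abs=1e-9)
        assert p2.ca_peak - p1.ca_peak == pytest.approx(delta, abs=1e-9)
        assert p2.ca_width == pytest.approx(p1.ca_width, abs=1e-9)


class TestPoolReference:
    def test_pooling_identical_curves_is_idempotent(self):
        c = gaussian_curve(22.0, 1.2)
        ref = om.pool_reference([c, c, c])
        np.testing.assert_allclose(ref.pooled.frequency, c.frequency, atol=1e-12)

    def test_two_single_bin_curves_hand_computed_percentiles(self):
        edges = np.arange(0, 45.001, 0.17)

        def single(ca):
            freq = np.zeros(len(edges) - 1)
            freq[int(ca // 0.17)] = 100.0
            return om.BMDDCurve(edges, freq)

        ref = om.pool_reference([single(18.0), single(26.0)])
        k18 = int(18.0 // 0.17)
        # CDF reaches 50% exactly at the upper edge of the 18-bin
        assert ref.pooled.quantile(50.0) == pytest.approx(edges[k18 + 1])
        # p5 lies inside the 18-bin: 5/50 of the way through it
        assert ref.ca_p5 == pytest.approx(edges[k18] + 0.17 * 5.0 / 50.0)
        assert edges[k18] < ref.ca_p5 < edges[k18 + 1]

    def test_cohort_percentiles_match_analytic_mixture(self, reference_cohort):
        curves, means = reference_cohort
        ref = om.pool_reference(curves)

        def mixture_cdf(x):
            return np.mean([sps.norm.cdf(x, mu, 1.5) for mu in means])

        p5 = optimize.brentq(lambda x: mixture_cdf(x) - 0.05, 10, 30)
        p95 = optimize.brentq(lambda x: mixture_cdf(x) - 0.95, 10, 35)
        assert ref.ca_p5 == pytest.approx(p5, abs=0.1)
        assert ref.ca_p95 == pytest.approx(p95, abs=0.1)

    def test_reference_evaluates_to_five_percent_tails(self, reference_cohort):
        curves, _ = reference_cohort
        ref = om.pool_reference(curves)
        p = om.derive_params(ref.pooled, ref)
        assert p.ca_low == pytest.approx(5.0, abs=0.2)
        assert p.ca_high == pytest.approx(5.0, abs=0.2)

    def test_mismatched_grids_rejected(self):
        c1 = gaussian_curve(22.0, 1.2, bin_width=0.17)
        c2 = gaussian_curve(22.0, 1.2, bin_width=0.2)
        with pytest.raises(GridMismatchError):
            om.pool_reference([c1, c2])


class TestMineralizedAreaFraction:
    def test_fully_mineralized(self):
        assert om.mineralized_area_fraction(make_ca_image(np.full((10, 10), 22.0))) == 100.0

    def test_checkerboard_half_mineralized(self):
        values = np.indices((20, 20)).sum(axis=0) % 2 * 22.0
        assert om.mineralized_area_fraction(make_ca_image(values)) == 50.0

    def test_constructed_fraction_exact(self):
        values = np.zeros(400)
        values[:136] = 25.0  # 34% of pixels mineralized by construction
        assert om.mineralized_area_fraction(
            make_ca_image(values.reshape(20, 20))) == pytest.approx(34.0)

    def test_empty_mask_raises(self):
        ca = make_ca_image(np.full((5, 5), 22.0))
        with pytest.raises(EmptyCompartmentError):
            om.mineralized_area_fraction(ca, om.CORTICAL)


def test_curve_csv_round_trip_and_reference_directory(tmp_path):
    c = gaussian_curve(22.0, 1.2)
    om.save_curve_csv(c, tmp_path / "s1.csv")
    om.save_curve_csv(gaussian_curve(21.5, 1.4), tmp_path / "s2.csv")
    loaded = om.load_curve_csv(tmp_path / "s1.csv")
    np.testing.assert_allclose(loaded.bin_edges, c.bin_edges, atol=1e-9)
    np.testing.assert_allclose(loaded.frequency, c.frequency, atol=1e-9)
    ref = om.pool_reference(om.load_reference_curves(tmp_path))
    assert ref.ca_p5 < ref.ca_p95
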