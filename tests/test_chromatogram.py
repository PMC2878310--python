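"""XIC extraction, peak regions, overlap splitting, background, areas."""

import numpy as np
import pytest

from wavequant.chromatogram import (
    Chromatogram,
    PeakRegion,
    estimate_background,
    extract_xic,
    find_peak_region,
    locate_region,
    peak_area,
    split_overlap,
)
from wavequant.errors import EmptyInputError, NoPeakFoundError

from conftest import gaussian_trace


def make_chrom(intensities, interval=1.0):
    n = len(intensities)
    return Chromatogram(
        scan_numbers=np.arange(1, n + 1),
        retention_times=np.arange(n, dtype=float) * interval,
        intensities=np.asarray(intensities, dtype=float),
    )


class TestChromatogramInvariants:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            Chromatogram(np.array([1, 2]), np.array([0.0]), np.array([1.0, 2.0]))

    def test_non_monotone_scans_rejected(self):
        with pytest.raises(ValueError):
            Chromatogram(np.array([2, 1]), np.array([0.0, 1.0]), np.array([1.0, 2.0]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            make_chrom([-1.0, 2.0])


class TestExtractXic:
    def spectra(self):
        return [
            (0.0, np.array([500.0]), np.array([10.0])),
            (1.0, np.array([500.0]), np.array([20.0])),
            (2.0, np.array([500.0]), np.array([10.0])),
        ]

    def test_matching_center(self):
        chrom = extract_xic(self.spectra(), 500.0, 0.5)
        assert np.allclose(chrom.intensities, [10.0, 20.0, 10.0])
        assert np.array_equal(chrom.scan_numbers, [1, 2, 3])

    def test_offset_beyond_tolerance_is_zero(self):
        chrom = extract_xic(self.spectra(), 501.0, 0.5)
        assert np.allclose(chrom.intensities, 0.0)

    def test_multiple_peaks_in_window_are_summed(self):
        spectra = [
            (0.0, np.array([499.8, 500.2, 502.0]), np.array([3.0, 4.0, 50.0])),
            (1.0, np.array([499.9, 500.1]), np.array([6.0, 5.0])),
        ]
        chrom = extract_xic(spectra, 500.0, 0.5)
        assert np.allclose(chrom.intensities, [7.0, 11.0])

    def test_explicit_scan_numbers_and_window(self):
        spectra = [(s, float(s), np.array([500.0]), np.array([1.0 * s])) for s in (5, 6, 7, 8)]
        chrom = extract_xic(spectra, 500.0, 0.5, scan_window=(6, 7))
        assert np.array_equal(chrom.scan_numbers, [6, 7])
        assert np.allclose(chrom.intensities, [6.0, 7.0])

    def test_empty_source_rejected(self):
        with pytest.raises(EmptyInputError):
            extract_xic([], 500.0, 0.5)


class TestFindPeakRegion:
    def test_clean_gaussian_region_spans_a_few_sigma(self):
        sigma = 5.0
        y = gaussian_trace(101, 50.0, 100.0, sigma)
        chrom = make_chrom(y)
        region = find_peak_region(chrom, 51, y)
        assert region.apex_scan == 51
        half_width = (region.end_scan - region.start_scan) / 2.0
        # 5% decay level corresponds to sqrt(2 ln 20) ~ 2.45 sigma each side
        assert 2.0 * sigma <= half_width <= 3.5 * sigma

    def test_flat_zero_trace_raises(self):
        y = np.zeros(50)
        with pytest.raises(NoPeakFoundError):
            find_peak_region(make_chrom(y), 25, y)

    def test_plateau_apex_ties_to_earlier_scan(self):
        y = np.zeros(21)
        y[9] = y[10] = 8.0
        chrom = make_chrom(y)
        region = find_peak_region(chrom, 10, y)
        assert region.apex_scan == 10  # scan numbers are 1-based

    def test_seed_outside_range_rejected(self):
        y = np.ones(10)
        with pytest.raises(ValueError):
            find_peak_region(make_chrom(y), 99, y)


class TestSplitOverlap:
    def overlapping(self, minor_apex=80.0):
        y = gaussian_trace(160, 60.0, 90.0, 5.0) + gaussian_trace(160, minor_apex, 30.0, 5.0)
        return make_chrom(y), y

    def test_major_peak_isolated_with_accurate_area(self):
        chrom, y = self.overlapping()
        region = find_peak_region(chrom, 61, y, background=0.0)
        region.background = 0.0
        out = split_overlap(chrom, region, y, expected_rt=60.0)
        assert out.split_from_overlap
        assert out.start_scan >= region.start_scan and out.end_scan <= region.end_scan
        area = peak_area(chrom, out, y, 0.0)
        true_major = 90.0 * 5.0 * np.sqrt(2.0 * np.pi)
        assert abs(area - true_major) / true_major < 0.10

    def test_minor_peak_chosen_when_expected_rt_matches_it(self):
        chrom, y = self.overlapping()
        region = find_peak_region(chrom, 61, y, background=0.0)
        out = split_overlap(chrom, region, y, expected_rt=80.0)
        assert out.split_from_overlap
        assert abs(out.apex_scan - 81) <= 2

    def test_single_gaussian_unchanged(self):
        y = gaussian_trace(160, 60.0, 90.0, 5.0)
        chrom = make_chrom(y)
        region = find_peak_region(chrom, 61, y, background=0.0)
        out = split_overlap(chrom, region, y, expected_rt=60.0)
        assert not out.split_from_overlap
        assert (out.start_scan, out.end_scan) == (region.start_scan, region.end_scan)

    def test_fully_merged_peaks_not_split(self):
        chrom, y = self.overlapping(minor_apex=62.0)
        region = find_peak_region(chrom, 61, y, background=0.0)
        out = split_overlap(chrom, region, y, expected_rt=60.0)
        assert not out.split_from_overlap


class TestEstimateBackground:
    def test_constant_flanks(self):
        y = np.full(60, 5.0)
        y[25:35] = 50.0
        chrom = make_chrom(y)
        region = PeakRegion(start_scan=26, end_scan=35, apex_scan=30)
        assert estimate_background(chrom, region, y) == 5.0

    def test_zero_baseline_peak(self):
        y = gaussian_trace(101, 50.0, 100.0, 5.0)
        chrom = make_chrom(y)
        region = find_peak_region(chrom, 51, y)
        assert estimate_background(chrom, region, y) == pytest.approx(0.0, abs=0.5)

    def test_noisy_baseline_recovered(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            y = np.maximum(50.0 + rng.normal(0.0, 2.0, 80), 0.0)
            y[35:46] += gaussian_trace(11, 5.0, 200.0, 2.0)
            chrom = make_chrom(y)
            region = PeakRegion(start_scan=36, end_scan=46, apex_scan=41)
            if 46.0 <= estimate_background(chrom, region, y) <= 54.0:
                hits += 1
        assert hits >= 24

    def test_fallback_without_flanks(self):
        y = np.full(10, 7.0)
        chrom = make_chrom(y)
        region = PeakRegion(start_scan=1, end_scan=10, apex_scan=5)
        assert estimate_background(chrom, region, y) == 7.0


class TestPeakArea:
    def test_trace_at_background_integrates_to_zero(self):
        y = np.full(20, 5.0)
        chrom = make_chrom(y)
        region = PeakRegion(start_scan=5, end_scan=15, apex_scan=10)
        assert peak_area(chrom, region, y, background=5.0) == 0.0

    def test_rectangle_trapezoid(self):
        y = np.full(5, 15.0)  # background 5 + height 10, 5 scans at 1 s
        chrom = make_chrom(y)
        region = PeakRegion(start_scan=1, end_scan=5, apex_scan=3)
        assert peak_area(chrom, region, y, background=5.0) == pytest.approx(40.0)

    def test_gaussian_closed_form(self):
        sigma = 5.0
        y = gaussian_trace(101, 50.0, 1.0, sigma)
        chrom = make_chrom(y)
        region = PeakRegion(start_scan=26, end_scan=76, apex_scan=51)  # +/- 5 sigma
        area = peak_area(chrom, region, y, background=0.0)
        assert area == pytest.approx(np.sqrt(2.0 * np.pi) * sigma, rel=0.01)

    def test_area_scales_linearly_with_intensity(self):
        y = gaussian_trace(101, 50.0, 10.0, 5.0)
        chrom = make_chrom(y)
        chrom_scaled = make_chrom(3.0 * y)
        region = PeakRegion(start_scan=31, end_scan=71, apex_scan=51)
        a1 = peak_area(chrom, region, y, 0.0)
        a3 = peak_area(chrom_scaled, region, 3.0 * y, 0.0)
        assert a3 == pytest.approx(3.0 * a1, rel=1e-6)


class TestLocateRegion:
    def test_clean_trace_matches_single_pass(self):
        y = gaussian_trace(101, 50.0, 100.0, 5.0)
        chrom = make_chrom(y)
        one = find_peak_region(chrom, 51, y)
        two = locate_region(chrom, 51, y)
        assert (two.start_scan, two.apex_scan, two.end_scan) == (
            one.start_scan,
            one.apex_scan,
            one.end_scan,
        )

    def test_noisy_baseline_does_not_sprawl(self):
        """Boundaries stop near the peak even when smooth noise rides the baseline."""
        from wavequant.denoise import denoise

        rng = np.random.default_rng(8)
        clean = gaussian_trace(256, 128.0, 100.0, 8.0, baseline=60.0)
        y = np.maximum(clean + rng.normal(0.0, 20.0, 256), 0.0)
        chrom = make_chrom(y)
        region = locate_region(chrom, 129, denoise(y))
        width = region.end_scan - region.start_scan
        assert width <= 8 * 8  # a few peak sigmas, not the whole trace


def test_denoised_integration_not_worse_than_raw():
    """Under the same region protocol at SNR 5, de-noised areas err less than raw."""
    from wavequant.denoise import denoise

    true_area = 100.0 * 8.0 * np.sqrt(2.0 * np.pi)
    raw_errs, den_errs = [], []
    for seed in range(25):
        rng = np.random.default_rng(seed)
        clean = gaussian_trace(256, 128.0, 100.0, 8.0, baseline=60.0)
        y = np.maximum(clean + rng.normal(0.0, 20.0, 256), 0.0)
        chrom = make_chrom(y)
        for trace, sink in ((y, raw_errs), (denoise(y), den_errs)):
            region = locate_region(chrom, 129, trace)
            area = peak_area(chrom, region, trace, region.background)
            sink.append(abs(area - true_area) / true_area)
    assert np.median(den_errs) <= np.median(raw_errs)
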