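import numpy as np
import pytest

from faimsvoc import (
    Chromatogram,
    Peak,
    bin_retention_times,
    detect_peaks,
    find_class_unique_peaks,
    generate_chromatograms,
    read_chromatogram,
    screen_cohort,
    write_chromatogram,
)
from faimsvoc.gcms_screen import PeakBin
from faimsvoc.synthetic_data import UNIQUE_PEAK_RT


def trace(peaks, rt_max=12.0, step=0.005, baseline=0.3, sigma=0.02, noise=0.0, seed=0):
    rt = np.arange(0.0, rt_max, step)
    y = np.full_like(rt, baseline)
    for c, h in peaks:
        y += h * np.exp(-0.5 * ((rt - c) / sigma) ** 2)
    if noise:
        y += np.random.default_rng(seed).normal(0, noise, rt.shape)
    return Chromatogram("S", "CD", rt, y)


class TestDetectPeaks:
    def test_threshold_separates_clear_from_weak_peaks(self):
        chrom = trace([(4.0, 2.5), (8.0, 1.0)])
        found = detect_peaks(chrom, threshold=1.8)
        assert len(found) == 1
        assert found[0].rt_apex == pytest.approx(4.0, abs=0.005)

    def test_flat_trace_has_no_peaks(self):
        assert detect_peaks(trace([]), threshold=1.8) == []

    def test_two_peaks_5_sigma_apart_both_found(self):
        chrom = trace([(6.0, 3.0), (6.1, 2.5)])  # 5 sigma apart
        found = detect_peaks(chrom, threshold=1.8)
        assert len(found) == 2
        assert found[0].rt_apex == pytest.approx(6.0, abs=0.005)
        assert found[1].rt_apex == pytest.approx(6.1, abs=0.005)

    def test_no_peak_at_or_below_threshold(self):
        chrom = trace([(3.0, 1.8), (5.0, 1.799), (7.0, 4.0)], noise=0.05)
        for p in detect_peaks(chrom, threshold=1.8):
            assert p.height > 1.8

    def test_baseline_drift_subtracted(self):
        rt = np.arange(0.0, 12.0, 0.005)
        drift = 2.0 + 0.2 * rt  # slow ramp well above the raw threshold
        y = drift + 2.5 * np.exp(-0.5 * ((rt - 6.0) / 0.02) ** 2)
        found = detect_peaks(Chromatogram("S", "CD", rt, y), threshold=1.8)
        assert len(found) == 1 and found[0].rt_apex == pytest.approx(6.0, abs=0.01)

    def test_unsorted_rt_rejected(self):
        with pytest.raises(ValueError):
            Chromatogram("S", "CD", np.array([1.0, 0.5, 2.0]), np.zeros(3))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(Chromatogram("S", "CD", np.array([0.0, 1.0]), np.ones(2)))

    def test_bounds_bracket_apex(self):
        for p in detect_peaks(trace([(4.0, 3.0), (9.0, 2.2)])):
            assert p.left < p.rt_apex < p.right


def mkpeak(rt, h=2.0):
    return Peak(rt, h, rt - 0.05, rt + 0.05)


class TestBinning:
    def test_no_peaks_no_bins(self):
        assert bin_retention_times([], 0.05) == []

    def test_hand_grouping(self):
        peaks = [("a", "CD", mkpeak(4.66)), ("b", "CD", mkpeak(4.68)),
                 ("c", "D-IBS", mkpeak(7.95))]
        bins = bin_retention_times(peaks, tolerance=0.05)
        assert len(bins) == 2
        assert bins[0].center == pytest.approx(4.67)
        assert len(bins[0].members) == 2

    def test_single_peak_bin_centered_on_apex(self):
        bins = bin_retention_times([("a", "CD", mkpeak(5.3))], 0.05)
        assert len(bins) == 1 and bins[0].center == pytest.approx(5.3)

    def test_binning_is_a_partition(self):
        rng = np.random.default_rng(0)
        peaks = [(f"s{i}", "CD", mkpeak(float(rt)))
                 for i, rt in enumerate(rng.uniform(1, 11, 60))]
        bins = bin_retention_times(peaks, 0.05)
        assert sum(len(b.members) for b in bins) == 60

    def test_bin_span_bounded(self):
        rng = np.random.default_rng(1)
        peaks = [(f"s{i}", "CD", mkpeak(float(rt)))
                 for i, rt in enumerate(np.sort(rng.uniform(4, 6, 80)))]
        for b in bin_retention_times(peaks, 0.05):
            apexes = [p.rt_apex for _, _, p in b.members]
            assert max(apexes) - min(apexes) <= 2 * 0.05 + 1e-12

    def test_adjacent_reported_compounds_not_merged(self):
        # distinct compounds at 7.63 and 7.95 must stay in separate bins
        bins = bin_retention_times(
            [("a", "CD", mkpeak(7.63)), ("b", "CD", mkpeak(7.95))], 0.05)
        assert len(bins) == 2


class TestClassUnique:
    def _bin(self, members):
        b = PeakBin(center=4.67, members=[(s, lab, mkpeak(4.67)) for s, lab in members])
        return b

    def test_full_prevalence_one_class_absent_other(self):
        b = self._bin([(f"c{i}", "CD") for i in range(10)])
        hits = find_class_unique_peaks([b], {"CD": 10, "D-IBS": 8})
        assert hits == [b] and b.unique_class == "CD"

    def test_identical_peak_sets_give_empty_result(self):
        b = self._bin([("c1", "CD"), ("i1", "D-IBS")])
        assert find_class_unique_peaks([b], {"CD": 1, "D-IBS": 1}) == []

    def test_single_other_class_occurrence_disqualifies(self):
        members = [(f"c{i}", "CD") for i in range(20)] + [("i0", "D-IBS")]
        b = self._bin(members)
        assert find_class_unique_peaks([b], {"CD": 20, "D-IBS": 20}) == []

    def test_low_prevalence_not_flagged(self):
        b = self._bin([("c1", "CD"), ("c2", "CD")])
        assert find_class_unique_peaks([b], {"CD": 10, "D-IBS": 5}) == []


class TestEndToEnd:
    def test_default_synthetic_cohort_recovers_the_marker_peak(self):
        cd, ibs = generate_chromatograms(27, 20, seed=5)
        bins, unique = screen_cohort(cd + ibs)
        assert len(unique) == 1
        assert unique[0].unique_class == "CD"
        assert abs(unique[0].center - UNIQUE_PEAK_RT) <= 0.05
        for b in bins:
            for _, _, p in b.members:
                assert p.height > 1.8

    def test_chromatogram_csv_round_trip(self, tmp_path):
        cd, _ = generate_chromatograms(1, 1, seed=6)
        path = tmp_path / "c.csv"
        write_chromatogram(cd[0], path)
        back = read_chromatogram(path, label="CD")
        assert np.allclose(back.rt, cd[0].rt, atol=1e-5)
        assert np.allclose(back.intensity, cd[0].intensity, atol=1e-4)
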