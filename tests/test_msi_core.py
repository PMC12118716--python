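"""MSI containers, I/O round trips, TIC normalisation, peak finding."""

import numpy as np
import pytest

from msic.msi_core import (
    MSIDataset,
    PeakTable,
    Spectrum,
    build_feature_matrix,
    detect_peaks,
    mean_spectrum,
    read_msi,
    tic_normalize,
    write_imzml,
    write_msi,
)
from conftest import make_random_processed_dataset


class TestContainers:
    def test_spectrum_rejects_unsorted_mz(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum([3.0, 2.0, 1.0], [1, 1, 1])

    def test_spectrum_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Spectrum([1.0, 2.0], [1.0])

    def test_dataset_rejects_duplicate_pixels(self):
        s = Spectrum([1000.0], [1.0])
        with pytest.raises(ValueError, match="unique"):
            MSIDataset([(0, 0), (0, 0)], 50.0, [s, s])

    def test_peak_table_rejects_overlapping_intervals(self):
        with pytest.raises(ValueError, match="disjoint"):
            PeakTable([1000.0, 1000.5], [999.6, 1000.1], [1000.4, 1000.9])


class TestIO:
    def test_fixture_round_trip_is_exact(self, tmp_path):
        ds = make_random_processed_dataset(0)
        write_msi(ds, tmp_path / "d.npz")
        back = read_msi(tmp_path / "d.npz")
        assert back.spacing_um == ds.spacing_um
        assert np.array_equal(back.coords, ds.coords)
        for a, b in zip(ds.spectra, back.spectra):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_imzml_round_trip(self, tmp_path):
        ds = make_random_processed_dataset(1, n_pixels=4)
        write_imzml(ds, tmp_path / "d.imzML")
        back = read_msi(tmp_path / "d.imzML", spacing_um=50.0)
        assert back.n_pixels == ds.n_pixels
        order = {tuple(c): i for i, c in enumerate(back.coords)}
        for i, c in enumerate(ds.coords):
            j = order[tuple(c)]
            np.testing.assert_allclose(back.spectra[j].mz, ds.spectra[i].mz, atol=1e-6)
            np.testing.assert_allclose(
                back.spectra[j].intensity, ds.spectra[i].intensity, atol=1e-6
            )

    def test_imzml_without_pixel_size_names_missing_field(self, tmp_path):
        ds = make_random_processed_dataset(2, n_pixels=4)
        write_imzml(ds, tmp_path / "d.imzML")
        with pytest.raises(ValueError, match="pixel size x"):
            read_msi(tmp_path / "d.imzML")


class TestTicNormalize:
    def test_two_pixel_mean_tic_scaling(self):
        # TICs {10, 30} -> both scaled to the mean 20: x2 and x(2/3)
        ds = MSIDataset(
            [(0, 0), (1, 0)],
            50.0,
            [Spectrum([1000.0, 1100.0], [4.0, 6.0]), Spectrum([1000.0], [30.0])],
        )
        out = tic_normalize(ds)
        np.testing.assert_allclose(out.spectra[0].intensity, [8.0, 12.0])
        np.testing.assert_allclose(out.spectra[1].intensity, [20.0])

    def test_single_pixel_unchanged(self):
        ds = MSIDataset([(0, 0)], 50.0, [Spectrum([1000.0, 1200.0], [2.0, 5.0])])
        out = tic_normalize(ds)
        np.testing.assert_allclose(out.spectra[0].intensity, [2.0, 5.0])

    def test_relative_intensities_preserved(self):
        ds = make_random_processed_dataset(3)
        out = tic_normalize(ds)
        for a, b in zip(ds.spectra, out.spectra):
            np.testing.assert_allclose(
                b.intensity / b.intensity.sum(), a.intensity / a.intensity.sum()
            )

    def test_idempotent_and_equalised(self):
        ds = make_random_processed_dataset(4, n_pixels=9)
        once = tic_normalize(ds)
        twice = tic_normalize(once)
        tics = once.tics()
        assert tics.std() < 1e-9 * tics.mean()
        for a, b in zip(once.spectra, twice.spectra):
            np.testing.assert_allclose(b.intensity, a.intensity, rtol=1e-9)

    def test_zero_tic_pixels_flagged_and_all_zero_errors(self):
        ds = MSIDataset(
            [(0, 0), (1, 0)],
            50.0,
            [Spectrum([1000.0], [0.0]), Spectrum([1000.0], [10.0])],
        )
        out = tic_normalize(ds)
        assert out.metadata["excluded_pixels"] == [0]
        all_zero = MSIDataset([(0, 0)], 50.0, [Spectrum([1000.0], [0.0])])
        with pytest.raises(ValueError, match="zero TIC"):
            tic_normalize(all_zero)


class TestMeanSpectrum:
    def test_identical_pixels_equal_single_binned(self):
        s = Spectrum([1000.05, 1000.55, 1200.15], [5.0, 2.0, 7.0])
        ds = MSIDataset([(0, 0), (1, 0)], 50.0, [s, s])
        m = mean_spectrum(ds, grid_da=0.1, mz_range=(1000.0, 1201.0))
        m1 = mean_spectrum(
            MSIDataset([(0, 0)], 50.0, [s]), grid_da=0.1, mz_range=(1000.0, 1201.0)
        )
        np.testing.assert_allclose(m.intensity, m1.intensity)

    def test_mean_of_present_and_absent_bin_values(self):
        # one pixel has 4 in the bin, the other nothing -> mean 2
        ds = MSIDataset(
            [(0, 0), (1, 0)],
            50.0,
            [Spectrum([1000.05], [4.0]), Spectrum([1500.0], [1.0])],
        )
        m = mean_spectrum(ds, grid_da=0.1, mz_range=(1000.0, 1000.1))
        np.testing.assert_allclose(m.intensity, [2.0])

    def test_matches_brute_force_loop(self):
        ds = make_random_processed_dataset(5, n_pixels=5)
        lo, hi, grid = 800.0, 3200.0, 0.5
        m = mean_spectrum(ds, grid, (lo, hi))
        n_bins = int(np.ceil((hi - lo) / grid))
        expect = np.zeros(n_bins)
        for b in range(n_bins):
            blo, bhi = lo + b * grid, lo + (b + 1) * grid
            tot = 0.0
            for s in ds.spectra:
                inside = s.intensity[(s.mz >= blo) & (s.mz < bhi)]
                tot += inside.max() if len(inside) else 0.0
            expect[b] = tot / ds.n_pixels
        np.testing.assert_allclose(m.intensity, expect)

    def test_rejects_bad_grid(self):
        ds = make_random_processed_dataset(6)
        with pytest.raises(ValueError, match="grid_da"):
            mean_spectrum(ds, grid_da=0.0)


def _gaussian_mean_spectrum(centers, rng, lo=900.0, hi=1600.0, grid=0.1,
                            noise_sd=0.0, baseline=2.0):
    mz = np.arange(lo, hi, grid)
    y = baseline + np.abs(rng.normal(0.0, noise_sd, len(mz))) if noise_sd else (
        np.full(len(mz), baseline)
    )
    for c in centers:
        y = y + 50.0 * np.exp(-0.5 * ((mz - c) / 0.2) ** 2)
    return Spectrum(mz, y)


class TestDetectPeaks:
    def test_recovers_planted_gaussians(self):
        mean = _gaussian_mean_spectrum([1000.0, 1500.0], np.random.default_rng(0))
        pt = detect_peaks(mean, snr_min=3.0, half_width_da=0.4)
        containing = [
            c for c in (1000.0, 1500.0) if np.any((pt.lo <= c) & (pt.hi >= c))
        ]
        assert containing == [1000.0, 1500.0]
        assert len(pt) == 2

    def test_flat_spectrum_has_no_peaks(self):
        mean = Spectrum(np.arange(1000.0, 1010.0, 0.1), np.full(100, 3.0))
        assert len(detect_peaks(mean)) == 0

    def test_close_peaks_truncated_at_midpoint(self):
        mz = np.arange(999.0, 1001.5, 0.1)
        y = np.zeros(len(mz))
        y[np.argmin(np.abs(mz - 1000.0))] = 10.0
        y[np.argmin(np.abs(mz - 1000.5))] = 8.0
        pt = detect_peaks(Spectrum(mz, y), half_width_da=0.4, noise_mode="none")
        assert len(pt) == 2
        assert pt.hi[0] <= pt.lo[1]
        mid = (pt.centers[0] + pt.centers[1]) / 2
        np.testing.assert_allclose([pt.hi[0], pt.lo[1]], [mid, mid])

    def test_intervals_always_disjoint_sorted(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mean = _gaussian_mean_spectrum(
                rng.uniform(950, 1550, 12), rng, noise_sd=0.5
            )
            pt = detect_peaks(mean)
            assert np.all(np.diff(pt.centers) > 0)
            assert np.all(pt.hi[:-1] <= pt.lo[1:])


class TestFeatureMatrix:
    def test_max_in_interval_by_hand(self):
        ds = MSIDataset(
            [(0, 0)], 50.0, [Spectrum([1477.7, 1477.9], [10.0, 12.0])]
        )
        pt = PeakTable([1477.8], [1477.4], [1478.2])
        fm = build_feature_matrix(ds, pt)
        assert fm.values[0, 0] == 12.0

    def test_empty_interval_is_zero(self):
        ds = MSIDataset([(0, 0)], 50.0, [Spectrum([1600.0], [9.0])])
        pt = PeakTable([1477.8], [1477.4], [1478.2])
        assert build_feature_matrix(ds, pt).values[0, 0] == 0.0

    def test_matches_per_pixel_brute_force(self):
        ds = make_random_processed_dataset(7, n_pixels=8, n_points=60)
        rng = np.random.default_rng(8)
        centers = np.sort(rng.uniform(900, 3100, 20))
        pt = detect_peaks(
            _gaussian_mean_spectrum(centers, rng, 800, 3200), half_width_da=0.4
        )
        fm = build_feature_matrix(ds, pt)
        for p, s in enumerate(ds.spectra):
            for k in range(len(pt)):
                inside = s.intensity[(s.mz >= pt.lo[k]) & (s.mz <= pt.hi[k])]
                expect = inside.max() if len(inside) else 0.0
                assert fm.values[p, k] == expect

    def test_empty_peak_table_rejected(self):
        ds = make_random_processed_dataset(9)
        with pytest.raises(ValueError, match="empty"):
            build_feature_matrix(ds, PeakTable([], [], []))
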