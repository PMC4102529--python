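"""Spectrum containers, the plate-scan format, and band arithmetic."""

import numpy as np
import pytest

from fretassay import (
    EmissionSpectrum,
    PlateScan,
    SimulationSpec,
    WellRole,
    average_replicates,
    integrate_band,
    peak_intensity,
    read_plate_scan,
    simulate_titration,
    subtract_background,
    write_plate_scan,
)
from fretassay.spectra import (
    ConsistencyError,
    FormatError,
    RangeError,
    ValidationError,
)

from conftest import make_spectrum


class TestContainers:
    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            make_spectrum([1.0, 2.0, 3.0], wavelengths=[500.0, 502.0, 501.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError, match="equally long"):
            make_spectrum([1.0, 2.0], wavelengths=[500.0, 501.0, 502.0])

    def test_well_role_requires_inhibitor_fields_iff_inhibitor_role(self):
        with pytest.raises(ValidationError):
            WellRole(role="mixture", inhibitor_id="x", inhibitor_conc_uM=1.0)
        with pytest.raises(ValidationError):
            WellRole(role="mixture_inhibitor")
        WellRole(role="mixture_inhibitor", donor_conc_nM=100.0, acceptor_conc_nM=100.0,
                 inhibitor_id="x", inhibitor_conc_uM=1.0)

    def test_plate_requires_every_layout_well_at_each_excitation(self):
        s = make_spectrum([1.0, 2.0])
        with pytest.raises(ConsistencyError, match="missing a scan"):
            PlateScan(
                spectra={("A1", 470.0): s},
                layout={"A1": WellRole(role="blank"), "A2": WellRole(role="blank")},
            )


class TestPlateFormat:
    def test_fixture_counts_and_roundtrip(self, tmp_path):
        spec = SimulationSpec(
            seed=5, noise_cv=0.02, n_samples=1, n_reads=1,
            acceptor_totals_nM=(0.0, 100.0, 400.0),
            donor_cal_concs_nM=(100.0,), acceptor_cal_concs_nM=(100.0,),
            n_blanks=1,
        )
        plate, _ = simulate_titration(spec)
        path = tmp_path / "plate.tsv"
        write_plate_scan(plate, path)
        back = read_plate_scan(path)
        assert len(back.spectra) == len(plate.spectra)
        assert back.layout == plate.layout
        for key, s in plate.spectra.items():
            np.testing.assert_array_equal(back.spectra[key].intensities, s.intensities)
        # write -> read -> write is byte-identical
        path2 = tmp_path / "again.tsv"
        write_plate_scan(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#gain=100\n#oops\nwell_id\n")
        with pytest.raises(FormatError, match="line 2"):
            read_plate_scan(path)

    def test_duplicate_scan_point_rejected(self, tmp_path):
        header = "\t".join(
            ["well_id", "role", "donor_conc_nM", "acceptor_conc_nM", "inhibitor_id",
             "inhibitor_conc_uM", "excitation_nm", "wavelength_nm", "intensity"]
        )
        row = "A1\tblank\t0\t0\t\t\t470\t520\t1.0"
        path = tmp_path / "dup.tsv"
        path.write_text(f"#gain=100\n{header}\n{row}\n{row}\n")
        with pytest.raises(ConsistencyError, match="duplicated"):
            read_plate_scan(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("well_id\trole\nA1\tblank\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_plate_scan(path)


class TestBackground:
    def test_identity_and_zero_blank(self):
        s = make_spectrum([10.0, 20.0])
        assert np.all(subtract_background(s, s).intensities == 0.0)
        zero = s.with_intensities([0.0, 0.0])
        np.testing.assert_array_equal(
            subtract_background(s, zero).intensities, s.intensities
        )

    def test_pointwise_difference_and_inverse(self):
        s = make_spectrum([10.0, 20.0])
        blank = make_spectrum([1.0, 2.0])
        out = subtract_background(s, blank)
        np.testing.assert_array_equal(out.intensities, [9.0, 18.0])
        restored = out.with_intensities(out.intensities + blank.intensities)
        np.testing.assert_array_equal(restored.intensities, s.intensities)

    def test_grid_mismatch_is_error_not_interpolation(self):
        s = make_spectrum([1.0, 2.0], wavelengths=[500.0, 501.0])
        blank = make_spectrum([1.0, 2.0], wavelengths=[500.5, 501.5])
        with pytest.raises(ValidationError, match="grids"):
            subtract_background(s, blank)


class TestAverageReplicates:
    def test_identical_spectra_mean_equals_input_rms_zero(self):
        s = make_spectrum([3.0, 4.0])
        mean, rms = average_replicates([s, s])
        np.testing.assert_array_equal(mean.intensities, s.intensities)
        np.testing.assert_array_equal(rms, 0.0)

    def test_hand_computed_mean_and_rms(self):
        a = make_spectrum([0.0, 10.0])
        b = make_spectrum([2.0, 10.0])
        mean, rms = average_replicates([a, b])
        np.testing.assert_allclose(mean.intensities, [1.0, 10.0])
        np.testing.assert_allclose(rms, [1.0, 0.0])

    def test_mean_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        scans = [make_spectrum(rng.uniform(1, 2, size=5)) for _ in range(5)]
        mean_fwd, rms_fwd = average_replicates(scans)
        mean_rev, rms_rev = average_replicates(scans[::-1])
        np.testing.assert_allclose(mean_fwd.intensities, mean_rev.intensities)
        np.testing.assert_allclose(rms_fwd, rms_rev)

    def test_multiplicative_noise_recovers_cv(self):
        rng = np.random.default_rng(42)
        sigma = np.sqrt(np.log1p(0.02**2))
        base = np.full(8, 1000.0)
        scans = [
            make_spectrum(base * np.exp(sigma * rng.standard_normal(8) - sigma**2 / 2))
            for _ in range(500)
        ]
        mean, rms = average_replicates(scans)
        ratio = rms / mean.intensities
        assert np.all((ratio > 0.015) & (ratio < 0.025))

    def test_mixed_excitation_rejected(self):
        a = make_spectrum([1.0, 2.0], excitation_nm=470.0)
        b = make_spectrum([1.0, 2.0], excitation_nm=530.0)
        with pytest.raises(ValidationError, match="excitation"):
            average_replicates([a, b])


class TestIntegrateBand:
    def test_constant_spectrum_rectangle(self):
        wl = np.arange(550.0, 621.0)
        s = make_spectrum(np.full(len(wl), 7.0), wavelengths=wl)
        assert integrate_band(s, 560.0, 610.0) == pytest.approx(50.0 * 7.0)

    def test_triangle_area(self):
        wl = np.array([500.0, 510.0, 520.0])
        s = make_spectrum([0.0, 100.0, 0.0], wavelengths=wl)
        assert integrate_band(s, 500.0, 520.0) == pytest.approx(0.5 * 20.0 * 100.0)

    def test_gaussian_band_against_oversampled_oracle(self):
        def gauss(x):
            return np.exp(-0.5 * ((x - 570.0) / 15.0) ** 2)

        coarse = np.arange(500.0, 651.0, 1.0)
        fine = np.arange(500.0, 650.01, 0.1)
        coarse_val = integrate_band(make_spectrum(gauss(coarse), coarse), 560.0, 610.0)
        fine_val = integrate_band(make_spectrum(gauss(fine), fine), 560.0, 610.0)
        assert coarse_val == pytest.approx(fine_val, rel=5e-3)

    def test_interpolated_endpoints_off_grid(self):
        wl = np.array([500.0, 502.0])
        s = make_spectrum([0.0, 2.0], wavelengths=wl)  # slope 1
        # integral of (x - 500) over [500.5, 501.5] = 1.0
        assert integrate_band(s, 500.5, 501.5) == pytest.approx(1.0)

    def test_additive_over_adjacent_windows(self):
        rng = np.random.default_rng(3)
        wl = np.arange(500.0, 601.0)
        s = make_spectrum(rng.uniform(0, 100, len(wl)), wavelengths=wl)
        total = integrate_band(s, 505.3, 590.7)
        split = integrate_band(s, 505.3, 547.1) + integrate_band(s, 547.1, 590.7)
        assert split == pytest.approx(total, rel=1e-12)

    def test_window_outside_span_rejected(self):
        s = make_spectrum([1.0, 2.0], wavelengths=[500.0, 501.0])
        with pytest.raises(RangeError):
            integrate_band(s, 499.0, 501.0)
        with pytest.raises(RangeError):
            integrate_band(s, 501.0, 500.0)


class TestPeakIntensity:
    def test_zero_halfwidth_at_grid_point_is_exact(self):
        wl = np.arange(500.0, 511.0)
        s = make_spectrum(2.0 * wl, wavelengths=wl)
        assert peak_intensity(s, 505.0, 0.0) == pytest.approx(1010.0)

    def test_zero_halfwidth_midpoint_interpolates(self):
        s = make_spectrum([10.0, 20.0], wavelengths=[500.0, 501.0])
        assert peak_intensity(s, 500.5, 0.0) == pytest.approx(15.0)

    def test_windowed_mean_of_quadratic_band_matches_closed_form(self):
        wl = np.arange(500.0, 541.0)
        s = make_spectrum(100.0 - (wl - 520.0) ** 2, wavelengths=wl)
        # mean of max - (x-c)^2 over c +- h is max - h^2/3; trapezoid on the
        # 1-nm grid adds the standard -1/6 per-interval correction.
        hw = 2.0
        expected = 100.0 - hw**2 / 3.0
        assert peak_intensity(s, 520.0, hw) == pytest.approx(expected, abs=0.2)
        assert peak_intensity(s, 520.0, hw) == pytest.approx(100.0, rel=0.02)

    def test_window_outside_span_rejected(self):
        s = make_spectrum([1.0, 2.0], wavelengths=[500.0, 501.0])
        with pytest.raises(RangeError):
            peak_intensity(s, 502.0, 0.0)
        with pytest.raises(RangeError):
            peak_intensity(s, 500.5, 1.0)
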