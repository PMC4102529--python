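"""Cross-talk factors, FRET decomposition, and the efficiency estimator."""

import numpy as np
import pytest

from fretassay import (
    AnalysisWindows,
    RatioFactors,
    SimulationSpec,
    fret_efficiency,
    fret_signal,
    ratio_factor_a,
    ratio_factor_b,
    simulate_screen,
    simulate_titration,
)
from fretassay.fret import (
    background_corrected,
    calibration_factors,
    titration_from_plate,
)
from fretassay.simulate import InhibitorSpec
from fretassay.spectra import (
    DegenerateInputError,
    ValidationError,
    average_replicates,
)

from conftest import make_spectrum


def band_with_ratio(ratio, conc=1.0, wl=None):
    """A two-peak spectrum whose 570:520 windowed readout equals ``ratio``."""
    if wl is None:
        wl = np.arange(480.0, 651.0)
    donor = np.exp(-0.5 * ((wl - 520.0) / 12.0) ** 2)
    red = np.exp(-0.5 * ((wl - 570.0) / 12.0) ** 2)
    # calibrate through the same +-2 nm readout the estimator uses
    from fretassay.spectra import peak_intensity

    def m(profile, c):
        return peak_intensity(make_spectrum(profile, wl), c, 2.0)

    mat = np.array([[m(donor, 520.0), m(red, 520.0)], [m(donor, 570.0), m(red, 570.0)]])
    alpha, beta = np.linalg.solve(mat, [1.0, ratio])
    return make_spectrum(conc * (alpha * donor + beta * red), wl)


class TestRatioFactorA:
    def test_reported_bleed_through_recovered_across_concentrations(self):
        spectra = [band_with_ratio(0.129, conc) for conc in (100.0, 200.0, 300.0)]
        a, rms = ratio_factor_a(spectra)
        assert a == pytest.approx(0.129, abs=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_zero_red_emission_gives_zero(self):
        wl = np.arange(480.0, 651.0)
        donor_only = np.where(wl < 560.0, np.exp(-0.5 * ((wl - 520.0) / 12.0) ** 2), 0.0)
        a, _ = ratio_factor_a([make_spectrum(donor_only, wl)])
        assert a == 0.0

    def test_scale_invariance_zero_rms(self):
        base = band_with_ratio(0.2)
        scaled = [base.with_intensities(c * base.intensities) for c in (1.0, 3.0, 7.5)]
        a, rms = ratio_factor_a(scaled)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_zero_donor_peak_is_degenerate(self):
        wl = np.arange(480.0, 651.0)
        with pytest.raises(DegenerateInputError):
            ratio_factor_a([make_spectrum(np.zeros_like(wl), wl)])


class TestRatioFactorB:
    def test_target_crosstalk_recovered(self):
        wl = np.arange(480.0, 651.0)
        band = np.exp(-0.5 * ((wl - 570.0) / 15.0) ** 2)
        ex_a = [make_spectrum(c * band, wl, excitation_nm=530.0) for c in range(1, 6)]
        ex_470 = [make_spectrum(0.101 * c * band, wl) for c in range(1, 6)]
        b, rms = ratio_factor_b(ex_470, ex_a)
        assert b == pytest.approx(0.101, abs=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_zero_direct_excitation_gives_zero(self):
        wl = np.arange(480.0, 651.0)
        band = np.exp(-0.5 * ((wl - 570.0) / 15.0) ** 2)
        ex_a = [make_spectrum(band, wl, excitation_nm=530.0)]
        b, _ = ratio_factor_b([make_spectrum(np.zeros_like(wl), wl)], ex_a)
        assert b == 0.0

    def test_identical_scans_flagged_as_boundary(self):
        wl = np.arange(480.0, 651.0)
        band = [make_spectrum(np.exp(-0.5 * ((wl - 570.0) / 15.0) ** 2), wl)]
        with pytest.warns(UserWarning, match="b >= 1"):
            b, _ = ratio_factor_b(band, band)
        assert b == pytest.approx(1.0)

    def test_unmatched_series_rejected(self):
        wl = np.arange(480.0, 651.0)
        s = make_spectrum(np.ones_like(wl), wl)
        with pytest.raises(ValidationError, match="equal length"):
            ratio_factor_b([s, s], [s])


class TestFretSignal:
    FACTORS = RatioFactors(a=0.129, b=0.101)

    def test_direct_arithmetic(self):
        assert fret_signal(1000.0, 2000.0, 3000.0, self.FACTORS) == pytest.approx(439.0)

    def test_no_fret_identity(self):
        f_d, f_a = 1500.0, 800.0
        f_da = 0.129 * f_d + 0.101 * f_a
        assert fret_signal(f_da, f_d, f_a, self.FACTORS) == pytest.approx(0.0, abs=1e-12)

    def test_zero_factors_pass_through(self):
        z = RatioFactors(a=0.0, b=0.0)
        assert fret_signal(1234.0, 99.0, 99.0, z) == 1234.0

    def test_linearity_in_each_argument(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            da, d, a_, s, t = rng.uniform(0.1, 1e4, 5)
            lhs = fret_signal(s * da, d, a_, self.FACTORS) + fret_signal(
                t * da, d, a_, self.FACTORS
            )
            rhs = fret_signal((s + t) * da, d, a_, self.FACTORS) + fret_signal(
                0.0, d, a_, self.FACTORS
            )
            assert lhs == pytest.approx(rhs, rel=1e-9)


@pytest.fixture(scope="module")
def references():
    """Noiseless screen plate's reference spectra and absorbances."""
    spec = SimulationSpec(
        seed=2, noise_cv=0.0, n_samples=1, n_reads=1,
        inhibitors=(InhibitorSpec("i", 1.0, (1.0,)),),
    )
    plate, ledger = simulate_screen(spec)
    corrected = background_corrected(plate)
    groups = corrected.conditions()

    def mean_of(role, ex, conc=None, idx=2):
        keys = sorted(
            k for k in groups if k[0] == role and (conc is None or k[idx] == conc)
        )
        scans = [corrected.spectrum(w, ex) for w in groups[keys[0]]]
        return scans[0] if len(scans) == 1 else average_replicates(scans)[0]

    return {
        "mix": mean_of("mixture", 470.0),
        "donor": mean_of("donor_only", 470.0, 100.0, idx=1),
        "acc470": mean_of("acceptor_only", 470.0, 100.0),
        "accA": mean_of("acceptor_only", 530.0, 100.0),
        "a_d": ledger["truth"]["a_d_470"],
        "a_a": ledger["truth"]["a_a_470"],
    }


class TestEfficiency:
    def test_target_efficiency_roundtrip(self, references):
        r = references
        res = fret_efficiency(r["mix"], r["donor"], r["acc470"], r["accA"],
                              a_d=r["a_d"], a_a=r["a_a"])
        assert res.efficiency_pct == pytest.approx(53.51, rel=1e-6)

    def test_no_sensitization_gives_zero(self, references):
        r = references
        synthetic_mix = r["mix"].with_intensities(
            0.7 * r["donor"].intensities + r["acc470"].intensities
        )
        res = fret_efficiency(synthetic_mix, r["donor"], r["acc470"], r["accA"],
                              a_d=r["a_d"], a_a=r["a_a"])
        assert res.efficiency_pct == pytest.approx(0.0, abs=1e-9)

    def test_homogeneity_degree_zero(self, references):
        r = references
        scaled = {
            k: r[k].with_intensities(3.7 * r[k].intensities)
            for k in ("mix", "donor", "acc470", "accA")
        }
        base = fret_efficiency(r["mix"], r["donor"], r["acc470"], r["accA"],
                               a_d=r["a_d"], a_a=r["a_a"])
        up = fret_efficiency(scaled["mix"], scaled["donor"], scaled["acc470"],
                             scaled["accA"], a_d=r["a_d"], a_a=r["a_a"])
        assert up.efficiency_pct == pytest.approx(base.efficiency_pct, rel=1e-9)

    def test_zero_acceptor_reference_is_degenerate(self, references):
        r = references
        zero = r["accA"].with_intensities(np.zeros_like(r["accA"].intensities))
        with pytest.raises(DegenerateInputError):
            fret_efficiency(r["mix"], r["donor"], r["acc470"], zero,
                            a_d=r["a_d"], a_a=r["a_a"])


class TestPlatePipeline:
    def test_calibration_factors_match_generator(self, noiseless_titration):
        _, plate, ledger = noiseless_titration
        factors = calibration_factors(plate)
        assert factors.a == pytest.approx(ledger["truth"]["a"], abs=1e-9)
        assert factors.b == pytest.approx(ledger["truth"]["b"], abs=1e-9)
        assert factors.n_a == 3 and factors.n_b == 5

    def test_noiseless_f_fret_matches_latent_truth(self, noiseless_titration):
        _, plate, ledger = noiseless_titration
        series, records = titration_from_plate(plate)
        truth = np.array([c["f_fret_true"] for c in ledger["truth"]["conditions"]])
        np.testing.assert_allclose(series.f_fret, truth, atol=1e-8)
        assert all(np.isclose(r["F_FRET"], t, atol=1e-8) for r, t in zip(records, truth))

    def test_zero_binding_yields_zero_fret_and_zero_efficiency(self):
        spec = SimulationSpec(
            seed=9, noise_cv=0.0, n_samples=1, n_reads=1, kd_nM=1e6,
            f_fret_max_RFU=1e-9, e_complex=0.0,
        )
        plate, _ = simulate_titration(spec)
        series, _ = titration_from_plate(plate)
        np.testing.assert_allclose(series.f_fret, 0.0, atol=1e-6)

    def test_f_fret_monotone_in_bound_fraction(self):
        """Lower kd -> larger bound fraction -> strictly larger F_FRET."""
        extracted = []
        for kd in (300.0, 30.0, 3.0):
            spec = SimulationSpec(seed=4, noise_cv=0.0, n_samples=1, n_reads=1, kd_nM=kd)
            plate, _ = simulate_titration(spec)
            series, _ = titration_from_plate(plate)
            extracted.append(series.f_fret[1:])  # skip acceptor == 0
        assert np.all(extracted[1] > extracted[0])
        assert np.all(extracted[2] > extracted[1])

    def test_factor_scale_invariance_under_global_gain(self):
        """Doubling every band amplitude (instrument gain) leaves a, b fixed."""
        lo = SimulationSpec(seed=6, noise_cv=0.0, n_samples=1, n_reads=1)
        hi_bands = {
            "donor_band": type(lo.donor_band)(520.0, 35.0, 0.15, 80.0),
            "acceptor_band": type(lo.acceptor_band)(570.0, 40.0, 0.15, 20.0),
        }
        hi = SimulationSpec(seed=6, noise_cv=0.0, n_samples=1, n_reads=1, **hi_bands)
        f_lo = calibration_factors(simulate_titration(lo)[0])
        f_hi = calibration_factors(simulate_titration(hi)[0])
        assert f_hi.a == pytest.approx(f_lo.a, rel=1e-9)
        assert f_hi.b == pytest.approx(f_lo.b, rel=1e-9)
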