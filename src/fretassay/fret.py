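"""Cross-talk ratio factors, FRET-signal decomposition, and the
cross-talk-corrected sensitized-emission efficiency estimator.

A two-color steady-state FRET well read under donor excitation mixes three
contributions at the acceptor emission wavelength (570 nm): donor
bleed-through, directly excited acceptor emission, and the sensitized
emission that actually reports energy transfer.  Two plate-wide calibration
factors separate them:

``a``
    donor bleed-through: the 570/520 nm emission ratio of donor-only wells
    under donor (470 nm) excitation.
``b``
    acceptor direct-excitation factor: the 570 nm emission of acceptor-only
    wells under 470 nm excitation divided by that under acceptor-band
    excitation.

The sensitized FRET signal of a mixture well is then

    F_FRET = F_DA - a * F_D - b * F_A

with F_D the mixture's 520-nm intensity (ex 470), F_DA its 570-nm intensity
(ex 470) and F_A its 570-nm intensity under acceptor-band excitation.

The spectral efficiency estimator generalizes the same bookkeeping to the
560-610 nm window:

    S  = integral over the window of
         [ f_mix - (f_mix(520)/f_D(520)) * f_D - f_A,470 ]
    E% = 100 * (A_A / A_D) * S / integral(f_A,exA)

where f_D, f_A,470, f_A,exA are donor-only and acceptor-only reference scans
measured at the mixture's conjugate concentrations, and A_D, A_A are the
donor and acceptor absorbances at 470 nm.  Scaling the donor reference to
the mixture's own 520-nm peak subtracts the bleed-through of the remaining
unquenched donor (the spectral analogue of the ``a`` factor).  The exact
published algebra of this estimator exists only as a figure in the source
literature; this reconstruction follows the standard sensitized-emission
method and is kept behind this single function so it can be swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding import TitrationSeries
from .spectra import (
    DegenerateInputError,
    EmissionSpectrum,
    PlateScan,
    ValidationError,
    average_replicates,
    integrate_band,
    peak_intensity,
    subtract_background,
)

__all__ = [
    "AnalysisWindows",
    "RatioFactors",
    "FretDecomposition",
    "EfficiencyResult",
    "ratio_factor_a",
    "ratio_factor_b",
    "fret_signal",
    "decompose",
    "fret_efficiency",
    "background_corrected",
    "condition_mean_spectra",
    "titration_from_plate",
]


@dataclass(frozen=True)
class AnalysisWindows:
    """Wavelength windows and excitation settings driving the analysis.

    ``acceptor_ex_nm`` is authoritative for which scan counts as the
    acceptor's direct-excitation read (the instrument protocol quotes both
    530 and 540 nm; default 530).
    """

    donor_peak_nm: float = 520.0
    acceptor_peak_nm: float = 570.0
    peak_halfwidth_nm: float = 2.0
    window_nm: tuple[float, float] = (560.0, 610.0)
    donor_ex_nm: float = 470.0
    acceptor_ex_nm: float = 530.0
    a_d_470: float | None = None  # donor absorbance at 470 nm
    a_a_470: float | None = None  # acceptor absorbance at 470 nm


@dataclass(frozen=True)
class RatioFactors:
    """Plate-wide cross-talk factors with their spreads across the
    calibration concentration series."""

    a: float
    b: float
    a_rms: float = 0.0
    b_rms: float = 0.0
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValidationError("ratio factors must be >= 0")
        if self.a_rms < 0 or self.b_rms < 0:
            raise ValidationError("ratio factor rms must be >= 0")
        for name, v in (("a", self.a), ("b", self.b)):
            if v >= 1:
                warnings.warn(
                    f"ratio factor {name} = {v:.3g} is outside the expected "
                    "[0, 1) range; cross-talk exceeding the reference signal "
                    "indicates a calibration problem",
                    stacklevel=2,
                )

    @classmethod
    def from_calibration(
        cls,
        donor_only_ex470: Sequence[EmissionSpectrum],
        acceptor_only_ex470: Sequence[EmissionSpectrum],
        acceptor_only_exA: Sequence[EmissionSpectrum],
        windows: AnalysisWindows = AnalysisWindows(),
    ) -> "RatioFactors":
        a, a_rms = ratio_factor_a(donor_only_ex470, windows)
        b, b_rms = ratio_factor_b(acceptor_only_ex470, acceptor_only_exA, windows)
        return cls(
            a=a,
            b=b,
            a_rms=a_rms,
            b_rms=b_rms,
            n_a=len(donor_only_ex470),
            n_b=len(acceptor_only_ex470),
        )


def ratio_factor_a(
    donor_only: Sequence[EmissionSpectrum],
    windows: AnalysisWindows = AnalysisWindows(),
) -> tuple[float, float]:
    """Donor bleed-through factor from a donor-only concentration series.

    Per spectrum: I(570)/I(520) under donor excitation.  Returns the mean
    and the population rms across the series; the ratio is independent of
    concentration, so the rms reflects measurement noise only.
    """
    if len(donor_only) < 1:
        raise ValidationError("need at least one donor-only spectrum")
    hw = windows.peak_halfwidth_nm
    ratios = []
    for s in donor_only:
        i_donor = peak_intensity(s, windows.donor_peak_nm, hw)
        if i_donor <= 0:
            raise DegenerateInputError(
                f"well {s.well_id}: donor peak intensity <= 0; "
                "cannot form the bleed-through ratio"
            )
        ratios.append(peak_intensity(s, windows.acceptor_peak_nm, hw) / i_donor)
    arr = np.asarray(ratios)
    a = float(arr.mean())
    if a >= 1:
        warnings.warn("ratio factor a >= 1: donor-only 570 nm emission exceeds its "
                      "520 nm peak", stacklevel=2)
    return a, float(arr.std())


def ratio_factor_b(
    acceptor_only_ex470: Sequence[EmissionSpectrum],
    acceptor_only_exA: Sequence[EmissionSpectrum],
    windows: AnalysisWindows = AnalysisWindows(),
) -> tuple[float, float]:
    """Acceptor direct-excitation factor from a matched concentration series.

    Per concentration: I_470(570) / I_exA(570).  The two input lists must be
    matched pairwise (same concentration order).
    """
    if len(acceptor_only_ex470) != len(acceptor_only_exA):
        raise ValidationError(
            "acceptor-only series under the two excitations must have equal length"
        )
    if len(acceptor_only_ex470) < 1:
        raise ValidationError("need at least one acceptor-only concentration")
    hw = windows.peak_halfwidth_nm
    ratios = []
    for s470, s_a in zip(acceptor_only_ex470, acceptor_only_exA):
        denom = peak_intensity(s_a, windows.acceptor_peak_nm, hw)
        if denom <= 0:
            raise DegenerateInputError(
                f"well {s_a.well_id}: acceptor direct-excitation intensity <= 0"
            )
        ratios.append(peak_intensity(s470, windows.acceptor_peak_nm, hw) / denom)
    arr = np.asarray(ratios)
    b = float(arr.mean())
    if b >= 1:
        warnings.warn("ratio factor b >= 1: identical excitation responses? "
                      "check that the two scans differ", stacklevel=2)
    return b, float(arr.std())


@dataclass(frozen=True)
class FretDecomposition:
    """Bookkeeping of one mixture condition's 570-nm decomposition."""

    f_d: float
    f_da: float
    f_a: float
    factors: RatioFactors
    f_fret: float

    def __post_init__(self) -> None:
        expected = self.f_da - self.factors.a * self.f_d - self.factors.b * self.f_a
        if not np.isclose(self.f_fret, expected, rtol=1e-9, atol=1e-9):
            raise ValidationError("F_FRET does not satisfy F_DA - a*F_D - b*F_A")


def fret_signal(f_da: float, f_d: float, f_a: float, factors: RatioFactors) -> float:
    """Sensitized FRET emission at 570 nm: F_DA - a*F_D - b*F_A.

    Negative outputs (possible at zero acceptor, or from noise) are returned
    as-is; clipping is a reporting-time decision, and truncation here would
    bias the downstream binding fit.
    """
    for name, v in (("f_da", f_da), ("f_d", f_d), ("f_a", f_a)):
        if not np.isfinite(v):
            raise ValidationError(f"{name} must be finite")
    return float(f_da - factors.a * f_d - factors.b * f_a)


def decompose(
    mix_ex470: EmissionSpectrum,
    mix_exA: EmissionSpectrum,
    factors: RatioFactors,
    windows: AnalysisWindows = AnalysisWindows(),
) -> FretDecomposition:
    """Extract (F_D, F_DA, F_A) from a mixture well's two scans and apply
    the cross-talk correction."""
    hw = windows.peak_halfwidth_nm
    f_d = peak_intensity(mix_ex470, windows.donor_peak_nm, hw)
    f_da = peak_intensity(mix_ex470, windows.acceptor_peak_nm, hw)
    f_a = peak_intensity(mix_exA, windows.acceptor_peak_nm, hw)
    return FretDecomposition(
        f_d=f_d,
        f_da=f_da,
        f_a=f_a,
        factors=factors,
        f_fret=fret_signal(f_da, f_d, f_a, factors),
    )


@dataclass(frozen=True)
class EfficiencyResult:
    """Cross-talk-corrected FRET efficiency with its ingredients."""

    efficiency_pct: float
    sen_integral: float
    acc_integral: float
    a_d: float
    a_a: float

    @property
    def efficiency_pct_clipped(self) -> float:
        """Presentation-time value, clipped into [0, 100]%."""
        return float(np.clip(self.efficiency_pct, 0.0, 100.0))


def fret_efficiency(
    mix_ex470: EmissionSpectrum,
    donor_only_ex470: EmissionSpectrum,
    acceptor_only_ex470: EmissionSpectrum,
    acceptor_only_exA: EmissionSpectrum,
    a_d: float,
    a_a: float,
    windows: AnalysisWindows = AnalysisWindows(),
) -> EfficiencyResult:
    """Cross-talk-corrected FRET efficiency (%) of one mixture condition.

    The reference scans must be measured at the mixture's own conjugate
    concentrations.  ``a_d`` and ``a_a`` are the donor and acceptor
    absorbances at the donor excitation wavelength.  See the module
    docstring for the estimator; it is homogeneous of degree 0 in a common
    rescaling of all four spectra.
    """
    if not a_d > 0:
        raise ValidationError("donor absorbance a_d must be > 0")
    if a_a < 0:
        raise ValidationError("acceptor absorbance a_a must be >= 0")
    lo, hi = windows.window_nm
    hw = windows.peak_halfwidth_nm
    d_peak = peak_intensity(donor_only_ex470, windows.donor_peak_nm, hw)
    if d_peak <= 0:
        raise DegenerateInputError("donor-only 520 nm intensity <= 0")
    scale = peak_intensity(mix_ex470, windows.donor_peak_nm, hw) / d_peak

    sen = (
        integrate_band(mix_ex470, lo, hi)
        - scale * integrate_band(donor_only_ex470, lo, hi)
        - integrate_band(acceptor_only_ex470, lo, hi)
    )
    acc = integrate_band(acceptor_only_exA, lo, hi)
    if acc <= 0:
        raise DegenerateInputError(
            "acceptor direct-excitation integral <= 0; efficiency undefined"
        )
    e = 100.0 * (a_a / a_d) * sen / acc
    return EfficiencyResult(
        efficiency_pct=float(e), sen_integral=float(sen), acc_integral=float(acc),
        a_d=float(a_d), a_a=float(a_a),
    )


# ---------------------------------------------------------------------------
# Plate-level pipeline steps
# ---------------------------------------------------------------------------


def background_corrected(plate: PlateScan) -> PlateScan:
    """Subtract the per-excitation mean blank from every non-blank well.

    Blanks are per-plate; with several blank wells their pointwise mean is
    used.  A plate without blank wells is returned unchanged.
    """
    blanks = plate.wells_with_role("blank")
    if not blanks:
        return plate
    blank_mean: dict[float, EmissionSpectrum] = {}
    for ex in plate.excitations():
        scans = [plate.spectrum(w, ex) for w in blanks]
        if len(scans) == 1:
            blank_mean[ex] = scans[0]
        else:
            blank_mean[ex], _ = average_replicates(scans)
    spectra = {}
    for (well, ex), s in plate.spectra.items():
        if plate.layout[well].role == "blank":
            spectra[(well, ex)] = s
        else:
            spectra[(well, ex)] = subtract_background(s, blank_mean[ex])
    return PlateScan(spectra=spectra, layout=dict(plate.layout), metadata=dict(plate.metadata))


def condition_mean_spectra(
    plate: PlateScan, excitation_nm: float
) -> dict[tuple, EmissionSpectrum]:
    """Replicate-mean spectrum per condition at one excitation.

    Conditions are groups of wells sharing an identical :class:`WellRole`;
    single-well conditions pass through unchanged.
    """
    out = {}
    for key, wells in plate.conditions().items():
        scans = [plate.spectrum(w, excitation_nm) for w in wells]
        if len(scans) == 1:
            out[key] = scans[0]
        else:
            out[key], _ = average_replicates(scans)
    return out


def calibration_factors(
    plate: PlateScan, windows: AnalysisWindows = AnalysisWindows()
) -> RatioFactors:
    """Compute plate-wide ratio factors from the dedicated calibration wells.

    Donor-only and acceptor-only conditions are averaged over replicates
    first; the factor statistics run across the concentration series, as in
    the calibration experiment.
    """
    corrected = background_corrected(plate)
    groups = corrected.conditions()

    donor_keys = sorted(k for k in groups if k[0] == "donor_only")
    acc_keys = sorted(k for k in groups if k[0] == "acceptor_only")
    if not donor_keys or not acc_keys:
        raise ValidationError(
            "plate lacks donor-only and/or acceptor-only calibration wells"
        )
    mean470 = condition_mean_spectra(corrected, windows.donor_ex_nm)
    meanA = condition_mean_spectra(corrected, windows.acceptor_ex_nm)
    donor_only = [mean470[k] for k in donor_keys]
    acc470 = [mean470[k] for k in acc_keys]
    accA = [meanA[k] for k in acc_keys]
    return RatioFactors.from_calibration(donor_only, acc470, accA, windows)


def titration_from_plate(
    plate: PlateScan,
    factors: RatioFactors | None = None,
    windows: AnalysisWindows = AnalysisWindows(),
) -> tuple[TitrationSeries, list[dict]]:
    """Extract the F_FRET titration from a plate scan.

    Background-corrects, derives ratio factors from calibration wells when
    not supplied, decomposes every mixture replicate well, and aggregates
    per acceptor concentration (mean and rms over replicates).

    Returns the series plus one decomposition record per condition
    (dictionaries ready for tabular export: F_D, F_A, F_DA, a, b, F_FRET,
    rms).
    """
    corrected = background_corrected(plate)
    if factors is None:
        factors = calibration_factors(plate, windows)

    groups = corrected.conditions()
    mix_keys = [k for k in groups if k[0] == "mixture"]
    if not mix_keys:
        raise ValidationError("plate contains no mixture wells")
    donor_concs = {k[1] for k in mix_keys}
    if len(donor_concs) != 1:
        raise ValidationError(
            f"titration requires a fixed donor concentration; found {sorted(donor_concs)}"
        )
    donor_total = donor_concs.pop()

    mix_keys.sort(key=lambda k: k[2])  # by acceptor concentration
    acceptor_totals, f_mean, f_rms, reps, records = [], [], [], [], []
    for key in mix_keys:
        wells = groups[key]
        values = []
        for w in wells:
            dec = decompose(
                corrected.spectrum(w, windows.donor_ex_nm),
                corrected.spectrum(w, windows.acceptor_ex_nm),
                factors,
                windows,
            )
            values.append(dec)
        f_vals = np.array([d.f_fret for d in values])
        acceptor_totals.append(key[2])
        f_mean.append(float(f_vals.mean()))
        f_rms.append(float(f_vals.std()))
        reps.append(f_vals)
        records.append(
            {
                "acceptor_nM": key[2],
                "F_D": float(np.mean([d.f_d for d in values])),
                "F_A": float(np.mean([d.f_a for d in values])),
                "F_DA": float(np.mean([d.f_da for d in values])),
                "a": factors.a,
                "b": factors.b,
                "F_FRET": float(f_vals.mean()),
                "F_FRET_rms": float(f_vals.std()),
                "n_replicates": len(wells),
            }
        )
    series = TitrationSeries(
        donor_total_nM=donor_total,
        acceptor_totals_nM=np.array(acceptor_totals),
        f_fret=np.array(f_mean),
        f_fret_rms=np.array(f_rms),
        replicate_f_fret=tuple(np.asarray(r) for r in reps),
    )
    return series, records
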