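"""Physically structured synthetic plate scans.

No raw instrument data accompany the assay this package analyzes, so the
generator here is a first-class citizen: it emits full plate scans —
emission bands, binding equilibria, competitive inhibition, cross-talk and
replicate noise — whose latent ground truth is recorded in a ledger
sidecar, making parameter recovery by the pipeline checkable end to end.

Model
-----
* Emission bands are split Gaussians (two half-Gaussians sharing the peak;
  the red half is widened by the ``asymmetry`` factor), giving an exact
  unit peak at ``peak_nm`` and exact symmetry at ``asymmetry = 0``.
* The donor's emission shape carries a red tail such that its 570:520 nm
  readout ratio equals the requested bleed-through factor ``a``; the
  acceptor's direct emission under donor excitation is ``b`` times its
  emission under acceptor-band excitation.
* Band shapes are calibrated through the same windowed readout operator
  the analysis pipeline uses (mean intensity over peak ± 2 nm), so that on
  noiseless data the pipeline recovers the generator's latent quantities
  exactly rather than up to a window-curvature factor.  The acceptor shape
  is additionally constructed to have a zero 520-nm readout (the real dye's
  blue tail is a few permille there), which makes the F_FRET bookkeeping
  identity exact.
* Binding follows the one-to-one ligand-depletion equilibrium
  (:func:`fretassay.binding.bound_complex`); a competitive inhibitor adds a
  second equilibrium D + I <-> DI solved by damped fixed-point iteration.
* Donor quenching: the donor band of a mixture is scaled by
  ``1 - e_complex * bound/D``; sensitized acceptor emission has a 570-nm
  readout of ``f_fret_max * bound/D`` (titration mode) or the value implied
  by a target control FRET efficiency (screen mode).  The tie between the
  two parameterizations is written to the ledger.
* Noise: per-wavelength multiplicative log-normal with mean 1 and the
  requested CV, applied to signal plus background; replicates are emitted
  as 3 samples x 3 reads = 9 wells per condition by default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .binding import bound_complex
from .photophysics import FluorophoreParams
from .spectra import (
    EmissionSpectrum,
    FretAssayError,
    PlateScan,
    RangeError,
    ValidationError,
    WellRole,
    peak_intensity,
    write_plate_scan,
)

__all__ = [
    "SolverError",
    "BandShape",
    "InhibitorSpec",
    "SimulationSpec",
    "emission_band",
    "band_profile",
    "competitive_equilibrium",
    "simulate_titration",
    "simulate_screen",
    "simulate_conjugate_absorbance",
    "write_fixture",
    "DEFAULT_EMISSION_GRID",
    "DEFAULT_ABSORBANCE_GRID",
]


class SolverError(FretAssayError):
    """The equilibrium solver failed to converge (unphysical inputs)."""


DEFAULT_EMISSION_GRID = np.arange(450.0, 751.0, 1.0)
DEFAULT_ABSORBANCE_GRID = np.arange(240.0, 651.0, 1.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandShape:
    """A split-Gaussian emission band.

    ``width_nm`` is the FWHM of the symmetric core; ``asymmetry`` widens the
    red (long-wavelength) half-Gaussian by the factor ``1 + asymmetry``.
    ``amplitude_per_nM`` is the peak readout in RFU per nM of conjugate
    (quantum yield and instrument gain folded in).
    """

    peak_nm: float
    width_nm: float = 35.0
    asymmetry: float = 0.0
    amplitude_per_nM: float = 1.0

    def __post_init__(self) -> None:
        if not self.width_nm > 0:
            raise ValidationError("width_nm must be > 0")
        if not self.amplitude_per_nM > 0:
            raise ValidationError("amplitude_per_nM must be > 0")
        if self.asymmetry < 0:
            raise ValidationError("asymmetry must be >= 0")


def band_profile(shape: BandShape, grid: np.ndarray) -> np.ndarray:
    """Unit-peak split-Gaussian profile of ``shape`` on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    sigma = shape.width_nm * _FWHM_TO_SIGMA
    sigma_red = sigma * (1.0 + shape.asymmetry)
    delta = grid - shape.peak_nm
    s = np.where(delta <= 0, sigma, sigma_red)
    return np.exp(-0.5 * (delta / s) ** 2)


def emission_band(
    shape: BandShape,
    conc_nM: float,
    grid: np.ndarray = DEFAULT_EMISSION_GRID,
    well_id: str = "A1",
    excitation_nm: float = 470.0,
) -> EmissionSpectrum:
    """A noiseless emission spectrum, linear in concentration.

    The grid must cover peak ± 3 standard deviations of the band.
    """
    grid = np.asarray(grid, dtype=float)
    if conc_nM < 0:
        raise ValidationError("conc_nM must be >= 0")
    sigma = shape.width_nm * _FWHM_TO_SIGMA
    lo = shape.peak_nm - 3.0 * sigma
    hi = shape.peak_nm + 3.0 * sigma * (1.0 + shape.asymmetry)
    if grid[0] > lo or grid[-1] < hi:
        raise RangeError(
            f"grid [{grid[0]}, {grid[-1]}] too narrow for band requiring [{lo:.1f}, {hi:.1f}]"
        )
    return EmissionSpectrum(
        well_id=well_id,
        excitation_nm=excitation_nm,
        wavelengths=grid,
        intensities=shape.amplitude_per_nM * conc_nM * band_profile(shape, grid),
    )


@dataclass(frozen=True)
class InhibitorSpec:
    """One competitive inhibitor: identifier, K_i, and its dose series."""

    inhibitor_id: str
    ki_uM: float
    doses_uM: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ki_uM > 0:
            raise ValidationError("ki_uM must be > 0")
        if any(d < 0 for d in self.doses_uM):
            raise ValidationError("doses must be >= 0")


# Default inhibitor panel for the screen: a potent lovastatin-like positive
# control at 0.2-200 uM and three receptor-derived peptides of graded
# potency at 0.02-20 uM.
DEFAULT_INHIBITORS: tuple[InhibitorSpec, ...] = (
    InhibitorSpec("lovastatin", 0.05, (0.2, 2.0, 20.0, 200.0)),
    InhibitorSpec("CD11a_237-261", 2.0, (0.02, 0.2, 2.0, 20.0)),
    InhibitorSpec("CD11a_441-465", 8.0, (0.02, 0.2, 2.0, 20.0)),
    InhibitorSpec("CD11a_456-465", 40.0, (0.02, 0.2, 2.0, 20.0)),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters of a simulated experiment.

    Defaults reproduce the study design: donor fixed at 100 nM, acceptor
    titrated over 12 concentrations up to 1.6 uM, K_d = 17.93 nM,
    F_FRETmax = 6.33e3 RFU, cross-talk factors a = 0.129 and b = 0.101,
    F/P ratios 1.48 and 3.14, 3 samples x 3 reads with 2% multiplicative
    noise.  The seed is mandatory: there is no hidden global randomness.
    """

    seed: int
    kd_nM: float = 17.93
    f_fret_max_RFU: float = 6330.0
    donor_total_nM: float = 100.0
    acceptor_totals_nM: tuple[float, ...] = (
        0.0, 25.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 600.0, 800.0, 1200.0, 1600.0,
    )
    crosstalk_a: float = 0.129
    crosstalk_b: float = 0.101
    fp_donor: float = 1.48
    fp_acceptor: float = 3.14
    target_efficiency_pct: float = 53.51
    e_complex: float = 0.6
    inhibitors: tuple[InhibitorSpec, ...] = ()
    noise_cv: float = 0.02
    background_RFU: float = 50.0
    n_samples: int = 3
    n_reads: int = 3
    donor_ex_nm: float = 470.0
    acceptor_ex_nm: float = 530.0
    donor_band: BandShape = field(
        default_factory=lambda: BandShape(520.0, 35.0, 0.15, 40.0)
    )
    acceptor_band: BandShape = field(
        default_factory=lambda: BandShape(570.0, 40.0, 0.15, 10.0)
    )
    donor_cal_concs_nM: tuple[float, ...] = (100.0, 200.0, 300.0)
    acceptor_cal_concs_nM: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0, 500.0)
    n_blanks: int = 3
    eps_donor_470: float = 60_000.0  # M^-1 cm^-1 at the donor excitation
    eps_acceptor_470: float = 12_000.0
    pathlength_cm: float = 0.5
    readout_halfwidth_nm: float = 2.0
    grid: tuple[float, ...] = tuple(DEFAULT_EMISSION_GRID)

    def __post_init__(self) -> None:
        for name in (
            "kd_nM", "f_fret_max_RFU", "donor_total_nM", "target_efficiency_pct",
            "eps_donor_470", "eps_acceptor_470", "pathlength_cm",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0.0 <= self.crosstalk_a < 1.0 or not 0.0 <= self.crosstalk_b < 1.0:
            raise ValidationError("cross-talk factors must lie in [0, 1)")
        if not 0.0 <= self.e_complex <= 1.0:
            raise ValidationError("e_complex must lie in [0, 1]")
        if self.noise_cv < 0 or self.background_RFU < 0:
            raise ValidationError("noise_cv and background_RFU must be >= 0")
        if self.n_samples < 1 or self.n_reads < 1:
            raise ValidationError("replicate structure must be >= 1 x 1")
        a = np.asarray(self.acceptor_totals_nM)
        if np.any(a < 0) or (len(a) >= 2 and not np.all(np.diff(a) > 0)):
            raise ValidationError("acceptor series must be non-negative, increasing")

    @property
    def a_d_470(self) -> float:
        """Donor absorbance at the donor excitation (Beer-Lambert)."""
        return self.eps_donor_470 * self.donor_total_nM * 1e-9 * self.pathlength_cm

    def a_a_470(self, acceptor_nM: float) -> float:
        """Acceptor absorbance at the donor excitation for a given conc."""
        return self.eps_acceptor_470 * acceptor_nM * 1e-9 * self.pathlength_cm


# ---------------------------------------------------------------------------
# Spectral composition
# ---------------------------------------------------------------------------


class _SpectralModel:
    """Donor/acceptor emission shapes calibrated through the pipeline's
    windowed readout so the latent parameters are recovered exactly."""

    def __init__(self, spec: SimulationSpec):
        self.spec = spec
        self.grid = np.asarray(spec.grid, dtype=float)
        b_d = band_profile(spec.donor_band, self.grid)
        b_a = band_profile(spec.acceptor_band, self.grid)
        # Narrow cancellation profile confined to the donor readout window:
        # removes the acceptor band's small blue-tail readout at 520 nm.
        cancel = band_profile(BandShape(520.0, 10.0), self.grid)

        hw = spec.readout_halfwidth_nm

        def readout(profile: np.ndarray, center: float) -> float:
            s = EmissionSpectrum("cal", 470.0, self.grid, profile)
            return peak_intensity(s, center, hw)

        # Donor shape: alpha*B_D + beta*B_A with 520-readout 1, 570-readout a.
        m = np.array(
            [
                [readout(b_d, 520.0), readout(b_a, 520.0)],
                [readout(b_d, 570.0), readout(b_a, 570.0)],
            ]
        )
        alpha, beta = np.linalg.solve(m, [1.0, spec.crosstalk_a])
        if beta < 0:
            raise ValidationError(
                "crosstalk_a below the donor band's intrinsic red tail; "
                "use a narrower donor band or a larger factor"
            )
        self.donor_shape = alpha * b_d + beta * b_a

        # Acceptor shape: B_A minus the cancellation needed for a zero
        # 520-readout, renormalized to unit 570-readout.
        gamma = readout(b_a, 520.0) / readout(cancel, 520.0)
        s_a = b_a - gamma * cancel
        self.acceptor_shape = s_a / readout(s_a, 570.0)

    def donor_only(self, conc_nM: float) -> np.ndarray:
        return self.spec.donor_band.amplitude_per_nM * conc_nM * self.donor_shape

    def acceptor_only_exA(self, conc_nM: float) -> np.ndarray:
        return self.spec.acceptor_band.amplitude_per_nM * conc_nM * self.acceptor_shape

    def acceptor_only_ex470(self, conc_nM: float) -> np.ndarray:
        return self.spec.crosstalk_b * self.acceptor_only_exA(conc_nM)

    def mixture_ex470(
        self, donor_nM: float, acceptor_nM: float, bound_nM: float, f_sens: float
    ) -> np.ndarray:
        quench = 1.0 - self.spec.e_complex * bound_nM / donor_nM if donor_nM > 0 else 1.0
        donor_term = self.donor_only(donor_nM) * quench
        direct = self.acceptor_only_ex470(acceptor_nM)
        sensitized = f_sens * self.acceptor_shape
        return donor_term + direct + sensitized

    def mixture_exA(self, acceptor_nM: float) -> np.ndarray:
        # the donor dye is essentially not excited in the acceptor band
        return self.acceptor_only_exA(acceptor_nM)


def _well_ids(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    ids = []
    for i in range(n):
        row, col = divmod(i, 12)
        prefix = "" if row < 26 else letters[row // 26 - 1]
        ids.append(f"{prefix}{letters[row % 26]}{col + 1}")
    return ids


class _PlateBuilder:
    """Accumulates wells; applies noise and background per replicate read."""

    def __init__(self, spec: SimulationSpec, model: _SpectralModel):
        self.spec = spec
        self.model = model
        self.rng = np.random.default_rng(spec.seed)
        sigma2 = np.log1p(spec.noise_cv**2)
        self.sigma = np.sqrt(sigma2)
        self.entries: list[tuple[WellRole, dict[float, np.ndarray]]] = []
        self.well_conditions: list[str] = []

    def add(self, role: WellRole, signals: dict[float, np.ndarray], n_wells: int, tag: str):
        for _ in range(n_wells):
            self.entries.append((role, signals))
            self.well_conditions.append(tag)

    def build(self) -> tuple[PlateScan, dict[str, str]]:
        spec = self.spec
        ids = _well_ids(len(self.entries))
        spectra: dict[tuple[str, float], EmissionSpectrum] = {}
        layout: dict[str, WellRole] = {}
        grid = self.model.grid
        for well, (role, signals) in zip(ids, self.entries):
            layout[well] = role
            for ex, signal in signals.items():
                raw = signal + spec.background_RFU
                if spec.noise_cv > 0:
                    eta = np.exp(
                        self.sigma * self.rng.standard_normal(len(grid))
                        - 0.5 * self.sigma**2
                    )
                    raw = raw * eta
                spectra[(well, ex)] = EmissionSpectrum(
                    well_id=well, excitation_nm=ex, wavelengths=grid, intensities=raw
                )
        plate = PlateScan(
            spectra=spectra,
            layout=layout,
            metadata={"instrument": "synthetic", "seed": str(spec.seed)},
        )
        return plate, dict(zip(ids, self.well_conditions))


def _calibration_wells(builder: _PlateBuilder) -> None:
    spec, model = builder.spec, builder.model
    zero = np.zeros_like(model.grid)
    blank = WellRole(role="blank")
    builder.add(blank, {spec.donor_ex_nm: zero, spec.acceptor_ex_nm: zero},
                spec.n_blanks, "blank")
    for conc in spec.donor_cal_concs_nM:
        builder.add(
            WellRole(role="donor_only", donor_conc_nM=conc),
            {spec.donor_ex_nm: model.donor_only(conc), spec.acceptor_ex_nm: zero},
            1,
            f"donor_only:{conc}",
        )
    for conc in spec.acceptor_cal_concs_nM:
        builder.add(
            WellRole(role="acceptor_only", acceptor_conc_nM=conc),
            {
                spec.donor_ex_nm: model.acceptor_only_ex470(conc),
                spec.acceptor_ex_nm: model.acceptor_only_exA(conc),
            },
            1,
            f"acceptor_only:{conc}",
        )


def _base_ledger(spec: SimulationSpec, conditions: list[dict]) -> dict:
    raw = asdict(spec)
    raw["inhibitors"] = [asdict(i) for i in spec.inhibitors]
    return {
        "spec": raw,
        "seed": spec.seed,
        "truth": {
            "a": spec.crosstalk_a,
            "b": spec.crosstalk_b,
            "kd_nM": spec.kd_nM,
            "a_d_470": spec.a_d_470,
            "conditions": conditions,
        },
    }


def simulate_titration(spec: SimulationSpec) -> tuple[PlateScan, dict]:
    """Simulate the K_d titration: fixed donor, acceptor series, blanks and
    calibration wells, replicate mixture wells with noise.

    Returns the plate plus a ground-truth ledger recording, per acceptor
    concentration, the bound complex, the latent F_FRET
    (= F_FRETmax * bound/D) and the donor quench factor.
    """
    model = _SpectralModel(spec)
    builder = _PlateBuilder(spec, model)
    _calibration_wells(builder)

    d = spec.donor_total_nM
    conditions = []
    for a_tot in spec.acceptor_totals_nM:
        bound = bound_complex(a_tot, d, spec.kd_nM)
        f_sens = spec.f_fret_max_RFU * bound / d
        signals = {
            spec.donor_ex_nm: model.mixture_ex470(d, a_tot, bound, f_sens),
            spec.acceptor_ex_nm: model.mixture_exA(a_tot),
        }
        builder.add(
            WellRole(role="mixture", donor_conc_nM=d, acceptor_conc_nM=a_tot),
            signals,
            spec.n_samples * spec.n_reads,
            f"mixture:{a_tot}",
        )
        conditions.append(
            {
                "acceptor_nM": a_tot,
                "bound_nM": bound,
                "bound_fraction": bound / d,
                "f_fret_true": f_sens,
                "quench_factor": 1.0 - spec.e_complex * bound / d,
            }
        )

    plate, wells = builder.build()
    ledger = _base_ledger(spec, conditions)
    ledger["truth"]["f_fret_max_RFU"] = spec.f_fret_max_RFU
    ledger["wells"] = wells
    return plate, ledger


def competitive_equilibrium(
    a_total_nM: float,
    d_total_nM: float,
    i_total_nM: float,
    kd_nM: float,
    ki_nM: float,
    rtol: float = 1e-12,
    max_iter: int = 200_000,
) -> tuple[float, float, float]:
    """Coupled equilibria D+A<->DA (K_d) and D+I<->DI (K_i).

    Solved by damped fixed-point iteration on the free-donor concentration,

        D_free <- (1-w) D_free + w * D_tot / (1 + A/(K_d+D_free) + I/(K_i+D_free)),

    to relative tolerance ``rtol``.  Returns ([DA], D_free, [DI]) in nM.
    ``ki_nM = inf`` encodes an impotent inhibitor.
    """
    for name, v in (("a_total_nM", a_total_nM), ("d_total_nM", d_total_nM),
                    ("i_total_nM", i_total_nM)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    if not kd_nM > 0 or not ki_nM > 0:
        raise ValidationError("kd and ki must be > 0")
    if d_total_nM == 0:
        return 0.0, 0.0, 0.0
    d_free = d_total_nM
    w = 0.5
    for _ in range(max_iter):
        target = d_total_nM / (
            1.0 + a_total_nM / (kd_nM + d_free) + i_total_nM / (ki_nM + d_free)
        )
        new = (1.0 - w) * d_free + w * target
        if abs(new - d_free) <= rtol * max(new, np.finfo(float).tiny):
            d_free = new
            break
        d_free = new
    else:
        raise SolverError("competitive equilibrium did not converge")
    da = a_total_nM * d_free / (kd_nM + d_free)
    di = i_total_nM * d_free / (ki_nM + d_free) if np.isfinite(ki_nM) else 0.0
    return float(da), float(d_free), float(di)


def simulate_screen(spec: SimulationSpec) -> tuple[PlateScan, dict]:
    """Simulate the competitive-inhibition screen.

    The uninhibited control mixture is generated so that the pipeline's
    efficiency estimator returns ``spec.target_efficiency_pct``; inhibitor
    conditions scale the sensitized emission (and donor quenching) by the
    ratio of the inhibited to uninhibited bound complex.
    """
    if not spec.inhibitors:
        raise ValidationError("simulate_screen requires at least one inhibitor")
    model = _SpectralModel(spec)
    builder = _PlateBuilder(spec, model)
    _calibration_wells(builder)

    d = spec.donor_total_nM
    a_tot = 100.0 if 100.0 in spec.acceptor_totals_nM else spec.acceptor_totals_nM[-1]
    a_a = spec.a_a_470(a_tot)
    bound0 = bound_complex(a_tot, d, spec.kd_nM)
    # Sensitized 570-nm readout making the estimator report the target
    # control efficiency; scales with the bound fraction thereafter.
    amp_a = spec.acceptor_band.amplitude_per_nM
    f_sens0 = (spec.target_efficiency_pct / 100.0) * (spec.a_d_470 / a_a) * amp_a * a_tot
    n_rep = spec.n_samples * spec.n_reads

    def add_mixture(role: WellRole, bound: float, tag: str) -> dict:
        f_sens = f_sens0 * bound / bound0
        builder.add(
            role,
            {
                spec.donor_ex_nm: model.mixture_ex470(d, a_tot, bound, f_sens),
                spec.acceptor_ex_nm: model.mixture_exA(a_tot),
            },
            n_rep,
            tag,
        )
        return {
            "bound_nM": bound,
            "f_sens": f_sens,
            "true_efficiency_pct": spec.target_efficiency_pct * bound / bound0,
            "true_inhibition_pct": 100.0 * (1.0 - bound / bound0),
        }

    conditions = [
        {
            "role": "mixture", "inhibitor": None, "dose_uM": None,
            **add_mixture(
                WellRole(role="mixture", donor_conc_nM=d, acceptor_conc_nM=a_tot),
                bound0,
                "control",
            ),
        }
    ]
    for inh in spec.inhibitors:
        for dose in inh.doses_uM:
            da, _, _ = competitive_equilibrium(
                a_tot, d, dose * 1000.0, spec.kd_nM, inh.ki_uM * 1000.0
            )
            role = WellRole(
                role="mixture_inhibitor",
                donor_conc_nM=d,
                acceptor_conc_nM=a_tot,
                inhibitor_id=inh.inhibitor_id,
                inhibitor_conc_uM=dose,
            )
            conditions.append(
                {
                    "role": "mixture_inhibitor",
                    "inhibitor": inh.inhibitor_id,
                    "dose_uM": dose,
                    "ki_uM": inh.ki_uM,
                    **add_mixture(role, da, f"{inh.inhibitor_id}:{dose}"),
                }
            )

    plate, wells = builder.build()
    ledger = _base_ledger(spec, conditions)
    ledger["truth"]["a_a_470"] = a_a
    ledger["truth"]["control_efficiency_pct"] = spec.target_efficiency_pct
    ledger["truth"]["f_sens_control"] = f_sens0
    ledger["wells"] = wells
    return plate, ledger


def simulate_conjugate_absorbance(
    fluor: FluorophoreParams,
    protein_eps280: float,
    fp_true: float,
    protein_conc_M: float,
    grid: np.ndarray = DEFAULT_ABSORBANCE_GRID,
    pathlength_cm: float = 1.0,
):
    """Synthetic conjugate absorbance: protein 280-nm band plus dye band.

    The dye contributes ``a280_correction`` of its peak absorbance at
    280 nm, so the degree-of-labeling arithmetic recovers ``fp_true``
    exactly in the noiseless case.
    """
    from .spectra import AbsorbanceSpectrum

    if fp_true < 0 or not protein_conc_M > 0 or not protein_eps280 > 0:
        raise ValidationError("fp_true >= 0 and positive concentrations required")
    grid = np.asarray(grid, dtype=float)
    protein_profile = np.exp(-0.5 * ((grid - 280.0) / (50.0 * _FWHM_TO_SIGMA)) ** 2)
    dye_profile = band_profile(BandShape(fluor.ex_max_nm, 35.0, 0.0), grid)
    a_max = fp_true * protein_conc_M * fluor.extinction_at_max * pathlength_cm
    protein_a280 = protein_eps280 * protein_conc_M * pathlength_cm
    absorbance = (
        protein_a280 * protein_profile
        + a_max * dye_profile
        + fluor.a280_correction * a_max * protein_profile
    )
    return AbsorbanceSpectrum(
        wavelengths=grid,
        absorbance=absorbance,
        pathlength_cm=pathlength_cm,
        sample_id=f"{fluor.name}-conjugate",
    )


def write_fixture(scan: PlateScan, path, ledger: dict | None = None,
                  dialect: str = "tsv") -> None:
    """Write a plate fixture in the documented format, plus an optional
    ground-truth ledger sidecar at ``<path>.ledger.json``."""
    write_plate_scan(scan, path, dialect=dialect)
    if ledger is not None:
        with open(f"{path}.ledger.json", "w", encoding="utf-8") as fh:
            json.dump(ledger, fh, indent=1, sort_keys=True)
            fh.write("\n")
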