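"""Fluorophore parameterization and degree-of-labeling arithmetic.

The degree of labeling (F/P, moles of fluorophore per mole of protein) of a
dye-protein conjugate is obtained from its UV-visible absorbance by
Beer-Lambert bookkeeping:

    F/P = A_max / (eps_fluorophore * l * [protein])

where ``A_max`` is the conjugate absorbance at the dye's absorbance maximum,
``eps_fluorophore`` the dye's molar extinction coefficient there, ``l`` the
path length and ``[protein]`` the molar protein concentration.  The protein
concentration itself comes from the 280-nm absorbance after removing the
fraction of dye absorbance that bleeds into 280 nm (the dye vendor's
"A280 correction factor"):

    [protein] = (A280 - cf * A_max) / (eps_protein_280 * l)

The acceptor-to-donor fluorophore ratio (A/D) of an assay mixture is the
number of acceptor fluorophores per donor fluorophore:

    A/D = ([acceptor] * F/P_acceptor) / ([donor] * F/P_donor)

Extinction coefficients and correction factors are vendor-documented
constants shipped as editable defaults, never hard-coded inside the
computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .spectra import (
    AbsorbanceSpectrum,
    DegenerateInputError,
    RangeError,
    ValidationError,
)

__all__ = [
    "FluorophoreParams",
    "ConjugateSpec",
    "Measurement",
    "DEFAULT_FLUOROPHORES",
    "load_fluorophores",
    "absorbance_at_max",
    "protein_concentration",
    "fp_ratio",
    "ad_ratio",
]


class Measurement(NamedTuple):
    """A scalar with an rms uncertainty (0.0 when no replicates exist)."""

    value: float
    rms: float


@dataclass(frozen=True)
class FluorophoreParams:
    """Photophysical constants of one dye.

    ``a280_correction`` is the fraction of the dye's peak absorbance that
    appears at 280 nm and therefore contaminates the protein readout.
    """

    name: str
    ex_max_nm: float
    em_max_nm: float
    extinction_at_max: float  # M^-1 cm^-1
    quantum_yield: float
    a280_correction: float = 0.0

    def __post_init__(self) -> None:
        if not self.extinction_at_max > 0:
            raise ValidationError("extinction_at_max must be > 0")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValidationError("quantum_yield must be within [0, 1]")
        if not 0.0 <= self.a280_correction < 1.0:
            raise ValidationError("a280_correction must be within [0, 1)")


# Vendor-documented defaults for the Alexa-488-like donor dye and the
# Alexa-555-like acceptor dye.  Editable: pass your own FluorophoreParams or
# a parameter file; these values never enter any computation implicitly.
DEFAULT_FLUOROPHORES: dict[str, FluorophoreParams] = {
    "alexa488": FluorophoreParams(
        name="alexa488",
        ex_max_nm=490.0,
        em_max_nm=520.0,
        extinction_at_max=71_000.0,
        quantum_yield=0.92,
        a280_correction=0.11,
    ),
    "alexa555": FluorophoreParams(
        name="alexa555",
        ex_max_nm=555.0,
        em_max_nm=570.0,
        extinction_at_max=150_000.0,
        quantum_yield=0.10,
        a280_correction=0.08,
    ),
}


def load_fluorophores(path) -> dict[str, FluorophoreParams]:
    """Load dye parameters from a YAML mapping ``name -> {field: value}``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, fields in raw.items():
        out[name] = FluorophoreParams(name=name, **fields)
    return out


@dataclass(frozen=True)
class ConjugateSpec:
    """A dye-protein conjugate: absorbance data plus derived quantities."""

    protein_id: str
    fluorophore: FluorophoreParams
    absorbance: AbsorbanceSpectrum
    protein_eps280: float  # M^-1 cm^-1
    protein_conc_M: float | None = None
    fp_ratio: Measurement | None = None
    absorbance_replicates: tuple[AbsorbanceSpectrum, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.fp_ratio is not None:
            if self.protein_conc_M is None or not self.protein_conc_M > 0:
                raise ValidationError("protein_conc_M must be > 0 when fp_ratio is set")
            if self.fp_ratio.value < 0:
                raise ValidationError("fp_ratio must be >= 0")


def absorbance_at_max(
    spectrum: AbsorbanceSpectrum, fluor: FluorophoreParams, search_halfwidth_nm: float = 5.0
) -> float:
    """Conjugate absorbance at the dye maximum (A_max).

    Read as the maximum within ±``search_halfwidth_nm`` of the dye's nominal
    ex_max, tolerating small conjugation-induced spectral shifts.
    """
    wl = spectrum.wavelengths
    lo = fluor.ex_max_nm - search_halfwidth_nm
    hi = fluor.ex_max_nm + search_halfwidth_nm
    if lo < wl[0] or hi > wl[-1]:
        raise RangeError(
            f"absorbance grid [{wl[0]}, {wl[-1]}] does not cover "
            f"{fluor.name} maximum window [{lo}, {hi}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    return float(spectrum.absorbance[mask].max())


def protein_concentration(
    spectrum: AbsorbanceSpectrum,
    fluor: FluorophoreParams,
    protein_eps280: float,
) -> float:
    """Molar protein concentration from 280-nm absorbance.

    The dye's bleed into 280 nm is removed as ``a280_correction * A_max``
    before Beer-Lambert inversion.
    """
    if not protein_eps280 > 0:
        raise ValidationError("protein_eps280 must be > 0")
    a280 = spectrum.at(280.0)
    a_max = absorbance_at_max(spectrum, fluor)
    corrected = a280 - fluor.a280_correction * a_max
    if corrected <= 0:
        raise DegenerateInputError(
            "corrected A280 <= 0: the 280-nm absorbance is entirely explained "
            "by fluorophore bleed-through"
        )
    return corrected / (protein_eps280 * spectrum.pathlength_cm)


def fp_ratio(conjugate: ConjugateSpec) -> Measurement:
    """Degree of labeling F/P = A_max / (eps * l * [protein]).

    The protein concentration is taken from ``conjugate.protein_conc_M`` if
    set, otherwise derived from the same absorbance scan via
    :func:`protein_concentration`.  If replicate absorbance scans are
    attached, the rms of the per-replicate ratios is reported; otherwise the
    rms is 0.
    """
    fluor = conjugate.fluorophore

    def one(spec: AbsorbanceSpectrum) -> float:
        a_max = absorbance_at_max(spec, fluor)
        conc = conjugate.protein_conc_M
        if conc is None:
            conc = protein_concentration(spec, fluor, conjugate.protein_eps280)
        if not conc > 0:
            raise ValidationError("protein concentration must be > 0")
        return a_max / (fluor.extinction_at_max * spec.pathlength_cm * conc)

    center = one(conjugate.absorbance)
    reps = conjugate.absorbance_replicates
    if reps:
        values = np.array([one(r) for r in reps])
        return Measurement(center, float(np.sqrt(np.mean((values - center) ** 2))))
    return Measurement(center, 0.0)


def ad_ratio(
    donor_conc_nM: float,
    acceptor_conc_nM: float,
    fp_donor: float,
    fp_acceptor: float,
) -> float:
    """Acceptor-to-donor fluorophore ratio of a mixture.

    A/D = (acceptor protein conc * acceptor F/P) / (donor protein conc *
    donor F/P); all inputs must be strictly positive.
    """
    for name, v in (
        ("donor_conc_nM", donor_conc_nM),
        ("acceptor_conc_nM", acceptor_conc_nM),
        ("fp_donor", fp_donor),
        ("fp_acceptor", fp_acceptor),
    ):
        if not v > 0:
            raise ValidationError(f"{name} must be > 0 (got {v})")
    return (acceptor_conc_nM * fp_acceptor) / (donor_conc_nM * fp_donor)
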