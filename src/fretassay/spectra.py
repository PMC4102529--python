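"""Plate-reader spectrum containers, the delimited plate-scan format, and
band arithmetic.

Every downstream stage (cross-talk factors, FRET decomposition, efficiency,
binding fit, screening) consumes :class:`EmissionSpectrum` objects produced
here.  Wavelength grids are treated as sacrosanct: spectra are never
resampled silently, and any grid mismatch between operands is an error —
silent interpolation hides acquisition mistakes.

Intensities are in relative fluorescence units (RFU).  Negative intensities
are legitimate after background subtraction and are deliberately retained
(clipping is a presentation-time concern; truncation would bias the
downstream least-squares fits).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FretAssayError",
    "FormatError",
    "ValidationError",
    "ConsistencyError",
    "RangeError",
    "DegenerateInputError",
    "EmissionSpectrum",
    "AbsorbanceSpectrum",
    "WellRole",
    "PlateScan",
    "ROLES",
    "read_plate_scan",
    "write_plate_scan",
    "read_absorbance",
    "subtract_background",
    "average_replicates",
    "integrate_band",
    "peak_intensity",
]


class FretAssayError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FretAssayError):
    """A file does not conform to the documented plate-scan dialect."""


class ValidationError(FretAssayError):
    """An object or argument violates a documented invariant."""


class ConsistencyError(FretAssayError):
    """Layout and spectra disagree (duplicates, missing wells, ...)."""


class RangeError(FretAssayError):
    """A requested wavelength window falls outside the measured grid."""


class DegenerateInputError(FretAssayError):
    """Input is formally valid but leaves the requested quantity undefined."""


ROLES = ("blank", "donor_only", "acceptor_only", "mixture", "mixture_inhibitor")


def _as_float_array(x: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class EmissionSpectrum:
    """One wavelength-resolved emission scan of one well.

    Parameters
    ----------
    well_id : plate coordinate, e.g. ``"A1"``.
    excitation_nm : excitation wavelength in nm.
    wavelengths : strictly increasing grid in nm.
    intensities : RFU, same length as ``wavelengths``.
    gain, ex_bandwidth_nm, em_bandwidth_nm, integration_time_us :
        instrument metadata, carried through unchanged.
    """

    well_id: str
    excitation_nm: float
    wavelengths: np.ndarray
    intensities: np.ndarray
    gain: float = 100.0
    ex_bandwidth_nm: float = 9.0
    em_bandwidth_nm: float = 20.0
    integration_time_us: float = 20.0

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths)
        it = _as_float_array(self.intensities)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or len(wl) != len(it):
            raise ValidationError(
                f"well {self.well_id}: wavelengths and intensities must be "
                f"1-D and equally long (got {len(wl)} vs {len(it)})"
            )
        if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
            raise ValidationError(
                f"well {self.well_id}: wavelength grid not strictly increasing"
            )
        if not self.excitation_nm > 0:
            raise ValidationError("excitation_nm must be positive")
        if not np.all(np.isfinite(it)):
            raise ValidationError(f"well {self.well_id}: non-finite intensities")

    def with_intensities(self, intensities: np.ndarray) -> "EmissionSpectrum":
        """Copy of this spectrum with new intensities, metadata preserved."""
        return replace(self, intensities=_as_float_array(intensities))


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """A UV-visible absorbance scan (optical density vs wavelength)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    pathlength_cm: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths)
        ab = _as_float_array(self.absorbance)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if len(wl) != len(ab):
            raise ValidationError("wavelengths and absorbance differ in length")
        if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
            raise ValidationError("absorbance grid not strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise ValidationError("non-finite absorbance values")
        if not self.pathlength_cm > 0:
            raise ValidationError("pathlength_cm must be positive")

    def at(self, nm: float) -> float:
        """Linearly interpolated absorbance at ``nm``."""
        wl = self.wavelengths
        if not (wl[0] <= nm <= wl[-1]):
            raise RangeError(f"{nm} nm outside absorbance grid [{wl[0]}, {wl[-1]}]")
        return float(np.interp(nm, wl, self.absorbance))


@dataclass(frozen=True)
class WellRole:
    """Condition of one well: role, protein concentrations, inhibitor.

    Concentrations follow the assay convention: they are concentrations of
    the *protein* in the fluorophore-protein conjugate solution, not of the
    fluorophore.
    """

    role: str
    donor_conc_nM: float = 0.0
    acceptor_conc_nM: float = 0.0
    inhibitor_id: str | None = None
    inhibitor_conc_uM: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.donor_conc_nM < 0 or self.acceptor_conc_nM < 0:
            raise ValidationError("concentrations must be >= 0")
        has_inh = self.inhibitor_id is not None
        if has_inh != (self.role == "mixture_inhibitor"):
            raise ValidationError(
                "inhibitor fields must be present iff role == 'mixture_inhibitor'"
            )
        if has_inh and (self.inhibitor_conc_uM is None or self.inhibitor_conc_uM < 0):
            raise ValidationError("inhibitor_conc_uM must be a non-negative number")

    def condition_key(self) -> tuple:
        """Hashable key grouping replicate wells of the same condition."""
        return (
            self.role,
            self.donor_conc_nM,
            self.acceptor_conc_nM,
            self.inhibitor_id,
            self.inhibitor_conc_uM,
        )


@dataclass
class PlateScan:
    """A full plate read: spectra keyed by (well_id, excitation_nm), plus layout."""

    spectra: dict[tuple[str, float], EmissionSpectrum]
    layout: dict[str, WellRole]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        excitations = self.excitations()
        for well in self.layout:
            for ex in excitations:
                if (well, ex) not in self.spectra:
                    raise ConsistencyError(
                        f"well {well} missing a scan at excitation {ex} nm"
                    )
        for well, _ in self.spectra:
            if well not in self.layout:
                raise ConsistencyError(f"well {well} has spectra but no layout entry")

    def excitations(self) -> tuple[float, ...]:
        return tuple(sorted({ex for _, ex in self.spectra}))

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, r in self.layout.items() if r.role == role]

    def spectrum(self, well_id: str, excitation_nm: float) -> EmissionSpectrum:
        try:
            return self.spectra[(well_id, excitation_nm)]
        except KeyError:
            raise ConsistencyError(
                f"no spectrum for well {well_id} at {excitation_nm} nm"
            ) from None

    def conditions(self) -> dict[tuple, list[str]]:
        """Group well ids by identical condition (replicate groups)."""
        groups: dict[tuple, list[str]] = {}
        for well, role in self.layout.items():
            groups.setdefault(role.condition_key(), []).append(well)
        for wells in groups.values():
            wells.sort()
        return groups


# ---------------------------------------------------------------------------
# Plate-scan file format
#
# UTF-8 delimited text.  Leading header lines of the form ``#key=value``
# (instrument, gain, ex_bandwidth_nm, em_bandwidth_nm, integration_time_us),
# then a column-header row and one data row per (well, excitation,
# wavelength):
#   well_id, role, donor_conc_nM, acceptor_conc_nM, inhibitor_id,
#   inhibitor_conc_uM, excitation_nm, wavelength_nm, intensity
# ---------------------------------------------------------------------------

_COLUMNS = [
    "well_id",
    "role",
    "donor_conc_nM",
    "acceptor_conc_nM",
    "inhibitor_id",
    "inhibitor_conc_uM",
    "excitation_nm",
    "wavelength_nm",
    "intensity",
]

_DIALECTS = {"tsv": "\t", "csv": ","}

_HEADER_KEYS = (
    "instrument",
    "gain",
    "ex_bandwidth_nm",
    "em_bandwidth_nm",
    "integration_time_us",
)


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def read_plate_scan(path, dialect: str = "tsv") -> PlateScan:
    """Read a plate scan in the documented delimited-text format.

    Raises
    ------
    FormatError
        malformed header line or missing columns (the message names the
        offending line).
    ValidationError
        non-increasing wavelength grid.
    ConsistencyError
        duplicated (well, excitation, wavelength) rows or conflicting
        role metadata for one well.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {list(_DIALECTS)}")
    sep = _DIALECTS[dialect]
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    metadata: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if "=" not in line:
            raise FormatError(f"line {i + 1}: malformed header line {line!r} (missing '=')")
        key, _, value = line[1:].partition("=")
        metadata[key.strip()] = value.strip()
    else:
        body_start = len(lines)

    body = "\n".join(lines[body_start:])
    if not body.strip():
        return PlateScan(spectra={}, layout={}, metadata=metadata)

    table = pd.read_csv(
        io.StringIO(body),
        sep=sep,
        dtype={"well_id": str, "role": str, "inhibitor_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"line {body_start + 1}: column header missing columns {missing}"
        )

    dupes = table.duplicated(subset=["well_id", "excitation_nm", "wavelength_nm"])
    if dupes.any():
        row = table[dupes].iloc[0]
        raise ConsistencyError(
            f"duplicated scan point: well {row['well_id']} at "
            f"ex {row['excitation_nm']} nm, {row['wavelength_nm']} nm"
        )

    meta_kwargs = {
        "gain": float(metadata.get("gain", 100.0)),
        "ex_bandwidth_nm": float(metadata.get("ex_bandwidth_nm", 9.0)),
        "em_bandwidth_nm": float(metadata.get("em_bandwidth_nm", 20.0)),
        "integration_time_us": float(metadata.get("integration_time_us", 20.0)),
    }

    spectra: dict[tuple[str, float], EmissionSpectrum] = {}
    layout: dict[str, WellRole] = {}
    for (well, ex), grp in table.groupby(["well_id", "excitation_nm"], sort=False):
        spectra[(well, float(ex))] = EmissionSpectrum(
            well_id=well,
            excitation_nm=float(ex),
            wavelengths=grp["wavelength_nm"].to_numpy(float),
            intensities=grp["intensity"].to_numpy(float),
            **meta_kwargs,
        )
        inh = grp["inhibitor_id"].iloc[0]
        inh_id = None if pd.isna(inh) or inh == "" else str(inh)
        inh_conc = grp["inhibitor_conc_uM"].iloc[0]
        role = WellRole(
            role=str(grp["role"].iloc[0]),
            donor_conc_nM=float(grp["donor_conc_nM"].iloc[0]),
            acceptor_conc_nM=float(grp["acceptor_conc_nM"].iloc[0]),
            inhibitor_id=inh_id,
            inhibitor_conc_uM=None if inh_id is None else float(inh_conc),
        )
        if well in layout and layout[well] != role:
            raise ConsistencyError(f"well {well}: conflicting role metadata between rows")
        layout[well] = role

    return PlateScan(spectra=spectra, layout=layout, metadata=metadata)


def write_plate_scan(scan: PlateScan, path, dialect: str = "tsv") -> None:
    """Write a plate scan in the documented format.

    Output is deterministic (rows sorted by well, excitation, wavelength) and
    floats are serialized with shortest round-trip representation, so
    write -> read -> write is byte-identical.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    sep = _DIALECTS[dialect]
    lines: list[str] = []
    meta = dict(scan.metadata)
    meta.setdefault("instrument", "synthetic")
    first = next(iter(scan.spectra.values()), None)
    if first is not None:
        meta.setdefault("gain", _fmt(first.gain))
        meta.setdefault("ex_bandwidth_nm", _fmt(first.ex_bandwidth_nm))
        meta.setdefault("em_bandwidth_nm", _fmt(first.em_bandwidth_nm))
        meta.setdefault("integration_time_us", _fmt(first.integration_time_us))
    for key in _HEADER_KEYS:
        if key in meta:
            lines.append(f"#{key}={meta[key]}")
    for key in sorted(set(meta) - set(_HEADER_KEYS)):
        lines.append(f"#{key}={meta[key]}")
    lines.append(sep.join(_COLUMNS))
    for (well, ex) in sorted(scan.spectra):
        s = scan.spectra[(well, ex)]
        role = scan.layout[well]
        inh_id = "" if role.inhibitor_id is None else role.inhibitor_id
        inh_conc = "" if role.inhibitor_conc_uM is None else _fmt(role.inhibitor_conc_uM)
        prefix = sep.join(
            [
                well,
                role.role,
                _fmt(role.donor_conc_nM),
                _fmt(role.acceptor_conc_nM),
                inh_id,
                inh_conc,
                _fmt(ex),
            ]
        )
        for wl, it in zip(s.wavelengths, s.intensities):
            lines.append(f"{prefix}{sep}{_fmt(wl)}{sep}{_fmt(it)}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_absorbance(path, dialect: str = "tsv") -> dict[str, AbsorbanceSpectrum]:
    """Read absorbance scans: ``#pathlength_cm=`` header then columns
    sample_id, wavelength_nm, absorbance.  Returns one spectrum per sample."""
    sep = _DIALECTS.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r}")
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    pathlength = 1.0
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if "=" not in line:
            raise FormatError(f"line {i + 1}: malformed header line {line!r}")
        key, _, value = line[1:].partition("=")
        if key.strip() == "pathlength_cm":
            pathlength = float(value)
    table = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep=sep,
                        dtype={"sample_id": str}, float_precision="round_trip")
    for col in ("sample_id", "wavelength_nm", "absorbance"):
        if col not in table.columns:
            raise FormatError(f"absorbance file missing column {col!r}")
    out = {}
    for sample, grp in table.groupby("sample_id", sort=False):
        out[sample] = AbsorbanceSpectrum(
            wavelengths=grp["wavelength_nm"].to_numpy(float),
            absorbance=grp["absorbance"].to_numpy(float),
            pathlength_cm=pathlength,
            sample_id=sample,
        )
    return out


# ---------------------------------------------------------------------------
# Spectrum arithmetic
# ---------------------------------------------------------------------------


def _check_same_grid(a: EmissionSpectrum, b: EmissionSpectrum) -> None:
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise ValidationError(
            f"wavelength grids of wells {a.well_id} and {b.well_id} differ; "
            "spectra are never resampled implicitly"
        )
    if a.excitation_nm != b.excitation_nm:
        raise ValidationError(
            f"excitation mismatch: {a.excitation_nm} vs {b.excitation_nm} nm"
        )


def subtract_background(s: EmissionSpectrum, blank: EmissionSpectrum) -> EmissionSpectrum:
    """Pointwise ``s - blank`` on identical grids; metadata of ``s`` kept.

    The result may contain small negative values; they are retained.
    """
    _check_same_grid(s, blank)
    return s.with_intensities(s.intensities - blank.intensities)


def average_replicates(
    scans: Sequence[EmissionSpectrum],
) -> tuple[EmissionSpectrum, np.ndarray]:
    """Pointwise mean spectrum and pointwise rms deviation about the mean.

    The rms is the population root-mean-square deviation (ddof=0), matching
    the "mean and associated rms of repeated measurements" convention.
    """
    if len(scans) < 2:
        raise ValidationError("need at least 2 replicate spectra to average")
    first = scans[0]
    for s in scans[1:]:
        _check_same_grid(first, s)
    stack = np.stack([s.intensities for s in scans])
    mean = stack.mean(axis=0)
    rms = np.sqrt(np.mean((stack - mean) ** 2, axis=0))
    return first.with_intensities(mean), rms


def _window_points(s: EmissionSpectrum, lo_nm: float, hi_nm: float):
    wl = s.wavelengths
    if lo_nm >= hi_nm:
        raise RangeError(f"empty window [{lo_nm}, {hi_nm}]")
    if lo_nm < wl[0] or hi_nm > wl[-1]:
        raise RangeError(
            f"window [{lo_nm}, {hi_nm}] outside grid span [{wl[0]}, {wl[-1]}]"
        )
    inner = wl[(wl > lo_nm) & (wl < hi_nm)]
    xs = np.concatenate(([lo_nm], inner, [hi_nm]))
    ys = np.interp(xs, wl, s.intensities)
    return xs, ys


def integrate_band(s: EmissionSpectrum, lo_nm: float, hi_nm: float) -> float:
    """Trapezoidal integral of the spectrum over the closed window, RFU*nm.

    Window endpoints that do not fall on the grid are obtained by linear
    interpolation.
    """
    xs, ys = _window_points(s, lo_nm, hi_nm)
    return float(np.trapezoid(ys, xs))


def peak_intensity(s: EmissionSpectrum, center_nm: float, halfwidth_nm: float = 2.0) -> float:
    """Mean intensity over [center-halfwidth, center+halfwidth] (RFU).

    ``halfwidth_nm == 0`` returns the linearly interpolated intensity at
    ``center_nm``.  Averaging over a small window makes the readout robust
    to 1-2 nm grid offsets relative to the nominal band position.
    """
    if halfwidth_nm < 0:
        raise RangeError("halfwidth_nm must be >= 0")
    wl = s.wavelengths
    if halfwidth_nm == 0:
        if center_nm < wl[0] or center_nm > wl[-1]:
            raise RangeError(f"{center_nm} nm outside grid span [{wl[0]}, {wl[-1]}]")
        return float(np.interp(center_nm, wl, s.intensities))
    lo, hi = center_nm - halfwidth_nm, center_nm + halfwidth_nm
    return integrate_band(s, lo, hi) / (hi - lo)
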