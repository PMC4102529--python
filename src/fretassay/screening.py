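"""Competitive-inhibition screening analytics.

A candidate inhibitor competing with the acceptor-labeled ligand for the
donor-labeled receptor lowers the mixture's FRET efficiency.  For each
inhibitor condition x the inhibition efficiency is

    inhibition% = 100 * (F_control - F_x) / F_control

where F_control is the FRET efficiency of the uninhibited donor/acceptor
mixture and F_x that of the mixture incubated with the inhibitor.
Inhibition is computed per replicate (each inhibitor replicate paired with
the matching control replicate) and averaged; the value derived from the
two condition means is reported alongside, since the two differ slightly
whenever the control replicates scatter.

Group differences are annotated with a two-sample Student t-test:
``**`` for p < 0.005, ``*`` for p < 0.05, ``NS`` otherwise.  No
multiple-testing correction is applied by default; Holm correction is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fret import AnalysisWindows, RatioFactors, background_corrected, fret_efficiency
from .spectra import (
    DegenerateInputError,
    FretAssayError,
    PlateScan,
    ValidationError,
    average_replicates,
)

__all__ = [
    "ConfigurationError",
    "ScreeningRecord",
    "ScreenResult",
    "inhibition_efficiency",
    "propagate_inhibition_rms",
    "compare_inhibitors",
    "star_code",
    "analyze_screen",
]


class ConfigurationError(FretAssayError):
    """The plate lacks wells the analysis requires (controls, calibration)."""


def inhibition_efficiency(f_control_pct: float, f_x_pct: float) -> float:
    """Inhibition efficiency 100*(F_control - F_x)/F_control, in percent.

    Negative values (FRET enhancers) are returned as-is; callers flag them.
    """
    if not f_control_pct > 0:
        raise DegenerateInputError(
            f"control FRET efficiency must be > 0 (got {f_control_pct})"
        )
    return 100.0 * (f_control_pct - f_x_pct) / f_control_pct


def propagate_inhibition_rms(
    f_control_pct: float, f_x_pct: float, rms_control: float, rms_x: float
) -> float:
    """First-order rms of the inhibition efficiency.

    rms(inh) = 100 * (f_x/f_c) * sqrt((rms_c/f_c)^2 + (rms_x/f_x)^2);
    degenerates gracefully to the direct term when f_x == 0.
    """
    if not f_control_pct > 0:
        raise DegenerateInputError("control FRET efficiency must be > 0")
    if f_x_pct == 0:
        return 100.0 * rms_x / f_control_pct
    return (
        100.0
        * abs(f_x_pct / f_control_pct)
        * float(np.hypot(rms_control / f_control_pct, rms_x / f_x_pct))
    )


def star_code(p: float) -> str:
    """Significance annotation: ** (p<0.005), * (p<0.05), else NS."""
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def compare_inhibitors(
    rep_a: Sequence[float], rep_b: Sequence[float], equal_var: bool = True
) -> tuple[float, str]:
    """Two-sided two-sample t-test on replicate-level efficiencies.

    Student's (equal-variance) test by default; pass ``equal_var=False``
    for Welch.  Degenerate zero-variance groups are resolved by the limit:
    equal means give p = 1, distinct means give p = 0.
    """
    a = np.asarray(rep_a, dtype=float)
    b = np.asarray(rep_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 replicates per group for a t-test")
    if a.std() == 0.0 and b.std() == 0.0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return p, star_code(p)


@dataclass(frozen=True)
class ScreeningRecord:
    """Per-inhibitor, per-dose efficiencies and derived inhibition."""

    inhibitor_id: str
    dose_uM: float
    fret_efficiency_pct: float
    efficiency_rms: float
    inhibition_pct: float
    inhibition_rms: float
    inhibition_pct_mean_based: float
    replicate_efficiencies: np.ndarray
    p_vs_control: float
    stars: str
    enhancer: bool = False

    def __post_init__(self) -> None:
        if self.dose_uM < 0:
            raise ValidationError("dose_uM must be >= 0")
        if self.inhibition_pct > 100.0 + 1e-9:
            raise ValidationError("inhibition cannot exceed 100%")


@dataclass(frozen=True)
class ScreenResult:
    """Full screen summary: control, per-condition records, ranking."""

    control_efficiency_pct: float
    control_rms: float
    control_replicates: np.ndarray
    records: tuple[ScreeningRecord, ...]
    ranking: dict[float, tuple[str, ...]]

    def to_table(self) -> pd.DataFrame:
        """Delimited-table view mirroring the per-dose report layout."""
        rows = [
            {
                "inhibitor_id": r.inhibitor_id,
                "dose_uM": r.dose_uM,
                "fret_efficiency_pct": r.fret_efficiency_pct,
                "efficiency_rms": r.efficiency_rms,
                "inhibition_pct": r.inhibition_pct,
                "inhibition_rms": r.inhibition_rms,
                "p_vs_control": r.p_vs_control,
                "stars": r.stars,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows).sort_values(["inhibitor_id", "dose_uM"]).reset_index(drop=True)


def _holm(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def analyze_screen(
    plate: PlateScan,
    factors: RatioFactors | None = None,
    windows: AnalysisWindows = AnalysisWindows(),
    equal_var: bool = True,
    holm: bool = False,
) -> ScreenResult:
    """Run the screening analysis on a plate.

    Requires control mixture wells, at least one inhibitor condition, and
    donor-only/acceptor-only reference wells at the mixture concentrations.
    Efficiencies are computed per replicate well against replicate-mean
    reference spectra; the ``factors`` argument is accepted for pipeline
    symmetry (the efficiency estimator derives its bleed correction from
    the donor-only scan directly).
    """
    if windows.a_d_470 is None or windows.a_a_470 is None:
        raise ConfigurationError(
            "analysis windows must carry a_d_470 and a_a_470 (donor and "
            "acceptor absorbance at the donor excitation wavelength)"
        )
    corrected = background_corrected(plate)
    groups = corrected.conditions()

    control_keys = [k for k in groups if k[0] == "mixture"]
    inhibitor_keys = sorted(
        (k for k in groups if k[0] == "mixture_inhibitor"),
        key=lambda k: (k[3], k[4]),
    )
    if not control_keys:
        raise ConfigurationError("plate has no uninhibited mixture (control) wells")
    if not inhibitor_keys:
        raise ConfigurationError("plate has no inhibitor wells to screen")
    if len(control_keys) > 1:
        raise ConfigurationError(
            "multiple control mixture conditions found; the screen expects one"
        )
    control_key = control_keys[0]
    donor_conc, acceptor_conc = control_key[1], control_key[2]

    def reference(role: str, conc_index: int, conc: float, ex: float):
        keys = [k for k in groups if k[0] == role and k[conc_index] == conc]
        if not keys:
            keys = [k for k in groups if k[0] == role]
        if not keys:
            raise ConfigurationError(f"plate lacks {role} reference wells")
        wells = groups[sorted(keys)[0]]
        scans = [corrected.spectrum(w, ex) for w in wells]
        return scans[0] if len(scans) == 1 else average_replicates(scans)[0]

    donor_ref = reference("donor_only", 1, donor_conc, windows.donor_ex_nm)
    acc_ref_470 = reference("acceptor_only", 2, acceptor_conc, windows.donor_ex_nm)
    acc_ref_exA = reference("acceptor_only", 2, acceptor_conc, windows.acceptor_ex_nm)

    def replicate_efficiencies(key) -> np.ndarray:
        values = []
        for well in groups[key]:
            res = fret_efficiency(
                corrected.spectrum(well, windows.donor_ex_nm),
                donor_ref,
                acc_ref_470,
                acc_ref_exA,
                a_d=windows.a_d_470,
                a_a=windows.a_a_470,
                windows=windows,
            )
            values.append(res.efficiency_pct)
        return np.asarray(values)

    control_reps = replicate_efficiencies(control_key)
    control_mean = float(control_reps.mean())
    control_rms = float(control_reps.std())
    if control_mean <= 0:
        raise DegenerateInputError("control FRET efficiency <= 0; screen undefined")

    records: list[ScreeningRecord] = []
    pvalues: list[float] = []
    for key in inhibitor_keys:
        reps = replicate_efficiencies(key)
        eff_mean = float(reps.mean())
        eff_rms = float(reps.std())
        # per-replicate inhibition, paired with the matching control replicate
        n = min(len(reps), len(control_reps))
        per_rep = np.array(
            [inhibition_efficiency(control_reps[i], reps[i]) for i in range(n)]
        )
        inh_mean_based = inhibition_efficiency(control_mean, eff_mean)
        if len(reps) >= 2 and len(control_reps) >= 2:
            p, _ = compare_inhibitors(control_reps, reps, equal_var=equal_var)
        else:
            p = float("nan")  # single-replicate plates carry no test
        pvalues.append(p)
        records.append(
            ScreeningRecord(
                inhibitor_id=key[3],
                dose_uM=key[4],
                fret_efficiency_pct=eff_mean,
                efficiency_rms=eff_rms,
                inhibition_pct=float(per_rep.mean()),
                inhibition_rms=propagate_inhibition_rms(
                    control_mean, eff_mean, control_rms, eff_rms
                ),
                inhibition_pct_mean_based=inh_mean_based,
                replicate_efficiencies=reps,
                p_vs_control=p,
                stars="NS",  # reassigned below once correction is settled
                enhancer=per_rep.mean() < 0,
            )
        )

    if holm:
        pvalues = _holm(pvalues)
    records = [
        ScreeningRecord(
            **{
                **{f: getattr(r, f) for f in r.__dataclass_fields__},
                "p_vs_control": p,
                "stars": star_code(p),
            }
        )
        for r, p in zip(records, pvalues)
    ]

    ranking: dict[float, tuple[str, ...]] = {}
    doses = sorted({r.dose_uM for r in records})
    for dose in doses:
        at_dose = [r for r in records if r.dose_uM == dose]
        at_dose.sort(key=lambda r: -r.inhibition_pct)
        ranking[dose] = tuple(r.inhibitor_id for r in at_dose)

    return ScreenResult(
        control_efficiency_pct=control_mean,
        control_rms=control_rms,
        control_replicates=control_reps,
        records=tuple(records),
        ranking=ranking,
    )
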