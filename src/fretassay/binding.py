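"""One-to-one binding with ligand depletion and the K_d titration fit.

For a bimolecular complex D + A <-> DA at equilibrium with totals D, A and
dissociation constant K_d, mass action gives the quadratic

    [DA]^2 - (A + D + K_d) [DA] + A D = 0

whose physically admissible root is

    [DA] = ( (A + D + K_d) - sqrt((A + D + K_d)^2 - 4 A D) ) / 2,

satisfying 0 <= [DA] <= min(A, D).  No "excess ligand" approximation is
made: at the nanomolar K_d and 100 nM donor of this assay a large fraction
of the titrant is depleted into the complex, and the hyperbolic
approximation would bias K_d.

The sensitized FRET signal is proportional to the bound donor fraction,

    F_FRET(A) = F_FRETmax * [DA](A, D, K_d) / D,

saturating at F_FRETmax when every donor is complexed.  ``fit_binding``
estimates (K_d, F_FRETmax) by nonlinear least squares with multi-start
initialization, and ``bootstrap_ci`` supplies percentile confidence
intervals by case resampling of replicate-level points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .spectra import FretAssayError, ValidationError

__all__ = [
    "DegenerateDataError",
    "FitError",
    "TitrationSeries",
    "BindingFitResult",
    "bound_complex",
    "predicted_fret",
    "fit_binding",
    "bootstrap_ci",
]

KD_BOUNDS_NM = (1e-3, 1e6)


class DegenerateDataError(FretAssayError):
    """The data cannot identify the model parameters (e.g. all-zero signal)."""


class FitError(FretAssayError):
    """The optimizer failed to converge from any start."""

    def __init__(self, message: str, best_params: tuple[float, float] | None = None):
        super().__init__(message)
        self.best_params = best_params


def bound_complex(a_total, d_total, kd):
    """Equilibrium complex concentration [DA] (nM) under ligand depletion.

    Evaluated as 2AD / (s + sqrt(s^2 - 4AD)) with s = A + D + K_d, the
    numerically stable form of the quadratic root (no catastrophic
    cancellation when K_d << A + D).  Accepts scalars or arrays.
    """
    a = np.asarray(a_total, dtype=float)
    d = np.asarray(d_total, dtype=float)
    if np.any(a < 0) or np.any(d < 0):
        raise ValidationError("concentrations must be >= 0")
    if not np.all(np.asarray(kd) > 0):
        raise ValidationError("kd must be > 0")
    s = a + d + kd
    disc = s * s - 4.0 * a * d
    out = 2.0 * a * d / (s + np.sqrt(np.maximum(disc, 0.0)))
    if np.isscalar(a_total) and np.isscalar(d_total):
        return float(out)
    return out


def predicted_fret(a_total, d_total, kd, f_max):
    """Model FRET signal F_FRETmax * [DA]/D; saturates at F_FRETmax."""
    if np.any(np.asarray(d_total) <= 0):
        raise ValidationError("donor concentration must be > 0")
    return f_max * bound_complex(a_total, d_total, kd) / d_total


@dataclass(frozen=True)
class TitrationSeries:
    """F_FRET vs acceptor concentration at fixed donor concentration.

    ``replicate_f_fret`` optionally carries the replicate-level values per
    concentration (used by the bootstrap); ``f_fret`` holds the per-
    concentration means the fit runs on.
    """

    donor_total_nM: float
    acceptor_totals_nM: np.ndarray
    f_fret: np.ndarray
    f_fret_rms: np.ndarray | None = None
    replicate_f_fret: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.acceptor_totals_nM, dtype=float)
        f = np.asarray(self.f_fret, dtype=float)
        object.__setattr__(self, "acceptor_totals_nM", a)
        object.__setattr__(self, "f_fret", f)
        if self.f_fret_rms is not None:
            object.__setattr__(self, "f_fret_rms", np.asarray(self.f_fret_rms, dtype=float))
        if not self.donor_total_nM > 0:
            raise ValidationError("donor_total_nM must be > 0")
        if len(a) != len(f):
            raise ValidationError("one F_FRET entry required per acceptor concentration")
        if np.any(a < 0) or (len(a) >= 2 and not np.all(np.diff(a) > 0)):
            raise ValidationError("acceptor series must be non-negative, strictly increasing")
        if self.replicate_f_fret is not None and len(self.replicate_f_fret) != len(a):
            raise ValidationError("replicate_f_fret must align with the concentration series")


@dataclass(frozen=True)
class BindingFitResult:
    """Least-squares estimates with diagnostics."""

    kd_nM: float
    kd_se_nM: float
    f_fret_max: float
    f_fret_max_se: float
    adj_r_squared: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    kd_rms_nM: float | None = None  # replicate spread of kd, when bootstrapped
    bounds_hit: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.kd_nM > 0:
            raise ValidationError("fitted kd must be > 0")
        if self.converged and not self.f_fret_max > 0:
            raise ValidationError("fitted f_fret_max must be > 0 on convergence")
        if not self.adj_r_squared <= 1.0:
            raise ValidationError("adjusted R^2 cannot exceed 1")


def _initial_kd(a: np.ndarray, f: np.ndarray) -> float:
    """Acceptor concentration at half-maximal signal, by linear interpolation."""
    f_max = f.max()
    half = 0.5 * f_max
    above = np.nonzero(f >= half)[0]
    if len(above) == 0 or above[0] == 0:
        positive = a[a > 0]
        return float(np.median(positive)) if len(positive) else 1.0
    i = above[0]
    f0, f1 = f[i - 1], f[i]
    a0, a1 = a[i - 1], a[i]
    if f1 == f0:
        return float(a1)
    return float(a0 + (half - f0) * (a1 - a0) / (f1 - f0))


def fit_binding(
    series: TitrationSeries,
    weights: np.ndarray | None = None,
) -> BindingFitResult:
    """Fit (K_d, F_FRETmax) to a titration by nonlinear least squares.

    Unweighted by default; pass per-point standard deviations as ``weights``
    for inverse-variance weighting.  Initialization is multi-start: K_d
    seeds log-spaced over [kd0/10, kd0*10] around the half-maximum estimate,
    because the quadratic model's flat saturation tail can trap a
    single-start optimizer.  Standard errors come from the Jacobian-based
    covariance; the adjusted R^2 uses the number of fitted (per-
    concentration mean) points and p = 2.
    """
    a = series.acceptor_totals_nM
    f = series.f_fret
    d = series.donor_total_nM
    n = len(a)
    if n < 4:
        raise ValidationError("need >= 4 acceptor concentrations to fit (kd, f_max)")
    if np.allclose(f, 0.0):
        raise DegenerateDataError("all F_FRET values are zero; nothing to fit")

    f_max0 = float(f.max())
    kd0 = _initial_kd(a, f)
    upper_fmax = 100.0 * abs(f_max0)
    bounds = ([KD_BOUNDS_NM[0], np.finfo(float).tiny], [KD_BOUNDS_NM[1], upper_fmax])
    kd0 = float(np.clip(kd0, *KD_BOUNDS_NM))

    def model(a_arr, kd, f_max):
        return predicted_fret(a_arr, d, kd, f_max)

    sigma = np.asarray(weights, dtype=float) if weights is not None else None
    best = None
    for kd_start in np.geomspace(kd0 / 10.0, kd0 * 10.0, 5):
        kd_start = float(np.clip(kd_start, *KD_BOUNDS_NM))
        try:
            popt, pcov = curve_fit(
                model,
                a,
                f,
                p0=[kd_start, f_max0],
                sigma=sigma,
                bounds=bounds,
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((f - model(a, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)

    if best is None:
        raise FitError("optimizer failed to converge from every start", None)

    ssr, popt, pcov = best
    kd_hat, f_max_hat = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    residuals = f - model(a, kd_hat, f_max_hat)
    sst = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    p = 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if sst > 0 else np.nan

    hits = []
    for name, value, (lo, hi) in (
        ("kd", kd_hat, KD_BOUNDS_NM),
        ("f_max", f_max_hat, (0.0, upper_fmax)),
    ):
        if np.isclose(value, lo, rtol=1e-6) or np.isclose(value, hi, rtol=1e-6):
            hits.append(name)

    return BindingFitResult(
        kd_nM=kd_hat,
        kd_se_nM=float(se[0]),
        f_fret_max=f_max_hat,
        f_fret_max_se=float(se[1]),
        adj_r_squared=float(adj_r2) if np.isfinite(adj_r2) else float("-inf"),
        residuals=residuals,
        converged=True,
        n_points=n,
        bounds_hit=tuple(hits),
    )


def bootstrap_ci(
    series: TitrationSeries,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for K_d and F_FRETmax.

    Case resampling at replicate level, stratified within each acceptor
    concentration so every resample keeps the full titration design.  When
    the series carries no replicate-level values, each concentration's mean
    acts as its single replicate (noiseless data then yields zero-width
    intervals).  Reproducible under a fixed seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100 for stable percentiles")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    full = fit_binding(series)  # must converge before resampling
    rng = np.random.default_rng(seed)
    reps = series.replicate_f_fret
    if reps is None:
        reps = tuple(np.array([v]) for v in series.f_fret)

    kds, fmaxs = [], []
    for _ in range(n_boot):
        f_resampled = np.array(
            [rng.choice(r, size=len(r), replace=True).mean() for r in reps]
        )
        boot = TitrationSeries(
            donor_total_nM=series.donor_total_nM,
            acceptor_totals_nM=series.acceptor_totals_nM,
            f_fret=f_resampled,
        )
        try:
            res = _single_start_fit(boot, p0=(full.kd_nM, full.f_fret_max))
        except (FitError, DegenerateDataError):
            continue
        kds.append(res[0])
        fmaxs.append(res[1])

    alpha = 100.0 * (1.0 - level) / 2.0
    return {
        "kd_nM": tuple(np.percentile(kds, [alpha, 100.0 - alpha])),
        "f_fret_max": tuple(np.percentile(fmaxs, [alpha, 100.0 - alpha])),
    }


def _single_start_fit(series: TitrationSeries, p0: tuple[float, float]) -> tuple[float, float]:
    """One curve_fit solve from a given start (used inside the bootstrap)."""
    d = series.donor_total_nM
    f_scale = max(abs(p0[1]), 1e-12)
    try:
        popt, _ = curve_fit(
            lambda a_arr, kd, f_max: predicted_fret(a_arr, d, kd, f_max),
            series.acceptor_totals_nM,
            series.f_fret,
            p0=list(p0),
            bounds=([KD_BOUNDS_NM[0], np.finfo(float).tiny], [KD_BOUNDS_NM[1], 100.0 * f_scale]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"bootstrap refit failed: {exc}") from exc
    return float(popt[0]), float(popt[1])
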