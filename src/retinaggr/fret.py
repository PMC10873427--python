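"""FRET-based quantification of receptor oligomerization and aggregation.

The assay expresses donor (mTq2) and acceptor (YFP) tagged rhodopsin in
HEK293 cells and reads donor dequenching at 476 nm after detergent
treatments.  Mild detergent (DM, n-dodecyl-beta-D-maltoside) dissolves
oligomers of properly folded receptor but leaves aggregates intact; SDS
dissolves everything and yields the fully dequenched, zero-FRET reference.
Total FRET therefore splits into a DM-sensitive component (oligomers) and a
DM-insensitive component (aggregates), and each component's saturation with
the acceptor:donor expression ratio (A:D) is summarized by a rectangular
hyperbola E = Emax * x / (EC50 + x).

A fitted Emax only indicates physiologically relevant complexes if it
exceeds a non-specific FRET ceiling (an empirical level produced by random
collisions at high expression).  Specificity is assessed with an extra
sum-of-squares F test against a null fit whose Emax is pinned at the
ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

DONOR_READOUT_NM = 476.0

FretComponent = Literal["total", "dm_sensitive", "dm_insensitive"]


class FretError(Exception):
    """Base class for FRET-stage failures."""


class SpectrumRangeError(FretError, ValueError):
    """Requested wavelength lies outside the measured grid."""


class InvalidReferenceError(FretError, ValueError):
    """SDS (zero-FRET) donor intensity is non-positive."""


class InsufficientDataError(FretError, ValueError):
    """Too few points for the requested fit."""


class FitFailureError(FretError, RuntimeError):
    """Non-linear regression failed to converge; carries diagnostics."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission spectrum on an ascending wavelength grid."""

    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # arbitrary units, >= 0
    excitation: float = 425.0  # nm (donor excitation by default)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or w.shape != i.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if w.size < 2 or not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing with >= 2 points")
        if np.any(i < 0) or not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)


@dataclass(frozen=True)
class TreatmentSeries:
    """Donor-excitation spectra of one sample under the three treatments."""

    spectrum_untreated: EmissionSpectrum
    spectrum_dm: EmissionSpectrum
    spectrum_sds: EmissionSpectrum
    acceptor_donor_ratio: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        grids = [
            self.spectrum_untreated.wavelengths,
            self.spectrum_dm.wavelengths,
            self.spectrum_sds.wavelengths,
        ]
        if not all(np.array_equal(grids[0], g) for g in grids[1:]):
            raise ValueError("all three spectra must share one wavelength grid")
        if not np.isfinite(self.acceptor_donor_ratio) or self.acceptor_donor_ratio < 0:
            raise ValueError("acceptor_donor_ratio must be finite and >= 0")


@dataclass(frozen=True)
class FretPoint:
    """Decomposed FRET efficiencies of one sample at its A:D ratio."""

    acceptor_donor_ratio: float
    e_total: float
    e_dm_sensitive: float
    e_dm_insensitive: float


@dataclass(frozen=True)
class FretCurveFit:
    """Rectangular-hyperbola fit of one FRET component vs A:D."""

    component: FretComponent
    e_max: float
    ec50: float
    se_e_max: float
    se_ec50: float
    residual_ss: float
    n_points: int

    def predict(self, acceptor_donor_ratio):
        x = np.asarray(acceptor_donor_ratio, dtype=float)
        return hyperbola(x, self.e_max, self.ec50)


@dataclass(frozen=True)
class SpecificityResult:
    """Extra sum-of-squares F test of Emax against the non-specific ceiling."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    e_max_nonspecific: float
    is_specific: bool
    ss_null: float
    ss_alt: float
    fit: FretCurveFit = field(repr=False, default=None)  # type: ignore[assignment]


def hyperbola(x, e_max, ec50):
    """Rectangular hyperbola E = Emax * x / (EC50 + x)."""
    x = np.asarray(x, dtype=float)
    return e_max * x / (ec50 + x)


def donor_intensity(spectrum: EmissionSpectrum, wavelength: float = DONOR_READOUT_NM) -> float:
    """Donor intensity at ``wavelength``, linearly interpolated on the grid.

    An exact grid hit returns the stored value; a wavelength outside the
    measured range raises :class:`SpectrumRangeError`.
    """
    w = spectrum.wavelengths
    if wavelength < w[0] or wavelength > w[-1]:
        raise SpectrumRangeError(
            f"wavelength {wavelength} nm outside measured grid [{w[0]}, {w[-1]}] nm"
        )
    return float(np.interp(wavelength, w, spectrum.intensities))


def compute_efficiencies(series: TreatmentSeries) -> FretPoint:
    """Decompose donor dequenching into total / DM-sensitive / DM-insensitive FRET.

    With F0, FDM, FSDS the donor intensities at 476 nm in untreated, DM- and
    SDS-treated cells, the SDS spectrum is the fully dissociated zero-FRET
    reference, so

        e_total          = (FSDS - F0)  / FSDS
        e_dm_insensitive = (FSDS - FDM) / FSDS
        e_dm_sensitive   = (FDM  - F0)  / FSDS

    Each component is computed directly from intensities and the total is
    their sum, so e_total == e_dm_sensitive + e_dm_insensitive holds exactly
    (bit for bit), not merely algebraically.
    """
    f0 = donor_intensity(series.spectrum_untreated)
    fdm = donor_intensity(series.spectrum_dm)
    fsds = donor_intensity(series.spectrum_sds)
    if fsds <= 0:
        raise InvalidReferenceError("SDS donor intensity at 476 nm must be > 0")
    e_ins = (fsds - fdm) / fsds
    e_sens = (fdm - f0) / fsds
    return FretPoint(
        acceptor_donor_ratio=series.acceptor_donor_ratio,
        e_total=e_sens + e_ins,
        e_dm_sensitive=e_sens,
        e_dm_insensitive=e_ins,
    )


def _fit_hyperbola(x: np.ndarray, y: np.ndarray, fixed_e_max: float | None = None):
    """Bounded least-squares hyperbola fit; returns (params, ss, cov).

    Multi-start (EC50 from the A:D quartiles, Emax from the max observed E)
    guards against the shallow valley at large EC50.  When ``fixed_e_max``
    is given only EC50 is free (the null model of the specificity test).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    positive = x[x > 0]
    ec50_starts = (
        np.unique(np.quantile(positive, [0.25, 0.5, 0.75])) if positive.size else np.array([1.0])
    )
    best = None
    for ec50_0 in ec50_starts:
        if fixed_e_max is None:
            emax_0 = float(np.clip(np.max(y, initial=0.0), 1e-3, 1.0))
            p0 = [emax_0, float(ec50_0)]
            lb, ub = [0.0, 1e-12], [1.0, np.inf]

            def resid(p):
                return hyperbola(x, p[0], p[1]) - y

        else:
            p0 = [float(ec50_0)]
            lb, ub = [1e-12], [np.inf]

            def resid(p):
                return hyperbola(x, fixed_e_max, p[0]) - y

        sol = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf")
        ss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or ss < best[1] - 1e-15):
            best = (sol, ss)
    if best is None:
        raise FitFailureError("hyperbola fit did not converge from any start")
    sol, ss = best
    n, p = x.size, sol.x.size
    cov = _covariance(sol.jac, ss, n, p)
    return sol.x, ss, cov


def _covariance(jac: np.ndarray, ss: float, n: int, p: int) -> np.ndarray:
    """Gauss-Newton covariance sigma^2 (J'J)^-1 with sigma^2 = SS/(n-p)."""
    dof = max(n - p, 1)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    return cov * (ss / dof)


def fit_fret_curve(
    points: Iterable[tuple[float, float]],
    component: FretComponent = "total",
) -> FretCurveFit:
    """Fit E = Emax * x / (EC50 + x) to (A:D, E) points by least squares.

    Small noise-induced negative efficiencies are retained: clipping them
    would bias Emax upward.  Requires at least 3 points.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("hyperbola fit needs at least 3 (A:D, E) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("A:D ratios must be >= 0")
    params, ss, cov = _fit_hyperbola(x, y)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return FretCurveFit(
        component=component,
        e_max=float(params[0]),
        ec50=float(params[1]),
        se_e_max=float(se[0]),
        se_ec50=float(se[1]),
        residual_ss=ss,
        n_points=int(x.size),
    )


def test_specificity(
    points: Iterable[tuple[float, float]],
    e_max_nonspecific: float,
    alpha: float = 0.05,
) -> SpecificityResult:
    """Extra sum-of-squares F test of the fitted Emax against the ceiling.

    The alternative model fits (Emax, EC50) freely; the null pins Emax at
    ``e_max_nonspecific`` and refits EC50.  F = ((SS0 - SS1)/1)/(SS1/(n-2))
    with p from the upper tail of F(1, n-2).  A component is specific only
    if the test rejects *and* the free Emax exceeds the ceiling (one-sided
    enrichment reading).
    """
    pts = np.asarray(list(points), dtype=float)
    n = pts.shape[0]
    if n <= 3:
        raise InsufficientDataError("specificity test needs n > p_free + 1 = 3 points")
    x, y = pts[:, 0], pts[:, 1]
    fit = fit_fret_curve(zip(x, y))
    null_params, ss_null, _ = _fit_hyperbola(x, y, fixed_e_max=e_max_nonspecific)
    # Re-polish the free fit from the null solution so SS_alt <= SS_null holds
    # even when the free optimum sits near the ceiling.
    alt_params, ss_alt, cov = _fit_hyperbola(x, y)
    repolish = optimize.least_squares(
        lambda p: hyperbola(x, p[0], p[1]) - y,
        [np.clip(e_max_nonspecific, 0.0, 1.0), null_params[0]],
        bounds=([0.0, 1e-12], [1.0, np.inf]),
        method="trf",
    )
    ss_re = float(np.sum(repolish.fun**2))
    if ss_re < ss_alt:
        alt_params, ss_alt = repolish.x, ss_re
        cov = _covariance(repolish.jac, ss_alt, n, 2)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        fit = FretCurveFit(
            component=fit.component,
            e_max=float(alt_params[0]),
            ec50=float(alt_params[1]),
            se_e_max=float(se[0]),
            se_ec50=float(se[1]),
            residual_ss=ss_alt,
            n_points=n,
        )
    df_num, df_den = 1, n - 2
    if ss_null <= 1e-12 or ss_null - ss_alt <= 1e-9 * ss_null:
        # A (near-)perfect null fit, or an SS difference below optimizer
        # resolution: the models are indistinguishable on these data.
        f_stat = 0.0
    elif ss_alt > 0:
        f_stat = (ss_null - ss_alt) / df_num / (ss_alt / df_den)
    else:
        f_stat = np.inf
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return SpecificityResult(
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        e_max_nonspecific=e_max_nonspecific,
        is_specific=bool(p_value < alpha and fit.e_max > e_max_nonspecific),
        ss_null=float(ss_null),
        ss_alt=float(ss_alt),
        fit=fit,
    )


def component_fractions(
    fit_sensitive: FretCurveFit,
    fit_insensitive: FretCurveFit,
    sensitive_specific: bool,
    insensitive_specific: bool,
) -> tuple[float, float] | None:
    """Fractions of the total *specific* FRET carried by each component.

    Non-specific components are censored to 0.  Returns ``None`` when both
    components are non-specific (the fraction is undefined, not zero).
    """
    e_sens = fit_sensitive.e_max if sensitive_specific else 0.0
    e_ins = fit_insensitive.e_max if insensitive_specific else 0.0
    total = e_sens + e_ins
    if not (sensitive_specific or insensitive_specific) or total <= 0:
        return None
    return e_sens / total, e_ins / total


def efficiencies_table(series_list: Sequence[TreatmentSeries]) -> "np.ndarray":
    """Convenience: decompose a series list into an (n, 4) array
    [A:D, e_total, e_sensitive, e_insensitive], sorted by A:D."""
    rows = []
    for s in series_list:
        p = compute_efficiencies(s)
        rows.append([p.acceptor_donor_ratio, p.e_total, p.e_dm_sensitive, p.e_dm_insensitive])
    out = np.asarray(rows, dtype=float)
    return out[np.argsort(out[:, 0])]
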