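"""Electroretinogram amplitude-vs-intensity (dose-response) fitting.

ERG a- and b-wave amplitudes R (microvolt) recorded over increasing flash
intensities I (cd s m^-2) are fit, in log10-intensity space, to either the
standard single-site dose-response model

    R = Rmax / (1 + 10^(logKA - logI))

or its biphasic extension

    R = Rmax*f / (1 + 10^(logKA - logI)) + Rmax*(1-f) / (1 + 10^(logKB - logI))

where KA (and KB) are the half-maximal intensities and f the fraction of
the response carried by the KA site.  The biphasic model nests the standard
one (f = 1), so the two are compared with an extra sum-of-squares F test
with 2 numerator degrees of freedom.  A drop in Rmax at unchanged KA is the
signature of photoreceptor cell loss with preserved phototransduction in
the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

ModelName = Literal["standard", "biphasic"]


class ErgError(Exception):
    pass


class InsufficientDataError(ErgError, ValueError):
    pass


class FitFailureError(ErgError, RuntimeError):
    pass


@dataclass(frozen=True)
class ErgSweep:
    """Eye-averaged wave amplitudes over an increasing flash-intensity ladder."""

    intensities: np.ndarray  # cd s / m^2, strictly increasing, > 0
    amplitudes: np.ndarray  # microvolt
    wave: Literal["a", "b"] = "b"
    regime: Literal["scotopic", "photopic"] = "scotopic"
    mouse_id: str = ""

    def __post_init__(self) -> None:
        i = np.asarray(self.intensities, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if i.ndim != 1 or i.shape != a.shape:
            raise ValueError("intensities and amplitudes must be 1-D and equal length")
        if np.any(i <= 0) or not np.all(np.diff(i) > 0):
            raise ValueError("intensities must be positive and strictly increasing")
        object.__setattr__(self, "intensities", i)
        object.__setattr__(self, "amplitudes", a)


@dataclass(frozen=True)
class DoseResponseFit:
    model: ModelName
    r_max: float  # microvolt
    log_ka: float  # log10 cd s / m^2
    se_r_max: float
    se_log_ka: float
    residual_ss: float
    n_points: int
    log_kb: float | None = None  # biphasic only; log_ka < log_kb by convention
    f: float | None = None
    se_log_kb: float | None = None
    se_f: float | None = None


@dataclass(frozen=True)
class ModelSelection:
    preferred: DoseResponseFit
    standard: DoseResponseFit
    biphasic: DoseResponseFit
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float


def _pow10(e):
    # exponent clip keeps the saturating tails finite when a half-max
    # parameter wanders far outside the data during optimization
    return 10.0 ** np.clip(e, -300.0, 300.0)


def standard_model(log_i, r_max, log_ka):
    return r_max / (1.0 + _pow10(log_ka - np.asarray(log_i, float)))


def biphasic_model(log_i, r_max, log_ka, log_kb, f):
    log_i = np.asarray(log_i, float)
    return r_max * f / (1.0 + _pow10(log_ka - log_i)) + r_max * (1.0 - f) / (
        1.0 + _pow10(log_kb - log_i)
    )


def _ls_cov(jac, ss, n, p):
    dof = max(n - p, 1)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    return cov * (ss / dof)


def _fit_standard(log_i, r):
    r_max0 = float(max(r.max(), 1e-6))
    best = None
    for log_ka0 in np.quantile(log_i, [0.25, 0.5, 0.75]):
        sol = optimize.least_squares(
            lambda p: standard_model(log_i, p[0], p[1]) - r,
            [r_max0, float(log_ka0)],
            bounds=([0.0, -np.inf], [np.inf, np.inf]),
            method="trf",
        )
        ss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or ss < best[1]):
            best = (sol, ss)
    if best is None:
        raise FitFailureError("standard dose-response fit did not converge")
    return best


def _grid_seed_biphasic(log_i, r):
    """Near-global biphasic start by separable least squares.

    For fixed (logKA, logKB) the model is linear in the site amplitudes
    A = Rmax*f and B = Rmax*(1-f), so a coarse grid over the half-max
    pair plus a non-negative linear solve locates the global basin.
    """
    lo, hi = float(log_i.min()) - 1.0, float(log_i.max()) + 1.0
    grid = np.linspace(lo, hi, 17)
    best = None
    for ia, log_ka in enumerate(grid):
        ca = 1.0 / (1.0 + _pow10(log_ka - log_i))
        for log_kb in grid[ia + 1 :]:
            design = np.column_stack([ca, 1.0 / (1.0 + _pow10(log_kb - log_i))])
            ab, _ = optimize.nnls(design, np.clip(r, 0.0, None))
            ss = float(np.sum((design @ ab - r) ** 2))
            if best is None or ss < best[0]:
                best = (ss, log_ka, log_kb, ab)
    ss, log_ka, log_kb, (a, b) = best
    r_max = max(a + b, 1e-6)
    return [r_max, log_ka, log_kb, float(np.clip(a / r_max, 0.0, 1.0))]


def _fit_biphasic(log_i, r, extra_starts=()):
    r_max0 = float(max(r.max(), 1e-6))
    mid = float(np.median(log_i))
    span = float(log_i.max() - log_i.min()) or 1.0
    starts = [
        _grid_seed_biphasic(log_i, r),
        [r_max0, mid - span / 4, mid + span / 4, 0.5],
        [r_max0, float(log_i.min()) + span / 4, float(log_i.max()) - span / 4, 0.5],
    ] + [list(s) for s in extra_starts]
    best = None
    for p0 in starts:
        sol = optimize.least_squares(
            lambda p: biphasic_model(log_i, p[0], p[1], p[2], p[3]) - r,
            p0,
            bounds=([0.0, -np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf, 1.0]),
            method="trf",
            max_nfev=400,  # f -> 1 leaves logKB unidentifiable (flat direction)
        )
        ss = float(np.sum(sol.fun**2))
        if np.isfinite(ss) and (best is None or ss < best[1] - 1e-12):
            best = (sol, ss)
    if best is None:
        raise FitFailureError("biphasic dose-response fit produced no finite residual")
    return best


def fit_dose_response(sweep: ErgSweep, model: ModelName = "standard") -> DoseResponseFit:
    """Least-squares dose-response fit in log10-intensity space.

    The biphasic fit enforces the identifiability convention logKA < logKB
    by reordering the two sites (with f -> 1 - f) after optimization.
    """
    log_i = np.log10(sweep.intensities)
    r = sweep.amplitudes
    n = log_i.size
    if model == "standard":
        if n < 3:
            raise InsufficientDataError("standard model needs >= 3 points")
        sol, ss = _fit_standard(log_i, r)
        cov = _ls_cov(sol.jac, ss, n, 2)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return DoseResponseFit(
            model="standard",
            r_max=float(sol.x[0]),
            log_ka=float(sol.x[1]),
            se_r_max=float(se[0]),
            se_log_ka=float(se[1]),
            residual_ss=ss,
            n_points=n,
        )
    if model != "biphasic":
        raise ValueError(f"unknown model {model!r}")
    if n < 5:
        raise InsufficientDataError("biphasic model needs >= 5 points")
    # Seed with the standard solution collapsed to one site (f = 1): the
    # nested optimum can then only improve on the standard residual SS.
    std_sol, std_ss = _fit_standard(log_i, r)
    sol, ss = _fit_biphasic(
        log_i, r, extra_starts=[[std_sol.x[0], std_sol.x[1], std_sol.x[1] + 1.0, 1.0]]
    )
    ss = min(ss, std_ss)  # nesting guarantee (numerical guard)
    r_max, log_ka, log_kb, f = (float(v) for v in sol.x)
    cov = _ls_cov(sol.jac, ss, n, 4)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    se_r_max, se_log_ka, se_log_kb, se_f = (float(v) for v in se)
    if log_ka > log_kb:
        log_ka, log_kb = log_kb, log_ka
        se_log_ka, se_log_kb = se_log_kb, se_log_ka
        f = 1.0 - f
    return DoseResponseFit(
        model="biphasic",
        r_max=r_max,
        log_ka=log_ka,
        se_r_max=se_r_max,
        se_log_ka=se_log_ka,
        residual_ss=ss,
        n_points=n,
        log_kb=log_kb,
        f=f,
        se_log_kb=se_log_kb,
        se_f=se_f,
    )


def predict(fit: DoseResponseFit, intensity) -> np.ndarray:
    """Evaluate a fitted dose-response curve at intensity I (cd s / m^2)."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ErgError("intensity must be > 0")
    log_i = np.log10(intensity)
    if fit.model == "standard":
        return standard_model(log_i, fit.r_max, fit.log_ka)
    return biphasic_model(log_i, fit.r_max, fit.log_ka, fit.log_kb, fit.f)


def select_model(sweep: ErgSweep, alpha: float = 0.05) -> ModelSelection:
    """Standard vs biphasic by nested extra sum-of-squares F test.

    The biphasic model adds logKB and f (df_num = 2); it is preferred only
    when the F test rejects at ``alpha``.
    """
    n = sweep.intensities.size
    if n <= 4:
        raise InsufficientDataError("model selection needs > 4 points")
    std = fit_dose_response(sweep, "standard")
    bi = fit_dose_response(sweep, "biphasic")
    df_num, df_den = 2, n - 4
    if df_den < 1:
        raise InsufficientDataError("no residual degrees of freedom for the biphasic model")
    ss0, ss1 = std.residual_ss, bi.residual_ss
    if ss1 > 0:
        f_stat = max((ss0 - ss1) / df_num / (ss1 / df_den), 0.0)
    else:  # perfect alternative fit: F degenerates (0 iff the null is perfect too)
        f_stat = 0.0 if ss0 <= 1e-300 else np.inf
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    preferred = bi if p_value < alpha else std
    return ModelSelection(
        preferred=preferred,
        standard=std,
        biphasic=bi,
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        alpha=alpha,
    )
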