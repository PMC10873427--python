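"""Photoreceptor degeneration kinetics from outer-nuclear-layer counts.

The ONL thickness, in nuclei spanning the layer, is measured along the
vertical meridian at signed eccentricities from the optic nerve (positive =
superior, negative = inferior).  For kinetics, counts at 600, 800 and
1000 um are averaged per region and followed over age.  Rod loss follows a
one-phase exponential decay

    y = (y0 - plateau) * exp(-k * x) + plateau

with the plateau fixed at 1 nucleus (the residual cone row, excluded from
the rod-loss model) and y0 shared across series fitted together.  Each
series keeps its own rate constant k (month^-1).  Exponential decay is the
signature of one-hit (stochastic, constant-risk) photoreceptor death;
cumulative-damage death instead predicts sigmoidal kinetics, so the two are
discriminated by small-sample AIC between the exponential and a logistic
alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize

Region = Literal["superior", "inferior"]

#: Eccentricities (um from the optic nerve) averaged into the kinetics window.
WINDOW_POSITIONS_UM = (600.0, 800.0, 1000.0)


class KineticsError(Exception):
    pass


class MissingPositionError(KineticsError, ValueError):
    pass


class FitFailureError(KineticsError, RuntimeError):
    pass


@dataclass(frozen=True)
class SpiderMeasurement:
    """Mean nuclei count at one signed eccentricity."""

    eccentricity: float  # um, signed (+ superior, - inferior)
    nuclei_count: float
    sd: float = 0.0
    n_mice: int = 1

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.nuclei_count < 0:
            raise ValueError("nuclei_count must be >= 0")


@dataclass(frozen=True)
class TimePoint:
    """Windowed mean nuclei count at one age."""

    age: float  # months
    value: float
    genotype: str = ""
    region: str = "superior"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be > 0 months")


@dataclass(frozen=True)
class SeriesFit:
    k: float  # month^-1
    se_k: float


@dataclass(frozen=True)
class JointDecayFit:
    """Joint one-phase-decay fit: one shared y0, fixed plateau, k per series."""

    shared_y0: float
    se_y0: float
    per_series: dict[str, SeriesFit]
    plateau_fixed: float
    residual_ss: float
    converged: bool

    def predict(self, label: str, age) -> np.ndarray:
        k = self.per_series[label].k
        return one_phase_decay(np.asarray(age, float), self.shared_y0, self.plateau_fixed, k)


@dataclass(frozen=True)
class RateComparison:
    ratio: float
    percent_difference: float
    rounded_ratio: int


@dataclass(frozen=True)
class ModelComparison:
    """Exponential (one-hit) vs sigmoid (cumulative-damage) discrimination."""

    ss_exponential: float
    ss_sigmoid: float
    aicc_exponential: float
    aicc_sigmoid: float
    preferred: Literal["exponential", "sigmoid"]


def one_phase_decay(x, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * np.asarray(x, float)) + plateau


def sigmoid_decay(x, y0, x50, s, floor=1.0):
    """Logistic decline from y0 toward ``floor``, midpoint x50, width s."""
    return floor + (y0 - floor) / (1.0 + np.exp((np.asarray(x, float) - x50) / s))


def window_average(profile: Sequence[SpiderMeasurement], region: Region) -> float:
    """Mean nuclei count over the 600/800/1000 um window of one region."""
    sign = 1.0 if region == "superior" else -1.0
    by_pos = {m.eccentricity: m.nuclei_count for m in profile}
    values = []
    for pos in WINDOW_POSITIONS_UM:
        key = sign * pos
        if key not in by_pos:
            raise MissingPositionError(f"profile lacks the {key:+.0f} um position")
        values.append(by_pos[key])
    return float(np.mean(values))


def fit_one_phase_decay(
    series: Mapping[str, Sequence[TimePoint]],
    share_y0: bool = True,
    plateau: float = 1.0,
) -> JointDecayFit:
    """Global least-squares fit of one-phase decay across series.

    All series fitted together share a single y0 (``share_y0=True``, the
    default) and the plateau is fixed; each series gets its own k >= 0.
    With a single series the joint fit reduces exactly to the ordinary
    two-parameter (y0, k) fit.
    """
    labels = list(series)
    if not labels:
        raise KineticsError("no series to fit")
    for lab in labels:
        if len(series[lab]) < 3:
            raise KineticsError(f"series {lab!r} has fewer than 3 time points")
    if not share_y0 and len(labels) > 1:
        # Independent y0 decouples the series: fit one at a time instead.
        raise KineticsError(
            "share_y0=False with multiple series: fit each series separately"
        )

    xs = {lab: np.array([tp.age for tp in series[lab]], float) for lab in labels}
    ys = {lab: np.array([tp.value for tp in series[lab]], float) for lab in labels}
    n_total = int(sum(x.size for x in xs.values()))
    n_params = 1 + len(labels)

    y0_start = float(max(y.max() for y in ys.values()))
    k_starts = []
    for lab in labels:
        x, y = xs[lab], ys[lab]
        # crude log-linear start on (y - plateau), guarded for flat series
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.log(np.clip(y - plateau, 1e-9, None))
        slope = np.polyfit(x, z, 1)[0] if np.ptp(z) > 0 else 0.0
        k_starts.append(float(np.clip(-slope, 1e-6, 50.0)))

    def resid(theta):
        y0 = theta[0]
        out = []
        for j, lab in enumerate(labels):
            out.append(one_phase_decay(xs[lab], y0, plateau, theta[1 + j]) - ys[lab])
        return np.concatenate(out)

    p0 = np.array([max(y0_start, plateau + 1e-6)] + k_starts)
    lb = np.array([plateau] + [0.0] * len(labels))
    ub = np.full(n_params, np.inf)
    sol = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise FitFailureError(f"joint decay fit failed: {sol.message}")
    ss = float(np.sum(sol.fun**2))
    dof = max(n_total - n_params, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * (ss / dof)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * (ss / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    per = {
        lab: SeriesFit(k=float(sol.x[1 + j]), se_k=float(se[1 + j]))
        for j, lab in enumerate(labels)
    }
    return JointDecayFit(
        shared_y0=float(sol.x[0]),
        se_y0=float(se[0]),
        per_series=per,
        plateau_fixed=float(plateau),
        residual_ss=ss,
        converged=True,
    )


def rate_ratio(k_a: float, k_b: float) -> RateComparison:
    """Fold difference between two decay rate constants.

    ``rounded_ratio`` rounds half away from zero, matching how fold
    statements are usually quoted ("2 times faster", "4 times faster").
    """
    if k_b <= 0:
        raise KineticsError("reference rate constant must be > 0")
    ratio = k_a / k_b
    rounded = int(math.floor(abs(ratio) + 0.5) * (1 if ratio >= 0 else -1))
    return RateComparison(
        ratio=float(ratio),
        percent_difference=float(100.0 * (ratio - 1.0)),
        rounded_ratio=rounded,
    )


def _aicc(ss: float, n: int, p: int) -> float:
    """Small-sample AIC for a Gaussian least-squares fit (p excludes sigma)."""
    k = p + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(ss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_decay_models(points: Sequence[TimePoint], floor: float = 1.0) -> ModelComparison:
    """Discriminate exponential (one-hit) from sigmoid (cumulative-damage) loss.

    Fits the one-phase decay (2 free parameters, plateau fixed) and a
    3-parameter logistic alternative with the same fixed floor, and prefers
    the model with the lower small-sample AIC.  The models are not nested,
    so an F test does not apply.
    """
    if len(points) < 5:
        raise KineticsError("model comparison needs >= 5 points (sigmoid df)")
    x = np.array([tp.age for tp in points], float)
    y = np.array([tp.value for tp in points], float)
    n = x.size

    exp_fit = fit_one_phase_decay({"_": list(points)}, plateau=floor)
    ss_exp = exp_fit.residual_ss

    y0_start = float(max(y.max(), floor + 1e-6))
    spans = (x.max() - x.min()) or 1.0
    best_ss, best = np.inf, None
    for x50_0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for s_0 in (spans / 10, spans / 4, spans):
            sol = optimize.least_squares(
                lambda p: sigmoid_decay(x, p[0], p[1], p[2], floor) - y,
                [y0_start, float(x50_0), float(s_0)],
                bounds=([floor, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                method="trf",
                max_nfev=200,  # the degenerate exponential limit never terminates
            )
            ss = float(np.sum(sol.fun**2))
            # The logistic family reaches exponential decay only as a
            # boundary limit (y0 -> inf, x50 -> -inf); the optimizer then
            # stops on the iteration cap with a converged SS.  Any finite
            # SS is therefore a usable (possibly degenerate) fit.
            if np.isfinite(ss) and ss < best_ss:
                best_ss, best = ss, sol
    if best is None:
        raise FitFailureError("sigmoid fit produced no finite residual from any start")

    aicc_exp = _aicc(ss_exp, n, 2)
    aicc_sig = _aicc(best_ss, n, 3)
    return ModelComparison(
        ss_exponential=ss_exp,
        ss_sigmoid=best_ss,
        aicc_exponential=aicc_exp,
        aicc_sigmoid=aicc_sig,
        preferred="exponential" if aicc_exp <= aicc_sig else "sigmoid",
    )
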