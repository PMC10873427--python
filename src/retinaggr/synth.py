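"""Seeded synthetic-data generators with known ground truth.

Every analysis stage has a matching generator that emulates the statistical
structure its inputs are assumed to have, records the generating parameters
in a :class:`GroundTruthManifest`, and is an exact right-inverse of its
analysis at zero noise.  Each call owns an explicit ``numpy`` Generator
seeded from its arguments; no global random state is touched, and the same
(seed, parameters) reproduce the output bit for bit.

Default parameter values mirror the study conditions each stage was
designed around: FRET saturation curves over an A:D ladder, outer-nuclear-
layer counts at 0.5/1/3/6 months with n = 6 mice, Naka-Rushton-shaped ERG
amplitude ladders over 0.001-20 cd s/m^2, disjoint disk-shaped particles in
a 317 x 317 um field, correlated Gaussian two-channel pixel fields, and CT
tables built so the noiseless delta-delta-CT returns the true fold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coloc import ChannelImage
from .erg import ErgSweep, biphasic_model, standard_model
from .expression import QpcrSample
from .fields import FIELD_SIZE_UM, FieldImage
from .fret import DONOR_READOUT_NM, EmissionSpectrum, TreatmentSeries, hyperbola
from .onl import TimePoint, one_phase_decay, sigmoid_decay


class SynthesisError(Exception):
    pass


@dataclass(frozen=True)
class GroundTruthManifest:
    """Generating parameters of one synthetic dataset; JSON-serializable."""

    generator: str
    seed: int
    parameters: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(generator=d["generator"], seed=int(d["seed"]), parameters=d["parameters"])


# ---------------------------------------------------------------------------
# FRET saturation datasets
# ---------------------------------------------------------------------------

#: Wavelength grid (nm) of the synthetic donor emission band.
_SPECTRUM_GRID = np.arange(440.0, 541.0, 2.0)
_BAND_SIGMA_NM = 18.0  # emission band width; only the 476 nm read matters

#: Default FRET truth: an aggregation-prone profile (both components present)
#: saturating within the expressed A:D range.
DEFAULT_FRET_TRUTH = {
    "e_max_sensitive": 0.20,
    "ec50_sensitive": 1.5,
    "e_max_insensitive": 0.10,
    "ec50_insensitive": 1.5,
}
DEFAULT_AD_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


def _donor_band(peak_intensity: float) -> EmissionSpectrum:
    profile = np.exp(-0.5 * ((_SPECTRUM_GRID - DONOR_READOUT_NM) / _BAND_SIGMA_NM) ** 2)
    return EmissionSpectrum(
        wavelengths=_SPECTRUM_GRID.copy(), intensities=peak_intensity * profile
    )


def make_fret_dataset(
    truth: Mapping[str, float] | None = None,
    ad_grid: Sequence[float] = DEFAULT_AD_GRID,
    noise_sigma: float = 0.0,
    seed: int = 0,
    f_sds: float = 100.0,
) -> tuple[list[TreatmentSeries], GroundTruthManifest]:
    """Synthesize treatment spectra whose decomposition realizes hyperbolic FRET.

    For each A:D the two component efficiencies are drawn from their
    hyperbolas plus independent Gaussian noise, then donor spectra are built
    so that the 476 nm reads satisfy the decomposition exactly:
    F0 = FSDS*(1 - e_total), FDM = FSDS*(1 - e_insensitive).
    """
    t = dict(DEFAULT_FRET_TRUTH if truth is None else truth)
    for comp in ("sensitive", "insensitive"):
        if not 0 <= t[f"e_max_{comp}"] <= 1:
            raise SynthesisError("Emax values must lie in [0, 1]")
        if t[f"ec50_{comp}"] <= 0:
            raise SynthesisError("EC50 values must be > 0")
    if noise_sigma < 0:
        raise SynthesisError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    series = []
    for i, ad in enumerate(ad_grid):
        e_sens = hyperbola(ad, t["e_max_sensitive"], t["ec50_sensitive"])
        e_ins = hyperbola(ad, t["e_max_insensitive"], t["ec50_insensitive"])
        e_sens = float(e_sens + rng.normal(0.0, noise_sigma))
        e_ins = float(e_ins + rng.normal(0.0, noise_sigma))
        e_total = e_sens + e_ins
        if e_total > 1:
            raise SynthesisError(f"infeasible total efficiency {e_total:.3f} > 1 at A:D {ad}")
        series.append(
            TreatmentSeries(
                spectrum_untreated=_donor_band(f_sds * (1.0 - e_total)),
                spectrum_dm=_donor_band(f_sds * (1.0 - e_ins)),
                spectrum_sds=_donor_band(f_sds),
                acceptor_donor_ratio=float(ad),
                sample_id=f"synthetic-{i}",
            )
        )
    manifest = GroundTruthManifest(
        generator="make_fret_dataset",
        seed=int(seed),
        parameters={**t, "ad_grid": list(map(float, ad_grid)),
                    "noise_sigma": float(noise_sigma), "f_sds": float(f_sds)},
    )
    return series, manifest


# ---------------------------------------------------------------------------
# Outer-nuclear-layer time courses
# ---------------------------------------------------------------------------

#: Study design: 2 weeks (0.5), 1, 3 and 6 months; 6 mice per age; the
#: per-mouse scatter of windowed ONL counts is about one nucleus.
DEFAULT_ONL_AGES = (0.5, 1.0, 3.0, 6.0)
DEFAULT_N_MICE = 6
DEFAULT_ONL_SIGMA = 1.0
DEFAULT_ONL_Y0 = 21.0


def make_onl_series(
    k_per_series: Mapping[str, float],
    y0: float = DEFAULT_ONL_Y0,
    plateau: float = 1.0,
    ages: Sequence[float] = DEFAULT_ONL_AGES,
    n_mice: int = DEFAULT_N_MICE,
    noise_sigma: float = DEFAULT_ONL_SIGMA,
    seed: int = 0,
    region: str = "superior",
) -> tuple[dict[str, dict], GroundTruthManifest]:
    """Per-mouse ONL counts from one-phase decay plus Gaussian noise.

    Returns, per series label, a dict with per-mouse :class:`TimePoint`
    lists (``points``), and the age-wise ``means`` / ``sds`` that would be
    plotted.  Counts are truncated at zero.
    """
    for lab, k in k_per_series.items():
        if k < 0:
            raise SynthesisError(f"rate constant for {lab!r} must be >= 0")
    if noise_sigma < 0:
        raise SynthesisError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for lab, k in k_per_series.items():
        points: list[TimePoint] = []
        means, sds = [], []
        for age in ages:
            mu = float(one_phase_decay(age, y0, plateau, k))
            counts = np.clip(mu + rng.normal(0.0, noise_sigma, size=n_mice), 0.0, None)
            points.extend(
                TimePoint(age=float(age), value=float(c), genotype=lab, region=region)
                for c in counts
            )
            means.append(float(counts.mean()))
            sds.append(float(counts.std(ddof=1)) if n_mice > 1 else 0.0)
        mean_points = [
            TimePoint(age=float(a), value=m, genotype=lab, region=region)
            for a, m in zip(ages, means)
        ]
        out[lab] = {"points": points, "mean_points": mean_points, "means": means, "sds": sds}
    manifest = GroundTruthManifest(
        generator="make_onl_series",
        seed=int(seed),
        parameters={
            "k_per_series": {k: float(v) for k, v in k_per_series.items()},
            "y0": float(y0), "plateau": float(plateau),
            "ages": list(map(float, ages)), "n_mice": int(n_mice),
            "noise_sigma": float(noise_sigma), "region": region,
        },
    )
    return out, manifest


def make_sigmoid_series(
    y0: float = DEFAULT_ONL_Y0,
    x50: float = 2.0,
    s: float = 0.4,
    floor: float = 1.0,
    ages: Sequence[float] = DEFAULT_ONL_AGES,
    n_mice: int = DEFAULT_N_MICE,
    noise_sigma: float = DEFAULT_ONL_SIGMA,
    seed: int = 0,
) -> tuple[list[TimePoint], GroundTruthManifest]:
    """Per-mouse counts from the cumulative-damage (logistic) alternative."""
    rng = np.random.default_rng(seed)
    points = []
    for age in ages:
        mu = float(sigmoid_decay(age, y0, x50, s, floor))
        counts = np.clip(mu + rng.normal(0.0, noise_sigma, size=n_mice), 0.0, None)
        points.extend(TimePoint(age=float(age), value=float(c)) for c in counts)
    manifest = GroundTruthManifest(
        generator="make_sigmoid_series",
        seed=int(seed),
        parameters={"y0": float(y0), "x50": float(x50), "s": float(s), "floor": float(floor),
                    "ages": list(map(float, ages)), "n_mice": int(n_mice),
                    "noise_sigma": float(noise_sigma)},
    )
    return points, manifest


# ---------------------------------------------------------------------------
# Correlated two-channel pixel fields
# ---------------------------------------------------------------------------


def make_coloc_pair(
    rho: float,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    mean: float = 100.0,
    scale: float = 20.0,
) -> tuple[ChannelImage, ChannelImage, GroundTruthManifest]:
    """Two Gaussian pixel fields with population correlation ``rho``.

    b = rho*a + sqrt(1-rho^2)*eps, then both channels are affinely mapped
    to non-negative intensities (Pearson r is affine-invariant, so the
    target correlation is preserved; rho = +/-1 gives r = +/-1 exactly).
    """
    if not -1.0 <= rho <= 1.0:
        raise SynthesisError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    za = rng.standard_normal(size)
    zb = rho * za + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(size)
    a = mean + scale * za
    b = mean + scale * zb
    shift = min(a.min(), b.min())
    if shift < 0:
        a, b = a - shift, b - shift
    pair = (
        ChannelImage(pixels=a, channel_label="receptor_yfp"),
        ChannelImage(pixels=b, channel_label="er_marker"),
    )
    manifest = GroundTruthManifest(
        generator="make_coloc_pair",
        seed=int(seed),
        parameters={"rho": float(rho), "size": list(size),
                    "mean": float(mean), "scale": float(scale)},
    )
    return pair[0], pair[1], manifest


# ---------------------------------------------------------------------------
# ERG amplitude sweeps
# ---------------------------------------------------------------------------

#: Scotopic flash ladder (cd s / m^2), log-spaced over the recorded range.
DEFAULT_ERG_GRID = tuple(float(v) for v in np.logspace(-3, np.log10(20.0), 8))
DEFAULT_ERG_TRUTH = {"model": "standard", "r_max": 400.0, "log_ka": -1.0}


def make_erg_sweep(
    truth: Mapping[str, float] | None = None,
    intensity_grid: Sequence[float] = DEFAULT_ERG_GRID,
    noise_sigma: float = 0.0,
    seed: int = 0,
    wave: str = "a",
    regime: str = "scotopic",
) -> tuple[ErgSweep, GroundTruthManifest]:
    """ERG amplitude ladder from the standard or biphasic model plus noise."""
    t = dict(DEFAULT_ERG_TRUTH if truth is None else truth)
    grid = np.asarray(intensity_grid, float)
    if np.any(grid <= 0) or not np.all(np.diff(grid) > 0):
        raise SynthesisError("intensity grid must be positive and increasing")
    log_i = np.log10(grid)
    if t.get("model", "standard") == "biphasic":
        mu = biphasic_model(log_i, t["r_max"], t["log_ka"], t["log_kb"], t["f"])
    else:
        mu = standard_model(log_i, t["r_max"], t["log_ka"])
    rng = np.random.default_rng(seed)
    amplitudes = mu + rng.normal(0.0, noise_sigma, size=grid.size)
    sweep = ErgSweep(intensities=grid, amplitudes=amplitudes, wave=wave, regime=regime)
    manifest = GroundTruthManifest(
        generator="make_erg_sweep",
        seed=int(seed),
        parameters={**{k: (v if isinstance(v, str) else float(v)) for k, v in t.items()},
                    "intensity_grid": list(map(float, grid)),
                    "noise_sigma": float(noise_sigma), "wave": wave, "regime": regime},
    )
    return sweep, manifest


# ---------------------------------------------------------------------------
# Particle-field images
# ---------------------------------------------------------------------------

DEFAULT_FIELD_SHAPE = (256, 256)


def make_field_image(
    n_particles: int = 15,
    radius_range: tuple[int, int] = (3, 6),
    intensity: float = 200.0,
    background: float = 20.0,
    noise_sigma: float = 4.0,
    shape: tuple[int, int] = DEFAULT_FIELD_SHAPE,
    seed: int = 0,
    stain: str = "TUNEL",
    max_tries: int = 10_000,
) -> tuple[FieldImage, GroundTruthManifest]:
    """Disjoint bright disks on a noisy background, with exact count recorded.

    Disk centers are rejection-sampled so that no two disks touch (>= 2 px
    clearance) and none clips the border; a capacity error is raised if the
    field cannot host ``n_particles`` within ``max_tries`` draws.
    """
    if n_particles < 0:
        raise SynthesisError("n_particles must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    pixel_size = FIELD_SIZE_UM / max(h, w)
    centers: list[tuple[int, int, int]] = []  # (row, col, radius)
    tries = 0
    while len(centers) < n_particles:
        tries += 1
        if tries > max_tries:
            raise SynthesisError(
                f"could not place {n_particles} disjoint disks in {shape} after {max_tries} tries"
            )
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        row = int(rng.integers(r + 1, h - r - 1))
        col = int(rng.integers(r + 1, w - r - 1))
        if all((row - r0) ** 2 + (col - c0) ** 2 >= (r + rr + 2) ** 2 for r0, c0, rr in centers):
            centers.append((row, col, r))
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for row, col, r in centers:
        img[(yy - row) ** 2 + (xx - col) ** 2 <= r**2] = intensity
    img = np.clip(img + rng.normal(0.0, noise_sigma, size=shape), 0.0, None)
    field = FieldImage(
        pixels=img,
        pixel_size=pixel_size,
        stain=stain,
        field_size=(w * pixel_size, h * pixel_size),
    )
    manifest = GroundTruthManifest(
        generator="make_field_image",
        seed=int(seed),
        parameters={
            "n_particles": int(n_particles), "radius_range": list(radius_range),
            "intensity": float(intensity), "background": float(background),
            "noise_sigma": float(noise_sigma), "shape": list(shape),
            "pixel_size": float(pixel_size),
            "centers": [list(c) for c in centers],
        },
    )
    return field, manifest


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------


def make_qpcr_table(
    true_folds: Mapping[str, float],
    reference_gene: str = "18s_rrna",
    ct_noise_sigma: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    ct_reference_level: float = 10.0,
    ct_target_control: float = 20.0,
) -> tuple[dict[str, QpcrSample], QpcrSample, GroundTruthManifest]:
    """CT tables whose noiseless delta-delta-CT reproduces the true folds.

    The control sample sits at a fixed delta-CT; each test sample's target
    CT is shifted by -log2(fold), so that ddCT = -log2(fold) and
    2^-ddCT = fold exactly at zero noise.
    """
    for lab, f in true_folds.items():
        if f <= 0:
            raise SynthesisError(f"fold for {lab!r} must be > 0")
    rng = np.random.default_rng(seed)

    def reps(center: float) -> tuple[float, ...]:
        return tuple(float(c) for c in center + rng.normal(0.0, ct_noise_sigma, size=replicates))

    control = QpcrSample(
        ct_target=reps(ct_target_control),
        ct_reference={reference_gene: reps(ct_reference_level)},
        sample="control",
    )
    samples = {}
    for lab, f in true_folds.items():
        samples[lab] = QpcrSample(
            ct_target=reps(ct_target_control - np.log2(f)),
            ct_reference={reference_gene: reps(ct_reference_level)},
            sample=lab,
        )
    manifest = GroundTruthManifest(
        generator="make_qpcr_table",
        seed=int(seed),
        parameters={
            "true_folds": {k: float(v) for k, v in true_folds.items()},
            "reference_gene": reference_gene,
            "ct_noise_sigma": float(ct_noise_sigma), "replicates": int(replicates),
            "ct_reference_level": float(ct_reference_level),
            "ct_target_control": float(ct_target_control),
        },
    )
    return samples, control, manifest
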