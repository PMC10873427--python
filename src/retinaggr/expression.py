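"""Rhodopsin expression quantification: blot densitometry and comparative-CT qPCR.

Western densitometry sums all bands attributable to rhodopsin in a lane
(monomer, dimer, higher multiples) and divides by the GAPDH loading band;
the normalized value is then expressed relative to the wild-type control
mean.  Transcript levels come from the comparative-CT (delta-delta-CT)
method with amplification efficiency fixed at 2: replicate CTs are averaged
on the cycle scale, delta-CT = CT(target) - CT(reference), and
fold = 2^-(delta-CT(sample) - delta-CT(control)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np


class ExpressionError(Exception):
    pass


@dataclass(frozen=True)
class BlotLane:
    """One Western-blot lane: rhodopsin band intensities plus GAPDH control."""

    rhodopsin_band_intensities: tuple[float, ...]
    gapdh_intensity: float
    sample: str = ""

    def __post_init__(self) -> None:
        bands = tuple(float(b) for b in self.rhodopsin_band_intensities)
        if any(b < 0 for b in bands):
            raise ValueError("band intensities must be >= 0")
        if self.gapdh_intensity <= 0:
            raise ExpressionError("gapdh_intensity must be > 0")
        object.__setattr__(self, "rhodopsin_band_intensities", bands)


@dataclass(frozen=True)
class QpcrSample:
    """Replicate CT values for the target and one or more reference genes."""

    ct_target: tuple[float, ...]
    ct_reference: dict[str, tuple[float, ...]]  # e.g. {"18s_rrna": (...), "gnat1": (...)}
    sample: str = ""

    def __post_init__(self) -> None:
        tgt = tuple(float(c) for c in self.ct_target)
        if len(tgt) < 1:
            raise ValueError("need >= 1 target CT replicate")
        refs = {g: tuple(float(c) for c in cts) for g, cts in self.ct_reference.items()}
        for g, cts in refs.items():
            if len(cts) < 1:
                raise ValueError(f"need >= 1 CT replicate for reference {g!r}")
        for c in tgt + tuple(c for cts in refs.values() for c in cts):
            if not (0 < c < 45):
                raise ValueError("CT values must lie in (0, 45) cycles")
        object.__setattr__(self, "ct_target", tgt)
        object.__setattr__(self, "ct_reference", refs)


@dataclass(frozen=True)
class RelativeQuantity:
    value: float  # fold relative to control
    basis: Literal["densitometry", "ddct"]
    sample: str = ""
    delta_delta_ct: float | None = None  # cycles, ddct basis only


def normalize_lane(lane: BlotLane) -> float:
    """Summed rhodopsin band intensity normalized to the GAPDH band."""
    return float(sum(lane.rhodopsin_band_intensities) / lane.gapdh_intensity)


def relative_to_control(
    values: Sequence[float], control_mean: float, samples: Sequence[str] | None = None
) -> list[RelativeQuantity]:
    """Express normalized densitometry values relative to the control mean."""
    if control_mean <= 0:
        raise ExpressionError("control_mean must be > 0")
    samples = list(samples) if samples is not None else [""] * len(values)
    return [
        RelativeQuantity(value=float(v) / control_mean, basis="densitometry", sample=s)
        for v, s in zip(values, samples)
    ]


def ddct_fold(sample: QpcrSample, control: QpcrSample, reference_gene: str) -> RelativeQuantity:
    """Comparative-CT fold change of the sample relative to the control.

    Replicates are averaged on the CT scale before differencing;
    fold = 2^-(ddCT) with ddCT = dCT(sample) - dCT(control).
    """
    for q, who in ((sample, "sample"), (control, "control")):
        if reference_gene not in q.ct_reference:
            raise ExpressionError(f"{who} lacks reference gene {reference_gene!r}")
    d_sample = float(np.mean(sample.ct_target)) - float(np.mean(sample.ct_reference[reference_gene]))
    d_control = float(np.mean(control.ct_target)) - float(
        np.mean(control.ct_reference[reference_gene])
    )
    ddct = d_sample - d_control
    return RelativeQuantity(
        value=float(2.0 ** (-ddct)),
        basis="ddct",
        sample=sample.sample,
        delta_delta_ct=float(ddct),
    )
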