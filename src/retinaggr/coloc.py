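"""Pearson colocalization of two-channel confocal images.

Mislocalization of mutant receptor is read out by correlating its
fluorescence channel against organelle markers (ER, plasma membrane) pixel
by pixel.  Only the Pearson correlation coefficient r is computed — no
automatic thresholding, Costes randomization or Manders coefficients — and
replicate images are summarized as mean +/- sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

ChannelLabel = Literal["receptor_yfp", "receptor_mtq2", "er_marker", "pm_marker", "nuclei"]


class ColocError(Exception):
    pass


class ZeroVarianceError(ColocError, ValueError):
    """A channel is constant over the analysed region."""


@dataclass(frozen=True)
class ChannelImage:
    """Single-channel grayscale image with physical pixel size."""

    pixels: np.ndarray  # 2-D, finite, >= 0
    pixel_size: float = 1.0  # micrometre / pixel
    channel_label: str = "receptor_yfp"

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixel intensities must be finite")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class ColocResult:
    r: float
    n_pixels: int
    pair: tuple[str, str]
    image_id: str = ""


@dataclass(frozen=True)
class ColocSummary:
    mean_r: float
    sd_r: float
    n: int
    pair: tuple[str, str]
    single_replicate: bool = False  # SD reported as 0 for n = 1, flagged here


def pearson_r(
    a: ChannelImage,
    b: ChannelImage,
    mask: np.ndarray | None = None,
    image_id: str = "",
) -> ColocResult:
    """Sample Pearson correlation of two channels over the (masked) pixels."""
    if a.pixels.shape != b.pixels.shape:
        raise ColocError(f"channel shapes differ: {a.pixels.shape} vs {b.pixels.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.pixels.shape:
            raise ColocError("mask shape must match the channels")
        xa, xb = a.pixels[mask], b.pixels[mask]
    else:
        xa, xb = a.pixels.ravel(), b.pixels.ravel()
    if xa.size < 2:
        raise ColocError("need at least 2 pixels")
    da, db = xa - xa.mean(), xb - xb.mean()
    va, vb = float(da @ da), float(db @ db)
    if va == 0 or vb == 0:
        raise ZeroVarianceError("a channel is constant over the analysed region")
    r = float(da @ db / np.sqrt(va * vb))
    return ColocResult(
        r=float(np.clip(r, -1.0, 1.0)),
        n_pixels=int(xa.size),
        pair=(a.channel_label, b.channel_label),
        image_id=image_id,
    )


def summarize_replicates(results: Sequence[ColocResult]) -> ColocSummary:
    """Mean and sample SD (n-1 denominator) of r over replicate images."""
    if len(results) == 0:
        raise ColocError("no replicates to summarize")
    pairs = {tuple(sorted(res.pair)) for res in results}
    if len(pairs) > 1:
        raise ColocError(f"mixed channel pairs in one summary: {sorted(pairs)}")
    rs = np.array([res.r for res in results], dtype=float)
    n = rs.size
    sd = float(rs.std(ddof=1)) if n > 1 else 0.0
    return ColocSummary(
        mean_r=float(rs.mean()),
        sd_r=sd,
        n=int(n),
        pair=results[0].pair,
        single_replicate=(n == 1),
    )
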