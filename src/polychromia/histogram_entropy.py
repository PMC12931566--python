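"""256-bin ROI histograms, Shannon entropy, and descriptive statistics.

Every metric in this package is a functional of the 256-bin intensity
histogram of the pixels an ROI selects; spatial arrangement never matters.
Entropy is Shannon entropy in bits,

    H = -sum_i p_i log2(p_i),    p_i = counts[i] / n,

with the convention 0·log 0 = 0, so H lies in [0, 8] for 8-bit data.

Descriptive statistics use the population formulas (divide by n, not n-1):
mean, SD, skewness m3/sd^3 and kurtosis m4/sd^4.  Kurtosis defaults to the
raw (non-excess) convention; pass ``kurtosis="excess"`` to subtract 3.
Skewness and kurtosis are undefined (NaN) for constant distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .exceptions import EmptyROIError, InconsistencyError, ShapeMismatchError
from .roi_image import ROIMask

KURTOSIS_CONVENTIONS = ("raw", "excess")

_INTENSITIES = np.arange(256, dtype=float)


@dataclass(frozen=True)
class Histogram256:
    """256-bin intensity counts; the substrate of all statistics."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ShapeMismatchError(f"expected 256 bins, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() < 1:
            raise EmptyROIError("histogram has no counts")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the histogram as a 256-row ``intensity,count`` CSV."""
        lines = ["intensity,count"]
        lines += [f"{v},{c}" for v, c in enumerate(self.counts)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class DescriptiveStats:
    """Histogram summary: mean, population SD, skewness, kurtosis, entropy.

    ``skewness`` and ``kurtosis`` are NaN when ``sd == 0``.
    """

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    entropy_bits: float


def build_histogram(plane: np.ndarray, mask: ROIMask) -> Histogram256:
    """Histogram the masked pixels of an intensity plane."""
    plane = np.asarray(plane)
    if plane.shape != mask.selected.shape:
        raise ShapeMismatchError(
            f"plane shape {plane.shape} != mask shape {mask.selected.shape}"
        )
    values = plane[mask.selected]
    return histogram_from_values(values)


def histogram_from_values(values: np.ndarray) -> Histogram256:
    """Histogram a flat array of intensities in [0, 255]."""
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise EmptyROIError("no pixels to histogram")
    if values.min() < 0 or values.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return Histogram256(np.bincount(values.astype(np.int64), minlength=256))


def shannon_entropy(h: Histogram256) -> float:
    """Shannon entropy of the histogram, in bits; empty bins contribute 0."""
    return float(_scipy_entropy(h.counts, base=2))


def stacked_rgb_histogram(
    hr: Histogram256, hg: Histogram256, hb: Histogram256
) -> Histogram256:
    """Bin-wise sum of three channel histograms (total count 3n).

    This is the alternative "stacked" composite dialect: instead of
    histogramming a per-pixel channel mean, the three channel histograms are
    superimposed.
    """
    if not (hr.n == hg.n == hb.n):
        raise InconsistencyError(
            f"channel histograms disagree in pixel count: {hr.n}, {hg.n}, {hb.n}"
        )
    return Histogram256(hr.counts + hg.counts + hb.counts)


def descriptive_stats(h: Histogram256, kurtosis: str = "raw") -> DescriptiveStats:
    """Mean, population SD, skewness, kurtosis, and entropy of a histogram."""
    if kurtosis not in KURTOSIS_CONVENTIONS:
        raise ValueError(
            f"kurtosis must be one of {KURTOSIS_CONVENTIONS}, got {kurtosis!r}"
        )
    p = h.probabilities
    mean = float(p @ _INTENSITIES)
    dev = _INTENSITIES - mean
    var = float(p @ dev**2)
    sd = math.sqrt(var)
    if sd == 0.0:
        skew = kurt = float("nan")
    else:
        m3 = float(p @ dev**3)
        m4 = float(p @ dev**4)
        skew = m3 / sd**3
        kurt = m4 / sd**4
        if kurtosis == "excess":
            kurt -= 3.0
    return DescriptiveStats(
        mean=mean, sd=sd, skewness=skew, kurtosis=kurt,
        entropy_bits=shannon_entropy(h),
    )
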