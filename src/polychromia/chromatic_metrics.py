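"""Channel-specific chromatic metrics, perilesional normalization, reports.

Global (grayscale or composite-RGB) entropy mostly measures luminance
dispersion.  The metrics here instead compare the three channel histograms
of one ROI:

* channel entropies ``H_R, H_G, H_B`` (bits);
* pairwise divergences ``Δ(R−G) = |H_R − H_G|`` etc.;
* red-channel asymmetry ``Aᴿ = (H_G + H_B)/2 − H_R`` (signed);
* the Polychromia Index ``Iᴾ = (Δ(R−G) + Δ(R−B) + Δ(G−B)) / 3``.

Every metric is then *normalized* by subtracting its value on the
perilesional ROI of the same photograph, removing illumination and device
baselines; normalized values are signed, and the normalized Iᴾ equals the
mean of the signed normalized deltas (subtraction and the mean commute).
A chromatically uniform lesion has normalized metrics near zero; a
variegated lesion retains large positive residuals.

``build_lesion_report`` assembles the full record for one lesion;
``compare_reports`` computes residual differences (and residual %) between
two lesions, e.g. a suspected melanoma against a benign reference.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .exceptions import FormatError
from .histogram_entropy import (
    DescriptiveStats,
    build_histogram,
    descriptive_stats,
    shannon_entropy,
    stacked_rgb_histogram,
)
from .roi_image import (
    ROIMask,
    RGBImage,
    composite_plane,
    to_grayscale_8bit,
    warn_if_overlapping,
)

COMPOSITE_DIALECTS = ("mean", "stacked")

_CHANNELS = ("red", "green", "blue")


@dataclass(frozen=True)
class ChannelEntropies:
    """Shannon entropies of the R, G, B channel histograms of one ROI."""

    h_r: float
    h_g: float
    h_b: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.h_r, self.h_g, self.h_b)


@dataclass(frozen=True)
class DeltaTriple:
    """Pairwise channel-entropy divergences.

    Raw (per-ROI) deltas are absolute values and hence >= 0; after
    perilesional normalization they are signed differences.
    """

    d_rg: float
    d_rb: float
    d_gb: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d_rg, self.d_rb, self.d_gb)


@dataclass(frozen=True)
class ChromaticMetrics:
    """All channel-specific metrics for a single ROI."""

    entropies: ChannelEntropies
    deltas: DeltaTriple
    a_r: float
    i_p: float
    channel_means: tuple[float, float, float]
    channel_sds: tuple[float, float, float]


@dataclass(frozen=True)
class NormalizedMetrics:
    """Lesional − perilesional value of every chromatic metric (signed)."""

    entropies: ChannelEntropies
    deltas: DeltaTriple
    a_r: float
    i_p: float
    channel_means: tuple[float, float, float]
    channel_sds: tuple[float, float, float]


def channel_entropies(img: RGBImage, mask: ROIMask) -> ChannelEntropies:
    """Entropy of each channel's ROI histogram."""
    return ChannelEntropies(
        *(shannon_entropy(build_histogram(img.channel(c), mask)) for c in _CHANNELS)
    )


def pairwise_deltas(e: ChannelEntropies) -> DeltaTriple:
    """Absolute pairwise differences between channel entropies."""
    return DeltaTriple(
        d_rg=abs(e.h_r - e.h_g),
        d_rb=abs(e.h_r - e.h_b),
        d_gb=abs(e.h_g - e.h_b),
    )


def red_asymmetry(e: ChannelEntropies) -> float:
    """Red-channel asymmetry Aᴿ = (H_G + H_B)/2 − H_R (sign preserved)."""
    return (e.h_g + e.h_b) / 2.0 - e.h_r


def polychromia_index(d: DeltaTriple) -> float:
    """Iᴾ: arithmetic mean of the three pairwise deltas.

    Applied to raw (absolute) deltas this is non-negative; applied to
    signed normalized deltas it may be negative.
    """
    return (d.d_rg + d.d_rb + d.d_gb) / 3.0


def roi_chromatic_metrics(img: RGBImage, mask: ROIMask) -> ChromaticMetrics:
    """Compute the full chromatic-metric panel for one ROI."""
    stats = [descriptive_stats(build_histogram(img.channel(c), mask)) for c in _CHANNELS]
    e = ChannelEntropies(*(s.entropy_bits for s in stats))
    d = pairwise_deltas(e)
    return ChromaticMetrics(
        entropies=e,
        deltas=d,
        a_r=red_asymmetry(e),
        i_p=polychromia_index(d),
        channel_means=tuple(s.mean for s in stats),
        channel_sds=tuple(s.sd for s in stats),
    )


def normalize_to_perilesional(
    lesional: ChromaticMetrics, perilesional: ChromaticMetrics
) -> NormalizedMetrics:
    """Element-wise lesional − perilesional for every metric."""
    les_e, per_e = lesional.entropies, perilesional.entropies
    les_d, per_d = lesional.deltas, perilesional.deltas
    return NormalizedMetrics(
        entropies=ChannelEntropies(
            les_e.h_r - per_e.h_r, les_e.h_g - per_e.h_g, les_e.h_b - per_e.h_b
        ),
        deltas=DeltaTriple(
            les_d.d_rg - per_d.d_rg,
            les_d.d_rb - per_d.d_rb,
            les_d.d_gb - per_d.d_gb,
        ),
        a_r=lesional.a_r - perilesional.a_r,
        i_p=lesional.i_p - perilesional.i_p,
        channel_means=tuple(
            l - p for l, p in zip(lesional.channel_means, perilesional.channel_means)
        ),
        channel_sds=tuple(
            l - p for l, p in zip(lesional.channel_sds, perilesional.channel_sds)
        ),
    )


def residual_difference(mel_norm: float, nev_norm: float) -> float:
    """Residual between two lesions' normalized metrics (sign preserved)."""
    return mel_norm - nev_norm


def residual_percent(residual: float, nev_norm: float) -> Optional[float]:
    """Residual as a percentage of the reference lesion's normalized value.

    Returns ``residual / |nev_norm| * 100``, or ``None`` when the reference
    value is zero (the percentage is undefined; percentages are inflated
    whenever the benign reference approaches zero).
    """
    if nev_norm == 0 or math.isnan(nev_norm):
        return None
    return residual / abs(nev_norm) * 100.0


# --------------------------------------------------------------------------
# Lesion report assembly and serialization


@dataclass(frozen=True)
class LesionReport:
    """Full analysis record for one lesion photograph."""

    lesion_id: str
    grayscale_lesional: DescriptiveStats
    grayscale_perilesional: DescriptiveStats
    composite_lesional: DescriptiveStats
    composite_perilesional: DescriptiveStats
    lesional: ChromaticMetrics
    perilesional: ChromaticMetrics
    normalized: NormalizedMetrics
    normalized_grayscale_entropy: float
    normalized_composite_entropy: float
    options: dict = field(default_factory=dict)
    roi_sizes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def stats(s: DescriptiveStats) -> dict:
            return {
                "mean": s.mean,
                "sd": s.sd,
                "skewness": None if math.isnan(s.skewness) else s.skewness,
                "kurtosis": None if math.isnan(s.kurtosis) else s.kurtosis,
                "entropy_bits": s.entropy_bits,
            }

        def panel(m) -> dict:
            return {
                "entropy_red": m.entropies.h_r,
                "entropy_green": m.entropies.h_g,
                "entropy_blue": m.entropies.h_b,
                "delta_rg": m.deltas.d_rg,
                "delta_rb": m.deltas.d_rb,
                "delta_gb": m.deltas.d_gb,
                "a_r": m.a_r,
                "i_p": m.i_p,
                "mean_red": m.channel_means[0],
                "mean_green": m.channel_means[1],
                "mean_blue": m.channel_means[2],
                "sd_red": m.channel_sds[0],
                "sd_green": m.channel_sds[1],
                "sd_blue": m.channel_sds[2],
            }

        return {
            "lesion_id": self.lesion_id,
            "grayscale": {
                "lesional": stats(self.grayscale_lesional),
                "perilesional": stats(self.grayscale_perilesional),
            },
            "composite": {
                "lesional": stats(self.composite_lesional),
                "perilesional": stats(self.composite_perilesional),
            },
            "lesional": panel(self.lesional),
            "perilesional": panel(self.perilesional),
            "normalized": panel(self.normalized),
            "normalized_grayscale_entropy": self.normalized_grayscale_entropy,
            "normalized_composite_entropy": self.normalized_composite_entropy,
            "options": self.options,
            "roi_sizes": self.roi_sizes,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        """Flat CSV: one row per metric, lesional/perilesional/normalized."""
        d = self.to_dict()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "lesional", "perilesional", "normalized"])
            for key in d["lesional"]:
                writer.writerow(
                    [key, d["lesional"][key], d["perilesional"][key], d["normalized"][key]]
                )
            for hist_type in ("grayscale", "composite"):
                writer.writerow(
                    [
                        f"{hist_type}_entropy",
                        d[hist_type]["lesional"]["entropy_bits"],
                        d[hist_type]["perilesional"]["entropy_bits"],
                        d[f"normalized_{hist_type}_entropy"],
                    ]
                )

    @staticmethod
    def metrics_from_dict(d: dict, panel: str) -> dict:
        """Extract one flat metric panel (e.g. ``"normalized"``) from a report dict."""
        return dict(d[panel])


def build_lesion_report(
    img: RGBImage,
    lesional_mask: ROIMask,
    perilesional_mask: ROIMask,
    *,
    lesion_id: str = "lesion",
    gray_mode: str = "unweighted_mean",
    composite_dialect: str = "mean",
    kurtosis: str = "raw",
) -> LesionReport:
    """Run the full pipeline for one image and its two ROIs.

    Deterministic for fixed inputs and options.  Overlapping ROIs are
    tolerated with a logged warning.
    """
    if composite_dialect not in COMPOSITE_DIALECTS:
        raise ValueError(
            f"composite_dialect must be one of {COMPOSITE_DIALECTS}, "
            f"got {composite_dialect!r}"
        )
    warn_if_overlapping(lesional_mask, perilesional_mask)

    gray = to_grayscale_8bit(img, gray_mode)
    gray_stats = {
        m.label: descriptive_stats(build_histogram(gray, m), kurtosis=kurtosis)
        for m in (lesional_mask, perilesional_mask)
    }

    if composite_dialect == "mean":
        comp = composite_plane(img)
        comp_stats = {
            m.label: descriptive_stats(build_histogram(comp, m), kurtosis=kurtosis)
            for m in (lesional_mask, perilesional_mask)
        }
    else:
        comp_stats = {}
        for m in (lesional_mask, perilesional_mask):
            stacked = stacked_rgb_histogram(
                *(build_histogram(img.channel(c), m) for c in _CHANNELS)
            )
            comp_stats[m.label] = descriptive_stats(stacked, kurtosis=kurtosis)

    lesional = roi_chromatic_metrics(img, lesional_mask)
    perilesional = roi_chromatic_metrics(img, perilesional_mask)
    normalized = normalize_to_perilesional(lesional, perilesional)

    return LesionReport(
        lesion_id=lesion_id,
        grayscale_lesional=gray_stats["lesional"],
        grayscale_perilesional=gray_stats["perilesional"],
        composite_lesional=comp_stats["lesional"],
        composite_perilesional=comp_stats["perilesional"],
        lesional=lesional,
        perilesional=perilesional,
        normalized=normalized,
        normalized_grayscale_entropy=(
            gray_stats["lesional"].entropy_bits
            - gray_stats["perilesional"].entropy_bits
        ),
        normalized_composite_entropy=(
            comp_stats["lesional"].entropy_bits
            - comp_stats["perilesional"].entropy_bits
        ),
        options={
            "gray_mode": gray_mode,
            "composite_dialect": composite_dialect,
            "kurtosis": kurtosis,
        },
        roi_sizes={
            "lesional": lesional_mask.n_pixels,
            "perilesional": perilesional_mask.n_pixels,
        },
    )


def compare_reports(report_a: dict, report_b: dict) -> list[dict]:
    """Residual differences (A − B) for every normalized metric.

    Takes two report dicts (as serialized by :meth:`LesionReport.to_json`)
    and returns one row per metric with the two normalized values, the
    residual, and the residual percentage (``None`` when B's value is 0).
    """
    rows = []
    try:
        norm_a = report_a["normalized"]
        norm_b = report_b["normalized"]
    except (KeyError, TypeError) as exc:
        raise FormatError("report JSON lacks a 'normalized' panel") from exc
    if set(norm_a) != set(norm_b):
        raise FormatError("reports have mismatched metric panels")
    for metric in norm_a:
        a, b = norm_a[metric], norm_b[metric]
        res = residual_difference(a, b)
        rows.append(
            {
                "metric": metric,
                "a_normalized": a,
                "b_normalized": b,
                "residual": res,
                "residual_percent": residual_percent(res, b),
            }
        )
    return rows
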