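"""Sky/plant segmentation of hemispherical imagery.

Stored JPEG/PNG intensities are gamma-encoded; they are linearized as
(v/255)**gamma (default gamma 2.2) before thresholding.  The automatic
threshold is the Ridler-Calvard (isodata) fixed point: iterate
t <- (mean below t + mean above t)/2 from the global mean.  Pixels at or
above the threshold are classified as sky (gap), the rest as plant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import HemisphericalImage

__all__ = [
    "SegmentationConfig",
    "BinaryMask",
    "DegenerateHistogramError",
    "to_gray",
    "ridler_calvard_threshold",
    "binarize",
    "segment",
]


class DegenerateHistogramError(ValueError):
    """Raised when automatic thresholding is impossible (constant image)."""


@dataclass
class SegmentationConfig:
    gamma: float = 2.2
    channel_mode: str = "rgb_mean"  # rgb_mean | red | green | blue
    threshold_mode: str = "ridler_calvard"  # ridler_calvard | manual
    manual_threshold: float = 0.5
    max_iterations: int = 100
    tolerance: float = 1e-4  # on the [0, 1] intensity scale

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 <= self.manual_threshold <= 1.0:
            raise ValueError("manual_threshold must be in [0, 1]")
        if self.channel_mode not in ("rgb_mean", "red", "green", "blue"):
            raise ValueError(f"unknown channel_mode {self.channel_mode!r}")
        if self.threshold_mode not in ("ridler_calvard", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass
class BinaryMask:
    """Sky/plant classification on the hemispherical disc.

    ``sky`` is True for gap (sky) pixels; only entries where
    ``outside_mask`` is False are meaningful.
    """

    sky: np.ndarray
    outside_mask: np.ndarray
    threshold: float | None = None

    @property
    def inside_mask(self) -> np.ndarray:
        return ~self.outside_mask

    def gap_fraction(self, region: np.ndarray | None = None) -> float:
        """Fraction of sky pixels over a region (default: whole disc)."""
        m = self.inside_mask if region is None else (region & self.inside_mask)
        n = int(m.sum())
        if n == 0:
            raise ValueError("empty region")
        return float(self.sky[m].sum()) / n


_CHANNEL = {"red": 0, "green": 1, "blue": 2}


def to_gray(image: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Linearize 0-255 intensities to [0, 1] and collapse channels.

    Each channel is linearized as (v/255)**gamma; rgb_mean averages the
    three linearized channels with equal weight.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        if cfg.channel_mode != "rgb_mean":
            raise ValueError("single-channel input requires channel_mode rgb_mean")
        return (img / 255.0) ** cfg.gamma
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected (H, W) or (H, W, 3) raster")
    lin = (img / 255.0) ** cfg.gamma
    if cfg.channel_mode == "rgb_mean":
        return lin.mean(axis=2)
    return lin[..., _CHANNEL[cfg.channel_mode]]


def ridler_calvard_threshold(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    cfg: SegmentationConfig | None = None,
) -> float:
    """Isodata fixed point t = (mean(gray < t) + mean(gray >= t)) / 2.

    Starts at the global mean and iterates until the change is below
    ``cfg.tolerance`` or ``cfg.max_iterations`` is reached.  If one side of
    the split is empty at some iterate, that side's mean is taken as the
    current threshold.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    gray = np.asarray(gray, dtype=float)
    vals = gray if mask is None else gray[np.asarray(mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size == 0:
        raise ValueError("no pixels to threshold")
    if np.ptp(vals) == 0:
        raise DegenerateHistogramError("degenerate histogram: constant image")

    t = float(vals.mean())
    for _ in range(cfg.max_iterations):
        below = vals < t
        m_lo = vals[below].mean() if below.any() else t
        m_hi = vals[~below].mean() if not below.all() else t
        t_new = 0.5 * (m_lo + m_hi)
        if abs(t_new - t) < cfg.tolerance:
            return float(t_new)
        t = float(t_new)
    return float(t)


def binarize(
    gray: np.ndarray, threshold: float, outside_mask: np.ndarray | None = None
) -> BinaryMask:
    """Classify pixels as sky where gray >= threshold."""
    gray = np.asarray(gray, dtype=float)
    if outside_mask is None:
        outside_mask = np.zeros(gray.shape, dtype=bool)
    sky = gray >= threshold
    return BinaryMask(sky=sky, outside_mask=np.asarray(outside_mask, dtype=bool),
                      threshold=float(threshold))


def segment(img: HemisphericalImage, cfg: SegmentationConfig | None = None) -> BinaryMask:
    """Full segmentation chain on a hemispherical image.

    Linearizes, picks the threshold per ``cfg.threshold_mode`` over inside
    pixels only, and binarizes.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    gray = to_gray(img.pixels, cfg)
    if cfg.threshold_mode == "manual":
        t = cfg.manual_threshold
    else:
        t = ridler_calvard_threshold(gray, img.inside_mask, cfg)
    return binarize(gray, t, img.outside_mask)
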