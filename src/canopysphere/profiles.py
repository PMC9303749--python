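"""Vertical PAI profiles and plant area density per layer.

Repeated PAI measurements at each flight height are averaged; plant area
density for the layer between consecutive heights z_i < z_j is the finite
difference

    PAD = (PAI_i - PAI_j) / (z_j - z_i)   [m^2 m^-3]

so that, without clipping, sum(PAD_l * dz_l) telescopes exactly to
PAI(lowest) - PAI(highest).  The per-height replicate spread is reported as
(max - min)/mean * 100 (%), the statistic used to judge measurement
repeatability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeightMeasurement", "HeightProfile", "aggregate", "pad_profile"]


@dataclass
class HeightMeasurement:
    """Replicate PAI values taken at one flight height (typically 3)."""

    height: float
    replicate_pais: list[float]

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("height must be >= 0")
        if len(self.replicate_pais) == 0:
            raise ValueError("at least one replicate required")


@dataclass
class HeightProfile:
    heights: np.ndarray
    pai: np.ndarray
    deviation_pct: np.ndarray | None = None
    pad: np.ndarray | None = None
    layer_midpoints: np.ndarray | None = None
    clipped: bool = False
    metadata: dict = field(default_factory=dict)


def aggregate(
    measurements: list[HeightMeasurement],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort by height and reduce replicates to (mean PAI, deviation %).

    Deviation per height = (max - min)/mean * 100.  Duplicate heights are
    merged (replicates pooled) with a warning.
    """
    if not measurements:
        raise ValueError("no measurements")
    pooled: dict[float, list[float]] = {}
    for m in measurements:
        key = float(m.height)
        if key in pooled:
            warnings.warn(f"duplicate height {key} m: replicates merged")
        pooled.setdefault(key, []).extend(float(v) for v in m.replicate_pais)
    heights = np.array(sorted(pooled))
    pai = np.empty_like(heights)
    dev = np.empty_like(heights)
    for i, h in enumerate(heights):
        reps = np.array(pooled[float(h)])
        pai[i] = reps.mean()
        if reps.size == 1 or pai[i] == 0:
            dev[i] = 0.0 if np.ptp(reps) == 0 else np.inf
        else:
            dev[i] = np.ptp(reps) / pai[i] * 100.0
    return heights, pai, dev


def pad_profile(
    heights: np.ndarray, pai: np.ndarray, clip_negative: bool = False
) -> HeightProfile:
    """Finite-difference PAD for each layer between consecutive heights.

    With ``clip_negative`` the (physically impossible but observationally
    common) negative layers are floored at 0, breaking the telescoping
    identity; the flag is recorded on the result.
    """
    heights = np.asarray(heights, dtype=float)
    pai = np.asarray(pai, dtype=float)
    if heights.ndim != 1 or heights.shape != pai.shape:
        raise ValueError("heights and pai must be equal-length 1-D")
    if heights.size < 2:
        raise ValueError("need at least two heights for a PAD profile")
    if np.any(np.diff(heights) <= 0):
        raise ValueError("heights must be strictly increasing")
    dz = np.diff(heights)
    pad = (pai[:-1] - pai[1:]) / dz
    clipped = False
    if clip_negative:
        clipped = bool(np.any(pad < 0))
        pad = np.maximum(pad, 0.0)
    return HeightProfile(
        heights=heights,
        pai=pai,
        pad=pad,
        layer_midpoints=0.5 * (heights[:-1] + heights[1:]),
        clipped=clipped,
        metadata={"clip_negative": clip_negative},
    )
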