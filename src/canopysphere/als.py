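"""Airborne-laser-scanning transmission proxy and extinction fitting.

A height-normalized point cloud clipped to a vertical cylinder around the
profile location yields a canopy transmission estimate at each level z:

    T(z) = 1 - N_c(z) / N_t

where N_c counts returns above z and N_t all returns including ground
returns (points below the ground cut, 1.5 m by default).  Transmission
converts to a PAI proxy through Beer's law, PAI(z) = -ln T(z) / k, with the
extinction coefficient k fitted by ordinary least squares through the
origin against an independent PAI profile measured in the same canopy.
PAD per layer follows by finite differencing, exactly as for the imaging
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import pad_profile

__all__ = [
    "PointCloud",
    "TransmissionProfile",
    "ALSProfile",
    "cylinder_filter",
    "transmission_profile",
    "fit_extinction",
    "als_pai_pad",
    "compare_pad",
]


@dataclass
class PointCloud:
    """(N, 3) array of x, y, z in meters; z is height above ground."""

    points: np.ndarray
    source: str = "xyz"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates in point cloud")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class TransmissionProfile:
    levels: np.ndarray          # ascending heights (m)
    T: np.ndarray               # transmission per level, in [0, 1]
    n_above: np.ndarray         # N_c per level
    n_total: int                # N_t (canopy + ground returns)
    ground_cut: float = 1.5
    radius: float | None = None

    @property
    def layer_width(self) -> float:
        return float(self.levels[1] - self.levels[0]) if len(self.levels) > 1 else np.inf


@dataclass
class ALSProfile:
    k: float
    levels: np.ndarray
    pai: np.ndarray             # proxy PAI per level (m^2 m^-2)
    pad: np.ndarray             # per layer between consecutive levels
    layer_midpoints: np.ndarray


def cylinder_filter(
    cloud: PointCloud, center: tuple[float, float], radius: float = 10.0
) -> PointCloud:
    """Keep points within horizontal distance <= radius of center (closed)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    dx = cloud.points[:, 0] - center[0]
    dy = cloud.points[:, 1] - center[1]
    keep = np.hypot(dx, dy) <= radius
    if not keep.any():
        raise ValueError("no points in cylinder")
    return PointCloud(points=cloud.points[keep], source=cloud.source)


def transmission_profile(
    cloud: PointCloud, n_levels: int = 50, ground_cut: float = 1.5
) -> TransmissionProfile:
    """T(z) = 1 - N_c(z)/N_t at n_levels equally spaced levels.

    Levels span [ground_cut, max z].  Points below the ground cut count as
    ground returns: they enter N_t but never N_c.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    z = cloud.z
    canopy = z >= ground_cut
    if not canopy.any():
        raise ValueError("no canopy returns above the ground cut")
    z_top = float(z.max())
    levels = np.linspace(ground_cut, z_top, n_levels)
    n_total = len(cloud)
    n_above = np.array([(z > lv).sum() for lv in levels], dtype=np.int64)
    T = 1.0 - n_above / n_total
    return TransmissionProfile(
        levels=levels, T=T, n_above=n_above, n_total=n_total, ground_cut=ground_cut
    )


def fit_extinction(
    T_at_heights: list[tuple[float, float]],
    uas_pai_at_heights: list[tuple[float, float]],
    max_height_gap: float | None = None,
    with_intercept: bool = False,
) -> tuple[float, dict]:
    """OLS fit of -ln T on PAI; slope is the extinction coefficient k.

    Each PAI measurement height is matched to the nearest transmission
    level; pairs farther apart than ``max_height_gap`` (default: the level
    spacing) are dropped, as are saturated pairs with T = 0.  Pairs with
    T = 1 (y = 0) are kept: the through-origin model passes through them
    naturally.  Default regression is through the origin, since Beer's law
    forces PAI = 0 at T = 1; ``with_intercept`` enables an intercept
    variant.
    """
    T_arr = np.asarray(T_at_heights, dtype=float)
    pai_arr = np.asarray(uas_pai_at_heights, dtype=float)
    if T_arr.ndim != 2 or pai_arr.ndim != 2:
        raise ValueError("expected lists of (height, value) pairs")
    spacing = np.min(np.diff(np.sort(T_arr[:, 0]))) if len(T_arr) > 1 else np.inf
    if max_height_gap is None:
        max_height_gap = spacing

    xs, ys = [], []
    for h, pai in pai_arr:
        j = int(np.argmin(np.abs(T_arr[:, 0] - h)))
        if abs(T_arr[j, 0] - h) > max_height_gap:
            continue
        T = T_arr[j, 1]
        if T <= 0.0:
            warnings.warn(f"dropping saturated level at height {h} m (T = 0)")
            continue
        if T > 1.0:
            raise ValueError("transmission above 1")
        xs.append(pai)
        ys.append(-np.log(T))
    if len(xs) < 2:
        raise ValueError("fewer than 2 usable (T, PAI) pairs")
    x = np.array(xs)
    y = np.array(ys)
    if with_intercept:
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        k, intercept = float(coef[0]), float(coef[1])
        resid = y - A @ coef
    else:
        k = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
        resid = y - k * x
    if k <= 0:
        raise ValueError("fitted extinction coefficient is not positive")
    diagnostics = {
        "n_pairs": len(x),
        "intercept": intercept,
        "rss": float(np.sum(resid**2)),
        "x": x,
        "y": y,
    }
    return k, diagnostics


def als_pai_pad(tp: TransmissionProfile, k: float) -> ALSProfile:
    """Beer's-law inversion PAI(z) = -ln T(z)/k plus layer PAD differences.

    T is floored at 1/N_t so the log never diverges at a fully occluded
    level.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    T = np.maximum(tp.T, 1.0 / tp.n_total)
    pai = -np.log(T) / k
    hp = pad_profile(tp.levels, pai)
    return ALSProfile(
        k=float(k),
        levels=tp.levels,
        pai=pai,
        pad=hp.pad,
        layer_midpoints=hp.layer_midpoints,
    )


def compare_pad(uas, als: ALSProfile) -> tuple[float, float]:
    """RSS between PAD profiles after averaging ALS layers into UAS layers.

    The finer ALS layers are mean-aggregated within each UAS layer
    (matching by layer midpoint), then RSS = sum((PAD_uas - PAD_als)**2).
    Returns (rss, height of the maximum absolute residual).
    """
    if uas.pad is None:
        raise ValueError("UAS profile has no PAD layers")
    uas_edges = uas.heights
    rss = 0.0
    max_resid = -1.0
    max_height = np.nan
    n_overlap = 0
    for l in range(len(uas.pad)):
        lo, hi = uas_edges[l], uas_edges[l + 1]
        in_layer = (als.layer_midpoints >= lo) & (als.layer_midpoints < hi)
        if not in_layer.any():
            continue
        n_overlap += 1
        resid = uas.pad[l] - float(als.pad[in_layer].mean())
        rss += resid**2
        if abs(resid) > max_resid:
            max_resid = abs(resid)
            max_height = float(uas.layer_midpoints[l])
    if n_overlap == 0:
        raise ValueError("no overlapping layers between profiles")
    return float(rss), max_height
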