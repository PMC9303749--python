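"""Synthetic canopies, panoramas and point clouds with closed-form truth.

A canopy is modelled as horizontally homogeneous slabs, each with a uniform
plant area density, under Beer's-law attenuation with projection
coefficient g (0.5 for a spherical leaf angle distribution).  The gap
fraction seen from a camera at height h at zenith angle theta is then
exactly

    P(theta) = exp(-g * PAI_above(h) / cos(theta))

which makes every stage of the imaging chain testable: panoramas are
rendered by per-pixel Bernoulli dithering of P(theta(row)) so the expected
per-annulus gap fraction after reprojection is known in closed form, and
LiDAR pulses descend vertically with survival exp(-k * PAI_above(z)), so
ground-return fractions and transmission profiles have binomial sampling
errors around known expectations.  Crown geometry, multiple echoes and
sensor noise are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import gap_fractions, miller_pai
from .profiles import HeightMeasurement
from .projection import AnnulusSet, LensFunction, Panorama, reproject_to_hemisphere
from .segmentation import (
    DegenerateHistogramError,
    SegmentationConfig,
    segment,
)
from .als import PointCloud

__all__ = [
    "SlabCanopy",
    "RenderConfig",
    "true_gap",
    "render_panorama",
    "simulate_point_cloud",
    "simulate_uas_profile",
]


@dataclass
class SlabCanopy:
    """Horizontally uniform canopy as (z_lo, z_hi, pad) slabs."""

    layers: list[tuple[float, float, float]]
    g: float = 0.5  # spherical leaf angle distribution

    def __post_init__(self) -> None:
        if not 0 < self.g <= 1:
            raise ValueError("g must be in (0, 1]")
        spans = []
        for z_lo, z_hi, pad in self.layers:
            if z_hi <= z_lo:
                raise ValueError("layer must have z_hi > z_lo")
            if pad < 0:
                raise ValueError("plant area density must be >= 0")
            spans.append((z_lo, z_hi))
        for (a0, a1), (b0, b1) in zip(sorted(spans), sorted(spans)[1:]):
            if b0 < a1:
                raise ValueError("layers must not overlap")

    def pai_above(self, z: float) -> float:
        """Plant area per unit ground area above height z (m² m⁻²)."""
        total = 0.0
        for z_lo, z_hi, pad in self.layers:
            overlap = max(0.0, z_hi - max(z_lo, z))
            total += pad * overlap
        return total

    @property
    def top(self) -> float:
        return max((z_hi for _, z_hi, _ in self.layers), default=0.0)


@dataclass
class RenderConfig:
    camera_height: float = 0.0
    pano_height: int = 1000  # panorama rows; width is always 2x
    seed: int = 0
    sky_level: float = 230.0
    plant_level: float = 20.0
    noise_sd: float = 0.0    # optional Gaussian intensity noise

    def __post_init__(self) -> None:
        if self.camera_height < 0:
            raise ValueError("camera_height must be >= 0")
        if self.sky_level <= self.plant_level:
            raise ValueError("sky_level must exceed plant_level")


def true_gap(canopy: SlabCanopy, camera_height: float, theta_deg) -> np.ndarray:
    """Closed-form gap fraction P(theta) = exp(-g * PAI_above / cos theta)."""
    theta = np.asarray(theta_deg, dtype=float)
    if np.any((theta < 0) | (theta >= 90)):
        raise ValueError("theta must be in [0, 90) degrees")
    pai = canopy.pai_above(camera_height)
    return np.exp(-canopy.g * pai / np.cos(np.deg2rad(theta)))


def render_panorama(canopy: SlabCanopy, cfg: RenderConfig) -> Panorama:
    """Equirectangular Bernoulli rendering of the canopy.

    Each upper-hemisphere pixel is sky with probability P(theta(row)),
    independently; the lower hemisphere is solid plant.  The expected gap
    fraction of any zenith band therefore equals the mean of P over the
    band, which is what the imaging chain should recover.
    """
    h = cfg.pano_height
    w = 2 * h
    rng = np.random.default_rng(cfg.seed)
    img = np.full((h, w, 3), cfg.plant_level, dtype=float)
    upper = h // 2
    # theta at each upper-hemisphere row center
    theta = (np.arange(upper) + 0.5) / h * 180.0
    theta = np.minimum(theta, 90.0 - 1e-9)
    P = true_gap(canopy, cfg.camera_height, theta)
    sky = rng.random((upper, w)) < P[:, None]
    img[:upper][sky] = cfg.sky_level
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, img.shape)
        img = np.clip(img, 0.0, 255.0)
    return Panorama(pixels=img)


def simulate_point_cloud(
    canopy: SlabCanopy,
    k_true: float,
    n_pulses: int,
    plot_radius: float = 10.0,
    seed: int = 0,
    ground_z: float = 0.5,
) -> PointCloud:
    """Vertically descending pulses attenuated by the slab canopy.

    Each pulse starts above the canopy at a uniform random (x, y) in the
    disc of ``plot_radius``.  Survival to height z is
    exp(-k_true * PAI_above(z)); the interception height is found by
    inverting that survival curve for a uniform deviate.  Pulses that
    survive the whole canopy become ground returns at z = ``ground_z``
    (below the 1.5 m ground cut).
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    rng = np.random.default_rng(seed)
    # uniform in the disc
    r = plot_radius * np.sqrt(rng.random(n_pulses))
    phi = rng.random(n_pulses) * 2 * np.pi
    x = r * np.cos(phi)
    y = r * np.sin(phi)

    u = rng.random(n_pulses)
    tau_target = -np.log(u) / k_true  # PAI_above at interception
    z = _invert_pai_above(canopy, tau_target)
    z = np.where(np.isnan(z), ground_z, z)  # survived: ground return
    return PointCloud(points=np.column_stack([x, y, z]), source="synthetic")


def _invert_pai_above(canopy: SlabCanopy, target: np.ndarray) -> np.ndarray:
    """Height z with PAI_above(z) == target; NaN where target > total PAI.

    PAI_above is piecewise linear and non-increasing in z, so the inverse
    is evaluated per slab from the top down.
    """
    out = np.full(target.shape, np.nan)
    total = canopy.pai_above(0.0)
    reachable = target <= total
    layers = sorted(canopy.layers, key=lambda l: -l[1])  # top down
    cum_top = 0.0  # PAI above the top of the current layer
    for z_lo, z_hi, pad in layers:
        cum_bot = cum_top + pad * (z_hi - z_lo)
        sel = reachable & (target >= cum_top) & (target <= cum_bot) & np.isnan(out)
        if pad > 0:
            out[sel] = z_hi - (target[sel] - cum_top) / pad
        else:
            out[sel] = z_hi
        cum_top = cum_bot
    return out


def simulate_uas_profile(
    canopy: SlabCanopy,
    heights,
    cfg: RenderConfig | None = None,
    n_replicates: int = 3,
    out_size: int = 2000,
    annuli: AnnulusSet | None = None,
    seg_cfg: SegmentationConfig | None = None,
    interpolation: str = "nearest",
) -> list[HeightMeasurement]:
    """Run the full imaging chain at each flight height.

    For each height, ``n_replicates`` panoramas are rendered with distinct
    sub-seeds and pushed through reprojection, segmentation, gap fractions
    and the Miller inversion.  When a rendered hemisphere is uniform (e.g.
    the camera is above the whole canopy) the automatic threshold has no
    histogram to split, so segmentation falls back to the midpoint between
    the configured plant and sky levels.

    Reprojection defaults to nearest-neighbor here, unlike the bilinear
    default for photographs: the Bernoulli dithering has no spatial
    coherence, and thresholding a locally averaged Bernoulli field returns
    the majority class rather than the mean, biasing gap fractions.
    Nearest sampling preserves the per-pixel statistics and hence the
    closed-form expectations.
    """
    if cfg is None:
        cfg = RenderConfig()
    if annuli is None:
        annuli = AnnulusSet()
    if seg_cfg is None:
        seg_cfg = SegmentationConfig()
    lens = LensFunction()
    # midpoint of the linearized plant/sky levels, used when thresholding
    # degenerates on a uniform image
    lo = (cfg.plant_level / 255.0) ** seg_cfg.gamma
    hi = (cfg.sky_level / 255.0) ** seg_cfg.gamma
    fallback = SegmentationConfig(
        gamma=seg_cfg.gamma,
        channel_mode=seg_cfg.channel_mode,
        threshold_mode="manual",
        manual_threshold=0.5 * (lo + hi),
    )

    ss = np.random.SeedSequence(cfg.seed)
    measurements = []
    for i, h in enumerate(heights):
        reps = []
        for j in range(n_replicates):
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            rc = RenderConfig(
                camera_height=float(h),
                pano_height=cfg.pano_height,
                seed=sub_seed,
                sky_level=cfg.sky_level,
                plant_level=cfg.plant_level,
                noise_sd=cfg.noise_sd,
            )
            pano = render_panorama(canopy, rc)
            hemi = reproject_to_hemisphere(
                pano, out_size=out_size, lens=lens, interpolation=interpolation
            )
            try:
                mask = segment(hemi, seg_cfg)
            except DegenerateHistogramError:
                mask = segment(hemi, fallback)
            gp = gap_fractions(mask, annuli, lens)
            reps.append(miller_pai(gp).pai_raw)
        measurements.append(HeightMeasurement(height=float(h), replicate_pais=reps))
    return measurements
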