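"""Equirectangular panorama -> upward-looking hemispherical image.

A levelled spherical panorama stores azimuth on the x-axis and zenith angle
on the y-axis (row 0 = zenith, bottom row = nadir), so the upper half of the
raster is the upper hemisphere.  Reprojection resamples that half onto a
polar (fisheye-equivalent) disc in which the radial position of a pixel
encodes its zenith angle through a lens function r/R = f(theta/theta_max).
The disc is then partitioned into concentric zenith-angle annuli for
gap-fraction statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Panorama",
    "LensFunction",
    "HemisphericalImage",
    "AnnulusSet",
    "reproject_to_hemisphere",
    "annulus_masks",
]


@dataclass
class Panorama:
    """Full-sphere equirectangular raster (width == 2 * height).

    ``pixels`` is (H, W) grayscale or (H, W, 3) RGB with intensities in
    [0, 255].  ``azimuth_origin`` records the compass azimuth of column 0
    (metadata only; the reprojection takes an explicit offset).
    """

    pixels: np.ndarray
    azimuth_origin: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("panorama must be 2-D or 2-D x 3-channel")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("color panorama must have exactly 3 channels")
        if self.width != 2 * self.height:
            raise ValueError(
                f"equirectangular panorama requires width == 2 * height, "
                f"got {self.width} x {self.height}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LensFunction:
    """Radial lens model mapping theta/theta_max -> r/R on [0, 1].

    ``kind`` is "linear" (equidistant: r/R = theta/theta_max, the model used
    for the drone sensor) or "polynomial" with ``coefficients`` c1..cn such
    that r/R = sum_i c_i * t**i, t = theta/theta_max.  The mapping must be
    strictly increasing with f(0) = 0 and f(1) = 1.
    """

    kind: str = "linear"
    coefficients: tuple[float, ...] = ()
    theta_max: float = 90.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial"):
            raise ValueError(f"unknown lens kind {self.kind!r}")
        if self.kind == "polynomial":
            self.coefficients = tuple(float(c) for c in self.coefficients)
            if not self.coefficients:
                raise ValueError("polynomial lens needs coefficients")
            if abs(self.forward(self.theta_max) - 1.0) > 1e-6:
                raise ValueError("lens must satisfy f(theta_max) = 1")
            t = np.linspace(0.0, 1.0, 1001)
            r = self._poly(t)
            if np.any(np.diff(r) <= 0):
                raise ValueError("lens function must be strictly increasing")
        if not 0 < self.theta_max <= 90:
            raise ValueError("theta_max must be in (0, 90] degrees")

    def _poly(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for i, c in enumerate(self.coefficients, start=1):
            out = out + c * t**i
        return out

    def forward(self, theta_deg):
        """r/R for zenith angle(s) in degrees."""
        t = np.asarray(theta_deg, dtype=float) / self.theta_max
        if self.kind == "linear":
            return t
        return self._poly(t)

    def inverse(self, r_norm):
        """Zenith angle in degrees for normalized radius r/R in [0, 1].

        Polynomial lenses are inverted by monotone bisection to 1e-10
        relative tolerance.
        """
        r = np.asarray(r_norm, dtype=float)
        if self.kind == "linear":
            return r * self.theta_max
        lo = np.zeros_like(r)
        hi = np.ones_like(r)
        for _ in range(60):  # 2**-60 << 1e-10
            mid = 0.5 * (lo + hi)
            below = self._poly(mid) < r
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi) * self.theta_max


@dataclass
class HemisphericalImage:
    """Square polar raster of the upper hemisphere.

    Pixels beyond ``radius`` from the center are outside the image circle;
    they carry a fill value and are flagged in ``outside_mask``.  All
    statistics must respect the mask, never the fill value.
    """

    pixels: np.ndarray
    lens: LensFunction
    outside_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    azimuth_offset: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        h, w = self.pixels.shape[:2]
        if h != w:
            raise ValueError("hemispherical image must be square")
        if h % 2 != 0:
            raise ValueError("hemispherical image size must be even")
        if self.outside_mask is None:
            self.outside_mask = ~_inside_circle(h)
        self.outside_mask = np.asarray(self.outside_mask, dtype=bool)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def radius(self) -> float:
        return self.size / 2.0

    @property
    def inside_mask(self) -> np.ndarray:
        return ~self.outside_mask

    def radial_theta(self) -> np.ndarray:
        """Per-pixel zenith angle (degrees); NaN outside the circle."""
        r = _radial_norm(self.size)
        theta = self.lens.inverse(np.clip(r, 0.0, 1.0))
        return np.where(self.outside_mask, np.nan, theta)


@dataclass
class AnnulusSet:
    """Contiguous zenith-angle rings starting at theta = 0."""

    n_annuli: int = 5
    width_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.n_annuli < 1:
            raise ValueError("need at least one annulus")
        if self.n_annuli * self.width_deg > 90 + 1e-9:
            raise ValueError("annuli must fit within the hemisphere")

    @property
    def boundaries(self) -> list[tuple[float, float]]:
        return [
            (i * self.width_deg, (i + 1) * self.width_deg)
            for i in range(self.n_annuli)
        ]

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_annuli) + 0.5) * self.width_deg

    @property
    def theta_max(self) -> float:
        return self.n_annuli * self.width_deg


def _radial_norm(size: int) -> np.ndarray:
    """Distance of each pixel center from the image center, in units of R."""
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return np.hypot(x - c, y - c) / (size / 2.0)


def _inside_circle(size: int) -> np.ndarray:
    return _radial_norm(size) <= 1.0


def reproject_to_hemisphere(
    pano: Panorama,
    out_size: int = 4000,
    lens: LensFunction | None = None,
    interpolation: str = "bilinear",
    azimuth_offset: float = 0.0,
    fill_value: float = 0.0,
) -> HemisphericalImage:
    """Resample the panorama's upper hemisphere onto a polar disc.

    For each inside output pixel at normalized radius r and image azimuth
    phi (up = north, clockwise = east): theta = lens.inverse(r), the source
    column is ((phi + azimuth_offset) mod 360)/360 * width and the source
    row is theta/180 * height.  Because theta <= theta_max <= 90 only the
    upper hemisphere is ever sampled.  Pixels outside the disc receive
    ``fill_value`` and are flagged in the output mask.
    """
    if lens is None:
        lens = LensFunction()
    if out_size < 2:
        raise ValueError("out_size must be >= 2")
    if out_size % 2 != 0:
        raise ValueError("out_size must be even")
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    size = int(out_size)
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    dx = x - c          # east component
    dy = c - y          # north component (row index grows downward)
    r = np.hypot(dx, dy) / (size / 2.0)
    inside = r <= 1.0

    theta = lens.inverse(np.clip(r, 0.0, 1.0))          # degrees
    phi = np.degrees(np.arctan2(dx, dy))                # from north, CW=east
    phi = np.mod(phi + azimuth_offset, 360.0)

    h, w = pano.height, pano.width
    src_col = phi / 360.0 * w
    src_row = theta / 180.0 * h

    # theta <= 90 means only rows [0, h/2) -- the upper hemisphere -- may
    # ever be touched, including by the interpolation stencil at theta = 90.
    upper_last = h // 2 - 1
    if interpolation == "nearest":
        cols = np.mod(np.floor(src_col).astype(np.int64), w)
        rows = np.clip(np.floor(src_row).astype(np.int64), 0, upper_last)
        out = pano.pixels[rows, cols].astype(float)
    else:
        out = _bilinear_sample(pano.pixels, src_row, src_col, row_max=upper_last)

    if out.ndim == 3:
        out[~inside, :] = fill_value
    else:
        out[~inside] = fill_value
    return HemisphericalImage(
        pixels=out, lens=lens, outside_mask=~inside, azimuth_offset=azimuth_offset
    )


def _bilinear_sample(
    img: np.ndarray, rows: np.ndarray, cols: np.ndarray, row_max: int | None = None
) -> np.ndarray:
    """Bilinear gather with azimuthal wrap in columns, clamped rows."""
    h, w = img.shape[:2]
    if row_max is None:
        row_max = h - 1
    # Sample at pixel centers: position p falls between centers p-0.5.
    rf = np.clip(rows - 0.5, 0.0, float(row_max))
    cf = cols - 0.5
    r0 = np.floor(rf).astype(np.int64)
    c0 = np.floor(cf).astype(np.int64)
    wr = rf - r0
    wc = cf - c0
    r1 = np.minimum(r0 + 1, row_max)
    c0m = np.mod(c0, w)
    c1m = np.mod(c0 + 1, w)
    if img.ndim == 3:
        wr = wr[..., None]
        wc = wc[..., None]
    p = img.astype(float)
    top = p[r0, c0m] * (1 - wc) + p[r0, c1m] * wc
    bot = p[r1, c0m] * (1 - wc) + p[r1, c1m] * wc
    return top * (1 - wr) + bot * wr


def annulus_masks(img: HemisphericalImage, annuli: AnnulusSet) -> list[np.ndarray]:
    """Boolean raster per annulus; each inside pixel lands in at most one.

    Pixels with zenith angle beyond the last boundary stay unassigned
    (they are imaged but excluded from the gap-fraction statistics).
    """
    if annuli.theta_max > img.lens.theta_max + 1e-9:
        raise ValueError("annuli extend beyond the lens field of view")
    theta = img.radial_theta()
    masks = []
    for lo, hi in annuli.boundaries:
        m = img.inside_mask & (theta >= lo) & (theta < hi)
        masks.append(m)
    return masks
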