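"""Gap fractions and Miller inversion to plant area index.

The gap-fraction model P(theta) = exp(-G(theta) * Omega(theta) * PAI /
cos(theta)) links canopy transmission at zenith angle theta to plant area
index.  Miller's theorem inverts it without knowing the leaf projection
function G:

    PAI = 2 * integral_0^{pi/2} -ln P(theta) cos(theta) sin(theta) dtheta

Here the integral is discretized over concentric annuli at their zenith
midpoints.  Because the outermost 75-90 degree band is not measured with
the default five 15-degree annuli, the truncated integral is rescaled by
1/(1 - cos theta_max), which is exact whenever -ln P is proportional to
1/cos(theta) (a spherical leaf angle distribution).  Shoot-level clumping
is corrected by dividing PAI by 4*STAR (silhouette-to-total-area ratio of
shoots); stand-level clumping and the woody fraction are left uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import AnnulusSet, LensFunction, annulus_masks
from .segmentation import BinaryMask

__all__ = [
    "GapProfile",
    "PAIEstimate",
    "gap_fractions",
    "miller_pai",
    "clumping_correct",
]

#: 4*STAR divisor uses species STAR values; spherical shoots have STAR = 1/4.
STAR_PINE = 0.147
STAR_SPRUCE = 0.161


@dataclass
class GapProfile:
    """Per-annulus gap fractions with the annulus geometry that produced them."""

    annuli: AnnulusSet
    P: np.ndarray
    pixel_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.annuli.n_annuli,):
            raise ValueError("one gap fraction per annulus required")
        if np.any((self.P < 0) | (self.P > 1)):
            raise ValueError("gap fractions must lie in [0, 1]")
        if self.pixel_counts is not None:
            self.pixel_counts = np.asarray(self.pixel_counts, dtype=np.int64)


@dataclass
class PAIEstimate:
    pai_raw: float
    theta_max: float
    truncation_corrected: bool
    star: float | None = None
    pai_clumping_corrected: float | None = None


def gap_fractions(
    mask: BinaryMask, annuli: AnnulusSet, lens: LensFunction | None = None
) -> GapProfile:
    """P_i = sky pixels / inside pixels, per annulus.

    The mask must live on a hemispherical disc; annulus membership is
    derived from each pixel's zenith angle under ``lens``.
    """
    if lens is None:
        lens = LensFunction()
    # Rebuild annulus geometry from the mask raster itself.
    from .projection import HemisphericalImage

    geom = HemisphericalImage(
        pixels=np.zeros(mask.sky.shape[:2]), lens=lens,
        outside_mask=mask.outside_mask,
    )
    rings = annulus_masks(geom, annuli)
    P = np.empty(annuli.n_annuli)
    counts = np.empty(annuli.n_annuli, dtype=np.int64)
    for i, ring in enumerate(rings):
        n = int(ring.sum())
        if n == 0:
            raise ValueError(f"empty annulus {i}")
        counts[i] = n
        P[i] = float(mask.sky[ring].sum()) / n
    return GapProfile(annuli=annuli, P=P, pixel_counts=counts)


def miller_pai(
    gp: GapProfile,
    truncation_correct: bool = True,
    p_floor: float | None = None,
) -> PAIEstimate:
    """Discretized Miller integral over annulus midpoints.

    PAI_raw = [2 * sum_i (-ln P_i) cos(theta_i) sin(theta_i) dtheta] / C
    with C = 1 - cos(theta_max) when ``truncation_correct`` else 1.

    ``p_floor`` replaces smaller gap fractions before the log; the default
    is one pixel's worth per annulus (1/pixel_count) when counts are known,
    otherwise 0 (so a fully saturated annulus raises).
    """
    P = gp.P.copy()
    if p_floor is None:
        if gp.pixel_counts is not None:
            P = np.maximum(P, 1.0 / gp.pixel_counts)
        elif np.any(P == 0):
            raise ValueError("saturated annulus: P = 0 with no floor")
    else:
        P = np.maximum(P, p_floor)
        if np.any(P == 0):
            raise ValueError("saturated annulus: P = 0 with p_floor = 0")

    theta = np.deg2rad(gp.annuli.midpoints)
    dtheta = np.deg2rad(gp.annuli.width_deg)
    theta_max = np.deg2rad(gp.annuli.theta_max)
    integral = 2.0 * np.sum(-np.log(P) * np.cos(theta) * np.sin(theta) * dtheta)
    C = (1.0 - np.cos(theta_max)) if truncation_correct else 1.0
    return PAIEstimate(
        pai_raw=float(integral / C),
        theta_max=float(gp.annuli.theta_max),
        truncation_corrected=truncation_correct,
    )


def clumping_correct(pai_raw: float, star: float) -> float:
    """Shoot-level clumping correction: PAI / (4 * STAR).

    STAR < 0.25 (clumped shoots) inflates PAI; STAR = 0.25 is the
    no-clumping spherical limit.
    """
    if star <= 0:
        raise ValueError("STAR must be positive")
    return float(pai_raw) / (4.0 * star)
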