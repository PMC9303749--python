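"""Readers, writers and run configuration.

Rasters are read with imageio (JPEG/PNG/TIFF); hemispherical images and
masks are written as PNG with a JSON sidecar carrying the geometry and
processing metadata, so every output can be reproduced from its provenance
record.  Point clouds are read from whitespace-delimited XYZ text.
Configuration lives in a YAML file whose defaults match the published
processing settings (gamma 2.2, five 15° annuli, STAR 0.147 pine / 0.161
spruce, 10 m cylinder, 50 levels, 1.5 m ground cut); command-line flags
override the file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .als import PointCloud
from .projection import AnnulusSet, HemisphericalImage, LensFunction

__all__ = [
    "RunConfig",
    "read_panorama_image",
    "read_point_cloud",
    "write_hemispherical",
    "read_hemispherical",
    "write_mask",
    "read_profile_csv",
    "write_profile_csv",
]


@dataclass
class RunConfig:
    """All tunables of the processing chain, with published defaults."""

    lens_kind: str = "linear"
    lens_coefficients: list = field(default_factory=list)
    out_size: int = 4000
    interpolation: str = "bilinear"
    azimuth_offset: float = 0.0
    gamma: float = 2.2
    channel_mode: str = "rgb_mean"
    threshold_mode: str = "ridler_calvard"
    manual_threshold: float = 0.5
    n_annuli: int = 5
    annulus_width_deg: float = 15.0
    star: float | None = None          # 0.147 pine, 0.161 spruce, None birch
    truncation_correct: bool = True
    clip_negative: bool = False
    als_radius: float = 10.0
    als_levels: int = 50
    als_ground_cut: float = 1.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    def lens(self) -> LensFunction:
        return LensFunction(
            kind=self.lens_kind, coefficients=tuple(self.lens_coefficients)
        )

    def annuli(self) -> AnnulusSet:
        return AnnulusSet(n_annuli=self.n_annuli, width_deg=self.annulus_width_deg)


def read_panorama_image(path: str | Path) -> np.ndarray:
    """Raster from JPEG/PNG/TIFF; alpha channel dropped if present."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    return img


def read_point_cloud(path: str | Path) -> PointCloud:
    """Whitespace-delimited XYZ text, one point per line."""
    pts = np.loadtxt(path, dtype=float)
    pts = np.atleast_2d(pts)
    if pts.shape[1] < 3:
        raise ValueError("point cloud text needs at least 3 columns (x y z)")
    return PointCloud(points=pts[:, :3], source="xyz")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_hemispherical(img: HemisphericalImage, path: str | Path) -> None:
    """PNG plus JSON sidecar (size, radius, lens, azimuth offset)."""
    path = Path(path)
    arr = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
    meta = {
        "size": img.size,
        "radius": img.radius,
        "lens": {
            "kind": img.lens.kind,
            "coefficients": list(img.lens.coefficients),
            "theta_max": img.lens.theta_max,
        },
        "azimuth_offset": img.azimuth_offset,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_hemispherical(path: str | Path) -> HemisphericalImage:
    path = Path(path)
    arr = np.asarray(iio.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    lens = LensFunction(
        kind=meta["lens"]["kind"],
        coefficients=tuple(meta["lens"]["coefficients"]),
        theta_max=meta["lens"]["theta_max"],
    )
    return HemisphericalImage(
        pixels=arr, lens=lens, azimuth_offset=meta.get("azimuth_offset", 0.0)
    )


def write_mask(mask, path: str | Path, extra: dict | None = None) -> None:
    """Binary mask as PNG (sky = 255) with threshold metadata sidecar."""
    path = Path(path)
    arr = np.where(mask.sky & mask.inside_mask, 255, 0).astype(np.uint8)
    iio.imwrite(path, arr)
    meta = {"threshold": mask.threshold, "gap_fraction": mask.gap_fraction()}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    """CSV of (location_id, height_m, replicate, pai)."""
    df = pd.read_csv(path)
    required = {"height_m", "pai"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    return df


def write_profile_csv(profile, heights_path: str | Path, pad_path: str | Path) -> None:
    """Two CSVs: per-height (pai, deviation) and per-layer PAD."""
    pd.DataFrame(
        {
            "height_m": profile.heights,
            "pai_mean": profile.pai,
            "deviation_pct": (
                profile.deviation_pct
                if profile.deviation_pct is not None
                else np.full_like(profile.heights, np.nan)
            ),
        }
    ).to_csv(heights_path, index=False)
    pd.DataFrame(
        {"layer_mid_m": profile.layer_midpoints, "pad": profile.pad}
    ).to_csv(pad_path, index=False)
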