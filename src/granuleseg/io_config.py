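"""Raster and table I/O plus the run configuration.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)`` internally.  CSV export uses
  ``centroid_x_px = col`` and ``centroid_y_px = row``.
* The physical pixel size (nm per pixel edge) is always supplied by the user
  or the config; TIFF resolution tags are ignored because they are unreliable
  across EM vendors.
* Grayscale images are 8-bit; instance label maps are 16-bit TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

GRANULE_TABLE_COLUMNS = [
    "id",
    "centroid_x_px",
    "centroid_y_px",
    "area_nm2",
    "perimeter_nm",
    "equiv_radius_nm",
    "core_radius_nm",
    "round_coefficient",
    "mean_gray",
    "membrane_distance_nm",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D 8-bit grayscale micrograph with its physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Intensities in [0, 255]; H, W >= 32.
    pixel_size_nm : float
        Edge length of one pixel in nanometres; must be positive.
    """

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected 8-bit intensities, got dtype {px.dtype}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"image too small: {px.shape}, need >= 32 in each axis")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_um2(self) -> float:
        """Physical area of the full frame in square micrometres."""
        h, w = self.pixels.shape
        return h * w * (self.pixel_size_nm * 1e-3) ** 2


@dataclass
class RunConfig:
    """Pipeline configuration, mirrored field-for-field by the YAML config.

    ``min_seed_separation_px`` and the area gates default to values derived
    from the 100-800 nm granule-diameter prior at the configured pixel size.
    """

    pixel_size_nm: float = 25.0
    binarization_threshold: float = 0.5
    min_seed_separation_px: float | None = None  # default: 50 nm / pixel_size_nm
    smoothing_sigma_px: float = 0.5
    matching_iou_threshold: float = 0.5
    membrane_bin_width_nm: float = 100.0
    epochs: int = 6
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0
    network: dict = field(default_factory=dict)  # NetworkSpec overrides

    def __post_init__(self) -> None:
        if not 0 < self.binarization_threshold < 1:
            raise ValueError("binarization_threshold must lie in (0, 1)")
        if not 0 < self.matching_iou_threshold < 1:
            raise ValueError("matching_iou_threshold must lie in (0, 1)")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.membrane_bin_width_nm <= 0:
            raise ValueError("membrane_bin_width_nm must be positive")
        if self.min_seed_separation_px is None:
            self.min_seed_separation_px = 50.0 / self.pixel_size_nm

    @property
    def min_area_px(self) -> int:
        """Lower instance-area gate: a 100 nm diameter disc in pixels."""
        r = 50.0 / self.pixel_size_nm
        return max(1, int(np.floor(np.pi * r * r)))

    @property
    def max_area_px(self) -> int:
        """Upper instance-area gate: an 800 nm diameter disc in pixels."""
        r = 400.0 / self.pixel_size_nm
        return int(np.ceil(np.pi * r * r))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_image(path: str | Path, pixel_size_nm: float) -> GrayImage:
    """Read an 8-bit single-channel TIFF or PNG micrograph.

    Multi-channel or non-8-bit rasters are rejected rather than silently
    converted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {px.shape}")
    if px.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got dtype {px.dtype}")
    return GrayImage(px, pixel_size_nm)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale raster as TIFF or PNG (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        iio.imwrite(path, img.pixels)


def read_instance_map(path: str | Path) -> np.ndarray:
    """Read a 16-bit TIFF instance label map as an int array."""
    imap = tifffile.imread(path)
    if imap.ndim != 2:
        raise ValueError(f"{path}: instance map must be 2-D, got shape {imap.shape}")
    return imap.astype(np.int32)

def write_instance_map(imap: np.ndarray, path: str | Path) -> None:
    if imap.min() < 0 or imap.max() > np.iinfo(np.uint16).max:
        raise ValueError("instance labels out of uint16 range")
    tifffile.imwrite(path, imap.astype(np.uint16))


def write_granule_table(records: list, path: str | Path) -> None:
    """Write one CSV row per granule with a fixed column header.

    Optional fields (``core_radius_nm``, ``membrane_distance_nm``) are left
    blank when absent.  Boundary polygons are not stored here (the CSV stays
    rectangular); use :func:`write_boundaries` for them.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "centroid_x_px": r.centroid[1],
                "centroid_y_px": r.centroid[0],
                "area_nm2": r.area_nm2,
                "perimeter_nm": r.perimeter_nm,
                "equiv_radius_nm": r.equiv_radius_nm,
                "core_radius_nm": r.core_radius_nm,
                "round_coefficient": r.round_coefficient,
                "mean_gray": r.mean_gray,
                "membrane_distance_nm": r.membrane_distance_nm,
            }
        )
    df = pd.DataFrame(rows, columns=GRANULE_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_granule_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_boundaries(records: list, path: str | Path) -> None:
    """Export granule boundary polygons as JSON: {id: [[row, col], ...]}."""
    data = {
        str(r.id): [[float(p[0]), float(p[1])] for p in r.boundary]
        for r in records
        if r.boundary is not None
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def write_membrane(points: np.ndarray, path: str | Path) -> None:
    """Write a membrane polyline as a JSON list of [row, col] points."""
    with open(path, "w") as fh:
        json.dump([[float(r), float(c)] for r, c in points], fh)


def read_membrane(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        pts = json.load(fh)
    return np.asarray(pts, dtype=float)
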