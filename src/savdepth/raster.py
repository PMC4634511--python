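"""Raster containers and TIFF I/O for multi-band image composites.

Coordinate convention: 0-based pixel indices, pixel-center origin, x to
the right and y down, geotransform in metres.  DN rasters are held as
float64 with NaN as the in-memory nodata sentinel; files are written as
multi-band TIFF with the geotransform, band definitions and bit depth
embedded as JSON in the image description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .bands import BandDefinition

__all__ = [
    "GeoTransform",
    "ImageBand",
    "MultiBandComposite",
    "write_composite",
    "read_composite",
    "write_raster",
    "read_raster",
    "crop_composite",
]


@dataclass(frozen=True)
class GeoTransform:
    """Maps pixel (row, col) centers to world (x, y) in metres."""

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 0.0024  # m per pixel

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def pixel_to_world(self, row, col):
        return (
            self.origin_x + np.asarray(col) * self.pixel_size,
            self.origin_y + np.asarray(row) * self.pixel_size,
        )

    def world_to_pixel(self, x, y):
        """Return fractional (row, col)."""
        return (
            (np.asarray(y) - self.origin_y) / self.pixel_size,
            (np.asarray(x) - self.origin_x) / self.pixel_size,
        )

    def shifted(self, row0: int, col0: int) -> "GeoTransform":
        x, y = self.pixel_to_world(row0, col0)
        return GeoTransform(float(x), float(y), self.pixel_size)


@dataclass
class ImageBand:
    """A single-band DN raster with its band definition and geotransform."""

    dn: np.ndarray
    band: BandDefinition
    transform: GeoTransform = field(default_factory=GeoTransform)

    def __post_init__(self) -> None:
        self.dn = np.asarray(self.dn, dtype=float)
        if self.dn.ndim != 2:
            raise ValueError("dn must be a 2-D raster")

    @property
    def shape(self):
        return self.dn.shape

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.dn)


class MultiBandComposite:
    """Co-registered DN rasters stacked on one grid with unique band names."""

    def __init__(self, bands: list[ImageBand], bit_depth: int = 8):
        if not bands:
            raise ValueError("composite needs at least one band")
        shape = bands[0].shape
        tr = bands[0].transform
        names = [b.band.name for b in bands]
        if len(set(names)) != len(names):
            raise ValueError(f"band names must be unique, got {names}")
        for b in bands:
            if b.shape != shape:
                raise ValueError("all bands must share one raster shape")
            if b.transform != tr:
                raise ValueError("all bands must share one geotransform")
        if bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        self.bands = list(bands)
        self.bit_depth = bit_depth
        self._by_name = {b.band.name: b for b in bands}

    @property
    def shape(self):
        return self.bands[0].shape

    @property
    def transform(self) -> GeoTransform:
        return self.bands[0].transform

    @property
    def band_names(self) -> list[str]:
        return [b.band.name for b in self.bands]

    @property
    def saturation_level(self) -> float:
        return float(2**self.bit_depth - 1)

    def band(self, name: str) -> ImageBand:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no band {name!r}; have {self.band_names}") from None

    def stack(self) -> np.ndarray:
        return np.stack([b.dn for b in self.bands])


def _meta_dict(transform: GeoTransform, bands=None, extra=None) -> dict:
    meta = {
        "geotransform": [transform.origin_x, transform.origin_y, transform.pixel_size],
    }
    if bands is not None:
        meta["bands"] = [[b.name, b.low_cut, b.high_cut] for b in bands]
    if extra:
        meta.update(extra)
    return meta


def write_composite(comp: MultiBandComposite, path) -> None:
    meta = _meta_dict(comp.transform, [b.band for b in comp.bands],
                      {"bit_depth": comp.bit_depth})
    tifffile.imwrite(
        Path(path), comp.stack().astype(np.float32), description=json.dumps(meta)
    )


def read_composite(path) -> MultiBandComposite:
    with tifffile.TiffFile(Path(path)) as tf:
        data = tf.asarray().astype(float)
        meta = json.loads(tf.pages[0].description)
    if data.ndim == 2:
        data = data[None]
    gt = GeoTransform(*meta["geotransform"])
    bands = [
        ImageBand(data[i], BandDefinition(name, lo, hi), gt)
        for i, (name, lo, hi) in enumerate(meta["bands"])
    ]
    return MultiBandComposite(bands, bit_depth=int(meta.get("bit_depth", 8)))


def write_raster(arr: np.ndarray, transform: GeoTransform, path, extra_meta=None) -> None:
    """Write a single 2-D float raster (e.g. a depth map) with metadata."""
    meta = _meta_dict(transform, extra=extra_meta)
    tifffile.imwrite(Path(path), np.asarray(arr, dtype=np.float32),
                     description=json.dumps(meta))


def read_raster(path):
    """Read a raster written by :func:`write_raster`; returns (array, transform, meta)."""
    with tifffile.TiffFile(Path(path)) as tf:
        data = tf.asarray().astype(float)
        meta = json.loads(tf.pages[0].description)
    return data, GeoTransform(*meta["geotransform"]), meta


def crop_composite(comp: MultiBandComposite, rows: slice, cols: slice) -> MultiBandComposite:
    """Crop all bands to a window, shifting the geotransform origin."""
    r0 = rows.indices(comp.shape[0])[0]
    c0 = cols.indices(comp.shape[1])[0]
    gt = comp.transform.shifted(r0, c0)
    bands = [ImageBand(b.dn[rows, cols].copy(), b.band, gt) for b in comp.bands]
    return MultiBandComposite(bands, bit_depth=comp.bit_depth)
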