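"""Per-pixel depth mapping and DEM post-processing.

Applies a fitted log-linear depth model pixel by pixel to a composite to
produce a submergence-depth raster (a "2.5D" canopy-surface DEM), removes
small-scale noise with a spatial mean filter, and renders a hillshade for
relief display.  Depths are positive-down submergence in cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import __version__
from .depth_model import DepthModel
from .raster import GeoTransform, MultiBandComposite, read_raster, write_raster

__all__ = [
    "DepthRaster",
    "map_depth",
    "spatial_mean_filter",
    "hillshade",
    "write_products",
    "read_products",
]


@dataclass
class DepthRaster:
    """Submergence-depth raster (cm, positive down) with provenance."""

    depth: np.ndarray
    transform: GeoTransform
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2-D raster")
        if not self.provenance:
            raise ValueError("provenance must be populated")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.depth)


def map_depth(
    composite: MultiBandComposite,
    model: DepthModel,
    veg_mask: np.ndarray | None = None,
) -> DepthRaster:
    """Invert the depth model per pixel.

    Pixel predictors are ln DN (single band) or ln of the band-DN ratio;
    nonpositive or nodata DN become nodata, as do pixels outside an
    optional vegetation mask.
    """
    if model.slope == 0:
        raise ValueError("model slope is zero; cannot map depth")
    spec = model.spec
    b1 = composite.band(spec.band1).dn
    with np.errstate(divide="ignore", invalid="ignore"):
        if spec.kind == "single":
            pred = np.where(b1 > 0, np.log(b1), np.nan)
        else:
            b2 = composite.band(spec.band2).dn
            ok = (b1 > 0) & (b2 > 0)
            pred = np.where(ok, np.log(b1) - np.log(b2), np.nan)
    depth = (pred - model.intercept) / model.slope
    if veg_mask is not None:
        if veg_mask.shape != depth.shape:
            raise ValueError("vegetation mask shape does not match the composite")
        depth = np.where(veg_mask, depth, np.nan)
    prov = {
        "model": model.spec.name,
        "intercept": model.intercept,
        "slope": model.slope,
        "site": model.site,
        "filter": None,
        "savdepth_version": __version__,
    }
    return DepthRaster(depth, composite.transform, prov)


def spatial_mean_filter(raster: DepthRaster, window: int = 5) -> DepthRaster:
    """Moving-window mean ignoring nodata, with reflecting (symmetric) edges.

    Odd windows are centered; even windows are anchored top-left (the
    output pixel is the window's top-left corner), a convention that must
    be fixed explicitly since an even window has no center pixel.  The
    valid-data footprint is never extended: output is nodata wherever the
    input was.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > min(raster.depth.shape):
        raise ValueError("window larger than the raster")
    a = raster.depth
    valid = np.isfinite(a)
    if window % 2 == 1:
        pad = ((window // 2, window // 2), (window // 2, window // 2))
    else:
        pad = ((0, window - 1), (0, window - 1))
    vals = np.pad(np.where(valid, a, 0.0), pad, mode="symmetric")
    cnts = np.pad(valid.astype(float), pad, mode="symmetric")
    win_vals = np.lib.stride_tricks.sliding_window_view(vals, (window, window))
    win_cnts = np.lib.stride_tricks.sliding_window_view(cnts, (window, window))
    s = win_vals.sum(axis=(-2, -1))
    c = win_cnts.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(c > 0, s / c, np.nan)
    mean[~valid] = np.nan
    prov = dict(raster.provenance)
    prov["filter"] = f"mean {window}x{window}"
    return DepthRaster(mean, raster.transform, prov)


def hillshade(
    raster: DepthRaster,
    azimuth_deg: float = 315.0,
    altitude_deg: float = 45.0,
    z_factor: float = 1.0,
) -> np.ndarray:
    """Horn-gradient hillshade of the DEM, in [0, 1].

    A flat raster shades to sin(altitude) everywhere.  The raster values
    are treated as elevations; pass ``z_factor=-1`` to light submergence
    depth as if it were inverted relief.
    """
    if not 0 < altitude_deg <= 90:
        raise ValueError("altitude must be in (0, 90] degrees")
    az = np.deg2rad(azimuth_deg)
    alt = np.deg2rad(altitude_deg)
    px = raster.transform.pixel_size * 100.0  # depth is cm; gradients per cm
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8.0 * px)
    ky = kx.T
    dzdx = ndimage.correlate(raster.depth, kx, mode="nearest") * z_factor
    dzdy = ndimage.correlate(raster.depth, ky, mode="nearest") * z_factor
    slope = np.arctan(np.hypot(dzdx, dzdy))
    aspect = np.arctan2(dzdy, -dzdx)
    shaded = np.sin(alt) * np.cos(slope) + np.cos(alt) * np.sin(slope) * np.cos(
        az - np.pi / 2.0 - aspect
    )
    return np.clip(shaded, 0.0, 1.0)


def write_products(
    depth: DepthRaster, shade: np.ndarray | None, out_dir
) -> dict[str, Path]:
    """Write depth (and optional hillshade) TIFFs plus run metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"depth": out / "depth.tif", "metadata": out / "metadata.json"}
    write_raster(depth.depth, depth.transform, paths["depth"],
                 extra_meta={"provenance": depth.provenance})
    if shade is not None:
        paths["hillshade"] = out / "hillshade.tif"
        write_raster(shade, depth.transform, paths["hillshade"])
    paths["metadata"].write_text(json.dumps(depth.provenance, indent=2))
    return paths


def read_products(out_dir) -> DepthRaster:
    out = Path(out_dir)
    arr, gt, meta = read_raster(out / "depth.tif")
    prov = meta.get("provenance") or json.loads((out / "metadata.json").read_text())
    return DepthRaster(arr, gt, prov)
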