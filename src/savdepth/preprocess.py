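"""Radiometric and geometric preparation of multi-band composites.

Radiometric: estimation and subtraction of a radial flare/vignetting mask
(lens-internal reflections produce circularly structured brightness,
vignetting a radial trend), and flagging of sunglint as saturated DN.
Geometric: least-squares polynomial co-registration from tie points with
nearest-neighbour resampling (DN values are never interpolated), band
stacking and cropping to the jointly covered extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .raster import GeoTransform, ImageBand, MultiBandComposite

logger = logging.getLogger(__name__)

__all__ = [
    "FlareMask",
    "TiePointSet",
    "PolynomialTransform2D",
    "build_flare_mask",
    "subtract_mask",
    "flag_glint",
    "fit_polynomial_transform",
    "warp_nearest",
    "stack_and_crop",
]


@dataclass
class FlareMask:
    """Radial correction mask: min(mask) = 0, so only structure is removed."""

    mask: np.ndarray
    center: tuple[float, float]  # (row, col)
    radii: np.ndarray
    profile: np.ndarray  # smoothed per-circle minimum DN at each radius


def _radius_map(shape, center):
    rows, cols = np.indices(shape)
    return np.hypot(rows - center[0], cols - center[1])


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    half = window // 2
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        lo = max(0, i - half)
        hi = min(y.size, i + half + 1)
        out[i] = np.nanmean(y[lo:hi])
    return out


def build_flare_mask(
    band: ImageBand,
    center: tuple[float, float] | None = None,
    n_circles: int = 90,
    smoothing_window: int = 5,
) -> FlareMask:
    """Estimate a radial flare/vignetting mask from per-circle minima.

    The lowest DN along each of ``n_circles`` concentric circles (center to
    farthest corner) is taken as the flare level at that radius — the
    darkest scene element on a circle bounds the additive artifact from
    above.  The radial profile of minima is smoothed with a centered
    moving average (default five points), interpolated linearly between
    circle radii (flat beyond the outermost) and normalised to min 0, so
    subtracting the mask removes radial structure but not overall level.
    """
    shape = band.shape
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    if not (0 <= center[0] < shape[0] and 0 <= center[1] < shape[1]):
        raise ValueError(f"center {center} outside raster of shape {shape}")
    if n_circles < 5:
        raise ValueError("need at least 5 circles")
    if smoothing_window % 2 != 1:
        raise ValueError("smoothing window must be odd")

    r = _radius_map(shape, center)
    corners = [(0, 0), (0, shape[1] - 1), (shape[0] - 1, 0), (shape[0] - 1, shape[1] - 1)]
    r_max = max(np.hypot(cr - center[0], cc - center[1]) for cr, cc in corners)
    radii = np.linspace(0.0, r_max, n_circles)
    dr = radii[1] - radii[0]
    bin_idx = np.clip(np.round(r / dr).astype(int), 0, n_circles - 1)

    flat_r = bin_idx.ravel()
    flat_dn = band.dn.ravel()
    finite = np.isfinite(flat_dn)
    prof = np.full(n_circles, np.inf)
    np.minimum.at(prof, flat_r[finite], flat_dn[finite])
    prof = np.where(np.isinf(prof), np.nan, prof)
    empty = np.isnan(prof)
    if empty.any():
        logger.info("flare mask: %d empty circle(s) merged with neighbours", empty.sum())
        valid = ~empty
        prof = np.interp(radii, radii[valid], prof[valid])

    smooth = _moving_average(prof, smoothing_window)
    mask = np.interp(r, radii, smooth)  # np.interp is flat beyond the ends
    mask -= mask.min()
    return FlareMask(mask=mask, center=center, radii=radii, profile=smooth)


def subtract_mask(band: ImageBand, mask: FlareMask, dn_max: float | None = None) -> ImageBand:
    """Subtract a flare mask from a band, clipping at 0 (and dn_max if given).

    Nodata (NaN) pixels are preserved.
    """
    if mask.mask.shape != band.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match band shape {band.shape}"
        )
    dn = band.dn - mask.mask
    dn = np.clip(dn, 0.0, dn_max)
    dn[~band.valid] = np.nan
    return ImageBand(dn, band.band, band.transform)


def flag_glint(
    values, saturation_level: float = 255.0, percentile: float | None = None
) -> np.ndarray:
    """Keep-mask for a DN sample: False where glint-suspect.

    Saturated DN (>= the bit-depth maximum) are always flagged; optionally
    the top ``percentile`` percent within the sample as well.  Flag counts
    are logged to support manual review of exclusions.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty DN sample")
    keep = np.isfinite(v) & (v < saturation_level)
    if percentile is not None:
        if not 0 < percentile < 50:
            raise ValueError("percentile must be in (0, 50)")
        if keep.any():
            cut = np.percentile(v[keep], 100 - percentile)
            keep &= v < cut
    flagged = int(np.isfinite(v).sum() - keep.sum())
    if flagged:
        logger.info("glint rule flagged %d of %d pixels", flagged, int(np.isfinite(v).sum()))
    return keep


@dataclass
class TiePointSet:
    """Pixel-coordinate tie points: source (x, y) -> reference (x, y)."""

    src: np.ndarray  # (n, 2) x, y
    dst: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.src = np.atleast_2d(np.asarray(self.src, dtype=float))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise ValueError("src and dst must both be (n, 2) arrays")
        uniq = {tuple(p) for p in self.src}
        if len(uniq) != len(self.src):
            raise ValueError("duplicate source points in tie point set")

    def __len__(self) -> int:
        return len(self.src)


def _poly_terms(xy: np.ndarray, order: int) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    cols = [np.ones_like(x), x, y]
    if order == 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


def _fit_poly(src, dst, order):
    A = _poly_terms(src, order)
    n_terms = A.shape[1]
    if len(src) < n_terms:
        raise ValueError(
            f"order-{order} fit needs at least {n_terms} tie points, got {len(src)}"
        )
    coef, _, rank, _ = np.linalg.lstsq(A, dst, rcond=None)
    if rank < n_terms:
        raise ValueError("tie point configuration is rank-deficient (collinear points)")
    resid = A @ coef - dst
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return coef, rmse


@dataclass
class PolynomialTransform2D:
    """2-D polynomial mapping fitted in both directions (source<->reference)."""

    order: int
    coef_fwd: np.ndarray  # maps source px -> reference px
    coef_inv: np.ndarray  # maps reference px -> source px
    rmse_px: float
    rmse_m: float | None = None

    def forward(self, xy) -> np.ndarray:
        return _poly_terms(np.atleast_2d(np.asarray(xy, dtype=float)), self.order) @ self.coef_fwd

    def inverse(self, xy) -> np.ndarray:
        return _poly_terms(np.atleast_2d(np.asarray(xy, dtype=float)), self.order) @ self.coef_inv


def fit_polynomial_transform(
    ties: TiePointSet, order: int = 2, pixel_size: float | None = None
) -> PolynomialTransform2D:
    """Least-squares polynomial co-registration transform from tie points.

    Reports RMSE in pixels, and in metres when a pixel size is given.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    coef_fwd, rmse = _fit_poly(ties.src, ties.dst, order)
    coef_inv, _ = _fit_poly(ties.dst, ties.src, order)
    return PolynomialTransform2D(
        order=order,
        coef_fwd=coef_fwd,
        coef_inv=coef_inv,
        rmse_px=rmse,
        rmse_m=rmse * pixel_size if pixel_size else None,
    )


def warp_nearest(
    band: ImageBand,
    transform: PolynomialTransform2D,
    target_shape: tuple[int, int] | None = None,
    target_transform: GeoTransform | None = None,
) -> ImageBand:
    """Resample a band onto the reference grid by nearest neighbour.

    Each target pixel takes the DN of the nearest source pixel under the
    inverse mapping; DN values are never interpolated, preserving the
    radiometry.  Target pixels mapping outside the source are nodata.
    """
    shape = target_shape or band.shape
    gt = target_transform or band.transform
    rows, cols = np.indices(shape)
    xy = np.column_stack([cols.ravel().astype(float), rows.ravel().astype(float)])
    src = transform.inverse(xy)
    if not np.all(np.isfinite(src)):
        raise ValueError("transform is degenerate over the target extent")
    sc = np.round(src[:, 0]).astype(int)
    sr = np.round(src[:, 1]).astype(int)
    inside = (sr >= 0) & (sr < band.shape[0]) & (sc >= 0) & (sc < band.shape[1])
    out = np.full(rows.size, np.nan)
    out[inside] = band.dn[sr[inside], sc[inside]]
    return ImageBand(out.reshape(shape), band.band, gt)


def stack_and_crop(bands: list[ImageBand], bit_depth: int = 8) -> MultiBandComposite:
    """Stack warped bands and crop to the jointly covered extent.

    Pixels valid in every band are retained; others become nodata.  The
    composite is cropped to the bounding box of the all-band-valid region.
    """
    if not bands:
        raise ValueError("no bands to stack")
    shape = bands[0].shape
    gt = bands[0].transform
    for b in bands[1:]:
        if b.shape != shape:
            raise ValueError("bands must share a raster shape after warping")
        if b.transform != gt:
            raise ValueError("bands must share a geotransform after warping")
    joint = np.logical_and.reduce([b.valid for b in bands])
    if not joint.any():
        raise ValueError("bands have no jointly covered extent")
    rows = np.flatnonzero(joint.any(axis=1))
    cols = np.flatnonzero(joint.any(axis=0))
    rs = slice(rows[0], rows[-1] + 1)
    cs = slice(cols[0], cols[-1] + 1)
    gt2 = gt.shifted(rows[0], cols[0])
    out = []
    for b in bands:
        dn = b.dn[rs, cs].copy()
        dn[~joint[rs, cs]] = np.nan
        out.append(ImageBand(dn, b.band, gt2))
    return MultiBandComposite(out, bit_depth=bit_depth)
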