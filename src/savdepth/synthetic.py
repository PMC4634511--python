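"""Synthetic spectra and scenes with the statistical structure the
analysis assumes.

Forward model (single-pass exponential attenuation with a lumped gain):

    L(lambda, d) = gain * [ r_b(lambda) * exp(-k(lambda) * d)
                            + r_c * (1 - exp(-k(lambda) * d)) ]

with bottom reflectance r_b, water-column reflectance r_c (default 0 for
shallow clear water), effective attenuation k per cm of submergence depth
d, followed by multiplicative log-normal sensor noise and optional DN
quantization.  With r_c = 0 and no noise, the log of any band ratio is
exactly linear in depth — the analytic contract every downstream stage is
tested against.  The two-way water path and scattering losses are lumped
into k.

Scenes emulate a shallow vegetated stream photographed at nadir: a
parabolic cross-channel depth profile, optional patchy vegetation over a
darker substrate, per-band auto-exposed gain, optional saturated glint
speckle, and an optional radial flare + vignetting artifact added to
selected NIR bands.  Circular depth-sample polygons annotated with the
true center depth mirror a field campaign's depth measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BandDefinition, DEFAULT_BANDS
from .raster import GeoTransform, ImageBand, MultiBandComposite
from .spectra import SpectralLibrary, Spectrum

__all__ = [
    "AttenuationCurve",
    "BottomSpectrum",
    "FlareSpec",
    "SceneConfig",
    "SceneTruth",
    "DEFAULT_GRID",
    "make_attenuation_curve",
    "make_bottom_spectrum",
    "simulate_submerged_spectrum",
    "simulate_spectral_survey",
    "simulate_scene",
]

#: Default hyperspectral grid: 400-1000 nm at the instrument's 1.5 nm step.
#: The sub-400 nm UV edge of field spectroradiometers is noisy and routinely
#: discarded, so it is excluded from the default working range.
DEFAULT_GRID = np.arange(400.0, 1000.0 + 1e-9, 1.5)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class AttenuationCurve:
    """Effective attenuation coefficient k (per cm) on a wavelength grid."""

    wavelengths: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.k.shape != self.wavelengths.shape:
            raise ValueError("k and wavelengths must have equal length")
        if np.any(self.k < 0):
            raise ValueError("attenuation coefficients must be >= 0")

    def band_mean(self, band: BandDefinition) -> float:
        inside = (self.wavelengths >= band.low_cut) & (self.wavelengths <= band.high_cut)
        if not inside.any():
            raise ValueError(f"band {band.name!r} outside attenuation grid")
        return float(self.k[inside].mean())


@dataclass
class BottomSpectrum:
    """Bottom (canopy/substrate) reflectance fraction on a wavelength grid."""

    wavelengths: np.ndarray
    r_b: np.ndarray
    label: str = "vegetation"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.r_b = np.asarray(self.r_b, dtype=float)
        if self.r_b.shape != self.wavelengths.shape:
            raise ValueError("r_b and wavelengths must have equal length")
        if np.any((self.r_b < 0) | (self.r_b > 1)):
            raise ValueError("bottom reflectance must lie in [0, 1]")

    def band_mean(self, band: BandDefinition) -> float:
        inside = (self.wavelengths >= band.low_cut) & (self.wavelengths <= band.high_cut)
        if not inside.any():
            raise ValueError(f"band {band.name!r} outside reflectance grid")
        return float(self.r_b[inside].mean())


def make_attenuation_curve(
    grid, preset: str = "water_like", scale: float = 1.0, value: float = 0.1
) -> AttenuationCurve:
    """Build an attenuation curve on a grid.

    Presets:

    * ``constant`` — k identically ``value`` (analytic toys).
    * ``water_like`` — small k in the blue/green, a steep rise beyond
      ~700 nm towards the strong NIR water absorption, and a local dip
      between 765 and 810 nm where water absorption slackens briefly.
      Magnitudes are of the order of clear-water absorption per cm.
    """
    wl = np.asarray(grid, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    if wl[0] < 350.0 or wl[-1] > 1050.0:
        raise ValueError("grid must lie within 350-1050 nm")
    if preset == "constant":
        k = np.full_like(wl, float(value))
    elif preset == "water_like":
        k = (
            0.0015
            + 0.0035 * ((wl - 350.0) / 650.0) ** 2
            + 0.030 * _sigmoid((wl - 715.0) / 12.0)
            + 0.060 * _sigmoid((wl - 880.0) / 45.0)
            - 0.007 * np.exp(-(((wl - 790.0) / 16.0) ** 2))
        )
    else:
        raise ValueError(f"unknown attenuation preset {preset!r}")
    return AttenuationCurve(wl, np.maximum(k * scale, 0.0))


def make_bottom_spectrum(
    grid,
    archetype: str = "vegetation",
    seed: int | None = None,
    level: float = 0.5,
    perturbation: float = 0.08,
) -> BottomSpectrum:
    """Build a bottom reflectance spectrum for a species/substrate archetype.

    * ``flat`` — reflectance identically ``level``.
    * ``vegetation`` — canopy archetype: green reflectance peak near
      550 nm, chlorophyll absorption minimum near 675 nm, red edge rising
      to a NIR plateau around 0.45.
    * ``substrate`` — dull, gently rising non-photosynthetic bed material.

    With a seed, a smooth multiplicative perturbation (log-sd
    ``perturbation``, ~50 nm correlation length) individualises the
    spectrum while preserving the archetype's qualitative features.
    """
    wl = np.asarray(grid, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    if archetype == "flat":
        r = np.full_like(wl, float(level))
    elif archetype == "vegetation":
        r = (
            0.04
            + 0.06 * np.exp(-(((wl - 550.0) / 40.0) ** 2))
            - 0.020 * np.exp(-(((wl - 672.0) / 15.0) ** 2))
            + 0.41 * _sigmoid((wl - 715.0) / 8.0)
        )
    elif archetype == "substrate":
        r = 0.12 + 0.08 * (wl - wl[0]) / max(wl[-1] - wl[0], 1.0)
    else:
        raise ValueError(f"unknown bottom archetype {archetype!r}")
    if seed is not None and perturbation > 0 and archetype != "flat":
        rng = np.random.default_rng(seed)
        knots = np.arange(wl[0], wl[-1] + 50.0, 50.0)
        rough = rng.normal(0.0, perturbation, knots.size)
        r = r * np.exp(np.interp(wl, knots, rough))
    return BottomSpectrum(wl, np.clip(r, 0.0, 1.0), label=archetype)


@dataclass(frozen=True)
class FlareSpec:
    """Radial sinusoid plus linear radial trend added to selected bands."""

    amplitude: float = 12.0  # DN
    period_px: float = 180.0
    phase: float = 0.0
    trend_per_px: float = -0.02  # DN per pixel of radius (vignetting)
    center: tuple[float, float] | None = None  # (row, col); None = image center
    bands: tuple[str, ...] = ("NIR_BP2",)

    def evaluate(self, shape) -> np.ndarray:
        center = self.center or ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        rows, cols = np.indices(shape)
        r = np.hypot(rows - center[0], cols - center[1])
        flare = self.amplitude * np.sin(2.0 * np.pi * r / self.period_px + self.phase)
        flare += self.trend_per_px * r
        return flare - flare.min()  # additive artifact, nonnegative


@dataclass
class SceneConfig:
    """Stated world of a synthetic scene / spectral survey.

    ``gain`` is the lumped illumination-exposure constant (downwelling
    irradiance, interface transmission, atmospheric transmittance and
    camera exposure collapse into one multiplicative factor per band).
    ``"auto"`` emulates per-filter-shot exposure: each band's gain is set
    so the brightest bottom at depth 0 maps to ``auto_expose_frac`` of
    full scale.  ``gain_scale`` applies a common illumination change on
    top (overcast vs bright sampling conditions).
    """

    gain: float | dict | str = "auto"
    gain_scale: float = 1.0
    auto_expose_frac: float = 0.7
    r_c: float = 0.0  # water-column reflectance; 0 = shallow clear water
    noise_sd: float = 0.1  # sd of ln-DN multiplicative noise
    depth_range_cm: tuple[float, float] = (5.0, 60.0)
    depth_profile: str = "parabolic"  # cross-channel profile of the truth raster
    veg_fraction: float = 1.0  # 1 = full canopy cover; <1 = patchy over substrate
    archetype: str = "vegetation"
    glint_fraction: float = 0.005
    flare: FlareSpec | None = None
    bit_depth: int = 8
    quantize: bool = True
    pixel_size_m: float = 0.0024
    polygon_diameter_m: float = 0.185
    n_polygons: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.glint_fraction < 1:
            raise ValueError("glint_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if not 0 <= self.r_c <= 1:
            raise ValueError("r_c must be in [0, 1]")
        lo, hi = self.depth_range_cm
        if lo < 0 or hi <= lo:
            raise ValueError("depth_range_cm must satisfy 0 <= min < max")

    @property
    def dn_max(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene: depth raster (cm), vegetation mask."""

    depth: np.ndarray
    veg_mask: np.ndarray
    config: SceneConfig
    band_k: dict = field(default_factory=dict)  # band name -> effective k (per cm)
    band_gain: dict = field(default_factory=dict)
    band_rb: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth.shape != self.veg_mask.shape:
            raise ValueError("depth and veg_mask rasters must share a shape")
        if not np.all(np.isfinite(self.depth)) or np.any(self.depth < 0):
            raise ValueError("truth depth must be finite and >= 0")


def _attenuate(r_b, k, depth, r_c):
    att = np.exp(-np.multiply.outer(depth, k)) if np.ndim(depth) else np.exp(-k * depth)
    return r_b * att + r_c * (1.0 - att)


def simulate_submerged_spectrum(
    bottom: BottomSpectrum,
    k: AttenuationCurve,
    depth: float,
    config: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Forward-model a single submerged spectrum at one depth (cm)."""
    config = config or SceneConfig()
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not np.array_equal(bottom.wavelengths, k.wavelengths):
        raise ValueError("bottom spectrum and attenuation curve grids differ")
    gain = 1.0 if config.gain == "auto" else float(config.gain)
    gain *= config.gain_scale
    radiance = gain * _attenuate(bottom.r_b, k.k, float(depth), config.r_c)
    if config.noise_sd > 0:
        rng = rng or np.random.default_rng(config.seed)
        radiance = radiance * np.exp(rng.normal(0.0, config.noise_sd, radiance.shape))
    return Spectrum(bottom.wavelengths, radiance, kind="radiance")


def simulate_spectral_survey(
    n: int,
    depth_range_cm: tuple[float, float] = (5.0, 50.0),
    archetypes: Sequence[str] = ("vegetation",),
    k: AttenuationCurve | None = None,
    config: SceneConfig | None = None,
    grid=None,
) -> tuple[SpectralLibrary, np.ndarray]:
    """Simulate a field-spectroscopy campaign: n spectra at uniform depths.

    Mixed archetypes mimic a multi-species survey; every spectrum gets its
    own seeded bottom-spectrum perturbation and sensor noise.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples (regression downstream)")
    lo, hi = depth_range_cm
    if lo < 0 or hi < lo:
        raise ValueError("invalid depth range")
    config = config or SceneConfig()
    wl = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if k is None:
        k = make_attenuation_curve(wl, "water_like")
    rng = np.random.default_rng(config.seed)
    depths = rng.uniform(lo, hi, n)
    labels = [archetypes[i % len(archetypes)] for i in range(n)]
    # one bottom spectrum per archetype: within-species spectral variation is
    # part of the sensor-noise term, keeping the noiseless library exactly
    # log-linear in depth for every band pair
    bottoms = {
        a: make_bottom_spectrum(wl, a, seed=config.seed + 7 * idx)
        for idx, a in enumerate(dict.fromkeys(archetypes))
    }
    values = np.empty((n, wl.size))
    for i in range(n):
        spec = simulate_submerged_spectrum(bottoms[labels[i]], k, depths[i], config, rng=rng)
        values[i] = spec.values
    lib = SpectralLibrary(
        wavelengths=wl, values=values, depths=depths, labels=labels, kind="radiance"
    )
    return lib, depths


def _depth_field(shape, config: SceneConfig) -> np.ndarray:
    lo, hi = config.depth_range_cm
    if config.depth_profile == "parabolic":
        c = (shape[0] - 1) / 2.0
        u = (np.arange(shape[0]) - c) / c
        profile = lo + (hi - lo) * (1.0 - u**2)
        return np.repeat(profile[:, None], shape[1], axis=1)
    if config.depth_profile == "flat":
        return np.full(shape, lo)
    raise ValueError(f"unknown depth profile {config.depth_profile!r}")


def _veg_mask(shape, config: SceneConfig, rng) -> np.ndarray:
    if config.veg_fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.normal(size=shape), sigma=min(shape) / 16.0)
    thresh = np.quantile(noise, 1.0 - config.veg_fraction)
    return noise >= thresh


def _place_polygons(shape, config: SceneConfig, depth, veg, gt, rng) -> pd.DataFrame:
    radius_px = 0.5 * config.polygon_diameter_m / config.pixel_size_m
    margin = int(np.ceil(radius_px)) + 2
    # keep sample centers off the extreme banks, as a field campaign would
    row_lo = max(margin, int(0.05 * shape[0]))
    row_hi = min(shape[0] - margin, int(0.95 * shape[0]))
    if row_hi <= row_lo or shape[1] - margin <= margin:
        raise ValueError("raster too small for the requested polygon diameter")
    # stratified placement: target depths drawn uniformly over the sampled
    # range, mirroring a campaign that marks vegetation at regular depth
    # intervals rather than at random positions
    inset = depth[row_lo:row_hi, margin : shape[1] - margin]
    veg_inset = veg[row_lo:row_hi, margin : shape[1] - margin]
    d_lo, d_hi = float(inset.min()), float(inset.max())
    tol = max((d_hi - d_lo) / 25.0, 0.5)
    centers: list[tuple[int, int]] = []
    min_sep = 2.0 * radius_px
    tries = 0
    while len(centers) < config.n_polygons and tries < 200 * config.n_polygons:
        tries += 1
        target = rng.uniform(d_lo, d_hi)
        cand = np.flatnonzero((np.abs(inset - target) <= tol) & veg_inset)
        if cand.size == 0:
            continue
        pick = int(cand[rng.integers(cand.size)])
        r = pick // inset.shape[1] + row_lo
        c = pick % inset.shape[1] + margin
        if all(np.hypot(r - r0, c - c0) >= min_sep for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < config.n_polygons:
        raise ValueError(
            f"could only place {len(centers)}/{config.n_polygons} polygons; "
            "reduce n_polygons or enlarge the scene"
        )
    xs, ys, ds = [], [], []
    for r, c in centers:
        x, y = gt.pixel_to_world(r, c)
        xs.append(float(x))
        ys.append(float(y))
        ds.append(float(depth[r, c]))
    return pd.DataFrame(
        {
            "id": [f"p{i:03d}" for i in range(len(centers))],
            "x": xs,
            "y": ys,
            "diameter_m": config.polygon_diameter_m,
            "depth_cm": ds,
        }
    )


def simulate_scene(
    config: SceneConfig | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    shape: tuple[int, int] = (512, 512),
    depth: np.ndarray | None = None,
) -> tuple[MultiBandComposite, SceneTruth, pd.DataFrame]:
    """Simulate a multi-band scene, its ground truth and sample polygons.

    Per band, the hyperspectral forward model is integrated top-hat over
    the band's 50% cuts: the band's effective attenuation and bottom
    reflectance are the in-band means of k and r_b, which keeps ln DN
    exactly linear in depth at zero noise.  An injected ``depth`` raster
    (cm) overrides the configured profile.
    """
    config = config or SceneConfig()
    if len(bands) < 1:
        raise ValueError("need at least one band")
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("scene shape must be at least 64x64 pixels")
    rng = np.random.default_rng(config.seed)
    gt = GeoTransform(0.0, 0.0, config.pixel_size_m)
    if depth is None:
        depth = _depth_field(shape, config)
    else:
        depth = np.asarray(depth, dtype=float)
        if depth.shape != tuple(shape):
            raise ValueError("injected depth raster does not match scene shape")
    veg = _veg_mask(shape, config, rng)

    wl = DEFAULT_GRID
    curve = make_attenuation_curve(wl, "water_like")
    veg_bottom = make_bottom_spectrum(wl, config.archetype, seed=config.seed)
    sub_bottom = make_bottom_spectrum(wl, "substrate", seed=config.seed + 1)

    band_k, band_gain, band_rb = {}, {}, {}
    rasters = []
    for b in bands:
        kb = curve.band_mean(b)
        rb_veg = veg_bottom.band_mean(b)
        rb_sub = sub_bottom.band_mean(b)
        rb = np.where(veg, rb_veg, rb_sub)
        if config.gain == "auto":
            g = config.auto_expose_frac * config.dn_max / max(rb_veg, rb_sub)
        elif isinstance(config.gain, dict):
            g = float(config.gain[b.name])
        else:
            g = float(config.gain)
        g *= config.gain_scale
        att = np.exp(-kb * depth)
        dn = g * (rb * att + config.r_c * (1.0 - att))
        if config.noise_sd > 0:
            dn = dn * np.exp(rng.normal(0.0, config.noise_sd, shape))
        if config.flare is not None and b.name in config.flare.bands:
            dn = dn + config.flare.evaluate(shape)
        if config.glint_fraction > 0:
            glint = rng.random(shape) < config.glint_fraction
            dn = np.where(glint, config.dn_max, dn)
        if config.quantize:
            dn = np.clip(np.round(dn), 0.0, config.dn_max)
        else:
            dn = np.clip(dn, 0.0, None)
        band_k[b.name] = kb
        band_gain[b.name] = g
        band_rb[b.name] = rb_veg
        rasters.append(ImageBand(dn, b, gt))

    composite = MultiBandComposite(rasters, bit_depth=config.bit_depth)
    truth = SceneTruth(
        depth=depth, veg_mask=veg, config=config,
        band_k=band_k, band_gain=band_gain, band_rb=band_rb,
    )
    polygons = _place_polygons(shape, config, depth, veg, gt, rng)
    return composite, truth, polygons
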