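"""Field-spectroscopy data handling.

Covers the processing chain from raw hand-held spectroradiometer output to
an analysis-ready spectral library: conversion of target radiance to
reflectance against a diffuse reference (Spectralon) panel, averaging of
replicate spectra, resampling of hyperspectral spectra onto broadband
filter bands, and CSV round-trip of libraries of spectra with paired
submergence depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bands import BandDefinition

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "reflectance_from_radiance",
    "average_spectra",
    "resample_to_bands",
    "read_library",
    "write_library",
]


def _as_grid(wavelengths) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    return wl


@dataclass
class Spectrum:
    """A single spectrum on an ascending wavelength grid (nm).

    ``kind`` distinguishes at-sensor radiance (instrument units) from
    reflectance fractions.  Reflectance above 1 is tolerated (specular
    glints can exceed the panel radiance) but flagged with a warning.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = _as_grid(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.kind not in ("radiance", "reflectance"):
            raise ValueError(f"kind must be 'radiance' or 'reflectance', got {self.kind!r}")
        if self.kind == "reflectance":
            if np.any(self.values < 0):
                raise ValueError("reflectance values must be >= 0")
            if np.any(self.values > 1):
                warnings.warn(
                    "reflectance exceeds 1 at some wavelengths (possible glint)",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectralLibrary:
    """Spectra on a shared grid with paired submergence depths (cm) and labels."""

    wavelengths: np.ndarray
    values: np.ndarray  # (n_samples, n_wavelengths)
    depths: np.ndarray  # cm, one per sample
    labels: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = _as_grid(self.wavelengths)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.depths = np.asarray(self.depths, dtype=float)
        n = self.values.shape[0]
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError("spectra do not match the wavelength grid length")
        if self.depths.shape != (n,):
            raise ValueError("one depth per spectrum is required")
        if np.any(self.depths < 0):
            raise ValueError("depths must be >= 0 cm")
        if not self.labels:
            self.labels = ["unknown"] * n
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(n)]
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length must match sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.values[i], kind=self.kind)


def reflectance_from_radiance(
    target: Spectrum, panel: Spectrum, panel_reflectance: float = 0.99
) -> Spectrum:
    """Convert target radiance to reflectance against a reference panel.

    reflectance = (target / panel) * panel_reflectance, elementwise on the
    shared grid.  The panel factor defaults to the 99% reflectance of a
    Spectralon standard.
    """
    if not np.array_equal(target.wavelengths, panel.wavelengths):
        raise ValueError("target and panel must share one wavelength grid")
    if not 0 < panel_reflectance <= 1:
        raise ValueError("panel_reflectance must be in (0, 1]")
    if np.any(panel.values <= 0):
        bad = np.flatnonzero(panel.values <= 0)
        raise ValueError(
            f"panel radiance must be positive everywhere; nonpositive at grid "
            f"indices {bad[:10].tolist()}"
        )
    refl = target.values / panel.values * panel_reflectance
    return Spectrum(target.wavelengths, refl, kind="reflectance")


def average_spectra(replicates: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra (shared grid and kind)."""
    if len(replicates) == 0:
        raise ValueError("need at least one spectrum to average")
    first = replicates[0]
    for s in replicates[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValueError("replicates must share one wavelength grid")
        if s.kind != first.kind:
            raise ValueError("cannot average spectra of mixed kind")
    mean = np.mean([s.values for s in replicates], axis=0)
    return Spectrum(first.wavelengths, mean, kind=first.kind)


def resample_to_bands(
    spectrum: Spectrum, bands: Iterable[BandDefinition]
) -> np.ndarray:
    """Top-hat resampling: unweighted mean of grid samples inside each band.

    Only the 50% transmission cuts of the filters are tabulated, so a
    rectangular (top-hat) response between the cuts is assumed.
    """
    out = []
    for band in bands:
        inside = (spectrum.wavelengths >= band.low_cut) & (
            spectrum.wavelengths <= band.high_cut
        )
        if not inside.any():
            raise ValueError(
                f"band {band.name!r} ({band.low_cut}-{band.high_cut} nm) contains "
                "no wavelength grid points"
            )
        out.append(spectrum.values[inside].mean())
    return np.asarray(out)


def write_library(lib: SpectralLibrary, spectra_path, samples_path=None) -> None:
    """Write a library as two CSVs: spectra (wavelength_nm + one column per
    sample) and a companion table ``sample_id,depth_cm,species``."""
    spectra_path = Path(spectra_path)
    samples_path = Path(samples_path) if samples_path else _companion_path(spectra_path)
    spec_df = pd.DataFrame(
        lib.values.T, columns=lib.sample_ids, index=pd.Index(lib.wavelengths, name="wavelength_nm")
    )
    spec_df.to_csv(spectra_path)
    pd.DataFrame(
        {"sample_id": lib.sample_ids, "depth_cm": lib.depths, "species": lib.labels}
    ).to_csv(samples_path, index=False)


def _companion_path(spectra_path: Path) -> Path:
    return spectra_path.with_name(spectra_path.stem + "_samples.csv")


def read_library(spectra_path, samples_path=None, kind: str = "reflectance") -> SpectralLibrary:
    """Read a library written by :func:`write_library`.

    Wavelengths are normalised to ascending order (with a warning if the
    file was descending); duplicated wavelength rows and missing depths are
    rejected.
    """
    spectra_path = Path(spectra_path)
    samples_path = Path(samples_path) if samples_path else _companion_path(spectra_path)
    spec_df = pd.read_csv(spectra_path, index_col=0)
    try:
        wl = spec_df.index.to_numpy(dtype=float)
        values = spec_df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {spectra_path}: {exc}") from exc
    if pd.Index(wl).duplicated().any():
        dups = wl[pd.Index(wl).duplicated()]
        raise ValueError(f"duplicated wavelength rows in {spectra_path}: {dups[:5]}")
    if np.any(np.diff(wl) < 0):
        warnings.warn(
            f"{spectra_path.name}: wavelengths not ascending; reordering",
            stacklevel=2,
        )
        order = np.argsort(wl)
        wl = wl[order]
        values = values[order]
    samples = pd.read_csv(samples_path)
    if "depth_cm" not in samples.columns:
        raise ValueError(f"depth column 'depth_cm' missing from {samples_path}")
    samples = samples.set_index("sample_id")
    sample_ids = list(spec_df.columns)
    missing = [s for s in sample_ids if s not in samples.index]
    if missing:
        raise ValueError(f"samples missing from {samples_path}: {missing}")
    depths = samples.loc[sample_ids, "depth_cm"]
    bad = depths.index[depths.isna()]
    if len(bad):
        raise ValueError(f"missing depth for sample(s): {list(bad)}")
    labels = (
        samples.loc[sample_ids, "species"].fillna("unknown").tolist()
        if "species" in samples.columns
        else ["unknown"] * len(sample_ids)
    )
    return SpectralLibrary(
        wavelengths=wl,
        values=values.T,
        depths=depths.to_numpy(dtype=float),
        labels=labels,
        sample_ids=sample_ids,
        kind=kind,
    )
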