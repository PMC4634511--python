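"""Broadband filter (image band) definitions.

A consumer DSLR with interchangeable lens filters yields broad spectral
bands; each band is summarised here by its estimated 50% transmission
cuts.  The six default bands are the Blue/Green/Red channels behind a
NIR-blocking filter, a VIS-blocking filter band covering the whole NIR
(``NIR_R72``), and two NIR bandpass filter bands centred near 710 nm
(``NIR_BP1``) and 828 nm (``NIR_BP2``).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandDefinition", "DEFAULT_BANDS", "band_by_name"]


@dataclass(frozen=True)
class BandDefinition:
    """A named broadband interval delimited by its 50% transmission cuts (nm)."""

    name: str
    low_cut: float
    high_cut: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("band name must be non-empty")
        if not self.low_cut < self.high_cut:
            raise ValueError(
                f"band {self.name!r}: low_cut ({self.low_cut}) must be below "
                f"high_cut ({self.high_cut})"
            )
        if self.low_cut < 300.0 or self.high_cut > 1100.0:
            raise ValueError(
                f"band {self.name!r}: cuts must lie within the 300-1100 nm "
                "instrument range"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low_cut + self.high_cut)

    @property
    def width(self) -> float:
        return self.high_cut - self.low_cut

    def contains(self, wavelength_nm: float) -> bool:
        return self.low_cut <= wavelength_nm <= self.high_cut


#: Six-band camera composite: RGB behind a NIR blocker, one wide NIR band
#: (VIS blocker) and two NIR bandpass bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("Blue", 400.0, 500.0),
    BandDefinition("Green", 500.0, 570.0),
    BandDefinition("Red", 570.0, 645.0),
    BandDefinition("NIR_R72", 720.0, 1000.0),
    BandDefinition("NIR_BP1", 662.0, 753.0),
    BandDefinition("NIR_BP2", 795.0, 860.0),
)


def band_by_name(name: str, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")
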