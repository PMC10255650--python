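"""Multispectral sensor definitions.

Two UAV cameras are modelled: a four-band Parrot Sequoia style sensor
("PS": green, red, red-edge, NIR) and a five-band DJI Phantom 4
Multispectral style sensor ("P4M": adds blue).  Bands are identified by
their nominal centre wavelength in nm, which is also how band columns are
named in spectra tables (``b560`` etc.).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Band:
    name: str            # short band code: B, G, R, RE, NIR
    range_nm: tuple[float, float]
    center_nm: float


@dataclass(frozen=True)
class SensorDef:
    """A multispectral camera: an ordered list of spectral bands."""

    name: str
    bands: tuple[Band, ...] = field(default_factory=tuple)

    @property
    def band_centers(self) -> tuple[float, ...]:
        return tuple(b.center_nm for b in self.bands)

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def center_for(self, band_name: str) -> float:
        for b in self.bands:
            if b.name == band_name:
                return b.center_nm
        raise KeyError(f"sensor {self.name!r} has no band {band_name!r}")

    def nearest_band(self, wavelength_nm: float) -> Band:
        """Band whose centre is closest to ``wavelength_nm``."""
        return min(self.bands, key=lambda b: abs(b.center_nm - wavelength_nm))

    def column(self, center_nm: float) -> str:
        """Column name used for this band in spectra tables."""
        if center_nm not in self.band_centers:
            raise KeyError(
                f"sensor {self.name!r} has no band centred at {center_nm} nm"
            )
        return band_column(center_nm)


def band_column(center_nm: float) -> str:
    return f"b{int(round(center_nm))}"


#: Four-band fixed-wing camera (green, red, red-edge, NIR).
PS = SensorDef(
    "PS",
    (
        Band("G", (530.0, 570.0), 550.0),
        Band("R", (640.0, 680.0), 660.0),
        Band("RE", (730.0, 740.0), 735.0),
        Band("NIR", (770.0, 810.0), 790.0),
    ),
)

#: Five-band quadcopter camera (blue, green, red, red-edge, NIR).
P4M = SensorDef(
    "P4M",
    (
        Band("B", (434.0, 466.0), 450.0),
        Band("G", (544.0, 576.0), 560.0),
        Band("R", (634.0, 666.0), 650.0),
        Band("RE", (714.0, 746.0), 730.0),
        Band("NIR", (814.0, 866.0), 840.0),
    ),
)

SENSORS: dict[str, SensorDef] = {"PS": PS, "P4M": P4M}


def get_sensor(name: str) -> SensorDef:
    try:
        return SENSORS[name]
    except KeyError:
        raise KeyError(
            f"unknown sensor {name!r}; available: {sorted(SENSORS)}"
        ) from None
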