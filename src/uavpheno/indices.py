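"""Generic vegetation-index families and band-assignment enumeration.

Fourteen index families are defined over one to four reflectance arguments
(Ra..Rd).  Rather than fixing bands a priori, every ordered assignment of
distinct sensor bands to the arguments is enumerated and screened by
regression quality downstream — the "generic index search" approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Mapping, Sequence

import numpy as np

from .sensors import SensorDef
from .simulate import SpectralSample

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexFamily:
    name: str
    arity: int
    formula: str                      # human-readable, in Ra..Rd notation
    fn: Callable[..., float]


def _nd(a, b):
    return (a - b) / (a + b)


FAMILIES: dict[str, IndexFamily] = {
    f.name: f for f in [
        IndexFamily("R", 1, "Ra", lambda a: a),
        IndexFamily("SR", 2, "Ra/Rb", lambda a, b: a / b),
        IndexFamily("DVI", 2, "Ra - Rb", lambda a, b: a - b),
        IndexFamily("ND", 2, "(Ra - Rb)/(Ra + Rb)", _nd),
        IndexFamily("mSR", 3, "(Ra - Rc)/(Rb - Rc)",
                    lambda a, b, c: (a - c) / (b - c)),
        IndexFamily("mSR2", 2, "(Ra/Rb) - 1", lambda a, b: a / b - 1.0),
        IndexFamily("mND", 3, "(Ra - Rb)/(Ra + Rb - 2*Rc)",
                    lambda a, b, c: (a - b) / (a + b - 2.0 * c)),
        IndexFamily("3SBI-Verrelst", 3, "(Ra - Rc)/(Rb + Rc)",
                    lambda a, b, c: (a - c) / (b + c)),
        IndexFamily("3SBI-Tian", 3, "(Ra - Rb - Rc)/(Ra + Rb + Rc)",
                    lambda a, b, c: (a - b - c) / (a + b + c)),
        IndexFamily("3SBI-Wang", 3, "(Ra - Rb + 2*Rc)/(Ra + Rb - 2*Rc)",
                    lambda a, b, c: (a - b + 2.0 * c) / (a + b - 2.0 * c)),
        IndexFamily("3SBI-Dash", 3, "(Ra - Rb)/(Rb - Rc)",
                    lambda a, b, c: (a - b) / (b - c)),
        IndexFamily("4SBI", 4,
                    "((Ra - Rb)/(Ra + Rb))/((Rc - Rd)/(Rc + Rd))",
                    lambda a, b, c, d: _nd(a, b) / _nd(c, d)),
        IndexFamily("EVI-like", 3,
                    "2.5*((Rb - Rc)/(Rb + 6*Rc + 7.5*Ra + 1))",
                    lambda a, b, c: 2.5 * (b - c) / (b + 6.0 * c + 7.5 * a + 1.0)),
        IndexFamily("EVI2-like", 2, "2.5*((Ra - Rb)/(Ra + 2*Rb + 1))",
                    lambda a, b: 2.5 * (a - b) / (a + 2.0 * b + 1.0)),
    ]
}


@dataclass(frozen=True)
class BandAssignment:
    """An index family with concrete band centres bound to Ra..Rd."""

    family: str
    bands: tuple[float, ...]       # ordered band centres (nm)

    def __post_init__(self) -> None:
        fam = FAMILIES[self.family]
        if len(self.bands) != fam.arity:
            raise ValueError(
                f"{self.family} takes {fam.arity} bands, got {len(self.bands)}"
            )
        if len(set(self.bands)) != len(self.bands):
            raise ValueError("bands within one assignment must be distinct")

    def label(self) -> str:
        inner = ",".join(str(int(b)) for b in self.bands)
        return f"{self.family} ({inner})"


def compute_index(assignment: BandAssignment,
                  sample: SpectralSample | Mapping[float, float]) -> float:
    """Evaluate the index formula on one sample.

    Returns NaN (with a debug log) for non-finite results such as zero
    denominators; raises if an assigned band is absent from the sample.
    """
    refl = (sample.reflectance if isinstance(sample, SpectralSample)
            else sample)
    try:
        # numpy scalars so zero denominators give inf/nan, not an exception
        args = [np.float64(refl[b]) for b in assignment.bands]
    except KeyError as exc:
        raise KeyError(
            f"sample lacks band {exc.args[0]} nm required by "
            f"{assignment.label()}"
        ) from None
    with np.errstate(divide="ignore", invalid="ignore"):
        val = FAMILIES[assignment.family].fn(*args)
    if not np.isfinite(val):
        log.debug("non-finite %s on bands %s", assignment.label(), args)
        return float("nan")
    return float(val)


def compute_index_matrix(assignment: BandAssignment,
                         band_values: Mapping[float, np.ndarray]) -> np.ndarray:
    """Vectorized index evaluation over arrays of per-band reflectance."""
    args = [np.asarray(band_values[b], dtype=float)
            for b in assignment.bands]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = FAMILIES[assignment.family].fn(*args)
    out = np.asarray(out, dtype=float)
    out[~np.isfinite(out)] = np.nan
    return out


def enumerate_assignments(
    families: Sequence[str | IndexFamily],
    sensor: SensorDef,
) -> list[BandAssignment]:
    """All ordered tuples of distinct sensor bands, per family arity.

    Ordered (not unordered) tuples are deliberate: the formulas are
    asymmetric in Ra..Rd, and symmetric duplicates are cheap at 4-5 bands.
    Families needing more bands than the sensor has are skipped with a log
    entry.
    """
    if not families:
        raise ValueError("family list is empty")
    centers = sensor.band_centers
    out = []
    for f in families:
        fam = FAMILIES[f] if isinstance(f, str) else f
        if fam.arity > len(centers):
            log.info("skipping %s: needs %d bands, sensor %s has %d",
                     fam.name, fam.arity, sensor.name, len(centers))
            continue
        out.extend(BandAssignment(fam.name, p)
                   for p in permutations(centers, fam.arity))
    return out


def registry_text() -> str:
    """Human-readable listing of the index registry."""
    lines = [f"{f.name:<14} arity {f.arity}   {f.formula}"
             for f in FAMILIES.values()]
    return "\n".join(lines)
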