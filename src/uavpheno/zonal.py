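"""Plot-level reflectance extraction from multiband rasters.

Plot polygons (in a projected metric CRS) are shrunk by an inward buffer to
avoid mixed edge pixels, then per-band means are taken over pixels whose
centres fall inside the buffered polygon.  Rasters are multiband TIFFs with
a JSON sidecar carrying the georeferencing (origin, pixel size, CRS, band
names, nodata); polygons are GeoJSON features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry

GEOGRAPHIC_MARKERS = ("4326", "geographic", "longlat", "degree")


@dataclass
class PlotPolygon:
    """A plot boundary with its attributive record."""

    plot_id: str
    geometry: BaseGeometry
    genotype_id: str = ""
    replicate: int = 0
    soil: bool = False

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"polygon for plot {self.plot_id!r} is invalid "
                             "(self-intersecting?)")


@dataclass
class RasterMosaic:
    """A multiband raster on a regular grid in a projected metric CRS.

    ``origin`` is the (x, y) of the top-left corner of the top-left pixel;
    y decreases down rows (north-up convention).
    """

    data: np.ndarray                 # (bands, rows, cols)
    origin: tuple[float, float]
    pixel_size: float                # ground sampling distance, m/pixel
    band_names: tuple[str, ...] = ()
    crs: str = "projected"
    nodata: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")
        if any(m in self.crs.lower() for m in GEOGRAPHIC_MARKERS):
            raise ValueError(
                f"raster CRS {self.crs!r} looks geographic; reproject to a "
                "projected metric CRS (e.g. UTM) first"
            )
        if not self.band_names:
            self.band_names = tuple(f"band{i + 1}"
                                    for i in range(self.data.shape[0]))

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of pixel-centre x (per column) and y (per row)."""
        x0, y0 = self.origin
        nrow, ncol = self.data.shape[1:]
        xs = x0 + (np.arange(ncol) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrow) + 0.5) * self.pixel_size
        return xs, ys


def inward_buffer(poly: PlotPolygon, distance: float) -> PlotPolygon:
    """Shrink a plot polygon inward by ``distance`` metres."""
    if distance < 0:
        raise ValueError("buffer distance must be >= 0")
    if distance == 0:
        return poly
    shrunk = poly.geometry.buffer(-distance)
    if shrunk.is_empty or shrunk.area <= 0:
        raise ValueError(
            f"inward buffer of {distance} m collapses plot "
            f"{poly.plot_id!r} (area {poly.geometry.area:.4f} m^2)"
        )
    return PlotPolygon(poly.plot_id, shrunk, poly.genotype_id,
                       poly.replicate, poly.soil)


def extract_plot_means(
    raster: RasterMosaic,
    polygons: Sequence[PlotPolygon],
    buffer: float = 0.10,
) -> pd.DataFrame:
    """Per-plot per-band mean reflectance over pixel centres in the polygon.

    Nodata pixels are excluded from the mean; the covered pixel count is
    reported per plot.  A plot covering zero pixels is an error.
    """
    xs, ys = raster.pixel_centers()
    rows = []
    for poly in polygons:
        shrunk = inward_buffer(poly, buffer)
        geom = shrunk.geometry
        minx, miny, maxx, maxy = geom.bounds
        ci = np.flatnonzero((xs >= minx) & (xs <= maxx))
        ri = np.flatnonzero((ys >= miny) & (ys <= maxy))
        if ci.size == 0 or ri.size == 0:
            raise ValueError(f"plot {poly.plot_id!r} covers no pixels")
        gx, gy = np.meshgrid(xs[ci], ys[ri])
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
        inside = inside.reshape(gy.shape)
        if not inside.any():
            raise ValueError(f"plot {poly.plot_id!r} covers no pixel centres")
        row = {"plot_id": poly.plot_id, "genotype_id": poly.genotype_id,
               "replicate": poly.replicate, "soil": poly.soil}
        n_used = None
        for b in range(raster.n_bands):
            window = raster.data[b][np.ix_(ri, ci)]
            vals = window[inside]
            if raster.nodata is not None:
                vals = vals[vals != raster.nodata]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(
                    f"plot {poly.plot_id!r}: all covered pixels are nodata "
                    f"in band {raster.band_names[b]}"
                )
            row[raster.band_names[b]] = float(vals.mean())
            n_used = vals.size if n_used is None else min(n_used, vals.size)
        row["n_pixels"] = int(n_used)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File formats: GeoJSON polygons; TIFF + JSON sidecar rasters.

def read_polygons(path: str | Path) -> list[PlotPolygon]:
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        out.append(PlotPolygon(
            plot_id=str(props.get("plot_id", f"plot{i + 1}")),
            geometry=geojson_shape(feat["geometry"]),
            genotype_id=str(props.get("genotype_id", "")),
            replicate=int(props.get("replicate", 0)),
            soil=bool(props.get("soil", False)),
        ))
    return out


def write_polygons(polygons: Sequence[PlotPolygon], path: str | Path) -> None:
    feats = []
    for p in polygons:
        feats.append({
            "type": "Feature",
            "geometry": json.loads(shapely.to_geojson(p.geometry)),
            "properties": {"plot_id": p.plot_id, "genotype_id": p.genotype_id,
                           "replicate": p.replicate, "soil": p.soil},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(raster: RasterMosaic, path: str | Path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, raster.data.astype(np.float32))
    meta = {"origin": list(raster.origin), "pixel_size": raster.pixel_size,
            "band_names": list(raster.band_names), "crs": raster.crs,
            "nodata": raster.nodata}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh)


def read_raster(path: str | Path) -> RasterMosaic:
    import tifffile

    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"georeferencing sidecar {sidecar} not found; rasters need "
            "origin/pixel-size metadata"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    return RasterMosaic(
        data=data, origin=tuple(meta["origin"]),
        pixel_size=float(meta["pixel_size"]),
        band_names=tuple(meta.get("band_names", ())),
        crs=meta.get("crs", "projected"), nodata=meta.get("nodata"),
    )
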