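"""Minimal georeferenced multi-band raster container and I/O.

A :class:`Raster` is a band-stacked numpy array with a north-up, axis-aligned
affine transform (origin of the top-left corner plus a square pixel size).
GeoTIFF files are written and read through :mod:`tifffile`, carrying the
georeferencing in the standard ``ModelPixelScale`` / ``ModelTiepoint`` tags and
the band centers in a JSON image description. Plot polygons travel as GeoJSON
``FeatureCollection`` files (one feature per plot, property ``plot_id``),
serialized with :mod:`json` and :mod:`shapely`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass
class Raster:
    """Multi-band raster with a simple north-up georeference.

    ``data`` has shape ``(n_bands, n_rows, n_cols)``; ``band_centers`` gives
    the wavelength (nm) of each band. ``x_origin, y_origin`` locate the
    *top-left corner* of pixel (0, 0); ``pixel_size`` is the ground sampling
    distance in map units (rows increase southwards).
    """

    data: np.ndarray
    band_centers: tuple[float, ...]
    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("raster data must be (bands, rows, cols)")
        if len(self.band_centers) != self.data.shape[0]:
            raise ValueError("band_centers length must match band count")
        self.band_centers = tuple(float(c) for c in self.band_centers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        rows, cols = self.shape
        return (
            self.x_origin,
            self.y_origin - rows * self.pixel_size,
            self.x_origin + cols * self.pixel_size,
            self.y_origin,
        )

    def band(self, center: float) -> np.ndarray:
        """Return the 2-D array of the band whose center is ``center`` nm."""
        for i, c in enumerate(self.band_centers):
            if abs(c - center) < 1e-9:
                return self.data[i]
        raise KeyError(f"no band centered at {center} nm")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every pixel center as ``(X, Y)`` 2-D grids."""
        rows, cols = self.shape
        xs = self.x_origin + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.y_origin - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def copy(self) -> "Raster":
        return Raster(
            self.data.copy(),
            self.band_centers,
            self.x_origin,
            self.y_origin,
            self.pixel_size,
        )

    def to_geotiff(self, path) -> None:
        import tifffile

        desc = json.dumps({"band_centers": list(self.band_centers)})
        extratags = [
            (_MODEL_PIXEL_SCALE, "d", 3, (self.pixel_size, self.pixel_size, 0.0)),
            (
                _MODEL_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, self.x_origin, self.y_origin, 0.0),
            ),
        ]
        tifffile.imwrite(
            path,
            self.data.astype("float32"),
            description=desc,
            extratags=extratags,
            photometric="minisblack",
            planarconfig="separate",
        )

    @classmethod
    def from_geotiff(cls, path) -> "Raster":
        import tifffile

        with tifffile.TiffFile(path) as tif:
            data = tif.asarray().astype(float)
            page = tif.pages[0]
            desc = page.tags.get("ImageDescription")
            scale = page.tags.get(_MODEL_PIXEL_SCALE)
            tie = page.tags.get(_MODEL_TIEPOINT)
            meta = json.loads(desc.value) if desc is not None else {}
            px = float(scale.value[0]) if scale is not None else 1.0
            if tie is not None:
                x0, y0 = float(tie.value[3]), float(tie.value[4])
            else:
                x0 = y0 = 0.0
        if data.ndim == 2:
            data = data[None]
        centers = meta.get("band_centers", list(range(data.shape[0])))
        return cls(data, tuple(centers), x0, y0, px)


def write_geojson(polygons, path) -> None:
    """Write ``[(plot_id, shapely geometry), ...]`` as a FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"plot_id": str(pid)},
            "geometry": mapping(geom),
        }
        for pid, geom in polygons
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_geojson(path) -> list[tuple[str, BaseGeometry]]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return [
        (f["properties"]["plot_id"], shape(f["geometry"]))
        for f in doc["features"]
    ]
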