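"""Gridded environmental layers: I/O, stacking, point extraction, bioclim derivation.

Layers are plain WGS84 lon/lat grids (the native WorldClim geometry); no
projection support. Grid cells are half-open intervals ``[west, east) x
[south, north)``: a point lying exactly on a shared boundary belongs to the
cell to its east/north, which makes point extraction deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RasterLayer",
    "RasterStack",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "extract_values",
    "derive_bioclim",
    "CANONICAL_LAYER_ORDER",
]

#: Fixed report order for the WorldClim-style layer set.
CANONICAL_LAYER_ORDER = ("ALT",) + tuple(f"Bio{i}" for i in range(1, 20))


class RasterFormatError(ValueError):
    """A raster file failed to parse; the message names the offending field."""


@dataclass
class RasterLayer:
    """One named environmental grid.

    Parameters
    ----------
    name : str
        Short layer name, e.g. ``"ALT"`` or ``"Bio7"``.
    values : ndarray of shape (nrows, ncols)
        Cell values with row 0 the northernmost row (image convention).
        Nodata cells hold ``nodata``.
    extent : tuple of float
        ``(lon_min, lon_max, lat_min, lat_max)`` in decimal degrees.
    cell_size : float
        Cell edge length in degrees; must be positive.
    nodata : float
        Sentinel value flagging missing cells.
    """

    name: str
    values: np.ndarray
    extent: tuple[float, float, float, float]
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        lon_min, lon_max, lat_min, lat_max = self.extent
        nrows, ncols = self.values.shape
        # geometry must agree with the grid shape to within one cell of rounding
        if abs((lon_max - lon_min) / self.cell_size - ncols) > 1:
            raise ValueError("extent width inconsistent with ncols * cell_size")
        if abs((lat_max - lat_min) / self.cell_size - nrows) > 1:
            raise ValueError("extent height inconsistent with nrows * cell_size")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean grid, True where the cell holds valid data."""
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the cell containing a point, or None if outside the extent.

        Half-open convention: a point on a shared cell boundary belongs to the
        east/north cell.  Points on the extreme east/north edge of the whole
        grid are kept in the last cell so the full extent is usable.
        """
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            return None
        col = int(np.floor((lon - lon_min) / self.cell_size))
        row_from_south = int(np.floor((lat - lat_min) / self.cell_size))
        nrows, ncols = self.values.shape
        col = min(col, ncols - 1)
        row_from_south = min(row_from_south, nrows - 1)
        return nrows - 1 - row_from_south, col

    def value_at(self, lon: float, lat: float) -> float | None:
        """Value of the containing cell; None if outside, NaN if nodata."""
        idx = self.cell_index(lon, lat)
        if idx is None:
            return None
        v = self.values[idx]
        if np.isclose(v, self.nodata) or not np.isfinite(v):
            return float("nan")
        return float(v)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]


class RasterStack:
    """Ordered collection of grid-aligned :class:`RasterLayer` objects.

    Layers must share extent and cell size; names are unique.  Iteration and
    reports use the canonical (ALT, Bio1..Bio19) order for those names, with
    any other layers following in insertion order.
    """

    def __init__(self, layers: Iterable[RasterLayer]):
        layers = list(layers)
        if not layers:
            raise ValueError("a RasterStack needs at least one layer")
        ref = layers[0]
        for lyr in layers[1:]:
            if lyr.values.shape != ref.values.shape:
                raise ValueError(f"layer {lyr.name!r} grid shape differs from {ref.name!r}")
            if not np.allclose(lyr.extent, ref.extent) or not np.isclose(
                lyr.cell_size, ref.cell_size
            ):
                raise ValueError(f"layer {lyr.name!r} geometry differs from {ref.name!r}")
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        order = {n: i for i, n in enumerate(CANONICAL_LAYER_ORDER)}
        layers.sort(key=lambda l: (order.get(l.name, len(order)),))
        self._layers: dict[str, RasterLayer] = {l.name: l for l in layers}

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self):
        return iter(self._layers.values())

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[name]

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return next(iter(self._layers.values())).extent

    @property
    def cell_size(self) -> float:
        return next(iter(self._layers.values())).cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._layers.values())).shape

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.shape, dtype=bool)
        for lyr in self:
            m &= lyr.mask()
        return m

    def add(self, layer: RasterLayer) -> "RasterStack":
        return RasterStack(list(self) + [layer])

    def table(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Flatten jointly-valid cells into a (cells x layers) DataFrame."""
        names = list(names) if names is not None else self.names
        m = self.valid_mask()
        for n in names:
            m &= self[n].mask()
        return pd.DataFrame({n: self[n].values[m] for n in names})


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_ASCII_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path: Path, name: str) -> RasterLayer:
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and re.fullmatch(r"[A-Za-z_]+", parts[0]):
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(f"ASCII grid header field {key!r}: {parts[1]!r} is not numeric") from exc
            i += 1
        else:
            break
    for key in _ASCII_KEYS:
        if key not in header:
            raise RasterFormatError(f"ASCII grid header missing field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if cellsize <= 0:
        raise RasterFormatError(f"ASCII grid field 'cellsize' must be > 0, got {cellsize}")
    if ncols <= 0 or nrows <= 0:
        raise RasterFormatError("ASCII grid fields 'ncols'/'nrows' must be positive")
    nodata = header.get("nodata_value", -9999.0)
    try:
        data = np.loadtxt(lines[i:], dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"ASCII grid data block unparsable: {exc}") from exc
    data = np.atleast_2d(data).reshape(nrows, ncols)
    lon_min = header["xllcorner"]
    lat_min = header["yllcorner"]
    extent = (lon_min, lon_min + ncols * cellsize, lat_min, lat_min + nrows * cellsize)
    return RasterLayer(name=name, values=data, extent=extent, cell_size=cellsize, nodata=nodata)


def _write_ascii_grid(layer: RasterLayer, path: Path) -> None:
    nrows, ncols = layer.shape
    lon_min, _, lat_min, _ = layer.extent
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {lon_min!r}\n")
        fh.write(f"yllcorner {lat_min!r}\n")
        fh.write(f"cellsize {layer.cell_size!r}\n")
        fh.write(f"NODATA_value {layer.nodata!r}\n")
        for row in layer.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band, via tifffile + GeoTIFF georeference tags)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113  # GDAL_NODATA


def _read_geotiff(path: Path, name: str) -> RasterLayer:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        if data.ndim != 2:
            raise RasterFormatError("GeoTIFF must hold one layer per band (2-D page)")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterFormatError(
                "GeoTIFF missing georeference tags ModelPixelScale/ModelTiepoint"
            )
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        # raster point (i, j, k) -> model (x, y, z); standard single tiepoint at (0, 0)
        _, _, _, x0, y0, _ = tie[:6]
        if sx <= 0 or sy <= 0:
            raise RasterFormatError(f"GeoTIFF ModelPixelScale must be positive, got ({sx}, {sy})")
        if not np.isclose(sx, sy):
            raise RasterFormatError("GeoTIFF pixel scale must be square (equal x/y cell size)")
        nodata = -9999.0
        if _TAG_NODATA in tags:
            nodata = float(tags[_TAG_NODATA].value)
        nrows, ncols = data.shape
        extent = (x0, x0 + ncols * sx, y0 - nrows * sy, y0)
    return RasterLayer(name=name, values=data, extent=extent, cell_size=float(sx), nodata=nodata)


def _write_geotiff(layer: RasterLayer, path: Path) -> None:
    import tifffile

    lon_min, _, _, lat_max = layer.extent
    cs = float(layer.cell_size)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, lon_min, lat_max, 0.0)),
        (_TAG_NODATA, "s", 0, str(layer.nodata)),
    ]
    tifffile.imwrite(str(path), layer.values.astype(np.float64), extratags=extratags)


def read_raster(path: str | Path, format: str | None = None, name: str | None = None) -> RasterLayer:
    """Read one environmental layer from GeoTIFF or ESRI ASCII grid.

    ``format`` is ``"geotiff"`` or ``"ascii_grid"``; when omitted it is
    inferred from the file suffix.  The layer name defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    name = name if name is not None else path.stem
    if format == "geotiff":
        return _read_geotiff(path, name)
    if format == "ascii_grid":
        return _read_ascii_grid(path, name)
    raise ValueError(f"unknown raster format {format!r}")


def write_raster(layer: RasterLayer, path: str | Path, format: str | None = None) -> None:
    """Write a layer as GeoTIFF or ESRI ASCII grid (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    if format == "geotiff":
        _write_geotiff(layer, path)
    elif format == "ascii_grid":
        _write_ascii_grid(layer, path)
    else:
        raise ValueError(f"unknown raster format {format!r}")


# ---------------------------------------------------------------------------
# Point extraction

ENV_TABLE_BASE_COLUMNS = ["species", "lon", "lat"]


def extract_values(stack: RasterStack, occurrences) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract per-point layer values from a stack.

    Parameters
    ----------
    stack : RasterStack
    occurrences : OccurrenceSet or DataFrame with species/lon/lat columns

    Returns
    -------
    env : DataFrame
        One row per retained point: ``species, lon, lat, <layer>...``.
        Points falling in a nodata cell of some layer keep a NaN in that
        column (flagged, not dropped); rows where *every* layer is missing
        are moved to the rejects report.
    rejects : DataFrame
        Points outside the stack extent or entirely nodata, with a reason.
    """
    df = occurrences.to_frame() if hasattr(occurrences, "to_frame") else pd.DataFrame(occurrences)
    rows, rejects = [], []
    for rec in df.itertuples(index=False):
        vals = {}
        outside = False
        for lyr in stack:
            v = lyr.value_at(rec.lon, rec.lat)
            if v is None:
                outside = True
                break
            vals[lyr.name] = v
        if outside:
            rejects.append({"species": rec.species, "lon": rec.lon, "lat": rec.lat,
                            "reason": "outside extent"})
            continue
        if all(np.isnan(v) for v in vals.values()):
            rejects.append({"species": rec.species, "lon": rec.lon, "lat": rec.lat,
                            "reason": "nodata cell"})
            continue
        rows.append({"species": rec.species, "lon": rec.lon, "lat": rec.lat, **vals})
    env = pd.DataFrame(rows, columns=ENV_TABLE_BASE_COLUMNS + stack.names)
    rej = pd.DataFrame(rejects, columns=ENV_TABLE_BASE_COLUMNS + ["reason"])
    return env, rej


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Derived bioclim layers


def derive_bioclim(stack: RasterStack) -> RasterStack:
    """Append derivable bioclim layers to a stack.

    Bio7 (temperature annual range) = Bio5 - Bio6; Bio3 (isothermality) =
    Bio2 / Bio7 x 100.  Each derivation runs only when its operands are in
    the stack and the result is not already present.  Nodata propagates;
    division by a zero annual range yields nodata in Bio3.
    """
    out = list(stack)
    have = set(stack.names)
    ref = next(iter(stack))
    nodata = ref.nodata

    def _grid(name: str) -> tuple[np.ndarray, np.ndarray]:
        lyr = stack[name] if name in stack else None
        if lyr is None:
            for cand in out:
                if cand.name == name:
                    lyr = cand
        return lyr.values, lyr.mask()

    if {"Bio5", "Bio6"} <= have and "Bio7" not in have:
        v5, m5 = _grid("Bio5")
        v6, m6 = _grid("Bio6")
        ok = m5 & m6
        vals = np.full(ref.shape, nodata)
        vals[ok] = v5[ok] - v6[ok]
        out.append(RasterLayer("Bio7", vals, ref.extent, ref.cell_size, nodata))
        have.add("Bio7")

    if {"Bio2", "Bio7"} <= have and "Bio3" not in have:
        lyr7 = next(l for l in out if l.name == "Bio7")
        v2, m2 = _grid("Bio2")
        v7, m7 = lyr7.values, lyr7.mask()
        ok = m2 & m7 & (v7 != 0)
        vals = np.full(ref.shape, nodata)
        vals[ok] = v2[ok] / v7[ok] * 100.0
        out.append(RasterLayer("Bio3", vals, ref.extent, ref.cell_size, nodata))

    return RasterStack(out)
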