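"""Reading and writing rasters as GeoTIFF and ESRI ASCII grid.

GeoTIFF is the primary container: georeferencing is stored in the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the
GDAL_NODATA convention, so files interchange with GDAL-based tools.  The
write/read round-trip is bit-exact for float64 data.  ESRI ASCII grid is
supported as a human-readable interchange/debug format; it round-trips
within the printed precision (we print full ``repr`` precision, so in
practice exactly).
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .grid import DEFAULT_NODATA, GridSpec, Raster

__all__ = ["read_raster", "write_raster"]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024      # 1 = projected, 2 = geographic
_GT_RASTER_TYPE = 1025     # 1 = PixelIsArea
_PROJECTED_CS_TYPE = 3072  # EPSG code of the projected CRS
_PROJ_LINEAR_UNITS = 3076  # 9001 = metre


def write_raster(raster: Raster, path: str | os.PathLike, format: str | None = None,
                 dtype: str = "float64") -> None:
    """Write a raster to ``path``.

    The format is inferred from the extension (``.tif``/``.tiff`` ->
    GeoTIFF, ``.asc`` -> ESRI ASCII grid) unless given explicitly as
    ``"GTiff"`` or ``"AAIGrid"``.  ``dtype`` may be ``"float32"`` to halve
    file size at the cost of precision; the default keeps the full 64-bit
    values so round-trips are bit-exact.
    """
    fmt = _resolve_format(path, format)
    if fmt == "GTiff":
        _write_geotiff(raster, path, dtype)
    else:
        _write_ascii(raster, path)


def read_raster(path: str | os.PathLike, format: str | None = None) -> Raster:
    """Read a GeoTIFF or ESRI ASCII grid written by :func:`write_raster`
    (or any GDAL-produced single-band file using the same conventions)."""
    fmt = _resolve_format(path, format)
    if fmt == "GTiff":
        return _read_geotiff(path)
    return _read_ascii(path)


def _resolve_format(path: str | os.PathLike, format: str | None) -> str:
    if format is not None:
        if format not in ("GTiff", "AAIGrid"):
            raise ValueError(f"unsupported format {format!r}")
        return format
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        return "GTiff"
    if ext in (".asc", ".agr"):
        return "AAIGrid"
    raise ValueError(f"cannot infer raster format from extension {ext!r}")


# ---------------------------------------------------------------- GeoTIFF

def _geokey_directory(spec: GridSpec) -> list[int]:
    code = spec.epsg_code()
    keys = [
        (_GT_MODEL_TYPE, 0, 1, 1),
        (_GT_RASTER_TYPE, 0, 1, 1),
        (_PROJ_LINEAR_UNITS, 0, 1, 9001),
    ]
    if code is not None:
        keys.insert(2, (_PROJECTED_CS_TYPE, 0, 1, code))
    keys.sort()
    directory = [1, 1, 0, len(keys)]
    for key in keys:
        directory.extend(key)
    return directory


def _write_geotiff(raster: Raster, path, dtype: str) -> None:
    if dtype not in ("float64", "float32"):
        raise ValueError(f"dtype must be float64 or float32, got {dtype!r}")
    spec = raster.spec
    data = raster.filled().astype(dtype)
    cs = float(spec.cell_size)
    geokeys = _geokey_directory(spec)
    nodata_text = repr(raster.nodata)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(spec.x_min), float(spec.y_max), 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", len(nodata_text) + 1, nodata_text),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_geotiff(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-band 2-D raster")
        tags = page.tags
        scale = tags.get(_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if not np.isclose(sx, sy):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        tp = tiepoint.value
        # tiepoint maps raster (i, j) to model (x, y)
        x_min = float(tp[3]) - float(tp[0]) * sx
        y_max = float(tp[4]) + float(tp[1]) * sy

        crs_label = "EPSG:28992"
        geokeys = tags.get(_GEO_KEY_DIRECTORY)
        if geokeys is not None:
            kv = _parse_geokeys(geokeys.value)
            if kv.get(_GT_MODEL_TYPE) == 2:
                raise ValueError(
                    f"{path}: geographic CRS; a projected metric CRS is required"
                )
            if _PROJECTED_CS_TYPE in kv:
                crs_label = f"EPSG:{kv[_PROJECTED_CS_TYPE]}"

        nodata = DEFAULT_NODATA
        nd_tag = tags.get(_GDAL_NODATA)
        if nd_tag is not None:
            nodata = float(str(nd_tag.value).strip().strip("\x00"))

    n_rows, n_cols = data.shape
    spec = GridSpec(x_min=x_min, y_max=y_max, cell_size=sx,
                    n_rows=n_rows, n_cols=n_cols, crs_label=crs_label)
    values = np.asarray(data, dtype=np.float64)
    mask = values == nodata
    return Raster(spec, values, mask, nodata=nodata)


def _parse_geokeys(directory) -> dict[int, int]:
    d = list(directory)
    if len(d) < 4:
        raise ValueError("malformed GeoKeyDirectory tag")
    n_keys = d[3]
    out = {}
    for i in range(n_keys):
        key_id, location, _count, value = d[4 + 4 * i: 8 + 4 * i]
        if location == 0:  # value stored inline; ignore ASCII/double params
            out[key_id] = value
    return out


# --------------------------------------------------------- ESRI ASCII grid

def _write_ascii(raster: Raster, path) -> None:
    spec = raster.spec
    data = raster.filled()
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_min!r}\n")
        fh.write(f"yllcorner {spec.y_min!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in data:
            fh.write(" ".join(repr(v) for v in row.tolist()))
            fh.write("\n")


def _read_ascii(path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {req!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = " ".join(lines[i:])
    flat = np.array(body.split(), dtype=np.float64)
    if flat.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: declared {n_rows}x{n_cols} = {n_rows * n_cols} cells "
            f"but found {flat.size} values"
        )
    values = flat.reshape(n_rows, n_cols)
    spec = GridSpec(
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    mask = values == nodata
    return Raster(spec, values, mask, nodata=nodata)
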