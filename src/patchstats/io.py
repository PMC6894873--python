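"""Raster and table I/O.

GeoTIFF support is implemented directly on :mod:`tifffile` using the GeoTIFF
tag set: ModelPixelScale (33550), ModelTiepoint (33922), ModelTransformation
(34264), the GDAL nodata tag (42113) and the GeoKey directory (34735) with its
ASCII parameters (34737).  Single-band integer rasters only — class codes are
categories, so float bands are rejected rather than silently cast.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_geotiff", "write_geotiff", "write_table"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORMATION = 34264
_TAG_GEO_KEYS = 34735
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113

# GeoKey ids carrying an EPSG code (geographic / projected CRS)
_EPSG_KEYS = (3072, 2048)
_CITATION_KEYS = (1026, 2049, 3073)


def read_geotiff(path):
    """Read a single-band integer GeoTIFF (or plain TIFF).

    Returns ``(cells, res, nodata, transform, crs)`` where ``res`` is the
    ``(x, y)`` cell size, ``transform`` the 6-tuple affine
    ``(a, b, c, d, e, f)`` mapping (col, row) to (x, y) as
    ``x = a*col + b*row + c``, ``y = d*col + e*row + f`` (GDAL convention),
    and ``nodata``/``crs`` are ``None`` when the file carries no metadata for
    them.  Non-geo TIFFs yield ``res=(1.0, 1.0)`` and ``transform=None``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if page.samplesperpixel != 1 or len(tif.pages) > 1:
                raise ValueError(f"only single-band rasters are supported: {path}")
            cells = page.asarray()
            if not np.issubdtype(cells.dtype, np.integer):
                raise TypeError(
                    f"raster band must be integer (categorical class codes), "
                    f"got dtype {cells.dtype}: {path}"
                )
            tags = page.tags
            transform = None
            res = (1.0, 1.0)
            if _TAG_PIXEL_SCALE in tags:
                sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
                res = (float(sx), float(sy))
                x0 = y0 = 0.0
                if _TAG_TIEPOINT in tags:
                    tp = tags[_TAG_TIEPOINT].value
                    # (i, j, k, X, Y, Z): raster point (i, j) maps to (X, Y)
                    x0 = float(tp[3]) - float(tp[0]) * res[0]
                    y0 = float(tp[4]) + float(tp[1]) * res[1]
                transform = (res[0], 0.0, x0, 0.0, -res[1], y0)
            elif _TAG_TRANSFORMATION in tags:
                m = tags[_TAG_TRANSFORMATION].value
                transform = (float(m[0]), float(m[1]), float(m[3]),
                             float(m[4]), float(m[5]), float(m[7]))
                res = (abs(transform[0]), abs(transform[4]))
            nodata = None
            if _TAG_GDAL_NODATA in tags:
                raw = tags[_TAG_GDAL_NODATA].value
                if isinstance(raw, bytes):
                    raw = raw.decode()
                nodata = int(float(str(raw).strip("\x00 ")))
            crs = _read_crs(tags)
    except tifffile.TiffFileError as exc:
        raise IOError(f"could not read raster {path}: {exc}") from exc
    except (ValueError, TypeError):
        raise
    except Exception as exc:  # malformed / non-TIFF input
        raise IOError(f"could not read raster {path}: {exc}") from exc
    return cells, res, nodata, transform, crs


def _read_crs(tags):
    ascii_params = tags[_TAG_GEO_ASCII].value if _TAG_GEO_ASCII in tags else ""
    if isinstance(ascii_params, bytes):
        ascii_params = ascii_params.decode(errors="replace")
    elif not isinstance(ascii_params, str):
        ascii_params = bytes(np.asarray(ascii_params, dtype=np.uint8)).decode(errors="replace")
    if _TAG_GEO_KEYS in tags:
        directory = np.asarray(tags[_TAG_GEO_KEYS].value).ravel()
        # entries of 4 shorts: key, tag location, count, value/offset
        entries = {}
        for i in range(4, len(directory) - 3, 4):
            key, loc, count, value = directory[i : i + 4]
            entries[int(key)] = (int(loc), int(count), int(value))
        for key in _EPSG_KEYS:
            if key in entries and entries[key][0] == 0:
                code = entries[key][2]
                if 1024 <= code <= 32766:
                    return f"EPSG:{code}"
        for key in _CITATION_KEYS:
            if key in entries and entries[key][0] == _TAG_GEO_ASCII:
                _, count, offset = entries[key]
                text = ascii_params[offset : offset + count].rstrip("|\x00")
                if text:
                    return text
    return ascii_params.rstrip("|\x00") or None


def write_geotiff(path, cells, res, nodata=None, transform=None, crs=None):
    """Write a single-band integer raster with GeoTIFF tags.

    ``transform`` defaults to a north-up affine with origin (0, 0); only
    axis-aligned affines can be represented through pixel-scale/tiepoint tags.
    """
    cells = np.asarray(cells)
    if not np.issubdtype(cells.dtype, np.integer):
        raise TypeError("cells must be an integer array")
    if transform is None:
        transform = (float(res[0]), 0.0, 0.0, 0.0, -float(res[1]), 0.0)
    if transform[1] != 0 or transform[3] != 0:
        raise ValueError("only axis-aligned affines are supported for writing")
    sx, sy = abs(transform[0]), abs(transform[4])
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform[2], transform[5], 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, f"{int(nodata)}"))
    geokeys = [(1025, 0, 1, 1)]  # RasterPixelIsArea
    ascii_params = ""
    if crs is not None:
        crs = str(crs)
        if crs.upper().startswith("EPSG:") and crs[5:].isdigit():
            geokeys.append((3072, 0, 1, int(crs[5:])))
        else:
            text = crs + "|"
            geokeys.append((1026, _TAG_GEO_ASCII, len(text), 0))
            ascii_params = text
    directory = [1, 1, 0, len(geokeys)]
    for entry in sorted(geokeys):
        directory.extend(entry)
    extratags.append((_TAG_GEO_KEYS, "H", len(directory), tuple(directory)))
    if ascii_params:
        payload = ascii_params.encode() + b"\x00"
        extratags.append((_TAG_GEO_ASCII, "B", len(payload), payload))
    tifffile.imwrite(path, cells, photometric="minisblack", extratags=extratags)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a metrics table as CSV: index columns first, then metric columns,
    header row, '.' decimal separator, NaN rendered as an empty field."""
    table.to_csv(path, na_rep="")
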