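"""GeoTIFF input/output for index cubes.

One single-band GeoTIFF per time step, following the conventions of
distributed vegetation-health products: nodata sentinel ``-9999`` declared
in the ``GDAL_NODATA`` tag, georeferencing through the ModelPixelScale /
ModelTiepoint tags, geographic CRS recorded in the GeoTIFF key directory.
Values are stored rounded to six decimal places; a write/read round trip
reproduces values to six decimals and the validity mask exactly.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .core import GridSpec, RasterCube, TimeLabel, label_str

__all__ = ["read_cube", "write_cube", "read_grid", "write_field", "read_field", "DEFAULT_NODATA"]

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory for a geographic CRS (EPSG code in key 2048).
_GEOKEY_VERSION = (1, 1, 0)


def _geokeys(epsg: int) -> tuple[int, ...]:
    # header (version, revision, minor, count), then 4-entry keys:
    # GTModelTypeGeoKey=2 (geographic), GTRasterTypeGeoKey=1 (PixelIsArea),
    # GeographicTypeGeoKey=epsg
    return (
        *_GEOKEY_VERSION, 3,
        1024, 0, 1, 2,
        1025, 0, 1, 1,
        2048, 0, 1, epsg,
    )


def _crs_to_epsg(crs_id: str) -> int | None:
    crs = crs_id.upper().replace(" ", "")
    if crs in ("EPSG:4326", "GCS_WGS_1984", "WGS84"):
        return 4326
    if crs.startswith("EPSG:"):
        try:
            return int(crs.split(":", 1)[1])
        except ValueError:
            return None
    return None


def _epsg_to_crs(epsg: int) -> str:
    return f"EPSG:{epsg}"


def write_cube(
    cube: RasterCube,
    out_dir: str | os.PathLike,
    name_pattern: str = "VHIopt_{year}.tif",
    nodata: float = DEFAULT_NODATA,
) -> list[Path]:
    """Write one GeoTIFF per time step; return the files written.

    ``name_pattern`` receives the formatted time label under the key
    ``year`` (``1981`` for annual cubes, ``1981_07`` for monthly/weekly).
    Values are rounded to six decimal places; invalid cells carry
    ``nodata``.
    """
    if cube.n_times == 0:
        raise ValueError("cannot write an empty cube")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = cube.grid
    epsg = _crs_to_epsg(grid.crs_id)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size_x, grid.pixel_size_y, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(int(nodata) if float(nodata).is_integer() else nodata), True),
    ]
    if epsg is not None:
        keys = _geokeys(epsg)
        extratags.append((_TAG_GEO_KEYS, "H", len(keys), keys, True))

    paths: list[Path] = []
    for i, label in enumerate(cube.times):
        layer = np.round(cube.values[i], 6).astype(np.float64)
        layer = np.where(cube.valid[i], layer, float(nodata))
        path = out_dir / name_pattern.format(year=label_str(label))
        tifffile.imwrite(path, layer, extratags=extratags)
        paths.append(path)
    return paths


def write_field(
    values: np.ndarray,
    valid: np.ndarray,
    grid: GridSpec,
    path: str | os.PathLike,
    nodata: float = DEFAULT_NODATA,
) -> Path:
    """Write one 2D field (e.g. ``a_opt`` or a trend slope) as a GeoTIFF."""
    cube = RasterCube(grid, [0], values[None], np.asarray(valid, bool)[None])
    path = Path(path)
    written = write_cube(cube, path.parent, name_pattern=path.name, nodata=nodata)
    return written[0]


def read_field(
    path: str | os.PathLike, background_value: float = DEFAULT_NODATA
) -> tuple[np.ndarray, np.ndarray, GridSpec]:
    """Read one 2D field: returns (values, valid, grid)."""
    data, grid, file_nodata = _read_page(Path(path))
    invalid = ~np.isfinite(data) | (data == background_value)
    if file_nodata is not None:
        invalid |= data == file_nodata
    return np.where(invalid, 0.0, data), ~invalid, grid


def _read_page(path: Path) -> tuple[np.ndarray, GridSpec, float | None]:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = np.asarray(page.asarray(), dtype=float)
            tag_values = {code: tag.value for code, tag in page.tags.items()}
    except (FileNotFoundError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read raster file {path}: {exc}") from exc
    if data.ndim != 2:
        raise IOError(f"{path}: expected a single-band raster, got shape {data.shape}")

    psx, psy = 1.0, 1.0
    ox, oy = 0.0, float(data.shape[0])
    if _TAG_PIXEL_SCALE in tag_values:
        scale = tag_values[_TAG_PIXEL_SCALE]
        psx, psy = float(scale[0]), float(scale[1])
    if _TAG_TIEPOINT in tag_values:
        tie = tag_values[_TAG_TIEPOINT]
        # tie: raster (i, j, k) -> model (x, y, z); offset back to corner
        ox = float(tie[3]) - float(tie[0]) * psx
        oy = float(tie[4]) + float(tie[1]) * psy

    crs = "EPSG:4326"
    if _TAG_GEO_KEYS in tag_values:
        keys = tuple(tag_values[_TAG_GEO_KEYS])
        for k in range(4, len(keys) - 3, 4):
            if keys[k] == 2048 and keys[k + 1] == 0:
                crs = _epsg_to_crs(int(keys[k + 3]))

    nodata: float | None = None
    if _TAG_GDAL_NODATA in tag_values:
        try:
            nodata = float(tag_values[_TAG_GDAL_NODATA])
        except (TypeError, ValueError):
            nodata = None

    grid = GridSpec(
        n_rows=data.shape[0], n_cols=data.shape[1],
        origin_x=ox, origin_y=oy, pixel_size_x=psx, pixel_size_y=psy,
        crs_id=crs,
    )
    return data, grid, nodata


def read_grid(path: str | os.PathLike) -> GridSpec:
    """Georeferencing of a single GeoTIFF, without loading a cube."""
    _, grid, _ = _read_page(Path(path))
    return grid


def read_cube(
    paths: Sequence[str | os.PathLike],
    time_labels: Sequence[TimeLabel],
    background_value: float = DEFAULT_NODATA,
    freq: str = "annual",
) -> RasterCube:
    """Read a stack of single-band GeoTIFFs into a cube.

    Cells equal to ``background_value``, equal to the file's declared
    nodata, or non-finite are masked invalid. All files must share one
    grid; a mismatch is a hard error naming the offending file.
    """
    if len(paths) == 0:
        raise ValueError("no input files")
    if len(paths) != len(time_labels):
        raise ValueError(
            f"{len(paths)} files but {len(time_labels)} time labels"
        )
    layers: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    ref_grid: GridSpec | None = None
    for path in paths:
        data, grid, file_nodata = _read_page(Path(path))
        if ref_grid is None:
            ref_grid = grid
        elif not grid.approx_equal(ref_grid):
            raise ValueError(
                f"grid of {path} does not match grid of {paths[0]}"
            )
        invalid = ~np.isfinite(data) | (data == background_value)
        if file_nodata is not None:
            invalid |= data == file_nodata
        data = np.where(invalid, 0.0, data)
        layers.append(data)
        masks.append(~invalid)
    assert ref_grid is not None
    return RasterCube(
        grid=ref_grid,
        times=list(time_labels),
        values=np.stack(layers),
        valid=np.stack(masks),
        freq=freq,
    )
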