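"""Plain-text readers/writers for clouds, DEM grids and rasters.

Point clouds travel as XYZ text (one ``x y z`` triple per line); elevation
grids and biomass rasters as ESRI ASCII grids (``.asc``), the interchange
raster format every GIS reads.  Tabular products (inventories, features,
biomass, VIP tables, validation reports) are pandas CSV round-trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import BiomassRaster
from .metrics import DemGrid, PointCloud

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_raster",
]


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([cloud.x, cloud.y, cloud.z]), fmt="%.4f")


def read_xyz(path: str | Path, normalized: bool = False) -> PointCloud:
    data = np.loadtxt(path, dtype=float)
    if data.size == 0:
        data = data.reshape(0, 3)
    data = np.atleast_2d(data)
    if data.shape[1] != 3:
        raise ValueError(f"expected 3 columns (x y z), got {data.shape[1]}")
    return PointCloud(x=data[:, 0], y=data[:, 1], z=data[:, 2], normalized=normalized)


def write_ascii_grid(
    values: np.ndarray,
    path: str | Path,
    x0: float,
    y0: float,
    cell_size: float,
    nodata: float = -9999.0,
) -> None:
    """ESRI ASCII grid; ``values`` row 0 is the southern edge (written last,
    since the format stores the north row first).  NaN becomes nodata."""
    vals = np.asarray(values, dtype=float)
    out = np.where(np.isfinite(vals), vals, nodata)
    header = (
        f"ncols {vals.shape[1]}\n"
        f"nrows {vals.shape[0]}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}"
    )
    np.savetxt(path, out[::-1], header=header, comments="", fmt="%.4f")


def read_ascii_grid(path: str | Path) -> DemGrid:
    """Read an ESRI ASCII grid as a :class:`DemGrid` (cell-center registered)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
            "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    vals = np.loadtxt(lines[n_header:], dtype=float)
    vals = np.atleast_2d(vals)[::-1]  # back to south-first rows
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    cs = header["cellsize"]
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:
        x0, y0 = header["xllcorner"] + cs / 2, header["yllcorner"] + cs / 2
    return DemGrid(values=vals, x0=x0, y0=y0, cell_size=cs)


def write_raster(raster: BiomassRaster, directory: str | Path, prefix: str = "agb") -> list[Path]:
    """One ``.asc`` file per component; masked cells become nodata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x0, y0 = raster.grid.origin
    paths = []
    for name, arr in raster.components.items():
        vals = np.where(raster.mask, np.nan, arr)
        path = directory / f"{prefix}_{name}.asc"
        write_ascii_grid(vals, path, x0, y0, raster.grid.cell_size)
        paths.append(path)
    return paths
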