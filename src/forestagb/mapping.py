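"""Wall-to-wall biomass mapping from gridded cloud metrics.

The normalized cloud is partitioned into square cells, each cell's metric
vector is computed exactly as for a field plot, and the trained per-component
models predict biomass cell by cell.  Cells with fewer returns than
``min_returns`` are masked (nodata).  Components are predicted independently,
so the predicted component rasters need not sum to the predicted total; the
``sum_minus_total`` diagnostic raster quantifies the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .metrics import MetricConfig, PointCloud, extract_features

__all__ = ["GridSpec", "BiomassRaster", "gridded_features", "predict_map"]


@dataclass(frozen=True)
class GridSpec:
    """Regular mapping grid: cells of ``cell_size`` m from ``origin``,
    ``nx`` columns (x) by ``ny`` rows (y)."""

    cell_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)
    extent: tuple[int, int] = (1, 1)  # (nx, ny)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.extent[0] < 1 or self.extent[1] < 1:
            raise ValueError("grid extent must be at least 1x1")

    @property
    def n_cells(self) -> int:
        return self.extent[0] * self.extent[1]


@dataclass(frozen=True)
class BiomassRaster:
    """Per-component 2-D biomass arrays (Mg/ha, shape ny×nx) plus nodata mask."""

    grid: GridSpec
    components: dict[str, np.ndarray]
    mask: np.ndarray  # True where nodata

    def __post_init__(self) -> None:
        nx, ny = self.grid.extent
        for name, arr in self.components.items():
            if arr.shape != (ny, nx):
                raise ValueError(f"component {name!r} has shape {arr.shape}, expected {(ny, nx)}")
            valid = arr[~self.mask]
            if valid.size and (np.any(~np.isfinite(valid)) or np.any(valid < 0)):
                raise ValueError(f"component {name!r} has non-finite or negative unmasked cells")


def gridded_features(
    cloud: PointCloud,
    grid: GridSpec,
    config: MetricConfig | None = None,
    min_returns: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell feature vectors for a normalized cloud.

    Returns a frame with one row per unmasked cell (index ``cell_<row>_<col>``)
    and the boolean nodata mask (ny×nx).  A cell is masked when it holds fewer
    than ``min_returns`` returns.
    """
    config = config or MetricConfig()
    if not cloud.normalized:
        raise ValueError("cloud must be normalized")
    nx, ny = grid.extent
    x0, y0 = grid.origin
    col = np.floor((cloud.x - x0) / grid.cell_size).astype(int)
    row = np.floor((cloud.y - y0) / grid.cell_size).astype(int)
    # points exactly on the far edge belong to the last cell
    on_x_edge = cloud.x == x0 + nx * grid.cell_size
    on_y_edge = cloud.y == y0 + ny * grid.cell_size
    col[on_x_edge] -= 1
    row[on_y_edge] -= 1
    inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)

    mask = np.ones((ny, nx), dtype=bool)
    rows = {}
    for r in range(ny):
        for c in range(nx):
            sel = inside & (row == r) & (col == c)
            n = int(np.count_nonzero(sel))
            if n < min_returns:
                continue
            cell_cloud = PointCloud(
                x=cloud.x[sel], y=cloud.y[sel], z=cloud.z[sel], normalized=True
            )
            rows[f"cell_{r}_{c}"] = extract_features(cell_cloud, config).values
            mask[r, c] = False
    feats = pd.DataFrame.from_dict(rows, orient="index")
    if len(feats):
        feats = feats[list(config.metric_registry)]
    feats.index.name = "cell"
    return feats, mask


def predict_map(
    models: Mapping[str, object],
    cell_features: pd.DataFrame,
    mask: np.ndarray,
    grid: GridSpec,
    selected_features: Mapping[str, list[str]] | None = None,
    clip_negative: bool = True,
) -> BiomassRaster:
    """Predict per-cell biomass with one trained model per component.

    ``selected_features[name]`` restricts the predictor columns per component
    (matching what each model was trained on); a missing column is an error
    naming it.  Masked cells stay nodata.  A ``sum_minus_total`` diagnostic
    layer (stem+bark+branch+leaf − total) is added when all five components
    are present.
    """
    nx, ny = grid.extent
    out: dict[str, np.ndarray] = {}
    cell_rc = [tuple(map(int, idx.split("_")[1:])) for idx in cell_features.index]
    for name, model in models.items():
        cols = list(selected_features[name]) if selected_features else list(cell_features.columns)
        missing = [c for c in cols if c not in cell_features.columns]
        if missing:
            raise KeyError(f"component {name!r}: missing predictor column(s) {missing}")
        arr = np.full((ny, nx), np.nan)
        if len(cell_features):
            preds = np.asarray(model.predict(cell_features[cols].to_numpy(dtype=float)))
            if clip_negative:
                preds = np.maximum(preds, 0.0)
            for (r, c), v in zip(cell_rc, preds):
                arr[r, c] = v
        out[name] = arr
    if set(out) >= {"total", "stem", "bark", "branch", "leaf"}:
        diag = out["stem"] + out["bark"] + out["branch"] + out["leaf"] - out["total"]
        raster = BiomassRaster(grid=grid, components=out, mask=mask)
        raster.components["sum_minus_total"] = diag
        return raster
    return BiomassRaster(grid=grid, components=out, mask=mask)
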