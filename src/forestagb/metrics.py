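"""Area-based LiDAR canopy height metrics.

Given a height-normalized point cloud clipped to a plot, this module computes
the standard area-based feature set used for plot-level biomass regression:

* height percentiles ``H_p`` of the returns above a cutoff (default 2 m),
* accumulated-interval-height percentiles ``AIH_p`` — the height at which the
  running sum of sorted return heights reaches p% of the total height sum,
* moment/summary statistics (mean, quadratic mean, dispersion, shape),
* layer densities ``d1..d10`` — the fraction of all returns falling in each of
  10 equal height layers between the cutoff and the maximum height,
* a few canopy-shape metrics (relief ratio, cover fractions, spread).

The default registry has 56 metrics.  Only returns strictly above the cutoff
enter the height statistics; the density denominator is the *full* clipped
cloud (ground included), so the ``d`` metrics are sensitive to canopy cover.
Percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "PointCloud",
    "DemGrid",
    "MetricConfig",
    "FeatureVector",
    "DEFAULT_PERCENTILES",
    "normalize_heights",
    "clip_to_plot",
    "height_percentiles",
    "aih_percentiles",
    "moment_metrics",
    "density_metrics",
    "extract_features",
    "ALIASES",
]

#: percentile levels of the default registry (15 levels, shared by H_p and AIH_p)
DEFAULT_PERCENTILES = (1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99)

MOMENT_NAMES = (
    "H_mean",
    "H_sqrt",
    "H_std",
    "H_cv",
    "H_skew",
    "H_curt",
    "H_mad",
    "H_aad",
    "H_min",
    "H_max",
    "H_median",
)

SHAPE_NAMES = ("H_crr", "pct_above_cutoff", "pct_above_mean", "H_spread", "d_cv")

#: decile-style shorthand used in some reports -> registry names
ALIASES = {f"H_{i}": f"H_p{i * 10}" for i in range(1, 10)}
ALIASES.update({f"AIH_{i}": f"AIH_p{i * 10}" for i in range(1, 10)})


@dataclass(frozen=True)
class PointCloud:
    """Return coordinates (m).  ``normalized`` means z is height above ground."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if not (x.shape == y.shape == z.shape and x.ndim == 1):
            raise ValueError("x, y, z must be 1-D arrays of equal length")
        if x.size and not np.all(np.isfinite(z)):
            raise ValueError("z contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class DemGrid:
    """Regular ground-elevation grid: ``values[i, j]`` at
    ``(x0 + j*cell_size, y0 + i*cell_size)`` (row 0 at the southern edge)."""

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("DEM grid must be 2-D with at least 2x2 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "values", v)

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + self.cell_size * np.arange(self.values.shape[1])

    @property
    def y_coords(self) -> np.ndarray:
        return self.y0 + self.cell_size * np.arange(self.values.shape[0])


def _default_registry() -> tuple[str, ...]:
    names = [f"H_p{p}" for p in DEFAULT_PERCENTILES]
    names += [f"AIH_p{p}" for p in DEFAULT_PERCENTILES]
    names += list(MOMENT_NAMES)
    names += [f"d{i}" for i in range(1, 11)]
    names += list(SHAPE_NAMES)
    return tuple(names)


@dataclass(frozen=True)
class MetricConfig:
    height_cutoff: float = 2.0
    percentile_set: tuple[int, ...] = DEFAULT_PERCENTILES
    aih_percentile_set: tuple[int, ...] = DEFAULT_PERCENTILES
    n_density_layers: int = 10
    metric_registry: tuple[str, ...] = field(default_factory=_default_registry)
    density_denominator: str = "all"  # "all" returns or only "above_cutoff"

    def __post_init__(self) -> None:
        for ps in (self.percentile_set, self.aih_percentile_set):
            arr = np.asarray(ps, dtype=float)
            if np.any(arr <= 0) or np.any(arr >= 100) or np.any(np.diff(arr) <= 0):
                raise ValueError("percentile sets must be strictly increasing within (0, 100)")
        if self.n_density_layers < 1:
            raise ValueError("n_density_layers must be >= 1")
        if len(set(self.metric_registry)) != len(self.metric_registry):
            raise ValueError("metric registry contains duplicate names")
        if self.density_denominator not in ("all", "above_cutoff"):
            raise ValueError("density_denominator must be 'all' or 'above_cutoff'")


@dataclass(frozen=True)
class FeatureVector:
    """Named metric values for one plot, ordered by the registry."""

    plot_id: str
    values: dict[str, float]

    def to_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def normalize_heights(cloud: PointCloud, dem: DemGrid) -> PointCloud:
    """Subtract the bilinearly interpolated DEM elevation from each return's z.

    Every point must fall inside the DEM extent; offenders are counted and
    reported in the error.
    """
    if cloud.normalized:
        raise ValueError("cloud is already normalized")
    xs, ys = dem.x_coords, dem.y_coords
    outside = (
        (cloud.x < xs[0]) | (cloud.x > xs[-1]) | (cloud.y < ys[0]) | (cloud.y > ys[-1])
    )
    n_out = int(np.count_nonzero(outside))
    if n_out:
        raise ValueError(f"{n_out} point(s) fall outside the DEM extent")
    interp = RegularGridInterpolator((ys, xs), dem.values, method="linear")
    ground = interp(np.column_stack([cloud.y, cloud.x]))
    return PointCloud(x=cloud.x, y=cloud.y, z=cloud.z - ground, normalized=True)


def clip_to_plot(cloud: PointCloud, corners: Sequence[tuple[float, float]]) -> PointCloud:
    """Keep returns inside or on the boundary of the polygon given by corners."""
    poly = shapely.Polygon(corners)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate or invalid plot polygon")
    keep = shapely.covers(poly, shapely.points(np.column_stack([cloud.x, cloud.y])))
    return PointCloud(
        x=cloud.x[keep], y=cloud.y[keep], z=cloud.z[keep], normalized=cloud.normalized
    )


def height_percentiles(z_above: np.ndarray, percentiles: Sequence[float]) -> dict[str, float]:
    """``H_p``: linear-interpolation percentiles of above-cutoff heights."""
    z = np.asarray(z_above, dtype=float)
    if z.size == 0:
        return {f"H_p{_fmt(p)}": np.nan for p in percentiles}
    vals = np.percentile(z, list(percentiles))
    return {f"H_p{_fmt(p)}": float(v) for p, v in zip(percentiles, vals)}


def aih_percentiles(z_above: np.ndarray, percentiles: Sequence[float]) -> dict[str, float]:
    """``AIH_p``: height at which the running sum of sorted heights reaches
    p% of the total height sum (first order statistic at or past the mark)."""
    z = np.sort(np.asarray(z_above, dtype=float))
    if z.size == 0:
        return {f"AIH_p{_fmt(p)}": np.nan for p in percentiles}
    csum = np.cumsum(z)
    total = csum[-1]
    out = {}
    for p in percentiles:
        idx = int(np.searchsorted(csum, p / 100.0 * total, side="left"))
        out[f"AIH_p{_fmt(p)}"] = float(z[min(idx, z.size - 1)])
    return out


def moment_metrics(z_above: np.ndarray) -> dict[str, float]:
    """Summary statistics of above-cutoff heights.

    ``H_sqrt`` is the quadratic mean sqrt(mean(z²)); ``H_mad`` the median
    absolute deviation from the median (unscaled); ``H_aad`` the mean absolute
    deviation from the mean; ``H_skew``/``H_curt`` the moment skewness and
    (non-excess) kurtosis m3/m2^1.5 and m4/m2².  Dispersion and shape metrics
    need at least two points; missing values are NaN.
    """
    z = np.asarray(z_above, dtype=float)
    out = dict.fromkeys(MOMENT_NAMES, np.nan)
    if z.size == 0:
        return out
    mean = float(np.mean(z))
    out["H_mean"] = mean
    out["H_sqrt"] = float(np.sqrt(np.mean(z**2)))
    out["H_min"] = float(np.min(z))
    out["H_max"] = float(np.max(z))
    out["H_median"] = float(np.median(z))
    out["H_mad"] = float(np.median(np.abs(z - np.median(z))))
    out["H_aad"] = float(np.mean(np.abs(z - mean)))
    if z.size >= 2:
        sd = float(np.std(z, ddof=1))
        out["H_std"] = sd
        out["H_cv"] = sd / mean if mean != 0 else np.nan
        if sd > 0:
            out["H_skew"] = float(stats.skew(z, bias=True))
            out["H_curt"] = float(stats.kurtosis(z, fisher=False, bias=True))
    return out


def density_metrics(
    z: np.ndarray,
    cutoff: float = 2.0,
    n_layers: int = 10,
    denominator: str = "all",
) -> dict[str, float]:
    """Layer densities d1..dn over equal height bins on [cutoff, max z].

    ``d_i`` is the point count of layer i divided by the total return count of
    the cloud (``denominator="all"``, ground included) or by the above-cutoff
    count (``denominator="above_cutoff"``).  The top bin is closed, so the sum
    over layers equals (above-cutoff count) / denominator exactly.  With no
    returns above the cutoff all densities are 0.
    """
    z = np.asarray(z, dtype=float)
    names = [f"d{i}" for i in range(1, n_layers + 1)]
    above = z[z > cutoff]
    if above.size == 0 or z.size == 0:
        return dict.fromkeys(names, 0.0)
    denom = z.size if denominator == "all" else above.size
    zmax = float(np.max(above))
    if zmax == cutoff:  # degenerate span: everything in the first layer
        counts = np.zeros(n_layers)
        counts[0] = above.size
    else:
        edges = np.linspace(cutoff, zmax, n_layers + 1)
        counts, _ = np.histogram(above, bins=edges)
    return {name: float(c) / denom for name, c in zip(names, counts)}


def _fmt(p: float) -> str:
    return str(int(p)) if float(p).is_integer() else str(p)


def extract_features(cloud: PointCloud, config: MetricConfig | None = None) -> FeatureVector:
    """Compute the full metric registry for one plot cloud, in fixed order.

    Requires a normalized, nonempty cloud.  Metrics whose preconditions fail
    (e.g. no returns above the cutoff) come back as NaN / 0 per the individual
    operations.
    """
    config = config or MetricConfig()
    if not cloud.normalized:
        raise ValueError("cloud must be height-normalized before feature extraction")
    if len(cloud) == 0:
        raise ValueError("cannot extract features from an empty cloud")
    z = cloud.z
    above = z[z > config.height_cutoff]

    pool: dict[str, float] = {}
    pool.update(height_percentiles(above, config.percentile_set))
    pool.update(aih_percentiles(above, config.aih_percentile_set))
    pool.update(moment_metrics(above))
    dens = density_metrics(
        z, config.height_cutoff, config.n_density_layers, config.density_denominator
    )
    pool.update(dens)

    # canopy-shape metrics
    if above.size:
        hmin, hmax, hmean = float(above.min()), float(above.max()), float(above.mean())
        pool["H_crr"] = (hmean - hmin) / (hmax - hmin) if hmax > hmin else np.nan
        pool["pct_above_mean"] = 100.0 * float(np.mean(z > hmean))
    else:
        pool["H_crr"] = np.nan
        pool["pct_above_mean"] = 0.0
    pool["pct_above_cutoff"] = 100.0 * above.size / len(cloud)
    p_hi = pool.get("H_p99", np.nan)
    p_lo = pool.get("H_p10", np.nan)
    pool["H_spread"] = p_hi - p_lo
    dvals = np.array(list(dens.values()))
    dmean = dvals.mean()
    pool["d_cv"] = float(dvals.std(ddof=1) / dmean) if dmean > 0 and dvals.size > 1 else np.nan

    missing = [m for m in config.metric_registry if m not in pool]
    if missing:
        raise KeyError(f"registry metrics not computable with this config: {missing}")
    return FeatureVector(
        plot_id="", values={m: float(pool[m]) for m in config.metric_registry}
    )
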