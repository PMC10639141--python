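"""Synthetic stand inventories and LiDAR-like point clouds.

Emulates the sampling design the estimation pipeline assumes: square plots
(default 40 m and 45 m sides) of larch/birch mixed stands, stem DBH drawn from
a log-normal, height tied to DBH through a power-law hypsometric model, and an
area-based point cloud (default density 5.6 returns/m²) whose vertical
distribution reflects the simulated canopy.

The cloud model is deliberately simple.  Each return is either a ground return
(z ~ N(0, vertical_noise_sd)) or a canopy return attached to one tree, with
height drawn from a triangular distribution between the crown base
(``base_fraction * H``) and the tree top, mode at ``mode_fraction * H``.  The
probability that a return is ground depends on canopy closure:

    p_ground = gf + (1 - gf) * (1 - cover),   cover = 1 - exp(-sum(crown area)/area)

where ``gf`` (``ground_fraction``) is the through-canopy penetration fraction.
Sparse stands therefore produce ground-dominated clouds and dense stands
canopy-dominated ones, which is what makes layer-density metrics informative.

Clouds are generated pre-normalized (z = height above ground).  A synthetic
tilted-plane DEM and the corresponding raw-elevation cloud can also be emitted
to exercise the height-normalization step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from . import allometry
from .metrics import MetricConfig, PointCloud, extract_features

__all__ = [
    "TreeRecord",
    "PlotInventory",
    "SimConfig",
    "simulate_inventory",
    "simulate_point_cloud",
    "tilted_dem",
    "denormalize_cloud",
    "make_dataset",
    "inventory_to_frame",
    "frame_to_inventories",
]


@dataclass(frozen=True)
class TreeRecord:
    """One stem: species, DBH (cm), height (m), position in plot coords (m)."""

    species: str
    dbh: float
    height: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.species not in ("larch", "birch"):
            raise ValueError(f"species must be 'larch' or 'birch', got {self.species!r}")
        if not (np.isfinite(self.dbh) and self.dbh > 0):
            raise ValueError(f"dbh must be finite and positive, got {self.dbh}")
        if not (np.isfinite(self.height) and self.height > 0):
            raise ValueError(f"height must be finite and positive, got {self.height}")


@dataclass(frozen=True)
class PlotInventory:
    """A square plot and its tree list.  ``area`` is the side length squared."""

    plot_id: str
    side_length: float
    trees: tuple[TreeRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        for t in self.trees:
            if not (0.0 <= t.x <= self.side_length and 0.0 <= t.y <= self.side_length):
                raise ValueError(f"tree at ({t.x}, {t.y}) outside plot of side {self.side_length}")

    @property
    def area(self) -> float:
        return self.side_length**2


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Stem density is drawn per plot from ``stems_per_ha`` (uniform over the
    range), DBH from log-normal(``dbh_lognormal``) in cm with a bounded
    per-plot location shift uniform on ±``dbh_mu_plot_halfwidth`` (between-plot
    stand-size variation without a heavy upper tail), and height from
    ``H = a * D^b * exp(eps)``, ``eps ~ N(0, sigma_eps)``.
    """

    n_plots: int = 200
    side_lengths: tuple[float, ...] = (40.0, 45.0)
    species_mix: float = 0.9  # fraction larch
    stems_per_ha: tuple[float, float] = (400.0, 1400.0)
    dbh_lognormal: tuple[float, float] = (math.log(14.0), 0.35)  # (mu, sigma) of ln DBH[cm]
    dbh_mu_plot_halfwidth: float = 0.25
    height_model: tuple[float, float, float] = (1.9, 0.75, 0.08)  # (a, b, sigma_eps)
    point_density: float = 5.6  # returns per m²
    ground_fraction: float = 0.25  # canopy penetration fraction
    crown_shape: tuple[float, float] = (0.45, 0.85)  # (base_fraction, mode_fraction) of H
    crown_radius_coef: float = 0.11  # crown radius as a fraction of tree height
    vertical_noise_sd: float = 0.12  # m
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [
            self.species_mix,
            *self.stems_per_ha,
            *self.dbh_lognormal,
            self.dbh_mu_plot_halfwidth,
            *self.height_model,
            self.point_density,
            self.ground_fraction,
            *self.crown_shape,
            self.crown_radius_coef,
            self.vertical_noise_sd,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all SimConfig parameters must be finite")
        if self.n_plots < 0:
            raise ValueError("n_plots must be >= 0")
        if not (0.0 <= self.species_mix <= 1.0):
            raise ValueError("species_mix must lie in [0, 1]")
        if not (0.0 <= self.ground_fraction <= 1.0):
            raise ValueError("ground_fraction must lie in [0, 1]")
        lo, hi = self.stems_per_ha
        if lo < 0 or hi < lo:
            raise ValueError("stems_per_ha must be a nonnegative (low, high) range")
        base, mode = self.crown_shape
        if not (0.0 <= base <= mode <= 1.0):
            raise ValueError("crown_shape must satisfy 0 <= base_fraction <= mode_fraction <= 1")
        if self.point_density < 0 or self.vertical_noise_sd < 0:
            raise ValueError("point_density and vertical_noise_sd must be nonnegative")


def simulate_inventory(config: SimConfig) -> list[PlotInventory]:
    """Draw ``config.n_plots`` plot inventories.

    Draw order per plot (single seeded generator): side length, stem density,
    plot DBH-location jitter, species, DBH, height noise, positions — so a
    given seed reproduces inventories bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    a, b, sigma_eps = config.height_model
    mu, sigma = config.dbh_lognormal
    plots: list[PlotInventory] = []
    for i in range(config.n_plots):
        side = float(rng.choice(np.asarray(config.side_lengths, dtype=float)))
        density = float(rng.uniform(*config.stems_per_ha))
        mu_plot = mu + float(rng.uniform(-1.0, 1.0)) * config.dbh_mu_plot_halfwidth
        n = int(rng.poisson(density * side**2 / 10_000.0))
        is_larch = rng.random(n) < config.species_mix
        dbh = np.exp(rng.normal(mu_plot, sigma, size=n))
        eps = rng.normal(0.0, sigma_eps, size=n)
        height = a * dbh**b * np.exp(eps)
        xy = rng.uniform(0.0, side, size=(n, 2))
        trees = tuple(
            TreeRecord(
                species="larch" if is_larch[j] else "birch",
                dbh=float(dbh[j]),
                height=float(height[j]),
                x=float(xy[j, 0]),
                y=float(xy[j, 1]),
            )
            for j in range(n)
        )
        plots.append(PlotInventory(plot_id=f"plot{i:03d}", side_length=side, trees=trees))
    return plots


def _canopy_cover(plot: PlotInventory, config: SimConfig) -> float:
    crown_area = sum(math.pi * (config.crown_radius_coef * t.height) ** 2 for t in plot.trees)
    return 1.0 - math.exp(-crown_area / plot.area)


def simulate_point_cloud(
    plot: PlotInventory, config: SimConfig, rng: np.random.Generator | None = None
) -> PointCloud:
    """Simulate a normalized cloud for one plot (z = height above ground, m).

    Total count ~ Poisson(point_density * area).  Canopy returns are assigned
    to trees with probability proportional to crown area, placed uniformly in
    the crown disc, with z triangular on [base_fraction*H, H] (mode at
    mode_fraction*H) plus vertical noise.
    """
    if plot.area <= 0:
        raise ValueError("plot area must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_total = int(rng.poisson(config.point_density * plot.area))
    cover = _canopy_cover(plot, config)
    p_ground = config.ground_fraction + (1.0 - config.ground_fraction) * (1.0 - cover)
    ground = rng.random(n_total) < p_ground if plot.trees else np.ones(n_total, dtype=bool)
    n_canopy = int(np.count_nonzero(~ground))

    sd = config.vertical_noise_sd
    x = rng.uniform(0.0, plot.side_length, size=n_total)
    y = rng.uniform(0.0, plot.side_length, size=n_total)
    # vertical noise truncated at +-3 sd so ground returns stay near z = 0
    z = np.clip(rng.normal(0.0, sd, size=n_total), -3 * sd, 3 * sd)

    if n_canopy:
        heights = np.array([t.height for t in plot.trees])
        tx = np.array([t.x for t in plot.trees])
        ty = np.array([t.y for t in plot.trees])
        radii = config.crown_radius_coef * heights
        weights = radii**2 / np.sum(radii**2)
        idx = rng.choice(len(heights), size=n_canopy, p=weights)
        base_f, mode_f = config.crown_shape
        h = heights[idx]
        zc = rng.triangular(base_f * h, mode_f * h, h)
        # uniform in the crown disc, clamped into the plot square
        r = radii[idx] * np.sqrt(rng.random(n_canopy))
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n_canopy)
        xc = np.clip(tx[idx] + r * np.cos(theta), 0.0, plot.side_length)
        yc = np.clip(ty[idx] + r * np.sin(theta), 0.0, plot.side_length)
        sel = np.flatnonzero(~ground)
        x[sel], y[sel] = xc, yc
        noise = np.clip(rng.normal(0.0, sd, size=n_canopy), -3 * sd, 3 * sd)
        z[sel] = zc + noise
    return PointCloud(x=x, y=y, z=z, normalized=True)


def tilted_dem(
    plot: PlotInventory,
    base_elevation: float = 700.0,
    slope_x: float = 0.05,
    slope_y: float = -0.03,
    cell_size: float = 5.0,
) -> tuple[np.ndarray, float, float, float]:
    """Tilted-plane ground elevation grid covering the plot (one cell margin).

    Returns ``(grid, x0, y0, cell_size)`` with ``grid[i, j]`` the elevation of
    the cell-center at ``(x0 + j*cs, y0 + i*cs)``; row 0 is the southern edge.
    """
    x0 = y0 = -cell_size
    n = int(math.ceil((plot.side_length + 2 * cell_size) / cell_size)) + 1
    xs = x0 + cell_size * np.arange(n)
    ys = y0 + cell_size * np.arange(n)
    grid = base_elevation + slope_x * xs[None, :] + slope_y * ys[:, None]
    return grid, x0, y0, cell_size


def denormalize_cloud(
    cloud: PointCloud,
    dem: tuple[np.ndarray, float, float, float],
    base_elevation: float = 700.0,
    slope_x: float = 0.05,
    slope_y: float = -0.03,
) -> PointCloud:
    """Raw-elevation variant of a normalized cloud: add the plane elevation back.

    The plane parameters must match those used for :func:`tilted_dem`; with a
    planar DEM, bilinear interpolation of the grid is exact, so normalizing the
    result recovers the original z to round-off.
    """
    if not cloud.normalized:
        raise ValueError("expected a normalized cloud")
    zg = base_elevation + slope_x * cloud.x + slope_y * cloud.y
    return PointCloud(x=cloud.x, y=cloud.y, z=cloud.z + zg, normalized=False)


def make_dataset(
    config: SimConfig,
    metric_config: MetricConfig | None = None,
    dbh_min: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate plots and return aligned (features, biomass) tables.

    One row per plot in both frames, indexed by plot_id: the left frame holds
    the LiDAR metric registry, the right the allometric total and component
    AGB in Mg/ha.
    """
    metric_config = metric_config or MetricConfig()
    plots = simulate_inventory(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    feat_rows = {}
    for plot in plots:
        cloud = simulate_point_cloud(plot, config, rng=rng)
        feat_rows[plot.plot_id] = extract_features(cloud, metric_config).values
    features = pd.DataFrame.from_dict(feat_rows, orient="index")
    features.index.name = "plot_id"
    if len(features):
        features = features[list(metric_config.metric_registry)]
    responses = allometry.plot_biomass_table(plots, dbh_min=dbh_min)
    responses = responses.reindex(features.index)
    return features, responses


def inventory_to_frame(plots: Iterable[PlotInventory]) -> pd.DataFrame:
    """Flatten inventories to a tree table (CSV-friendly)."""
    rows = [
        {
            "plot_id": p.plot_id,
            "side_length": p.side_length,
            "species": t.species,
            "dbh_cm": t.dbh,
            "height_m": t.height,
            "x": t.x,
            "y": t.y,
        }
        for p in plots
        for t in p.trees
    ]
    return pd.DataFrame(
        rows, columns=["plot_id", "side_length", "species", "dbh_cm", "height_m", "x", "y"]
    )


def frame_to_inventories(frame: pd.DataFrame) -> list[PlotInventory]:
    """Inverse of :func:`inventory_to_frame` (plots with >= 1 tree only)."""
    plots = []
    for plot_id, group in frame.groupby("plot_id", sort=True):
        side = float(group["side_length"].iloc[0])
        trees = tuple(
            TreeRecord(
                species=str(r.species),
                dbh=float(r.dbh_cm),
                height=float(r.height_m),
                x=float(r.x),
                y=float(r.y),
            )
            for r in group.itertuples()
        )
        plots.append(PlotInventory(plot_id=str(plot_id), side_length=side, trees=trees))
    return plots
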