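"""Species-specific allometric biomass equations with component partitioning.

Tree-level aboveground biomass (AGB) follows the power law ``M = a0 * D^a1 * H^a2``
with D the diameter at breast height (cm) and H the tree height (m).  Total mass
is split into stem, bark, branch and leaf components through the proportion
functions ``g1, g2, g3`` (bark, branch, leaf mass relative to a stem mass of 1),
each itself a power law in D and H.  Component fractions are

    f_stem = 1 / (1 + g1 + g2 + g3),    f_bark = g1 / (1 + g1 + g2 + g3),  ...

so the four components partition the total exactly.

Two boreal taxa are modeled: *Larix gmelinii* (larch) and *Betula platyphylla*
(birch).  The published birch total-AGB exponents (0.10850 on D, 0.52019 on H)
yield implausibly small masses for mature stems (< 1 kg at D = 20 cm); they are
kept as published but every coefficient is overridable via
:class:`SpeciesCoefficients`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import PlotInventory

__all__ = [
    "SpeciesCoefficients",
    "BiomassComponents",
    "DEFAULT_COEFFICIENTS",
    "COMPONENTS",
    "tree_total_agb",
    "component_fractions",
    "tree_component_agb",
    "plot_agb",
    "plot_biomass_table",
]

#: component names in canonical order (stem first, then the g1/g2/g3 components)
COMPONENTS = ("stem", "bark", "branch", "leaf")


@dataclass(frozen=True)
class SpeciesCoefficients:
    """Power-law coefficients for one species.

    ``total`` is ``(a0, a1, a2)`` of ``M = a0 * D^a1 * H^a2`` (kg, D in cm, H in m);
    ``g1``/``g2``/``g3`` are each ``(c0, c1, c2)`` of ``g = c0 * D^c1 * H^c2`` and give
    bark, branch and leaf mass relative to a stem mass of 1.
    """

    total: tuple[float, float, float]
    g1: tuple[float, float, float]
    g2: tuple[float, float, float]
    g3: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("total", "g1", "g2", "g3"):
            c = getattr(self, name)
            if len(c) != 3 or not all(np.isfinite(c)):
                raise ValueError(f"{name} coefficients must be 3 finite numbers, got {c!r}")
        if self.total[0] <= 0:
            raise ValueError(f"leading total coefficient must be positive, got {self.total[0]}")


# Published coefficients.  The larch total leading coefficient is printed without
# a decimal point in the source table; 0.060848 is adopted (the alternative
# 0.60848 puts a single 20 cm stem at ~1.4 Mg, an order of magnitude above the
# plot-level biomass the same study reports).
DEFAULT_COEFFICIENTS: dict[str, SpeciesCoefficients] = {
    "larch": SpeciesCoefficients(
        total=(0.060848, 2.01549, 0.59146),
        g1=(0.36742, -0.16892, -0.17313),
        g2=(2.30634, 0.72188, -1.45081),
        g3=(1.57804, 0.19527, -1.36274),
    ),
    "birch": SpeciesCoefficients(
        total=(0.06807, 0.10850, 0.52019),
        g1=(0.53498, 0.09004, -0.46520),
        g2=(1.05167, 0.66925, -1.04662),
        g3=(0.61793, 0.17097, -0.88182),
    ),
}


@dataclass(frozen=True)
class BiomassComponents:
    """Total and component masses: kg at tree scale, Mg/ha at plot scale."""

    total: float
    stem: float
    bark: float
    branch: float
    leaf: float
    scale: str = "tree"  # "tree" | "plot"

    def __post_init__(self) -> None:
        if self.scale not in ("tree", "plot"):
            raise ValueError(f"scale must be 'tree' or 'plot', got {self.scale!r}")
        parts = self.stem + self.bark + self.branch + self.leaf
        tol = 1e-9 * max(self.total, 1.0)
        if abs(parts - self.total) > tol:
            raise ValueError(
                f"components sum to {parts!r}, total is {self.total!r} (beyond 1e-9 relative)"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "total": self.total,
            "stem": self.stem,
            "bark": self.bark,
            "branch": self.branch,
            "leaf": self.leaf,
        }


def _coeffs(
    species: str, coefficients: Mapping[str, SpeciesCoefficients] | None
) -> SpeciesCoefficients:
    table = DEFAULT_COEFFICIENTS if coefficients is None else coefficients
    try:
        return table[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; known: {sorted(table)}"
        ) from None


def _check_dims(dbh, height) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(~np.isfinite(h)) or np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("DBH and height must be finite and positive")
    return d, h


def tree_total_agb(
    species: str,
    dbh,
    height,
    coefficients: Mapping[str, SpeciesCoefficients] | None = None,
):
    """Total tree AGB in kg from DBH (cm) and height (m).  Accepts arrays."""
    c = _coeffs(species, coefficients)
    d, h = _check_dims(dbh, height)
    a0, a1, a2 = c.total
    out = a0 * d**a1 * h**a2
    return float(out) if out.ndim == 0 else out


def component_fractions(
    species: str,
    dbh,
    height,
    coefficients: Mapping[str, SpeciesCoefficients] | None = None,
):
    """Mass fractions (f_stem, f_bark, f_branch, f_leaf); they sum to 1 exactly."""
    c = _coeffs(species, coefficients)
    d, h = _check_dims(dbh, height)
    gs = [c0 * d**c1 * h**c2 for (c0, c1, c2) in (c.g1, c.g2, c.g3)]
    denom = 1.0 + gs[0] + gs[1] + gs[2]
    fracs = (1.0 / denom, gs[0] / denom, gs[1] / denom, gs[2] / denom)
    if d.ndim == 0:
        return tuple(float(f) for f in fracs)
    return fracs


def tree_component_agb(
    species: str,
    dbh: float,
    height: float,
    coefficients: Mapping[str, SpeciesCoefficients] | None = None,
) -> BiomassComponents:
    """Tree-scale component masses (kg).  Sum of components equals the total."""
    total = tree_total_agb(species, dbh, height, coefficients)
    f_stem, f_bark, f_branch, f_leaf = component_fractions(species, dbh, height, coefficients)
    return BiomassComponents(
        total=total,
        stem=total * f_stem,
        bark=total * f_bark,
        branch=total * f_branch,
        leaf=total * f_leaf,
        scale="tree",
    )


def plot_agb(
    plot: "PlotInventory",
    dbh_min: float = 5.0,
    coefficients: Mapping[str, SpeciesCoefficients] | None = None,
) -> BiomassComponents:
    """Plot-scale AGB (Mg/ha): per-tree masses summed over stems with
    DBH >= ``dbh_min`` (the inventory censoring threshold), divided by plot
    area in hectares.
    """
    if plot.area <= 0:
        raise ValueError(f"plot area must be positive, got {plot.area}")
    sums = dict.fromkeys(("total",) + COMPONENTS, 0.0)
    for tree in plot.trees:
        if tree.dbh < dbh_min:
            continue
        comp = tree_component_agb(tree.species, tree.dbh, tree.height, coefficients)
        for key, val in comp.as_dict().items():
            sums[key] += val
    ha = plot.area / 10_000.0
    scale = 1.0 / (1000.0 * ha)  # kg -> Mg, per hectare
    return BiomassComponents(
        total=sums["total"] * scale,
        stem=sums["stem"] * scale,
        bark=sums["bark"] * scale,
        branch=sums["branch"] * scale,
        leaf=sums["leaf"] * scale,
        scale="plot",
    )


def plot_biomass_table(
    plots: Iterable["PlotInventory"],
    dbh_min: float = 5.0,
    coefficients: Mapping[str, SpeciesCoefficients] | None = None,
) -> pd.DataFrame:
    """Plot-level biomass table (Mg/ha), one row per plot, indexed by plot_id."""
    rows = {}
    for plot in plots:
        rows[plot.plot_id] = plot_agb(plot, dbh_min=dbh_min, coefficients=coefficients).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "plot_id"
    return df
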