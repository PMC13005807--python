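"""Dorling cartogram layout: non-overlapping circles with area ~ value.

Each administrative unit becomes a circle of radius ``k * sqrt(value)``
anchored at the unit centroid.  An iterative relaxation pushes
overlapping pairs apart along their centre line proportionally to the
overlap depth, and gently attracts circles that are currently free of
overlaps back toward their seed positions.  The layout is deterministic
for a given input order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from gridepi.exceptions import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class DorlingCircle:
    unit_id: object
    seed_x: float
    seed_y: float
    x: float
    y: float
    radius: float
    value: float


def default_scale(units: pd.DataFrame, fill: float = 0.55) -> float:
    """Radius scale ``k`` so the circles fill roughly ``fill`` of the seed
    bounding box (with a fallback for degenerate extents)."""
    pop = units["population"].to_numpy(dtype=float)
    w = units["x"].max() - units["x"].min()
    h = units["y"].max() - units["y"].min()
    area = float(w * h)
    if area <= 0:
        area = float(pop.sum())  # arbitrary positive reference
    return math.sqrt(fill * area / (math.pi * float(pop.sum())))


def dorling_layout(
    units: pd.DataFrame,
    k: Optional[float] = None,
    max_iter: int = 512,
    tolerance: float = 1e-6,
    repulsion: float = 0.8,
    attraction: float = 0.05,
) -> List[DorlingCircle]:
    """Compute the circle layout.

    Parameters
    ----------
    units:
        Table with ``unit_id, x, y, population`` columns (centroid
        coordinates in planar metres; populations strictly positive).
    k:
        Radius scale (``radius = k * sqrt(population)``); derived from
        the seed extent when omitted.
    max_iter, tolerance:
        Relaxation stops when the maximum pairwise overlap drops below
        ``tolerance`` (in metres) or after ``max_iter`` sweeps.
    repulsion, attraction:
        Damping of the pairwise separation step and of the drift back
        toward seed positions.

    Returns
    -------
    list of DorlingCircle, in input (unit ID) order.
    """
    units = units.sort_values("unit_id").reset_index(drop=True)
    pop = units["population"].to_numpy(dtype=float)
    if np.any(pop <= 0) or not np.all(np.isfinite(units[["x", "y"]].to_numpy())):
        raise ConfigurationError("populations must be > 0 and centroids finite")
    if k is None:
        k = default_scale(units)
    n = len(units)
    r = k * np.sqrt(pop)
    sx = units["x"].to_numpy(dtype=float)
    sy = units["y"].to_numpy(dtype=float)
    px, py = sx.copy(), sy.copy()

    for it in range(max_iter):
        dx = px[:, None] - px[None, :]
        dy = py[:, None] - py[None, :]
        dist = np.hypot(dx, dy)
        overlap = r[:, None] + r[None, :] - dist
        np.fill_diagonal(overlap, -np.inf)
        max_overlap = float(overlap.max()) if n > 1 else -math.inf
        if max_overlap < tolerance:
            break

        fx = np.zeros(n)
        fy = np.zeros(n)
        ii, jj = np.nonzero(np.triu(overlap > 0, k=1))
        for i, j in zip(ii, jj):
            d = dist[i, j]
            if d > 0:
                ux, uy = dx[i, j] / d, dy[i, j] / d
            else:
                # coincident centres: deterministic direction from indices
                theta = 2.0 * math.pi * ((0.6180339887 * (i * n + j)) % 1.0)
                ux, uy = math.cos(theta), math.sin(theta)
            step = 0.5 * overlap[i, j] * repulsion
            fx[i] += ux * step
            fy[i] += uy * step
            fx[j] -= ux * step
            fy[j] -= uy * step

        free = ~np.any(overlap > 0, axis=1)
        fx[free] += attraction * (sx[free] - px[free])
        fy[free] += attraction * (sy[free] - py[free])
        px += fx
        py += fy

        disp = float(np.hypot(px - sx, py - sy).sum())
        log.debug(
            "dorling iter=%d max_overlap=%.3g total_displacement=%.3g", it, max_overlap, disp
        )

    return [
        DorlingCircle(
            unit_id=units["unit_id"].iloc[i],
            seed_x=float(sx[i]),
            seed_y=float(sy[i]),
            x=float(px[i]),
            y=float(py[i]),
            radius=float(r[i]),
            value=float(pop[i]),
        )
        for i in range(n)
    ]


def max_overlap(circles: List[DorlingCircle]) -> float:
    """Largest pairwise overlap depth of a layout (negative if disjoint)."""
    worst = -math.inf
    for i in range(len(circles)):
        for j in range(i + 1, len(circles)):
            a, b = circles[i], circles[j]
            worst = max(
                worst, a.radius + b.radius - math.hypot(a.x - b.x, a.y - b.y)
            )
    return worst


def unit_centroids(grid: pd.DataFrame) -> pd.DataFrame:
    """Population and population-weighted centroid per unit, from a grid."""
    g = grid.copy()
    g["wx"] = g["x"] * g["population"]
    g["wy"] = g["y"] * g["population"]
    agg = g.groupby("unit_id").agg(
        population=("population", "sum"), wx=("wx", "sum"), wy=("wy", "sum")
    )
    agg["x"] = agg["wx"] / agg["population"]
    agg["y"] = agg["wy"] / agg["population"]
    return agg.reset_index()[["unit_id", "x", "y", "population"]]
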