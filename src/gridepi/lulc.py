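"""Land-use/land-cover profiling of circular clusters.

A categorical 17-class raster is aggregated into five classes (Urban,
Agriculture, Forest, Open land, Lakes and streams) and summarised over
circular zones with a cell-centre containment rule, mirroring a standard
zonal-histogram operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from gridepi.exceptions import EmptyZoneError, LegendError

#: The five aggregate classes, in reporting order.
CLASS5: Tuple[str, ...] = (
    "Urban",
    "Agriculture",
    "Forest",
    "Open land",
    "Lakes and streams",
)

#: Default synthetic 17-class legend: raster code -> detailed class name.
DEFAULT_LEGEND_17: Dict[int, str] = {
    1: "buildings",
    2: "other built-up land",
    3: "roads and railways",
    4: "arable land",
    5: "pasture land",
    6: "orchards and berry plantations",
    7: "coniferous forest",
    8: "deciduous forest",
    9: "mixed forest",
    10: "clear-cut forest",
    11: "young forest",
    12: "wetlands",
    13: "open land with vegetation",
    14: "open land without vegetation",
    15: "agricultural mosaic",
    16: "lakes",
    17: "streams",
}

#: Detailed class name -> aggregate class.
CLASS17_TO_CLASS5: Dict[str, str] = {
    "buildings": "Urban",
    "other built-up land": "Urban",
    "roads and railways": "Urban",
    "arable land": "Agriculture",
    "pasture land": "Agriculture",
    "orchards and berry plantations": "Agriculture",
    "agricultural mosaic": "Agriculture",
    "coniferous forest": "Forest",
    "deciduous forest": "Forest",
    "mixed forest": "Forest",
    "clear-cut forest": "Forest",
    "young forest": "Forest",
    "wetlands": "Open land",
    "open land with vegetation": "Open land",
    "open land without vegetation": "Open land",
    "lakes": "Lakes and streams",
    "streams": "Lakes and streams",
}


def reclassify(code: int, legend: Mapping[int, str] = DEFAULT_LEGEND_17) -> str:
    """Aggregate class for a 17-class raster code.

    The mapping is total over the configured legend; any code outside it
    raises :class:`LegendError`.
    """
    try:
        name = legend[code]
    except KeyError:
        raise LegendError(f"raster code {code!r} not in legend") from None
    try:
        return CLASS17_TO_CLASS5[name]
    except KeyError:
        raise LegendError(f"legend class {name!r} has no aggregate class") from None


@dataclass
class CategoricalRaster:
    """Georeferenced categorical raster in planar metres.

    ``values`` is stored top-down (row 0 is the northernmost row), as in
    the ESRI ASCII grid format; ``(x_origin, y_origin)`` is the lower-left
    corner.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def cell_centres(self) -> Tuple[np.ndarray, np.ndarray]:
        """Meshgrids of cell-centre coordinates, aligned with ``values``."""
        ny, nx = self.values.shape
        xs = self.x_origin + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y_origin + (ny - np.arange(ny) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def value_at(self, x: float, y: float) -> int:
        """Raster code of the cell containing (nearest to) a point."""
        ny, nx = self.values.shape
        col = int(np.clip((x - self.x_origin) // self.cell_size, 0, nx - 1))
        row_from_bottom = int(np.clip((y - self.y_origin) // self.cell_size, 0, ny - 1))
        return int(self.values[ny - 1 - row_from_bottom, col])


def zonal_histogram(
    raster: CategoricalRaster,
    circle: Tuple[float, float, float],
    legend: Mapping[int, str] = DEFAULT_LEGEND_17,
) -> Dict[str, int]:
    """Counts of raster cells inside a circle, by aggregate class.

    A cell belongs to the zone when its centre lies inside the circle.
    A circle smaller than one cell falls back to the single cell
    containing its centre.  A circle entirely outside the raster extent
    raises :class:`EmptyZoneError`.
    """
    cx, cy, r = circle
    ny, nx = raster.shape
    x_max = raster.x_origin + nx * raster.cell_size
    y_max = raster.y_origin + ny * raster.cell_size
    if (
        cx + r < raster.x_origin
        or cx - r > x_max
        or cy + r < raster.y_origin
        or cy - r > y_max
    ):
        raise EmptyZoneError("circle does not intersect the raster extent")
    gx, gy = raster.cell_centres()
    inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
    if inside.any():
        codes = raster.values[inside]
    else:
        # degenerate zone: the cell containing the circle centre
        codes = np.array([raster.value_at(cx, cy)])
    counts: Dict[str, int] = {cls: 0 for cls in CLASS5}
    uniq, n = np.unique(codes, return_counts=True)
    for code, cnt in zip(uniq, n):
        counts[reclassify(int(code), legend)] += int(cnt)
    return counts


def profile_cluster(
    raster: CategoricalRaster,
    circle: Tuple[float, float, float],
    legend: Mapping[int, str] = DEFAULT_LEGEND_17,
) -> Dict[str, float]:
    """Per-class share of raster cells inside a circle (sums to 1)."""
    counts = zonal_histogram(raster, circle, legend)
    total = sum(counts.values())
    return {cls: counts[cls] / total for cls in CLASS5}


def profile_clusters(
    raster: CategoricalRaster,
    clusters: pd.DataFrame,
    legend: Mapping[int, str] = DEFAULT_LEGEND_17,
) -> pd.DataFrame:
    """Shares for a table of circles.

    ``clusters`` needs ``x, y, radius_m`` columns; any extra columns
    (e.g. ``cluster_id, window, direction``) are carried through.
    """
    shares = [
        profile_cluster(raster, (row.x, row.y, row.radius_m), legend)
        for row in clusters.itertuples()
    ]
    return pd.concat(
        [clusters.reset_index(drop=True), pd.DataFrame(shares)], axis=1
    )


def group_mean_shares(
    profiles: pd.DataFrame, grouping: Sequence[str] = ("window", "direction")
) -> pd.DataFrame:
    """Unweighted mean share per aggregate class within each group.

    Empty groups simply do not appear; each row of the result sums to 1
    across the five classes.
    """
    cols = list(CLASS5)
    return profiles.groupby(list(grouping))[cols].mean().reset_index()
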