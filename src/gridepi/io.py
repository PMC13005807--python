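"""Readers and writers for the pipeline's standard text formats.

Tables travel as CSV, vector layers as GeoJSON (built with ``shapely``
geometries), and the categorical land-cover raster as an ESRI ASCII grid
(``.asc``) — all plain-text formats with exact round-trip fidelity on
the data model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from shapely.geometry import Point, box, mapping

from gridepi.cartogram import DorlingCircle
from gridepi.exceptions import DataIntegrityError
from gridepi.lulc import CategoricalRaster
from gridepi.scan import Cluster
from gridepi.synthetic import CaseHistory

PathLike = Union[str, Path]

CASE_COLUMNS = ["case_id", "sex", "birth_year", "diagnosis_year", "native", "year", "cell_id"]
GRID_COLUMNS = ["cell_id", "x", "y", "population", "unit_id"]
ASSIGNMENT_COLUMNS = ["case_id", "window", "cell_id", "n_years_used"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"{what}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Cases
# ---------------------------------------------------------------------------


def write_cases(cases: Sequence[CaseHistory], path: PathLike) -> None:
    """One row per case-year (long format)."""
    rows = [
        {
            "case_id": c.case_id,
            "sex": c.sex,
            "birth_year": c.birth_year,
            "diagnosis_year": c.diagnosis_year,
            "native": c.native,
            "year": year,
            "cell_id": cell,
        }
        for c in cases
        for year, cell in c.residence
    ]
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, index=False)


def read_cases(path: PathLike) -> List[CaseHistory]:
    df = pd.read_csv(path)
    _require_columns(df, CASE_COLUMNS, f"case file {path}")
    cases = []
    for case_id, g in df.groupby("case_id", sort=True):
        g = g.sort_values("year")
        first = g.iloc[0]
        cases.append(
            CaseHistory(
                case_id=case_id,
                sex=str(first["sex"]),
                birth_year=int(first["birth_year"]),
                diagnosis_year=int(first["diagnosis_year"]),
                native=bool(first["native"]),
                residence=[(int(r.year), int(r.cell_id)) for r in g.itertuples()],
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Grid / assignments
# ---------------------------------------------------------------------------


def write_grid(grid: pd.DataFrame, path: PathLike) -> None:
    _require_columns(grid, GRID_COLUMNS, "grid table")
    grid[GRID_COLUMNS].to_csv(path, index=False)


def read_grid(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, GRID_COLUMNS, f"grid file {path}")
    return df[GRID_COLUMNS]


def write_assignments(assignments: pd.DataFrame, path: PathLike) -> None:
    _require_columns(assignments, ASSIGNMENT_COLUMNS, "assignment table")
    assignments[ASSIGNMENT_COLUMNS].to_csv(path, index=False)


def read_assignments(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ASSIGNMENT_COLUMNS, f"assignment file {path}")
    return df[ASSIGNMENT_COLUMNS]


# ---------------------------------------------------------------------------
# GeoJSON layers
# ---------------------------------------------------------------------------


def _feature_collection(features: List[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))


def unit_polygons(grid: pd.DataFrame, cell_size: float) -> Dict[object, object]:
    """Dissolved rectangular footprint per unit from the cell lattice."""
    from shapely import union_all

    polys: Dict[object, object] = {}
    for unit, g in grid.groupby("unit_id"):
        boxes = [
            box(x - cell_size / 2, y - cell_size / 2, x + cell_size / 2, y + cell_size / 2)
            for x, y in zip(g["x"], g["y"])
        ]
        polys[unit] = union_all(boxes)
    return polys


def write_unit_polygons(
    grid: pd.DataFrame, cell_size: float, path: PathLike,
    unit_table: pd.DataFrame | None = None,
) -> None:
    polys = unit_polygons(grid, cell_size)
    extra = (
        unit_table.set_index("unit_id").to_dict("index") if unit_table is not None else {}
    )
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"unit_id": int(unit), **extra.get(unit, {})},
        }
        for unit, geom in sorted(polys.items())
    ]
    write_geojson(_feature_collection(features), path)


def write_clusters_geojson(
    results: Dict[Tuple[str, str], List[Cluster]],
    grid: pd.DataFrame,
    cell_size: float,
    path: PathLike,
) -> None:
    """Circle polygons with scan attributes, one feature per cluster."""
    xy = grid.set_index("cell_id")[["x", "y"]]
    features = []
    for (window, direction), clusters in sorted(results.items()):
        for cl in clusters:
            cx, cy = xy.loc[cl.centre_cell]
            geom = Point(cx, cy).buffer(max(cl.radius_m, cell_size / 2), quad_segs=32)
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {
                        "window": window,
                        "direction": direction,
                        "rank": cl.rank,
                        "centre_cell": cl.centre_cell,
                        "x": float(cx),
                        "y": float(cy),
                        "radius_m": cl.radius_m,
                        "n_cells": len(cl.member_cells),
                        "c": cl.c,
                        "expected": cl.expected,
                        "llr": cl.llr,
                        "rr": cl.rr if np.isfinite(cl.rr) else None,
                        "p_value": cl.p_value,
                    },
                }
            )
    write_geojson(_feature_collection(features), path)


def clusters_table(results: Dict[Tuple[str, str], List[Cluster]], grid: pd.DataFrame) -> pd.DataFrame:
    """Flat CSV-ready summary of scan results."""
    xy = grid.set_index("cell_id")[["x", "y"]]
    rows = []
    for (window, direction), clusters in sorted(results.items()):
        for cl in clusters:
            cx, cy = xy.loc[cl.centre_cell]
            rows.append(
                {
                    "window": window,
                    "direction": direction,
                    "rank": cl.rank,
                    "centre_cell": cl.centre_cell,
                    "x": float(cx),
                    "y": float(cy),
                    "radius_m": cl.radius_m,
                    "n_cells": len(cl.member_cells),
                    "c": cl.c,
                    "expected": cl.expected,
                    "llr": cl.llr,
                    "rr": cl.rr,
                    "p_value": cl.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "window", "direction", "rank", "centre_cell", "x", "y", "radius_m",
            "n_cells", "c", "expected", "llr", "rr", "p_value",
        ],
    )


def write_cartogram_geojson(circles: Sequence[DorlingCircle], path: PathLike) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(Point(c.x, c.y)),
            "properties": {
                "unit_id": int(c.unit_id),
                "radius": c.radius,
                "value": c.value,
                "seed_x": c.seed_x,
                "seed_y": c.seed_y,
            },
        }
        for c in circles
    ]
    write_geojson(_feature_collection(features), path)


# ---------------------------------------------------------------------------
# ESRI ASCII grid raster
# ---------------------------------------------------------------------------


def write_raster_asc(raster: CategoricalRaster, path: PathLike, nodata: int = -9999) -> None:
    ny, nx = raster.shape
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {raster.x_origin}\n"
        f"yllcorner {raster.y_origin}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in raster.values)
    Path(path).write_text(header + body + "\n")


def read_raster_asc(path: PathLike) -> CategoricalRaster:
    lines = Path(path).read_text().splitlines()
    header: Dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    try:
        nx, ny = int(header["ncols"]), int(header["nrows"])
        values = np.array(
            [[int(float(v)) for v in line.split()] for line in lines[i:] if line.strip()],
            dtype=np.int16,
        )
    except (KeyError, ValueError) as exc:
        raise DataIntegrityError(f"malformed ASCII grid {path} (line {i + 1}): {exc}")
    if values.shape != (ny, nx):
        raise DataIntegrityError(
            f"ASCII grid {path}: body shape {values.shape} != header ({ny}, {nx})"
        )
    return CategoricalRaster(
        values=values,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
    )
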