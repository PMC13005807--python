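"""Areal incidence mapping: per-unit counts, rates and display classes.

Rates are crude incidence per 100,000 person-years, with person-years
defined as the (static) mean population at risk multiplied by the length
of the study period.  Expected counts use the national incidence of the
analysed dataset itself, so observed and expected totals balance by
construction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from gridepi.exceptions import (
    ClassificationError,
    DataIntegrityError,
    UndefinedRateError,
)

PER = 100_000.0


def percentage(part: float, total: float, ndigits: int = 1) -> float:
    """``100 * part / total`` rounded to ``ndigits`` decimals."""
    if total <= 0:
        raise UndefinedRateError("total must be positive")
    return round(100.0 * part / total, ndigits)


def percent_change(old: float, new: float, ndigits: int = 1) -> float:
    """Relative change from ``old`` to ``new`` in percent."""
    if old == 0:
        raise UndefinedRateError("baseline value is zero")
    return round(100.0 * (new - old) / old, ndigits)


def count_cases_by_unit(
    assignments: pd.DataFrame,
    cell_to_unit: Mapping,
    window: str,
) -> pd.Series:
    """Number of assigned cases per administrative unit for one window.

    Every unit appearing in ``cell_to_unit`` is present in the result
    (zero-filled); counts sum to the number of assignments for the
    window.
    """
    sub = assignments[assignments["window"] == window]
    unknown = set(sub["cell_id"]) - set(cell_to_unit)
    if unknown:
        raise DataIntegrityError(
            f"cells with no unit mapping: {sorted(unknown)[:5]}"
        )
    units = sub["cell_id"].map(cell_to_unit)
    all_units = pd.Index(sorted(set(cell_to_unit.values())), name="unit_id")
    return (
        units.value_counts().reindex(all_units, fill_value=0).sort_index().rename("cases")
    )


def crude_incidence(cases: float, population: float, years: float) -> float:
    """Cases per 100,000 person-years."""
    if population <= 0 or years <= 0:
        raise UndefinedRateError("population and years must be positive")
    return cases / (population * years) * PER


def expected_and_difference(
    cases: float, population: float, national_incidence: float, years: float
) -> Tuple[float, float]:
    """Expected cases and observed-vs-expected difference in percent.

    ``national_incidence`` is on the per-person-year scale (cases per
    person-year), so ``expected = population * national_incidence *
    years``.
    """
    if population <= 0 or national_incidence <= 0 or years <= 0:
        raise UndefinedRateError(
            "population, national_incidence and years must be positive"
        )
    expected = population * national_incidence * years
    return expected, (cases - expected) / expected * 100.0


def classify_display(values: Sequence[float]) -> pd.DataFrame:
    """Quintile (1-5) and top-2% display classes for unit values.

    Quintile breaks sit at the 20/40/60/80th percentiles (linear
    interpolation); a value equal to a break falls in the lower
    quintile.  ``top2pct`` flags values at or above the 98th percentile.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ClassificationError("need at least 5 units to classify")
    breaks = np.percentile(arr, [20, 40, 60, 80])
    quintile = 1 + (arr[:, None] > breaks[None, :]).sum(axis=1)
    top = arr >= np.percentile(arr, 98)
    return pd.DataFrame({"quintile": quintile, "top2pct": top})


def standardised_incidence(
    stratum_cases: Sequence[float],
    stratum_populations: Sequence[float],
    reference_weights: Sequence[float],
    years: float = 1.0,
) -> float:
    """Directly standardised rate: weighted mean of stratum crude rates.

    ``reference_weights`` must sum to 1.  Strata with zero population
    and zero weight contribute nothing; zero population with cases is a
    data error.
    """
    c = np.asarray(stratum_cases, dtype=float)
    p = np.asarray(stratum_populations, dtype=float)
    w = np.asarray(reference_weights, dtype=float)
    if not (c.shape == p.shape == w.shape):
        raise DataIntegrityError("strata are not aligned")
    if not np.isclose(w.sum(), 1.0):
        raise DataIntegrityError("reference weights must sum to 1")
    if np.any((p == 0) & (c > 0)):
        raise DataIntegrityError("stratum with zero population but nonzero cases")
    rates = np.zeros_like(c)
    nz = p > 0
    rates[nz] = c[nz] / (p[nz] * years) * PER
    return float(np.sum(np.where(w > 0, w * rates, 0.0)))


def stratify(cases: Iterable, native: bool) -> list:
    """Subset of cases with the requested nativity flag.

    Works on any iterable of objects with a boolean ``native``
    attribute; the two strata partition the input.
    """
    out = []
    for case in cases:
        flag = getattr(case, "native", None)
        if flag is None:
            raise DataIntegrityError(f"case {case.case_id} has no nativity flag")
        if bool(flag) == native:
            out.append(case)
    return out


def unit_incidence_table(
    assignments: pd.DataFrame,
    grid: pd.DataFrame,
    years: float,
    windows: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full per-unit incidence table across exposure windows.

    The national incidence used for expected counts is computed from the
    analysed data itself (total cases / total person-years, per window),
    so expected totals equal observed totals.
    """
    from gridepi.windows import WINDOWS

    windows = list(windows) if windows is not None else list(WINDOWS)
    cell_to_unit = dict(zip(grid["cell_id"], grid["unit_id"]))
    unit_pop = grid.groupby("unit_id")["population"].sum()
    total_pop = float(unit_pop.sum())

    frames = []
    for window in windows:
        counts = count_cases_by_unit(assignments, cell_to_unit, window)
        counts = counts.reindex(unit_pop.index, fill_value=0)
        total_cases = float(counts.sum())
        national = total_cases / (total_pop * years)  # per person-year
        rows = pd.DataFrame(
            {
                "unit_id": unit_pop.index,
                "window": window,
                "cases": counts.to_numpy(),
                "population": unit_pop.to_numpy(dtype=float),
            }
        )
        rows["person_years"] = rows["population"] * years
        rows["crude_incidence"] = [
            crude_incidence(c, p, years)
            for c, p in zip(rows["cases"], rows["population"])
        ]
        if national > 0:
            ed = [
                expected_and_difference(c, p, national, years)
                for c, p in zip(rows["cases"], rows["population"])
            ]
            rows["expected"] = [e for e, _ in ed]
            rows["obs_vs_exp_pct"] = [d for _, d in ed]
        else:
            rows["expected"] = 0.0
            rows["obs_vs_exp_pct"] = np.nan
        cls = classify_display(rows["crude_incidence"].to_numpy())
        rows["quintile"] = cls["quintile"].to_numpy()
        rows["top2pct"] = cls["top2pct"].to_numpy()
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)
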