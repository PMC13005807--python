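"""Life-stage exposure windows over longitudinal residential histories.

Each case carries one residential cell per calendar year from birth to
diagnosis.  Four exposure windows summarise that trajectory into a single
representative ("most dominant") cell:

``at_diagnosis``
    the cell occupied in the diagnosis year;
``first5``
    the dominant cell over the first five calendar years of life
    (truncated at the diagnosis year for very young cases);
``last5``
    the dominant cell over the five calendar years up to and including
    the diagnosis year (truncated at the birth year);
``lifetime``
    the dominant cell over the whole birth-to-diagnosis span.

"Dominant" means occupied for the largest number of years inside the
window; ties are broken in favour of the cell occupied earliest within
the window, which makes the result independent of input ordering.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import pandas as pd

from gridepi.exceptions import InvalidCaseError, MissingDataError

#: Canonical window names, in reporting order.
WINDOWS: Tuple[str, ...] = ("at_diagnosis", "first5", "last5", "lifetime")

#: Width, in calendar years, of the truncated early/late windows.
WINDOW_SPAN = 5


def window_bounds(birth_year: int, diagnosis_year: int, window: str) -> Tuple[int, int]:
    """Inclusive calendar-year bounds of an exposure window.

    Parameters
    ----------
    birth_year, diagnosis_year:
        Case anchors; ``birth_year`` must not exceed ``diagnosis_year``.
    window:
        One of :data:`WINDOWS`.

    Returns
    -------
    tuple of (int, int)
        Inclusive ``(first_year, last_year)``.
    """
    if birth_year > diagnosis_year:
        raise InvalidCaseError(
            f"birth_year {birth_year} is after diagnosis_year {diagnosis_year}"
        )
    if window == "at_diagnosis":
        return diagnosis_year, diagnosis_year
    if window == "first5":
        return birth_year, min(birth_year + WINDOW_SPAN - 1, diagnosis_year)
    if window == "last5":
        return max(diagnosis_year - WINDOW_SPAN + 1, birth_year), diagnosis_year
    if window == "lifetime":
        return birth_year, diagnosis_year
    raise ValueError(f"unknown window {window!r}; expected one of {WINDOWS}")


def dominant_location(
    residence: Iterable[Tuple[int, object]], bounds: Tuple[int, int]
) -> object:
    """Cell occupied for the most years inside ``bounds``.

    Ties are broken by the cell occupied earliest within the window.
    The result is invariant under permutation of ``residence``.
    """
    cell, _ = _dominant_with_count(residence, bounds)
    return cell


def _dominant_with_count(
    residence: Iterable[Tuple[int, object]], bounds: Tuple[int, int]
) -> Tuple[object, int]:
    lo, hi = bounds
    counts: dict = {}
    earliest: dict = {}
    for year, cell in residence:
        if lo <= year <= hi:
            counts[cell] = counts.get(cell, 0) + 1
            if cell not in earliest or year < earliest[cell]:
                earliest[cell] = year
    if not counts:
        raise MissingDataError(f"no residence years inside window [{lo}, {hi}]")
    best = min(counts, key=lambda c: (-counts[c], earliest[c]))
    return best, counts[best]


def assign_all(cases: Iterable) -> pd.DataFrame:
    """Assign each case its representative cell for all four windows.

    Parameters
    ----------
    cases:
        Iterable of objects with ``case_id``, ``birth_year``,
        ``diagnosis_year`` and ``residence`` (list of ``(year, cell_id)``)
        attributes, e.g. :class:`gridepi.synthetic.CaseHistory`.

    Returns
    -------
    pandas.DataFrame
        Exactly four rows per case, columns
        ``case_id, window, cell_id, n_years_used``.
    """
    rows = []
    for case in cases:
        for window in WINDOWS:
            bounds = window_bounds(case.birth_year, case.diagnosis_year, window)
            try:
                cell, n_used = _dominant_with_count(case.residence, bounds)
            except MissingDataError as exc:
                raise MissingDataError(f"case {case.case_id}: {exc}") from exc
            rows.append(
                {
                    "case_id": case.case_id,
                    "window": window,
                    "cell_id": cell,
                    "n_years_used": n_used,
                }
            )
    return pd.DataFrame(rows, columns=["case_id", "window", "cell_id", "n_years_used"])
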