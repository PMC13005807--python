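"""Discrete-Poisson circular spatial scan statistic over grid-cell centroids.

Candidate windows are built per centre cell by absorbing neighbouring
cells in order of Euclidean distance (ties by cell ID), stopping before
any addition that would push the window population above
``max_pop_fraction`` of the total or beyond ``max_radius_m``.  For a
window with ``c`` observed cases out of ``C`` total and expectation
``E = C * window_population / total_population``, the one-sided
log-likelihood ratio is::

    LLR = c * ln(c / E) + (C - c) * ln((C - c) / (C - E))

when the directional condition holds (``c > E`` for a high-risk scan,
``c < E`` for low), and 0 otherwise; ``0 * ln 0`` is taken as 0.
Significance is assessed by Monte Carlo: each replication redistributes
the ``C`` cases multinomially with cell probabilities proportional to
population, and the replication's maximum LLR over the same candidate
window family is recorded.  A cluster's p-value is
``(1 + #{replications with max LLR >= cluster LLR}) / (n_replications + 1)``.
Reported clusters are selected greedily in decreasing LLR order subject
to sharing no cell with an already-reported cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from gridepi.exceptions import (
    ConfigurationError,
    DataIntegrityError,
    InvalidExpectationError,
    NoCasesError,
)
from gridepi.windows import WINDOWS

DIRECTIONS = ("high", "low")


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters; defaults mirror a 5% population cap, 100 km radius
    cap, 999 replications and a 0.05 significance level."""

    max_pop_fraction: float = 0.05
    max_radius_m: float = 100_000.0
    n_replications: int = 999
    alpha: float = 0.05
    direction: str = "high"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_pop_fraction <= 0.5:
            raise ConfigurationError("max_pop_fraction must be in (0, 0.5]")
        if self.max_radius_m <= 0:
            raise ConfigurationError("max_radius_m must be > 0")
        if self.n_replications < 9:
            raise ConfigurationError("n_replications must be >= 9")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(f"direction must be one of {DIRECTIONS}")


@dataclass(frozen=True)
class CandidateWindow:
    """Circular candidate window: a centre cell and its absorbed members."""

    centre_cell: int
    radius_m: float
    member_cells: Tuple[int, ...]
    c: Optional[int] = None
    expected: Optional[float] = None


@dataclass(frozen=True)
class Cluster:
    """A scored scan window with Monte Carlo inference attached."""

    centre_cell: int
    radius_m: float
    member_cells: Tuple[int, ...]
    c: int
    expected: float
    llr: float
    rr: float
    p_value: float
    rank: int


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def _check_expectation(c: float, E: float, C: float) -> None:
    if not 0 <= c <= C:
        raise InvalidExpectationError(f"c={c} outside [0, C={C}]")
    if E <= 0 or E >= C:
        raise InvalidExpectationError(f"E={E} must satisfy 0 < E < C={C}")


def poisson_llr(c: float, E: float, C: float, direction: str = "high") -> float:
    """One-sided discrete-Poisson log-likelihood ratio for a single window."""
    _check_expectation(c, E, C)
    if direction not in DIRECTIONS:
        raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
    if (direction == "high" and c <= E) or (direction == "low" and c >= E):
        return 0.0
    t1 = c * math.log(c / E) if c > 0 else 0.0
    t2 = (C - c) * math.log((C - c) / (C - E)) if c < C else 0.0
    return t1 + t2


def relative_risk(c: float, E: float, C: float) -> float:
    """Rate inside the window relative to the rate outside it."""
    _check_expectation(c, E, C)
    if c == C:
        return math.inf
    return (c / E) / ((C - c) / (C - E))


def _llr_matrix(
    c: np.ndarray, E: np.ndarray, C: float, direction: str, mask: np.ndarray
) -> np.ndarray:
    """Vectorised LLR over padded (centre, prefix-size) matrices."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(c > 0, c * np.log(c / E), 0.0)
        rem = C - c
        t2 = np.where(rem > 0, rem * np.log(rem / (C - E)), 0.0)
    cond = (c > E) if direction == "high" else (c < E)
    return np.where(cond & mask, t1 + t2, 0.0)


# ---------------------------------------------------------------------------
# Candidate-window geometry
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """Precomputed candidate-window family for one grid and scan config.

    ``order[i, :ksize[i]]`` lists grid-row indices absorbed by centre
    ``i`` in (distance, cell ID) order, the centre itself first; prefix
    ``k`` of that list is the ``k``-cell candidate window.  Building
    this once and reusing it across many scans on the same grid (e.g.
    Monte Carlo replications, or many simulated datasets) is the main
    performance lever.
    """

    cell_ids: np.ndarray
    population: np.ndarray
    total_population: float
    order: np.ndarray  # (n, kmax) int32, padded with -1
    ksize: np.ndarray  # (n,) valid prefix count per centre
    radius: np.ndarray  # (n, kmax) distance of k-th absorbed cell
    prefix_pop: np.ndarray  # (n, kmax) cumulative population, safe-padded
    mask: np.ndarray  # (n, kmax) valid-prefix mask
    order_clipped: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.order_clipped = np.where(self.order >= 0, self.order, 0)

    @classmethod
    def build(cls, cells: pd.DataFrame, config: ScanConfig) -> "WindowSet":
        if len(cells) == 0:
            raise NoCasesError("no populated cells")
        ids = cells["cell_id"].to_numpy()
        x = cells["x"].to_numpy(dtype=float)
        y = cells["y"].to_numpy(dtype=float)
        pop = cells["population"].to_numpy(dtype=float)
        if np.any(pop <= 0):
            raise DataIntegrityError("cells must have positive population")
        n = len(ids)
        P = float(pop.sum())
        cap = config.max_pop_fraction * P

        d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
        ksizes = np.empty(n, dtype=np.int64)
        orders = []
        for i in range(n):
            idx = np.lexsort((ids, d2[i]))
            dist = np.sqrt(d2[i][idx])
            cum = np.cumsum(pop[idx])
            ok = (cum <= cap) & (dist <= config.max_radius_m)
            ok[0] = True  # every singleton is a window
            k = int(np.argmin(ok)) if not ok.all() else n
            ksizes[i] = k
            orders.append(idx[:k].astype(np.int32))
        kmax = int(ksizes.max())
        order = np.full((n, kmax), -1, dtype=np.int32)
        radius = np.zeros((n, kmax))
        prefix_pop = np.full((n, kmax), P / 2.0)
        mask = np.zeros((n, kmax), dtype=bool)
        for i in range(n):
            k = int(ksizes[i])
            order[i, :k] = orders[i]
            radius[i, :k] = np.sqrt(d2[i][orders[i]])
            prefix_pop[i, :k] = np.cumsum(pop[orders[i]])
            mask[i, :k] = True
        return cls(
            cell_ids=ids,
            population=pop,
            total_population=P,
            order=order,
            ksize=ksizes,
            radius=radius,
            prefix_pop=prefix_pop,
            mask=mask,
        )

    def prefix_counts(self, counts: np.ndarray) -> np.ndarray:
        """Cumulative case counts along each centre's absorption order."""
        return np.cumsum(counts[self.order_clipped] * self.mask, axis=1)

    def members(self, centre: int, k: int) -> Tuple[int, ...]:
        return tuple(int(self.cell_ids[j]) for j in self.order[centre, :k])


def enumerate_windows(cells: pd.DataFrame, config: ScanConfig) -> List[CandidateWindow]:
    """Deduplicated list of all candidate windows for a grid."""
    ws = WindowSet.build(cells, config)
    seen: Dict[frozenset, CandidateWindow] = {}
    for i in range(len(ws.cell_ids)):
        for k in range(1, int(ws.ksize[i]) + 1):
            members = ws.members(i, k)
            key = frozenset(members)
            if key not in seen:
                seen[key] = CandidateWindow(
                    centre_cell=int(ws.cell_ids[i]),
                    radius_m=float(ws.radius[i, k - 1]),
                    member_cells=members,
                )
    return list(seen.values())


# ---------------------------------------------------------------------------
# The scan proper
# ---------------------------------------------------------------------------


def _counts_vector(
    case_counts: Union[Mapping, pd.Series], cell_ids: np.ndarray
) -> np.ndarray:
    if isinstance(case_counts, pd.Series):
        case_counts = case_counts.to_dict()
    unknown = set(case_counts) - set(int(i) for i in cell_ids)
    if unknown:
        raise DataIntegrityError(
            f"case counts reference unknown cells: {sorted(unknown)[:5]}"
        )
    lookup = {int(cid): j for j, cid in enumerate(cell_ids)}
    counts = np.zeros(len(cell_ids), dtype=np.int64)
    for cid, cnt in case_counts.items():
        counts[lookup[int(cid)]] = cnt
    return counts


def scan(
    cells: pd.DataFrame,
    case_counts: Union[Mapping, pd.Series],
    config: ScanConfig,
    window_set: Optional[WindowSet] = None,
) -> List[Cluster]:
    """Run one one-sided scan and return significant non-overlapping clusters.

    Parameters
    ----------
    cells:
        Grid table with ``cell_id, x, y, population`` columns.
    case_counts:
        Mapping (or Series) ``cell_id -> observed cases``; cells absent
        from the mapping count zero.
    config:
        Scan parameters, including direction and Monte Carlo seed.
    window_set:
        Optional precomputed :class:`WindowSet` for ``cells`` and
        ``config`` (must match; reused verbatim when given).

    Returns
    -------
    list of Cluster
        Clusters with ``p_value <= alpha``, ranked by decreasing LLR and
        mutually non-overlapping (no shared grid cell).  Empty when no
        window is significant.
    """
    ws = window_set if window_set is not None else WindowSet.build(cells, config)
    counts = _counts_vector(case_counts, ws.cell_ids)
    C = int(counts.sum())
    if C < 1:
        raise NoCasesError("scan requires at least one case")
    P = ws.total_population
    E_mat = (C / P) * ws.prefix_pop

    obs_llr = _llr_matrix(
        ws.prefix_counts(counts).astype(float), E_mat, C, config.direction, ws.mask
    )

    # Monte Carlo null distribution of the maximum LLR
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 404)))
    pvals_cells = ws.population / P
    null_max = np.empty(config.n_replications)
    for r in range(config.n_replications):
        rep = rng.multinomial(C, pvals_cells)
        rep_llr = _llr_matrix(
            ws.prefix_counts(rep).astype(float), E_mat, C, config.direction, ws.mask
        )
        null_max[r] = rep_llr.max()
    null_sorted = np.sort(null_max)

    def p_value(llr: float) -> float:
        ge = len(null_sorted) - int(np.searchsorted(null_sorted, llr, side="left"))
        return (1 + ge) / (config.n_replications + 1)

    # candidate ranking: decreasing LLR, then smaller radius, then centre ID
    cand_i, cand_k = np.nonzero(obs_llr > 0)
    if cand_i.size == 0:
        return []
    llrs = obs_llr[cand_i, cand_k]
    radii = ws.radius[cand_i, cand_k]
    centre_ids = ws.cell_ids[cand_i]
    order = np.lexsort((centre_ids, radii, -llrs))

    clusters: List[Cluster] = []
    used_cells: set = set()
    for pos in order:
        llr = float(llrs[pos])
        p = p_value(llr)
        if p > config.alpha:
            break  # later candidates have lower LLR, hence larger p
        i, k = int(cand_i[pos]), int(cand_k[pos]) + 1
        members = ws.members(i, k)
        if used_cells.intersection(members):
            continue
        c = int(counts[ws.order[i, :k]].sum())
        E = float(E_mat[i, k - 1])
        clusters.append(
            Cluster(
                centre_cell=int(ws.cell_ids[i]),
                radius_m=float(ws.radius[i, k - 1]),
                member_cells=members,
                c=c,
                expected=E,
                llr=llr,
                rr=relative_risk(c, E, C),
                p_value=p,
                rank=len(clusters) + 1,
            )
        )
        used_cells.update(members)
    return clusters


def most_likely_cluster(
    cells: pd.DataFrame,
    case_counts: Union[Mapping, pd.Series],
    config: ScanConfig,
    window_set: Optional[WindowSet] = None,
) -> Tuple[Tuple[int, ...], float]:
    """Best window and its LLR, without Monte Carlo inference.

    Tie-breaking follows the scan rule: maximum LLR, then smaller
    radius, then lower centre cell ID.
    """
    ws = window_set if window_set is not None else WindowSet.build(cells, config)
    counts = _counts_vector(case_counts, ws.cell_ids)
    C = int(counts.sum())
    if C < 1:
        raise NoCasesError("scan requires at least one case")
    E_mat = (C / ws.total_population) * ws.prefix_pop
    llr = _llr_matrix(
        ws.prefix_counts(counts).astype(float), E_mat, C, config.direction, ws.mask
    )
    cand_i, cand_k = np.nonzero(ws.mask)
    vals = llr[cand_i, cand_k]
    order = np.lexsort((ws.cell_ids[cand_i], ws.radius[cand_i, cand_k], -vals))
    best = order[0]
    i, k = int(cand_i[best]), int(cand_k[best]) + 1
    return ws.members(i, k), float(vals[best])


def run_all_windows(
    assignments: pd.DataFrame,
    cells: pd.DataFrame,
    config: ScanConfig,
    windows: Sequence[str] = WINDOWS,
    directions: Sequence[str] = DIRECTIONS,
) -> Dict[Tuple[str, str], List[Cluster]]:
    """Scan every exposure window in both directions.

    Each of the (window, direction) scans gets its own Monte Carlo null
    with a deterministically derived seed.
    """
    window_set = WindowSet.build(cells, config)
    results: Dict[Tuple[str, str], List[Cluster]] = {}
    for wi, window in enumerate(windows):
        sub = assignments[assignments["window"] == window]
        counts = sub["cell_id"].value_counts().to_dict()
        for di, direction in enumerate(directions):
            sub_seed = int(
                np.random.SeedSequence((config.seed, wi, di)).generate_state(1)[0]
            )
            cfg = replace(config, direction=direction, seed=sub_seed)
            results[(window, direction)] = scan(
                cells, counts, cfg, window_set=window_set
            )
    return results
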