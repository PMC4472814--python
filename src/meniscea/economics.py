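"""Cost-effectiveness arithmetic: ICER frontier, NMB, CEAC and CEAF.

Strategies are compared on the efficiency frontier: sort by cost, remove
strongly dominated options (costlier, no more effective), then iteratively
remove extendedly dominated ones (their incremental cost-effectiveness ratio
exceeds that of the next more effective option) until adjacent-pair ICERs
increase monotonically.  Probabilistic output is summarised by the
cost-effectiveness acceptability curve — at each willingness-to-pay (WTP)
threshold, the fraction of simulation draws in which each strategy has the
highest net monetary benefit — and the acceptability frontier, which reports
that fraction for the strategy with the highest mean NMB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterError

__all__ = [
    "NMBMatrix",
    "nmb",
    "nmb_matrix",
    "icer_table",
    "ceac",
    "ceaf",
    "ceaf_switch_points",
    "default_wtp_grid",
]

ON_FRONTIER = "on-frontier"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly-dominated"


def default_wtp_grid() -> np.ndarray:
    """$0-150,000/QALY in $1,000 steps (the range shown on CEAC/CEAF plots)."""
    return np.arange(0.0, 150_001.0, 1_000.0)


def nmb(cost: float, qalys: float, wtp: float) -> float:
    """Net monetary benefit: WTP x effectiveness - cost."""
    if wtp < 0:
        raise ParameterError("willingness-to-pay must be non-negative")
    return wtp * qalys - cost


@dataclass
class NMBMatrix:
    """Iterations x strategies net-monetary-benefit values at one WTP."""

    values: np.ndarray
    strategies: tuple[str, ...]
    wtp: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.strategies):
            raise ParameterError(
                "NMB matrix must be (iterations, strategies) matching the strategy list"
            )
        if not np.isfinite(self.values).all():
            raise ParameterError("NMB values must be finite")


def nmb_matrix(
    costs: np.ndarray, qalys: np.ndarray, strategies: tuple[str, ...], wtp: float
) -> NMBMatrix:
    """Build an :class:`NMBMatrix` from per-iteration costs and QALYs."""
    return NMBMatrix(wtp * np.asarray(qalys) - np.asarray(costs), tuple(strategies), wtp)


def icer_table(results) -> pd.DataFrame:
    """Efficiency-frontier table with dominance classification and ICERs.

    ``results`` is an iterable of ``(strategy, cost, qalys)`` triples.
    Returns a DataFrame ordered by ascending cost with columns ``strategy,
    cost, qalys, status, icer``; dominated rows carry NaN ICERs, and the
    cheapest frontier row is the reference (NaN ICER).  Equal-cost ties are
    ordered by descending QALYs, making the later row weakly dominated.
    """
    rows = [(str(s), float(c), float(q)) for s, c, q in results]
    if len(rows) < 2:
        raise ParameterError("icer_table requires at least 2 strategies")
    rows.sort(key=lambda r: (r[1], -r[2]))
    n = len(rows)
    status = [ON_FRONTIER] * n

    # strong (incl. weak) dominance: some cheaper-or-equal row is at least as
    # effective
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            _, ci, qi = rows[i]
            _, cj, qj = rows[j]
            if (cj < ci and qj >= qi) or (cj == ci and qj >= qi and j < i):
                status[i] = DOMINATED
                break

    # extended dominance: drop frontier rows until adjacent ICERs increase
    while True:
        idx = [i for i in range(n) if status[i] == ON_FRONTIER]
        changed = False
        for k in range(1, len(idx) - 1):
            lo, mid, hi = idx[k - 1], idx[k], idx[k + 1]
            icer_mid = _pair_icer(rows[lo], rows[mid])
            icer_hi = _pair_icer(rows[mid], rows[hi])
            if icer_mid >= icer_hi:
                status[mid] = EXT_DOMINATED
                changed = True
                break
        if not changed:
            break

    icers = [np.nan] * n
    idx = [i for i in range(n) if status[i] == ON_FRONTIER]
    for k in range(1, len(idx)):
        icers[idx[k]] = _pair_icer(rows[idx[k - 1]], rows[idx[k]])
    return pd.DataFrame(
        {
            "strategy": [r[0] for r in rows],
            "cost": [r[1] for r in rows],
            "qalys": [r[2] for r in rows],
            "status": status,
            "icer": icers,
        }
    )


def _pair_icer(lo, hi) -> float:
    dq = hi[2] - lo[2]
    dc = hi[1] - lo[1]
    if dq <= 0:
        return np.inf
    return dc / dq


def frontier_icer(table: pd.DataFrame, strategy: str) -> float:
    """The adjacent-pair ICER of one frontier strategy (NaN if reference)."""
    row = table[table["strategy"] == strategy]
    if row.empty:
        raise ParameterError(f"strategy {strategy!r} not in table")
    return float(row["icer"].iloc[0])


def ceac(
    costs: np.ndarray,
    qalys: np.ndarray,
    strategies,
    wtp_grid=None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each WTP on the grid, the fraction of iterations in which each
    strategy attains the highest net monetary benefit; exact ties split
    equally.  Columns: ``wtp`` then one column per strategy; rows sum to 1.
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    if costs.ndim != 2 or costs.shape[0] < 1:
        raise ParameterError("ceac requires a non-empty (iterations, strategies) array")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    n_iter, n_strat = costs.shape
    out = np.empty((len(wtp_grid), n_strat))
    for w, wtp in enumerate(wtp_grid):
        values = wtp * qalys - costs
        best = values.max(axis=1, keepdims=True)
        is_best = values == best
        share = is_best / is_best.sum(axis=1, keepdims=True)
        out[w] = share.mean(axis=0)
    frame = pd.DataFrame(out, columns=list(strategies))
    frame.insert(0, "wtp", wtp_grid)
    return frame


def ceaf(
    ceac_frame: pd.DataFrame,
    mean_costs: np.ndarray,
    mean_qalys: np.ndarray,
    strategies,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier.

    At each WTP, the strategy with the highest *mean* NMB is selected and its
    CEAC value reported.  Columns: ``wtp, strategy, probability``.
    """
    strategies = list(strategies)
    mean_costs = np.asarray(mean_costs, dtype=float)
    mean_qalys = np.asarray(mean_qalys, dtype=float)
    wtp_grid = ceac_frame["wtp"].to_numpy()
    mean_nmb = wtp_grid[:, None] * mean_qalys[None, :] - mean_costs[None, :]
    best = mean_nmb.argmax(axis=1)
    prob = np.array(
        [ceac_frame[strategies[b]].iloc[w] for w, b in enumerate(best)]
    )
    return pd.DataFrame(
        {"wtp": wtp_grid, "strategy": [strategies[b] for b in best], "probability": prob}
    )


def ceaf_switch_points(ceaf_frame: pd.DataFrame) -> list[tuple[float, str, str]]:
    """WTP thresholds at which the preferred (highest-mean-NMB) strategy
    changes, as ``(wtp, from_strategy, to_strategy)`` tuples."""
    out = []
    strat = ceaf_frame["strategy"].to_numpy()
    wtp = ceaf_frame["wtp"].to_numpy()
    for k in range(1, len(strat)):
        if strat[k] != strat[k - 1]:
            out.append((float(wtp[k]), str(strat[k - 1]), str(strat[k])))
    return out
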