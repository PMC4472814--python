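import numpy as np
import pytest

from meniscea.economics import (
    NMBMatrix,
    ceac,
    ceaf,
    ceaf_switch_points,
    default_wtp_grid,
    icer_table,
    nmb,
    nmb_matrix,
)
from meniscea.params import ParameterError


def brute_force_frontier(points):
    """Independent oracle: a strategy is on the convex cost-effectiveness
    frontier iff it uniquely maximises NMB at some non-negative WTP.

    Candidate WTPs are 0, the pairwise slopes, and midpoints between
    consecutive slopes, which cover every linear regime of max-NMB.
    """
    slopes = []
    for i, (_, ci, qi) in enumerate(points):
        for j, (_, cj, qj) in enumerate(points):
            if qj != qi:
                s = (cj - ci) / (qj - qi)
                if s > 0:
                    slopes.append(s)
    slopes = sorted(set(slopes))
    cands = [0.0] + slopes + [s * 1.01 + 1 for s in slopes] + [max(slopes, default=1.0) * 10]
    for a, b in zip(slopes, slopes[1:]):
        cands.append((a + b) / 2)
    frontier = set()
    for lam in cands:
        values = [lam * q - c for _, c, q in points]
        best = max(values)
        winners = [k for k, v in enumerate(values) if v == best]
        if len(winners) == 1:
            frontier.add(points[winners[0]][0])
    return frontier


class TestNMB:
    def test_definition(self):
        assert nmb(10800, 6.637, 50000) == pytest.approx(321050)
        assert nmb(0, 0, 123456) == 0
        assert nmb(500, 2.0, 0) == -500

    def test_negative_wtp_rejected(self):
        with pytest.raises(ParameterError):
            nmb(1, 1, -1)

    def test_matrix_validation(self):
        with pytest.raises(ParameterError):
            NMBMatrix(np.ones((3, 2)), ("a",), 1000.0)
        with pytest.raises(ParameterError):
            NMBMatrix(np.array([[np.inf, 0.0]]), ("a", "b"), 1000.0)
        mat = nmb_matrix(np.array([[100.0, 200.0]]), np.array([[1.0, 2.0]]), ("a", "b"), 1000.0)
        assert mat.values[0, 1] == pytest.approx(1800.0)


class TestIcerTable:
    def test_published_base_case_ladder(self):
        table = icer_table(
            [("PT", 10800, 6.637), ("Delayed", 11900, 6.723), ("Immediate", 12900, 6.732)]
        )
        assert list(table.strategy) == ["PT", "Delayed", "Immediate"]
        assert list(table.status) == ["on-frontier"] * 3
        assert table.icer.iloc[1] == pytest.approx(1100 / 0.086, rel=1e-9)
        assert table.icer.iloc[2] == pytest.approx(1000 / 0.009, rel=1e-9)

    def test_strong_dominance_flagged(self):
        # the delayed-efficacy sensitivity: immediate costs more, yields less
        table = icer_table(
            [("PT", 10800, 6.636), ("Delayed", 11600, 6.744), ("Immediate", 12900, 6.731)]
        )
        row = table[table.strategy == "Immediate"].iloc[0]
        assert row.status == "dominated"
        assert np.isnan(row.icer)

    def test_extended_dominance_removed(self):
        table = icer_table([("A", 0, 0.0), ("B", 100, 0.5), ("C", 150, 1.5)])
        assert table.set_index("strategy").status["B"] == "extendedly-dominated"
        assert table.set_index("strategy").icer["C"] == pytest.approx(100.0)

    def test_identical_strategies_second_dominated(self):
        table = icer_table([("A", 100, 1.0), ("B", 100, 1.0)])
        assert list(table.status) == ["on-frontier", "dominated"]

    def test_requires_two_strategies(self):
        with pytest.raises(ParameterError):
            icer_table([("A", 1, 1)])

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(3, 7)
            pts = [(f"s{k}", rng.uniform(0, 1e4), rng.uniform(0, 10)) for k in range(n)]
            table = icer_table(pts)
            icers = table[table.status == "on-frontier"].icer.dropna().to_numpy()
            assert (np.diff(icers) > 0).all()

    def test_matches_brute_force_convex_frontier_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 7))
            pts = [(f"s{k}", float(rng.uniform(0, 1e4)), float(rng.uniform(0, 10)))
                   for k in range(n)]
            table = icer_table(pts)
            mine = set(table[table.status == "on-frontier"].strategy)
            assert mine == brute_force_frontier(pts)


class TestCEAC:
    def test_single_iteration_is_an_indicator(self):
        costs = np.array([[100.0, 50.0, 200.0]])
        qalys = np.array([[1.0, 1.0, 1.0]])
        frame = ceac(costs, qalys, ["a", "b", "c"], [0.0, 1e5])
        assert (frame["b"] == 1.0).all()
        assert (frame[["a", "c"]].to_numpy() == 0.0).all()

    def test_exact_ties_split_equally(self):
        costs = np.full((4, 3), 10.0)
        qalys = np.full((4, 3), 2.0)
        frame = ceac(costs, qalys, ["a", "b", "c"], [0.0, 5e4])
        assert np.allclose(frame[["a", "b", "c"]].to_numpy(), 1 / 3)

    def test_curves_sum_to_one_and_lie_in_unit_interval(self):
        rng = np.random.default_rng(0)
        costs = rng.uniform(1e3, 2e4, size=(500, 3))
        qalys = rng.uniform(5, 8, size=(500, 3))
        frame = ceac(costs, qalys, ["a", "b", "c"])
        probs = frame[["a", "b", "c"]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            ceac(np.empty((0, 2)), np.empty((0, 2)), ["a", "b"])


class TestCEAF:
    def test_single_strategy_frontier_is_one_everywhere(self):
        costs = np.array([[100.0], [120.0]])
        qalys = np.array([[1.0], [1.1]])
        frame = ceac(costs, qalys, ["only"], [0.0, 1e4])
        out = ceaf(frame, costs.mean(axis=0), qalys.mean(axis=0), ["only"])
        assert (out.probability == 1.0).all()
        assert (out.strategy == "only").all()

    def test_preference_switches_at_the_adjacent_icer(self):
        # deterministic two-strategy problem: ICER = (200-100)/(2-1) = 100
        costs = np.array([[100.0, 200.0]])
        qalys = np.array([[1.0, 2.0]])
        grid = np.arange(0.0, 201.0, 1.0)
        frame = ceac(costs, qalys, ["cheap", "rich"], grid)
        out = ceaf(frame, costs[0], qalys[0], ["cheap", "rich"])
        switches = ceaf_switch_points(out)
        assert len(switches) == 1
        wtp, frm, to = switches[0]
        assert (frm, to) == ("cheap", "rich")
        # mean NMB ties exactly at the ICER; the switch lands on the first
        # grid point past it
        assert wtp == pytest.approx(101.0)

    def test_frontier_consistency_with_icer_table_on_psa_means(self, psa_10k):
        mean_c = psa_10k.direct_costs.mean(axis=0)
        mean_q = psa_10k.qalys.mean(axis=0)
        table = icer_table(list(zip(psa_10k.strategies, mean_c, mean_q)))
        frame = ceac(psa_10k.direct_costs, psa_10k.qalys, psa_10k.strategies)
        out = ceaf(frame, mean_c, mean_q, psa_10k.strategies)
        switches = ceaf_switch_points(out)
        # the mean-NMB preference changes exactly where the frontier ICERs sit
        frontier = table[table.status == "on-frontier"]
        icers = frontier.icer.dropna().to_numpy()
        assert len(switches) == len(icers)
        for (wtp, _, _), icer in zip(switches, sorted(icers)):
            assert abs(wtp - icer) <= 1000.0  # grid resolution


def test_default_wtp_grid_covers_published_range():
    grid = default_wtp_grid()
    assert grid[0] == 0.0 and grid[-1] == 150_000.0
    assert np.diff(grid).min() == 1000.0
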