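import dataclasses

import numpy as np
import pandas as pd
import pytest

import meniscea as m
from meniscea.engine import (
    RunOptions,
    discount_factor,
    entry_age_bins,
    run_strategy,
    time_cost_quarter,
    trajectory_stats,
)
from meniscea.params import ParameterError, fixed_spec


def _flat_specs(ps, p=0.5):
    """All treatment-window transition probabilities set to the same value,
    with resolution = 1 - persistence, so every strategy induces the same
    pain chain."""
    tp = {}
    for (ctx, band, kind) in ps.treatment_pain:
        tp[(ctx, band, kind)] = fixed_spec(1.0 - p if kind == "resolution" else p)
    return ps.replace_specs(treatment_pain=tp)


class TestDiscounting:
    @pytest.mark.parametrize(
        "quarter, r, factor", [(0, 0.03, 1.0), (4, 0.03, 1 / 1.03), (40, 0.0, 1.0)]
    )
    def test_quarterly_discount_factor(self, quarter, r, factor):
        assert discount_factor(quarter, r) == pytest.approx(factor)

    def test_negative_quarter_rejected(self):
        with pytest.raises(ParameterError):
            discount_factor(-1, 0.03)

    def test_discounted_total_below_undiscounted(self, ps):
        disc = run_strategy("PT", ps)
        undisc = run_strategy("PT", dataclasses.replace(ps, discount_rate_annual=0.0))
        assert disc.mean_qalys < undisc.mean_qalys
        assert disc.mean_direct_cost < undisc.mean_direct_cost


class TestTimeCostQuarter:
    def test_hours_times_wage_times_employment(self):
        assert time_cost_quarter(109, 22.33, 1.0) == pytest.approx(2433.97)
        assert time_cost_quarter(30, 22.33, 1.0) == pytest.approx(669.9)
        assert time_cost_quarter(87, 22.33, 0.0) == 0.0

    def test_employment_probability_validated(self):
        with pytest.raises(ParameterError):
            time_cost_quarter(10, 22.33, 1.5)


class TestCohortEngine:
    def test_zero_horizon_accrues_nothing(self, ps):
        r = run_strategy("PT", ps, horizon_years=0)
        assert r.mean_qalys == 0.0
        assert r.mean_direct_cost == 0.0

    def test_single_quarter_hand_accrual(self, ps):
        """An immortal cohort in moderate pain for one undiscounted quarter
        accrues exactly u_moderate / 4 QALYs."""
        immortal = pd.DataFrame(
            {"age": np.arange(40, 111), "annual_death_prob": np.zeros(71)}
        )
        tp = {k: fixed_spec(1.0 if k[2] == "failed_relief" else 0.0)
              for k in ps.treatment_pain}
        stuck = dataclasses.replace(
            ps.replace_specs(treatment_pain=tp),
            discount_rate_annual=0.0,
            adverse_events={
                k: dataclasses.replace(v, mortality=0.0)
                for k, v in ps.adverse_events.items()
            },
        )
        r = run_strategy("PT", stuck, RunOptions(horizon_years=0.25), life_table=immortal)
        assert r.mean_qalys == pytest.approx(0.771 / 4, abs=1e-12)
        assert r.trajectory_moderate_pain[1] == pytest.approx(1.0)

    def test_occupancy_is_conserved_every_quarter(self, base_results):
        for r in base_results.values():
            assert r.max_conservation_error < 1e-10

    def test_occupancy_conserved_under_sensitivity_options(self, ps):
        for options in (
            RunOptions(validate=True, delayed_efficacy_scenario="same_as_immediate"),
            RunOptions(validate=True, apm_progression_multiplier=2.5),
            RunOptions(validate=True, include_time_costs=True, horizon_years=5),
        ):
            r = run_strategy("DelayedAPM", ps, options)
            assert r.max_conservation_error < 1e-10

    def test_qalys_strictly_decrease_with_moderate_utility(self, ps, base_results):
        worse = dataclasses.replace(ps, utilities={"low": 0.869, "moderate": 0.70, "dead": 0.0})
        for strat, r in base_results.items():
            assert run_strategy(strat, worse).mean_qalys < r.mean_qalys

    def test_identical_pain_parameters_equalise_qalys(self, ps):
        """With one shared pain chain and no perioperative mortality the
        strategies differ only in treatment costs."""
        flat = _flat_specs(ps)
        flat = dataclasses.replace(
            flat,
            adverse_events={
                k: dataclasses.replace(v, mortality=0.0)
                for k, v in flat.adverse_events.items()
            },
        )
        results = {s: run_strategy(s, flat) for s in m.STRATEGIES}
        q = [r.mean_qalys for r in results.values()]
        assert max(q) - min(q) < 1e-9
        costs = sorted(r.mean_direct_cost for r in results.values())
        assert costs[0] < costs[-1]  # bundles still differ

    def test_progression_multiplier_spares_pt(self, ps, base_results):
        opts = RunOptions(apm_progression_multiplier=2.0)
        assert run_strategy("PT", ps, opts).mean_qalys == pytest.approx(
            base_results["PT"].mean_qalys, abs=1e-12
        )
        assert run_strategy("ImmediateAPM", ps, opts).mean_qalys < base_results[
            "ImmediateAPM"
        ].mean_qalys
        assert run_strategy("DelayedAPM", ps, opts).mean_qalys < base_results[
            "DelayedAPM"
        ].mean_qalys

    def test_delayed_efficacy_scenario_improves_delayed_only(self, ps, base_results):
        opts = RunOptions(delayed_efficacy_scenario="same_as_immediate")
        better = run_strategy("DelayedAPM", ps, opts)
        assert better.mean_qalys > base_results["DelayedAPM"].mean_qalys
        assert run_strategy("PT", ps, opts).mean_qalys == pytest.approx(
            base_results["PT"].mean_qalys
        )

    def test_unknown_strategy_rejected(self, ps):
        with pytest.raises(ParameterError):
            run_strategy("Arthroscopy", ps)


class TestTrajectories:
    def test_entry_state_is_all_moderate_no_tka(self, base_results):
        for r in base_results.values():
            assert trajectory_stats(r, 0) == (1.0, 0.0)

    def test_cumulative_tka_is_nondecreasing_and_bounded(self, base_results):
        for r in base_results.values():
            tka = r.cumulative_tka
            assert (np.diff(tka) >= -1e-15).all()
            assert 0 <= tka[-1] <= 1
            assert ((r.trajectory_moderate_pain >= 0) & (r.trajectory_moderate_pain <= 1)).all()

    def test_out_of_range_quarter_rejected(self, base_results):
        with pytest.raises(ParameterError):
            trajectory_stats(base_results["PT"], 41)


class TestMicrosim:
    def test_requires_n_subjects(self, ps):
        with pytest.raises(ParameterError):
            run_strategy("PT", ps, mode="microsim")

    def test_seeded_runs_are_identical(self, ps):
        a = run_strategy("PT", ps, mode="microsim", n_subjects=2000, seed=11)
        b = run_strategy("PT", ps, mode="microsim", n_subjects=2000, seed=11)
        assert a.mean_qalys == b.mean_qalys
        assert a.mean_direct_cost == b.mean_direct_cost
        assert (a.trajectory_moderate_pain == b.trajectory_moderate_pain).all()

    def test_reports_standard_errors(self, ps):
        r = run_strategy("PT", ps, mode="microsim", n_subjects=2000, seed=1)
        assert r.mode == "microsim" and r.n_subjects == 2000
        assert r.se_qalys > 0 and r.se_direct_cost > 0


class TestEntryAges:
    def test_bins_cover_range_with_unit_weights(self, ps):
        ages, w = entry_age_bins(ps)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert ages.min() >= 45 and ages.max() <= 75
        mean = (ages * w).sum()
        assert mean == pytest.approx(58, abs=0.5)  # truncation pulls slightly


class TestPSA:
    def test_iteration_outcomes_are_replayable(self, ps):
        res = m.run_psa(ps, 8, seed=31)
        # replay iteration 5 by reconstructing its parameter draw
        drawn = m.sample_psa(ps, seed=31, iteration=5)
        r = run_strategy("DelayedAPM", drawn)
        j = res.strategies.index("DelayedAPM")
        assert res.qalys[5, j] == pytest.approx(r.mean_qalys, abs=1e-12)
        assert res.direct_costs[5, j] == pytest.approx(r.mean_direct_cost, abs=1e-9)

    def test_chunking_does_not_change_results(self, ps):
        a = m.run_psa(ps, 7, seed=2, chunk_size=3)
        b = m.run_psa(ps, 7, seed=2, chunk_size=100)
        assert np.allclose(a.qalys, b.qalys)
        assert np.allclose(a.direct_costs, b.direct_costs)
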