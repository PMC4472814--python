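"""Value-of-information analysis: EVPI, nested-Monte-Carlo EVPPI, population VOI.

The per-person expected value of perfect information (EVPI) is the expected
gain, in net-monetary-benefit terms, from resolving all parameter
uncertainty before choosing a strategy:

    EVPI = E_theta[ max_s NMB_s(theta) ] - max_s E_theta[ NMB_s(theta) ]

The expected value of *partial* perfect information (EVPPI) restricts the
resolved uncertainty to a parameter group; it is estimated here by nested
two-level Monte Carlo (outer draws fix the group, inner draws integrate over
the complement).  Population VOI scales per-person EVPI by the number of
persons facing the treatment decision each year over the usable life of the
information, discounted annually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet, ParameterError, sample_psa
from .engine import RunOptions, STRATEGIES, _run_cohort_batch
from .natural_history import load_life_table

__all__ = [
    "PARAMETER_GROUPS",
    "VOIResult",
    "evpi",
    "evpi_curve",
    "evppi_nested",
    "evppi_nested_generic",
    "population_voi",
    "voi_summary",
]

#: named parameter groups for partial-information analysis: (section, key)
#: pairs matching ParameterSet.sampled_keys()
PARAMETER_GROUPS: dict[str, callable] = {
    "delayed_apm_efficacy": lambda section, key: section == "treatment_pain"
    and key[0] == "APM_after_PT",
    "apm_progression": lambda section, key: section == "kl_progression",
    "pain_management_costs": lambda section, key: section == "costs"
    and key in ("pain_mgmt_moderate", "pain_mgmt_low"),
    "time_costs": lambda section, key: section == "time_hours",
}


def evpi(values: np.ndarray) -> float:
    """Per-person EVPI from an (iterations, strategies) NMB array."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ParameterError("evpi requires >= 2 iterations and >= 2 strategies")
    # mean-of-max >= max-of-mean holds exactly; floor away rounding noise
    return max(0.0, float(values.max(axis=1).mean() - values.mean(axis=0).max()))


def evpi_curve(costs: np.ndarray, qalys: np.ndarray, wtp_grid) -> np.ndarray:
    """EVPI at each WTP on a grid, from per-iteration costs and QALYs."""
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    out = np.empty(len(wtp_grid))
    for w, wtp in enumerate(np.asarray(wtp_grid, dtype=float)):
        out[w] = evpi(wtp * qalys - costs)
    return out


def group_keys(ps: ParameterSet, group: str) -> set:
    """The (section, key) pairs a named parameter group resolves to."""
    if group not in PARAMETER_GROUPS:
        raise ParameterError(
            f"unknown parameter group {group!r}; known: {sorted(PARAMETER_GROUPS)}"
        )
    pred = PARAMETER_GROUPS[group]
    return {(s, k) for s, k in ps.sampled_keys() if pred(s, k)}


def evppi_nested_generic(
    draw_group,
    nmb_given_group,
    outer_n: int,
    inner_n: int,
    seed: int,
) -> float:
    """Nested two-level Monte Carlo EVPPI for an arbitrary decision model.

    ``draw_group(rng)`` samples the parameters whose uncertainty would be
    resolved; ``nmb_given_group(g, rng, inner_n)`` returns an
    ``(inner_n, strategies)`` NMB array with the complement sampled.  The
    estimate is floored at zero.
    """
    if outer_n < 2 or inner_n < 2:
        raise ParameterError("outer_n and inner_n must both be >= 2")
    rng = np.random.default_rng(seed)
    best_given_info = 0.0
    overall_sum = None
    for _ in range(outer_n):
        g = draw_group(rng)
        values = np.asarray(nmb_given_group(g, rng, inner_n), dtype=float)
        inner_mean = values.mean(axis=0)
        best_given_info += inner_mean.max()
        overall_sum = inner_mean if overall_sum is None else overall_sum + inner_mean
    best_given_info /= outer_n
    best_current = (overall_sum / outer_n).max()
    return max(0.0, float(best_given_info - best_current))


def evppi_nested(
    group: str,
    ps: ParameterSet,
    wtp: float,
    outer_n: int = 500,
    inner_n: int = 500,
    seed: int = 0,
    options: RunOptions | None = None,
    strategies: tuple[str, ...] = STRATEGIES,
) -> float:
    """Nested-MC EVPPI of a named parameter group for the treatment model.

    Outer iterations fix the group's parameters at a PSA draw; inner
    iterations sample every other distribution-carrying parameter and
    evaluate all strategies in cohort mode.  A group with no sampled members
    (for example structural-progression rates, which the PSA holds fixed)
    has zero EVPPI by construction.
    """
    keys = group_keys(ps, group)
    if not keys:
        return 0.0
    options = options or RunOptions()
    life_table = load_life_table(ps.life_table_path)
    complement = {k for k in ps.sampled_keys() if k not in keys}

    def draw_group(rng):
        # deterministic child stream per outer draw, derived from the rng
        sub_seed = int(rng.integers(0, 2**31 - 1))
        return sample_psa(ps, sub_seed, 0, subset=keys)

    def nmb_given_group(fixed_ps, rng, n_inner):
        base = int(rng.integers(0, 2**31 - 1))
        draws = [sample_psa(fixed_ps, base, i, subset=complement) for i in range(n_inner)]
        values = np.empty((n_inner, len(strategies)))
        for j, strat in enumerate(strategies):
            out = _run_cohort_batch(strat, draws, options, life_table)
            values[:, j] = wtp * out["qalys"] - (
                out["direct"] + (out["time"] if options.include_time_costs else 0.0)
            )
        return values

    return evppi_nested_generic(draw_group, nmb_given_group, outer_n, inner_n, seed)


def population_voi(
    evpi_pp: float, annual_count: float, usable_years: int, r_annual: float
) -> float:
    """Population value of information, USD.

    Per-person EVPI times the annual number of persons facing the decision,
    summed over the usable life of the information with each successive
    year's cohort discounted: ``evpi_pp * N * sum_{t=0}^{Y-1} (1+r)^-t``.
    """
    if min(evpi_pp, annual_count, usable_years) < 0 or r_annual < 0:
        raise ParameterError("population_voi inputs must be non-negative")
    annuity = sum((1.0 + r_annual) ** (-t) for t in range(int(usable_years)))
    return float(evpi_pp * annual_count * annuity)


@dataclass
class VOIResult:
    """Value-of-information summary at one willingness-to-pay threshold."""

    wtp: float
    evpi_pp: float
    population_voi: float
    qaly_equivalent: float  # population VOI expressed in QALYs at this WTP
    assumptions: dict = field(default_factory=dict)
    evppi_pp: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evpi_pp < 0 or self.population_voi < 0:
            raise ParameterError("value of information cannot be negative")


def voi_summary(
    costs: np.ndarray,
    qalys: np.ndarray,
    wtp: float,
    annual_count: float = 352_000.0,
    usable_years: int = 3,
    r_annual: float = 0.03,
    evppi_pp: dict | None = None,
) -> VOIResult:
    """EVPI and population VOI from per-iteration PSA costs and QALYs."""
    e = evpi(wtp * np.asarray(qalys) - np.asarray(costs))
    pop = population_voi(e, annual_count, usable_years, r_annual)
    return VOIResult(
        wtp=wtp,
        evpi_pp=e,
        population_voi=pop,
        qaly_equivalent=pop / wtp if wtp > 0 else float("nan"),
        assumptions={
            "annual_count": annual_count,
            "usable_years": usable_years,
            "discount_rate_annual": r_annual,
        },
        evppi_pp=evppi_pp or {},
    )
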