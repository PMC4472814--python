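"""Strategy evaluation engine: discounted QALY and cost accrual over the horizon.

Two evaluation modes share one set of transition rules:

``cohort``
    Exact expectation over a stratified state distribution (entry-age bins x
    KL grade x pain x TKA status x consecutive-pain counter).  Deterministic
    given a :class:`~meniscea.params.ParameterSet`; this is the default and
    what the probabilistic sensitivity analysis iterates.

``microsim``
    Per-subject Monte Carlo with sampled entry ages and KL grades and
    Bernoulli transitions.  Converges to the cohort expectation and is used
    for validation and distributional output.

Quarterly cycle order: death -> KL progression -> treatment/TKA election ->
pain update -> accrual.  No half-cycle correction is applied (quarterly
cycles are short).  Utilities and recurring costs accrue on the state
occupied during the quarter (post-update); one-time treatment costs accrue
in the quarter of the procedure.  Time (productivity) costs are tracked
separately from direct medical costs, so one run serves both the payer and
societal perspectives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, ParameterError, sample_psa
from .natural_history import load_life_table, life_table_array, to_quarterly

__all__ = [
    "STRATEGIES",
    "RunOptions",
    "StrategyResult",
    "PSAResult",
    "discount_factor",
    "time_cost_quarter",
    "run_strategy",
    "run_base_case",
    "run_psa",
    "trajectory_stats",
]

STRATEGIES = ("PT", "DelayedAPM", "ImmediateAPM")

_K, _P, _C = 4, 2, 3  # KL grades, pain levels, consecutive-moderate counter cap
_BANDS = ((slice(0, 2), "KL02"), (slice(2, 4), "KL34"))


@dataclass(frozen=True)
class RunOptions:
    """Options controlling one strategy evaluation."""

    horizon_years: float | None = None  # default: ParameterSet.horizon_years
    include_time_costs: bool = False
    delayed_efficacy_scenario: str = "crossover"  # or "same_as_immediate"
    apm_progression_multiplier: float = 1.0
    mode: str = "cohort"  # or "microsim"
    n_subjects: int | None = None
    seed: int | None = None
    validate: bool = False  # track state-occupancy conservation

    def __post_init__(self) -> None:
        if self.delayed_efficacy_scenario not in ("crossover", "same_as_immediate"):
            raise ParameterError(
                f"unknown delayed efficacy scenario {self.delayed_efficacy_scenario!r}"
            )
        if self.mode not in ("cohort", "microsim"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.apm_progression_multiplier < 1.0:
            raise ParameterError("apm_progression_multiplier must be >= 1")


@dataclass
class StrategyResult:
    """Discounted per-person outcomes of one strategy under one parameter set."""

    strategy: str
    mean_qalys: float
    mean_direct_cost: float
    mean_time_cost: float
    trajectory_moderate_pain: np.ndarray  # index = quarter, 0 = entry
    cumulative_tka: np.ndarray
    mode: str
    n_subjects: int | None = None
    se_qalys: float | None = None
    se_direct_cost: float | None = None
    max_conservation_error: float | None = None

    def total_cost(self, include_time_costs: bool = False) -> float:
        return self.mean_direct_cost + (self.mean_time_cost if include_time_costs else 0.0)


@dataclass
class PSAResult:
    """Per-iteration strategy outcomes from a probabilistic sensitivity analysis."""

    strategies: tuple[str, ...]
    qalys: np.ndarray  # (iterations, strategies)
    direct_costs: np.ndarray
    time_costs: np.ndarray
    seed: int

    def costs(self, include_time_costs: bool = False) -> np.ndarray:
        return self.direct_costs + (self.time_costs if include_time_costs else 0.0)

    @property
    def n_iterations(self) -> int:
        return self.qalys.shape[0]


def discount_factor(quarter_index: int, r_annual: float) -> float:
    """Present-value factor for a quarter: (1 + r) ** (-quarter/4)."""
    if quarter_index < 0:
        raise ParameterError("quarter_index must be >= 0")
    return float((1.0 + r_annual) ** (-quarter_index / 4.0))


def time_cost_quarter(hours: float, wage_rate: float, employment_prob: float) -> float:
    """Productivity cost of one quarter: hours lost x hourly wage x P(employed)."""
    if not (0.0 <= employment_prob <= 1.0):
        raise ParameterError("employment_prob must lie in [0, 1]")
    return hours * wage_rate * employment_prob


# -- entry-age distribution ---------------------------------------------------


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def entry_age_bins(ps: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """Integer-year entry-age bins (midpoint ages, weights) for cohort mode.

    Entry ages follow Normal(mean age, sd) truncated to the cohort age range;
    each one-year bin is represented by its midpoint.
    """
    lo, hi = ps.cohort_age_range
    mu, sd = ps.cohort_mean_age, ps.cohort_sd_age
    edges = np.arange(math.floor(lo), math.ceil(hi) + 1, dtype=float)
    cdf = np.array([_norm_cdf((e - mu) / sd) for e in edges])
    w = np.diff(cdf)
    w /= w.sum()
    mids = edges[:-1] + 0.5
    keep = w > 1e-12
    return mids[keep], w[keep] / w[keep].sum()


def _sample_entry_ages(ps: ParameterSet, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = ps.cohort_age_range
    ages = rng.normal(ps.cohort_mean_age, ps.cohort_sd_age, size=n)
    bad = (ages < lo) | (ages > hi)
    while bad.any():
        ages[bad] = rng.normal(ps.cohort_mean_age, ps.cohort_sd_age, size=int(bad.sum()))
        bad = (ages < lo) | (ages > hi)
    return ages


# -- parameter extraction -----------------------------------------------------


class _Vals:
    """Numeric parameter values for a batch of parameter sets.

    Sampled parameters become ``(B, 1)`` columns broadcasting over the cohort
    axes; structurally fixed parameters are taken from the first set (the PSA
    varies only distribution-carrying entries).
    """

    def __init__(self, ps_list: list[ParameterSet]):
        ps0 = ps_list[0]
        self.B = len(ps_list)
        self.ps0 = ps0

        def col(fn) -> np.ndarray:
            return np.array([fn(p) for p in ps_list])[:, None]

        self.ff = {
            (c, b): col(lambda p, c=c, b=b: p.treatment_pain[(c, b, "failed_relief")].mean)
            for c in ("APM", "APM_after_PT", "PT")
            for b in ("KL02", "KL34")
        }
        self.inc = {
            (c, b): col(lambda p, c=c, b=b: p.treatment_pain[(c, b, "incidence")].mean)
            for c in ("APM", "PT")
            for b in ("KL02", "KL34")
        }
        self.res = {
            (c, b): col(lambda p, c=c, b=b: p.treatment_pain[(c, b, "resolution")].mean)
            for c in ("APM", "PT")
            for b in ("KL02", "KL34")
        }
        self.cost = {k: col(lambda p, k=k: p.costs[k].mean) for k in ps0.costs}
        self.hours = {k: col(lambda p, k=k: p.time_hours[k].mean) for k in ps0.time_hours}

        self.u_low = ps0.utilities["low"]
        self.u_mod = ps0.utilities["moderate"]
        grades = ("KL01", "KL2", "KL3", "KL4")
        self.q_oa_inc = np.array([to_quarterly(ps0.oa_pain_incidence[g]) for g in grades])
        self.q_oa_res = np.array([to_quarterly(ps0.oa_pain_resolution[g]) for g in grades])
        self.eff_tka = np.array(
            [ps0.tka_efficacy_first_year] * 4 + [ps0.tka_efficacy_subsequent]
        )
        self.ae = ps0.adverse_events
        self.q_pharm = to_quarterly(ps0.adverse_events["pharm"].prob)
        self.wage = ps0.wage_rate
        self.r = ps0.discount_rate_annual

    def apm_bundle(self) -> np.ndarray:
        """Expected cost charged in an APM surgery quarter (procedure,
        post-operative healthcare, rehabilitation, expected complication)."""
        return (
            self.cost["apm_procedure"]
            + self.cost["apm_post_healthcare"]
            + self.cost["apm_rehab"]
            + self.ae["APM"].prob * self.cost["apm_complication"]
        )

    def apm_cross_bundle(self) -> np.ndarray:
        """Surgery-quarter cost for crossover subjects.  Their physical-
        therapy course was already charged in the PT quarter (PT costs apply
        only to cycles where PT was used), so no second rehabilitation
        bundle accrues."""
        return (
            self.cost["apm_procedure"]
            + self.cost["apm_post_healthcare"]
            + self.ae["APM"].prob * self.cost["apm_complication"]
        )

    def pt_bundle(self) -> np.ndarray:
        return self.cost["pt_healthcare"] + self.cost["pt_rehab"]

    def tka_bundle(self) -> np.ndarray:
        return self.cost["tka_procedure"] + self.ae["TKA"].prob * self.cost["tka_complication"]


def _age_grids(ps: ParameterSet, rep_ages: np.ndarray, n_quarters: int, life_table):
    """Per (entry-age, quarter) lookups: quarterly mortality, OA incidence,
    TKA uptake and employment probability."""
    lo, dense = life_table_array(life_table)
    ages = rep_ages[:, None] + np.arange(n_quarters)[None, :] / 4.0  # (A, T)
    iage = np.floor(ages).astype(int)
    if (iage < lo).any():
        raise ParameterError("entry ages fall below the life table range")
    idx = np.clip(iage - lo, 0, len(dense) - 1)
    q_annual = dense[idx]
    q_annual[iage - lo >= len(dense)] = 1.0
    q_mort = 1.0 - (1.0 - q_annual) ** 0.25

    def band_grid(bands):
        out = np.zeros_like(ages)
        for blo, bhi, p in bands:
            out[(iage >= blo) & (iage <= bhi)] = p
        return 1.0 - (1.0 - out) ** 0.25

    p_oa = band_grid(ps.oa_incidence_by_age)
    p_tka = band_grid(ps.tka_uptake_by_age)
    xs = [a for a, _ in ps.employment_schedule]
    ys = [p for _, p in ps.employment_schedule]
    emp = np.interp(ages, xs, ys)
    return q_mort, p_oa, p_tka, emp


# -- cohort engine ------------------------------------------------------------


def _run_cohort_batch(
    strategy: str,
    ps_list: list[ParameterSet],
    options: RunOptions,
    life_table,
) -> dict:
    """Evaluate one strategy for a batch of parameter sets in cohort mode."""
    v = _Vals(ps_list)
    ps0 = v.ps0
    horizon = options.horizon_years if options.horizon_years is not None else ps0.horizon_years
    T = int(round(horizon * 4))
    B = v.B
    rep_ages, age_w = entry_age_bins(ps0)
    A = len(rep_ages)
    mult = options.apm_progression_multiplier
    # a who-had-APM flag is needed only where surgery reaches part of the
    # cohort and structural progression depends on it
    h_dim = 2 if (strategy == "DelayedAPM" and mult != 1.0) else 1

    if T == 0:
        z = np.zeros(B)
        return {
            "qalys": z,
            "direct": z.copy(),
            "time": z.copy(),
            "traj_mod": np.ones((B, 1)),
            "traj_tka": np.zeros((B, 1)),
            "conservation_error": 0.0,
        }

    q_mort, p_oa, p_tka_grid, emp = _age_grids(ps0, rep_ages, T, life_table)

    # occupancy: pre-TKA (B, A, KL, pain, consec, had_apm) and post-TKA
    # (B, A, pain, quarters-since-TKA capped at 5)
    pre = np.zeros((B, A, _K, _P, _C, h_dim))
    pre[:, :, :, 1, 0, 0] = np.asarray(ps0.kl_shares)[None, None, :]  # enter in pain
    post = np.zeros((B, A, _P, 5))
    dead = np.zeros((B, A))
    cum_tka = np.zeros((B, A))

    qaly = np.zeros((B, A))
    dcost = np.zeros((B, A))
    tcost = np.zeros((B, A))
    traj_mod = np.ones((B, T + 1))
    traj_tka = np.zeros((B, T + 1))
    cons_err = 0.0

    arm = "APM" if strategy == "ImmediateAPM" else "PT"
    cross_ctx = "APM" if options.delayed_efficacy_scenario == "same_as_immediate" else "APM_after_PT"
    ff = {b: v.ff[(arm, b)] for b in ("KL02", "KL34")}
    fx = {b: v.ff[(cross_ctx, b)] for b in ("KL02", "KL34")}
    inc = {b: v.inc[(arm, b)] for b in ("KL02", "KL34")}
    res = {b: v.res[(arm, b)] for b in ("KL02", "KL34")}

    base23 = to_quarterly(ps0.kl_progression["kl2_to_kl3"])
    base34 = to_quarterly(ps0.kl_progression["kl3_to_kl4"])
    mult23 = to_quarterly(min(1.0, ps0.kl_progression["kl2_to_kl3"] * mult))
    mult34 = to_quarterly(min(1.0, ps0.kl_progression["kl3_to_kl4"] * mult))
    # per had-APM level when the flag is tracked (broadcasts on the last axis)
    h23 = np.array([base23, mult23])
    h34 = np.array([base34, mult34])

    pharm_death = v.q_pharm * v.ae["pharm"].mortality
    apm_death = v.ae["APM"].prob * v.ae["APM"].mortality
    tka_death = v.ae["TKA"].prob * v.ae["TKA"].mortality
    pharm_cost = v.q_pharm * v.cost["pain_mgmt_complication"]  # (B, 1)

    for t in range(1, T + 1):
        disc = (1.0 + v.r) ** (-(t - 1) / 4.0)
        ti = t - 1

        # 1. death: background mortality everywhere; pharmacologic adverse-
        # event mortality among subjects who spent the previous quarter in
        # moderate pain (no exposure before the first cycle completes)
        s = 1.0 - q_mort[:, ti]
        before = pre.sum(axis=(2, 3, 4, 5)) + post.sum(axis=(2, 3))
        pre *= s[None, :, None, None, None, None]
        post *= s[None, :, None, None]
        if t >= 2 and pharm_death > 0:
            pre[:, :, :, 1] *= 1.0 - pharm_death
            post[:, :, 1] *= 1.0 - pharm_death
        after = pre.sum(axis=(2, 3, 4, 5)) + post.sum(axis=(2, 3))
        dead += before - after

        # 2. structural progression (at most one KL step per quarter)
        if h_dim == 2:
            pr23, pr34 = h23, h34
        elif strategy == "ImmediateAPM" and t >= 2:
            pr23, pr34 = mult23, mult34  # surgery in quarter 1 reached everyone
        else:
            pr23, pr34 = base23, base34
        mv = pre[:, :, 2] * pr34
        pre[:, :, 3] += mv
        pre[:, :, 2] -= mv
        mv = pre[:, :, 1] * pr23
        pre[:, :, 2] += mv
        pre[:, :, 1] -= mv
        p01 = p_oa[:, ti][None, :, None, None, None]
        mv = pre[:, :, 0] * p01
        pre[:, :, 1] += mv
        pre[:, :, 0] -= mv

        # 3. treatment / TKA election
        m_cross = None
        if t == 1:
            alive_mass = pre.sum(axis=(2, 3, 4, 5))
            if strategy == "ImmediateAPM":
                dcost += alive_mass * v.apm_bundle() * disc
                surv = 1.0 - apm_death
                dead += alive_mass * (1.0 - surv)
                pre *= surv
            else:
                dcost += alive_mass * v.pt_bundle() * disc
        if t == 2 and strategy == "DelayedAPM":
            # every subject still in moderate pain after the PT quarter
            # elects surgery (probability 1): charge the APM bundle and apply
            # perioperative risk to exactly that mass
            m_cross = pre[:, :, :, 1].sum(axis=(2, 3, 4))
            dcost += m_cross * v.apm_cross_bundle() * disc
            surv = 1.0 - apm_death
            dead += m_cross * (1.0 - surv)
            pre[:, :, :, 1] *= surv
            m_cross = m_cross * surv
            if h_dim == 2:
                pre[:, :, :, 1, :, 1] += pre[:, :, :, 1, :, 0]
                pre[:, :, :, 1, :, 0] = 0.0
        if t >= 2:
            pt_q = p_tka_grid[:, ti][None, :, None, None]  # (1, A, 1, 1)
            elig = pre[:, :, 2:, 1, 2]  # KL3/4, moderate, >=2 consecutive quarters
            mv = elig * pt_q
            pre[:, :, 2:, 1, 2] -= mv
            m_tka = mv.sum(axis=(2, 3))
            cum_tka += m_tka
            dcost += m_tka * v.tka_bundle() * disc
            surv = 1.0 - tka_death
            dead += m_tka * (1.0 - surv)
            post[:, :, 1, 0] += m_tka * surv

        # 4. pain update
        low_by_band = {}
        if t == 1:
            for bi, band in _BANDS:
                tot = pre[:, :, bi].sum(axis=3)  # (B, A, k, C, h)
                f = ff[band][:, :, None, None, None]
                pre[:, :, bi, 1] = tot * f
                pre[:, :, bi, 0] = tot * (1.0 - f)
        elif t == 2:
            for bi, band in _BANDS:
                p1 = pre[:, :, bi, 1].copy()
                p0 = pre[:, :, bi, 0].copy()
                low_by_band[band] = p0.sum(axis=(2, 3, 4))
                i = inc[band][:, :, None, None, None]
                r_ = res[band][:, :, None, None, None]
                if strategy == "DelayedAPM":
                    # crossovers: a single failed-relief draw after surgery
                    f = fx[band][:, :, None, None, None]
                    pre[:, :, bi, 1] = p1 * f + p0 * i
                    pre[:, :, bi, 0] = p1 * (1.0 - f) + p0 * (1.0 - i)
                else:
                    pre[:, :, bi, 1] = p1 * (1.0 - r_) + p0 * i
                    pre[:, :, bi, 0] = p1 * r_ + p0 * (1.0 - i)
        else:
            qi = v.q_oa_inc[None, None, :, None, None]
            qr = v.q_oa_res[None, None, :, None, None]
            p1 = pre[:, :, :, 1].copy()
            p0 = pre[:, :, :, 0].copy()
            pre[:, :, :, 1] = p1 * (1.0 - qr) + p0 * qi
            pre[:, :, :, 0] = p1 * qr + p0 * (1.0 - qi)
        if t >= 2:
            # post-TKA pain: low with the first-year / subsequent efficacy
            tot = post.sum(axis=2)  # (B, A, 5)
            post[:, :, 0] = tot * v.eff_tka[None, None, :]
            post[:, :, 1] = tot * (1.0 - v.eff_tka[None, None, :])

        # 5. counters (only quarters after the initial treatment period count)
        if t >= 2:
            p1 = pre[:, :, :, 1]
            c0 = p1[..., 0, :].copy()
            c12 = p1[..., 1, :] + p1[..., 2, :]
            pre[:, :, :, 1, 0] = 0.0
            pre[:, :, :, 1, 1] = c0
            pre[:, :, :, 1, 2] = c12
            s0 = pre[:, :, :, 0].sum(axis=3)
            pre[:, :, :, 0] = 0.0
            pre[:, :, :, 0, 0] = s0
            post[:, :, :, 4] += post[:, :, :, 3]
            post[:, :, :, 1:4] = post[:, :, :, 0:3].copy()
            post[:, :, :, 0] = 0.0

        # 6. accrual on the post-update state
        mod = pre[:, :, :, 1].sum(axis=(2, 3, 4)) + post[:, :, 1].sum(axis=2)
        low = pre[:, :, :, 0].sum(axis=(2, 3, 4)) + post[:, :, 0].sum(axis=2)
        qaly += (low * v.u_low + mod * v.u_mod) * 0.25 * disc
        dcost += (
            mod * (v.cost["pain_mgmt_moderate"] + pharm_cost)
            + low * v.cost["pain_mgmt_low"]
        ) * disc
        # time costs: months 0-6 hours are already averaged over employed and
        # unemployed subjects; the employment schedule weights later quarters
        if t == 1:
            h_key = "apm_q1" if strategy == "ImmediateAPM" else "pt_q1"
            tcost += (mod + low) * v.hours[h_key] * v.wage * disc
        elif t == 2:
            if strategy == "DelayedAPM":
                # crossovers spend the quarter in surgery and recovery; the
                # rest follow the months 3-6 hours for their (incidence-drawn)
                # pain state
                hrs = m_cross * v.hours["apm_q1"]
                for band in ("KL02", "KL34"):
                    m0 = low_by_band[band]
                    hrs += m0 * (
                        inc[band] * v.hours["q2_moderate"]
                        + (1.0 - inc[band]) * v.hours["q2_low"]
                    )
            else:
                hrs = mod * v.hours["q2_moderate"] + low * v.hours["q2_low"]
            tcost += hrs * v.wage * disc
        else:
            hrs = mod * v.hours["later_moderate"] + low * v.hours["later_low"]
            tcost += hrs * emp[:, ti][None, :] * v.wage * disc

        alive = mod + low
        if options.validate:
            cons_err = max(cons_err, float(np.abs(alive + dead - 1.0).max()))
        traj_mod[:, t] = (mod * age_w[None, :]).sum(axis=1) / np.maximum(
            (alive * age_w[None, :]).sum(axis=1), 1e-300
        )
        traj_tka[:, t] = (cum_tka * age_w[None, :]).sum(axis=1)

    return {
        "qalys": (qaly * age_w[None, :]).sum(axis=1),
        "direct": (dcost * age_w[None, :]).sum(axis=1),
        "time": (tcost * age_w[None, :]).sum(axis=1),
        "traj_mod": traj_mod,
        "traj_tka": traj_tka,
        "conservation_error": cons_err,
    }


# -- microsimulation ----------------------------------------------------------


def _run_microsim(
    strategy: str,
    ps: ParameterSet,
    options: RunOptions,
    life_table,
) -> StrategyResult:
    """Per-subject Monte Carlo evaluation with the same transition rules."""
    if options.n_subjects is None:
        raise ParameterError("microsim mode requires n_subjects")
    n = int(options.n_subjects)
    rng = np.random.default_rng(options.seed if options.seed is not None else 0)
    v = _Vals([ps])
    horizon = options.horizon_years if options.horizon_years is not None else ps.horizon_years
    T = int(round(horizon * 4))
    lo_age, dense = life_table_array(life_table)

    ages0 = _sample_entry_ages(ps, n, rng)
    kl = rng.choice(4, size=n, p=np.asarray(ps.kl_shares))
    alive = np.ones(n, dtype=bool)
    pain = np.ones(n, dtype=np.int8)  # 1 = moderate
    consec = np.zeros(n, dtype=np.int8)
    tka_q = np.zeros(n, dtype=np.int16)  # 0 = no TKA, else quarters since
    had_apm = np.zeros(n, dtype=bool)

    qaly = np.zeros(n)
    dcost = np.zeros(n)
    tcost = np.zeros(n)
    traj_mod = np.ones(T + 1)
    traj_tka = np.zeros(T + 1)
    ever_tka = np.zeros(n, dtype=bool)

    arm = "APM" if strategy == "ImmediateAPM" else "PT"
    cross_ctx = "APM" if options.delayed_efficacy_scenario == "same_as_immediate" else "APM_after_PT"
    mult = options.apm_progression_multiplier

    def scalar(col):
        return float(col[0, 0])

    band_of = (kl >= 2).astype(np.int8)  # 0 -> KL 0-2, 1 -> KL 3-4

    def band_val(pair_02, pair_34):
        return np.where(band_of == 0, pair_02, pair_34)

    apm_bundle = scalar(v.apm_bundle())
    pt_bundle = scalar(v.pt_bundle())
    oa_bands = ps.oa_incidence_by_age
    tka_bands = ps.tka_uptake_by_age
    xs = [a for a, _ in ps.employment_schedule]
    ys = [p for _, p in ps.employment_schedule]

    def band_lookup(bands, iage):
        out = np.zeros_like(iage, dtype=float)
        for blo, bhi, p in bands:
            out[(iage >= blo) & (iage <= bhi)] = p
        return 1.0 - (1.0 - out) ** 0.25

    for t in range(1, T + 1):
        disc = (1.0 + v.r) ** (-(t - 1) / 4.0)
        age = ages0 + (t - 1) / 4.0
        iage = np.floor(age).astype(int)
        idx = np.clip(iage - lo_age, 0, len(dense) - 1)
        qm = dense[idx].copy()
        qm[iage - lo_age >= len(dense)] = 1.0
        qm = 1.0 - (1.0 - qm) ** 0.25

        # 1. death
        p_die = qm.copy()
        if t >= 2:
            p_die = np.where(
                pain == 1, 1.0 - (1.0 - qm) * (1.0 - v.q_pharm * v.ae["pharm"].mortality), qm
            )
        alive &= rng.random(n) >= p_die

        # 2. structural progression (pre-TKA knees)
        m23 = np.where(had_apm, mult, 1.0) * ps.kl_progression["kl2_to_kl3"]
        m34 = np.where(had_apm, mult, 1.0) * ps.kl_progression["kl3_to_kl4"]
        u = rng.random(n)
        pre_mask = alive & (tka_q == 0)
        step_up = np.zeros(n, dtype=bool)
        step_up |= pre_mask & (kl == 2) & (u < 1.0 - (1.0 - np.minimum(1.0, m34)) ** 0.25)
        step_up |= pre_mask & (kl == 1) & (u < 1.0 - (1.0 - np.minimum(1.0, m23)) ** 0.25)
        step_up |= pre_mask & (kl == 0) & (u < band_lookup(oa_bands, iage))
        kl = np.where(step_up, kl + 1, kl)
        band_of = (kl >= 2).astype(np.int8)

        # 3. treatment / TKA election
        crossed = np.zeros(n, dtype=bool)
        if t == 1:
            if strategy == "ImmediateAPM":
                dcost[alive] += scalar(v.cost["apm_procedure"] + v.cost["apm_post_healthcare"] + v.cost["apm_rehab"]) * disc
                ae_hit = alive & (rng.random(n) < v.ae["APM"].prob)
                dcost[ae_hit] += scalar(v.cost["apm_complication"]) * disc
                alive[ae_hit] &= rng.random(int(ae_hit.sum())) >= v.ae["APM"].mortality
                had_apm |= alive | ae_hit
            else:
                dcost[alive] += pt_bundle * disc
        if t == 2 and strategy == "DelayedAPM":
            crossed = alive & (pain == 1)
            # no second rehabilitation bundle: PT was charged in quarter 1
            dcost[crossed] += scalar(v.cost["apm_procedure"] + v.cost["apm_post_healthcare"]) * disc
            ae_hit = crossed & (rng.random(n) < v.ae["APM"].prob)
            dcost[ae_hit] += scalar(v.cost["apm_complication"]) * disc
            alive[ae_hit] &= rng.random(int(ae_hit.sum())) >= v.ae["APM"].mortality
            had_apm |= crossed
            crossed &= alive
        if t >= 2:
            elig = alive & (tka_q == 0) & (kl >= 2) & (consec >= 2) & (pain == 1)
            elect = elig & (rng.random(n) < band_lookup(tka_bands, iage))
            dcost[elect] += scalar(v.cost["tka_procedure"]) * disc
            ae_hit = elect & (rng.random(n) < v.ae["TKA"].prob)
            dcost[ae_hit] += scalar(v.cost["tka_complication"]) * disc
            alive[ae_hit] &= rng.random(int(ae_hit.sum())) >= v.ae["TKA"].mortality
            ever_tka |= elect
            tka_q[elect] = 1

        # 4. pain update
        u = rng.random(n)
        if t == 1:
            f = band_val(scalar(v.ff[(arm, "KL02")]), scalar(v.ff[(arm, "KL34")]))
            pain = (u < f).astype(np.int8)
        elif t == 2:
            f_x = band_val(scalar(v.ff[(cross_ctx, "KL02")]), scalar(v.ff[(cross_ctx, "KL34")]))
            i_ = band_val(scalar(v.inc[(arm, "KL02")]), scalar(v.inc[(arm, "KL34")]))
            r_ = band_val(scalar(v.res[(arm, "KL02")]), scalar(v.res[(arm, "KL34")]))
            p_mod = np.where(pain == 1, 1.0 - r_, i_)
            if strategy == "DelayedAPM":
                p_mod = np.where(crossed, f_x, np.where(pain == 1, 1.0, i_))
            pain = (u < p_mod).astype(np.int8)
        else:
            p_mod = np.where(
                pain == 1, 1.0 - v.q_oa_res[kl], v.q_oa_inc[kl]
            )
            pain = (u < p_mod).astype(np.int8)
        post_mask = tka_q >= 1
        if post_mask.any():
            eff = np.where(tka_q <= 4, ps.tka_efficacy_first_year, ps.tka_efficacy_subsequent)
            pain = np.where(post_mask, (rng.random(n) >= eff).astype(np.int8), pain)

        # 5. counters
        if t >= 2:
            consec = np.where(pain == 1, np.minimum(consec + 1, 2), 0).astype(np.int8)
            tka_q = np.where(tka_q >= 1, np.minimum(tka_q + 1, 1000), 0).astype(np.int16)

        # 6. accrual
        a1 = alive & (pain == 1)
        a0 = alive & (pain == 0)
        qaly[a1] += v.u_mod * 0.25 * disc
        qaly[a0] += v.u_low * 0.25 * disc
        dcost[a1] += scalar(v.cost["pain_mgmt_moderate"]) * disc
        dcost[a0] += scalar(v.cost["pain_mgmt_low"]) * disc
        pharm_hit = a1 & (rng.random(n) < v.q_pharm)
        dcost[pharm_hit] += scalar(v.cost["pain_mgmt_complication"]) * disc
        if t == 1:
            h_key = "apm_q1" if strategy == "ImmediateAPM" else "pt_q1"
            tcost[alive] += scalar(v.hours[h_key]) * v.wage * disc
        elif t == 2:
            hrs = np.where(pain == 1, scalar(v.hours["q2_moderate"]), scalar(v.hours["q2_low"]))
            if strategy == "DelayedAPM":
                hrs = np.where(crossed, scalar(v.hours["apm_q1"]), hrs)
            tcost[alive] += (hrs * v.wage * disc)[alive]
        else:
            emp_p = np.interp(age, xs, ys)
            hrs = np.where(pain == 1, scalar(v.hours["later_moderate"]), scalar(v.hours["later_low"]))
            tcost[alive] += (hrs * emp_p * v.wage * disc)[alive]

        n_alive = int(alive.sum())
        traj_mod[t] = a1.sum() / n_alive if n_alive else np.nan
        traj_tka[t] = ever_tka.sum() / n

    return StrategyResult(
        strategy=strategy,
        mean_qalys=float(qaly.mean()),
        mean_direct_cost=float(dcost.mean()),
        mean_time_cost=float(tcost.mean()),
        trajectory_moderate_pain=traj_mod,
        cumulative_tka=traj_tka,
        mode="microsim",
        n_subjects=n,
        se_qalys=float(qaly.std(ddof=1) / math.sqrt(n)),
        se_direct_cost=float(dcost.std(ddof=1) / math.sqrt(n)),
    )


# -- public API ---------------------------------------------------------------


def run_strategy(
    strategy: str,
    ps: ParameterSet,
    options: RunOptions | None = None,
    life_table=None,
    **kwargs,
) -> StrategyResult:
    """Evaluate one strategy under one parameter set.

    ``options`` may be given as a :class:`RunOptions` or as keyword
    arguments.  The cohort mode returns the exact expectation; microsim
    requires ``n_subjects`` (and uses ``seed``).
    """
    if strategy not in STRATEGIES:
        raise ParameterError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if options is None:
        options = RunOptions(**kwargs)
    elif kwargs:
        raise TypeError("pass either options or keyword arguments, not both")
    if life_table is None:
        life_table = load_life_table(ps.life_table_path)
    if options.mode == "microsim":
        return _run_microsim(strategy, ps, options, life_table)
    out = _run_cohort_batch(strategy, [ps], options, life_table)
    return StrategyResult(
        strategy=strategy,
        mean_qalys=float(out["qalys"][0]),
        mean_direct_cost=float(out["direct"][0]),
        mean_time_cost=float(out["time"][0]),
        trajectory_moderate_pain=out["traj_mod"][0],
        cumulative_tka=out["traj_tka"][0],
        mode="cohort",
        max_conservation_error=out["conservation_error"] if options.validate else None,
    )


def run_base_case(
    ps: ParameterSet,
    options: RunOptions | None = None,
    strategies: tuple[str, ...] = STRATEGIES,
    life_table=None,
) -> dict[str, StrategyResult]:
    """Cohort-mode evaluation of all strategies at the point estimates."""
    options = options or RunOptions()
    if life_table is None:
        life_table = load_life_table(ps.life_table_path)
    return {s: run_strategy(s, ps, options, life_table=life_table) for s in strategies}


def run_psa(
    ps: ParameterSet,
    n_iterations: int,
    seed: int,
    options: RunOptions | None = None,
    strategies: tuple[str, ...] = STRATEGIES,
    chunk_size: int = 500,
    life_table=None,
    progress=None,
) -> PSAResult:
    """Probabilistic sensitivity analysis: ``n_iterations`` independent
    parameter draws, each evaluated in cohort mode for every strategy.

    Iteration ``i`` uses the deterministic child seed ``(seed, i)``, so any
    single iteration can be replayed with
    :func:`meniscea.params.sample_psa`.
    """
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    options = options or RunOptions()
    if life_table is None:
        life_table = load_life_table(ps.life_table_path)
    S = len(strategies)
    qalys = np.empty((n_iterations, S))
    direct = np.empty((n_iterations, S))
    time_c = np.empty((n_iterations, S))
    for start in range(0, n_iterations, chunk_size):
        stop = min(start + chunk_size, n_iterations)
        draws = [sample_psa(ps, seed, i) for i in range(start, stop)]
        for j, strat in enumerate(strategies):
            out = _run_cohort_batch(strat, draws, options, life_table)
            qalys[start:stop, j] = out["qalys"]
            direct[start:stop, j] = out["direct"]
            time_c[start:stop, j] = out["time"]
        if progress is not None:
            progress(stop, n_iterations)
    return PSAResult(
        strategies=tuple(strategies),
        qalys=qalys,
        direct_costs=direct,
        time_costs=time_c,
        seed=seed,
    )


def trajectory_stats(result: StrategyResult, quarter: int) -> tuple[float, float]:
    """(moderate-pain fraction among the living, cumulative TKA fraction)
    at the end of a quarter; quarter 0 is model entry."""
    if not (0 <= quarter < len(result.trajectory_moderate_pain)):
        raise ParameterError(
            f"quarter {quarter} outside the simulated horizon "
            f"(0-{len(result.trajectory_moderate_pain) - 1})"
        )
    return (
        float(result.trajectory_moderate_pain[quarter]),
        float(result.cumulative_tka[quarter]),
    )
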