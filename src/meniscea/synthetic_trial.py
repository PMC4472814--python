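"""Synthetic individual-level trial records and parameter re-estimation.

The cost-effectiveness model consumes stratum-level summaries (beta counts
for pain outcomes, gamma moments for costs and hours).  This module closes
the loop from raw data to those summaries: it generates subject-level
records with the statistical structure the analysis assumes — binomial pain
outcomes per arm and KL stratum, gamma-distributed resource use — and
re-estimates the corresponding parameters, so that recovery accuracy and
end-to-end consistency can be tested without any external data.

Arms mirror the trial design the model draws on: an operative arm (``APM``),
a non-operative arm (``PT``), and a crossover arm (``PT_crossover_APM``)
whose subjects start PT and undergo surgery at three months if still in
pain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    ParameterSet,
    ParameterError,
    DistributionSpec,
    beta_from_counts,
)

__all__ = [
    "ARMS",
    "TrialRecord",
    "generate_trial",
    "estimate_from_trial",
    "gamma_method_of_moments",
    "records_to_frame",
    "apply_estimates",
]

ARMS = ("APM", "PT", "PT_crossover_APM")
LOW, MODERATE = "LOW", "MODERATE"


@dataclass
class TrialRecord:
    """One synthetic subject: arm, stratum, pain outcomes and resource use."""

    subject_id: int
    arm: str
    kl_band: str  # KL02 or KL34
    pain_3mo: str
    pain_6mo: str
    quarterly_cost_healthcare: float
    quarterly_cost_rehab: float
    hours_lost_q1: float
    hours_lost_q2: float
    employed: bool

    def __post_init__(self) -> None:
        if min(
            self.quarterly_cost_healthcare,
            self.quarterly_cost_rehab,
            self.hours_lost_q1,
            self.hours_lost_q2,
        ) < 0:
            raise ParameterError("costs and hours must be non-negative")


def _band_share_kl02(ps: ParameterSet) -> float:
    return ps.kl_shares[0] + ps.kl_shares[1]


def generate_trial(
    ps: ParameterSet,
    n_per_arm: int,
    employment_rate: float = 0.60,
    seed: int = 0,
) -> list[TrialRecord]:
    """Generate ``n_per_arm`` subjects per arm with the model's structure.

    KL bands follow the cohort shares; 3-month pain is Bernoulli in the
    arm-and-band failed-relief probability; 6-month pain follows the months
    3-6 incidence/resolution probabilities (crossover subjects in pain at 3
    months instead receive the post-crossover failed-relief draw).  Costs
    and hours are drawn from the corresponding gamma specifications.
    Unemployed subjects have hours recorded but no wage weight.
    """
    if n_per_arm < 0:
        raise ParameterError("n_per_arm must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    p_kl02 = _band_share_kl02(ps)
    n = int(n_per_arm)
    sid = 0

    def gamma_draws(spec: DistributionSpec, size: int) -> np.ndarray:
        if spec.family == "gamma":
            return rng.gamma(spec.a, 1.0 / spec.b, size)
        return np.full(size, spec.mean)

    def by_band(kind: str, ctx: str, is02: np.ndarray) -> np.ndarray:
        return np.where(
            is02,
            ps.treatment_pain[(ctx, "KL02", kind)].mean,
            ps.treatment_pain[(ctx, "KL34", kind)].mean,
        )

    for arm in ARMS:
        if n == 0:
            continue
        is02 = rng.random(n) < p_kl02
        q1_ctx = "APM" if arm == "APM" else "PT"
        pain3_mod = rng.random(n) < by_band("failed_relief", q1_ctx, is02)
        u = rng.random(n)
        if arm == "PT_crossover_APM":
            # subjects still in pain cross over to surgery at three months; a
            # single post-crossover failed-relief draw decides 6-month pain
            p6 = np.where(
                pain3_mod,
                by_band("failed_relief", "APM_after_PT", is02),
                by_band("incidence", q1_ctx, is02),
            )
        else:
            p6 = np.where(
                pain3_mod,
                1.0 - by_band("resolution", q1_ctx, is02),
                by_band("incidence", q1_ctx, is02),
            )
        pain6_mod = u < p6
        hc_key = "apm_post_healthcare" if arm == "APM" else "pt_healthcare"
        rehab_key = "apm_rehab" if arm == "APM" else "pt_rehab"
        hc = gamma_draws(ps.costs[hc_key], n)
        rehab = gamma_draws(ps.costs[rehab_key], n)
        h1 = gamma_draws(ps.time_hours["apm_q1" if arm == "APM" else "pt_q1"], n)
        h2 = np.where(
            pain6_mod,
            gamma_draws(ps.time_hours["q2_moderate"], n),
            gamma_draws(ps.time_hours["q2_low"], n),
        )
        employed = rng.random(n) < employment_rate
        for k in range(n):
            records.append(
                TrialRecord(
                    subject_id=sid,
                    arm=arm,
                    kl_band="KL02" if is02[k] else "KL34",
                    pain_3mo=MODERATE if pain3_mod[k] else LOW,
                    pain_6mo=MODERATE if pain6_mod[k] else LOW,
                    quarterly_cost_healthcare=float(hc[k]),
                    quarterly_cost_rehab=float(rehab[k]),
                    hours_lost_q1=float(h1[k]),
                    hours_lost_q2=float(h2[k]),
                    employed=bool(employed[k]),
                )
            )
            sid += 1
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def gamma_method_of_moments(values) -> DistributionSpec:
    """Gamma spec by method of moments: alpha = mean^2/var, lambda = mean/var."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ParameterError("need >= 2 observations for a gamma fit")
    mean = values.mean()
    var = values.var(ddof=1)
    if var <= 0 or mean <= 0:
        raise ParameterError("degenerate sample: gamma fit needs positive mean and variance")
    return DistributionSpec("gamma", float(mean), float(mean**2 / var), float(mean / var))


def estimate_from_trial(records: list[TrialRecord]) -> dict:
    """Re-estimate model parameters from synthetic trial records.

    Returns ``{"treatment_pain": {(context, band, kind): spec},
    "costs": {...}, "time_hours": {...}, "unestimable": [names]}``.
    Pain probabilities become beta specs from stratum counts; costs and
    hours become method-of-moments gamma fits.  Parameters whose stratum is
    empty or degenerate are listed as unestimable rather than guessed.
    """
    frame = records_to_frame(records)
    if frame.empty:
        raise ParameterError("no records to estimate from")
    tp: dict = {}
    unestimable: list[str] = []

    def beta_of(mask_mod, mask_all, name):
        n_mod = int(mask_mod.sum())
        n_all = int(mask_all.sum())
        if n_all == 0:
            unestimable.append(name)
            return None
        return beta_from_counts(n_mod, n_all - n_mod)

    for band in ("KL02", "KL34"):
        for arm, ctx in (("APM", "APM"), ("PT", "PT")):
            sub = frame[(frame.arm == arm) & (frame.kl_band == band)]
            spec = beta_of(sub.pain_3mo == MODERATE, sub.pain_3mo.notna(),
                           f"treatment_pain[{ctx},{band},failed_relief]")
            if spec is not None:
                tp[(ctx, band, "failed_relief")] = spec
            lo = sub[sub.pain_3mo == LOW]
            spec = beta_of(lo.pain_6mo == MODERATE, lo.pain_6mo.notna(),
                           f"treatment_pain[{ctx},{band},incidence]")
            if spec is not None:
                tp[(ctx, band, "incidence")] = spec
            mod = sub[sub.pain_3mo == MODERATE]
            spec = beta_of(mod.pain_6mo == LOW, mod.pain_6mo.notna(),
                           f"treatment_pain[{ctx},{band},resolution]")
            if spec is not None:
                tp[(ctx, band, "resolution")] = spec
        cross = frame[(frame.arm == "PT_crossover_APM") & (frame.kl_band == band)
                      & (frame.pain_3mo == MODERATE)]
        spec = beta_of(cross.pain_6mo == MODERATE, cross.pain_6mo.notna(),
                       f"treatment_pain[APM_after_PT,{band},failed_relief]")
        if spec is not None:
            tp[("APM_after_PT", band, "failed_relief")] = spec

    costs: dict = {}
    hours: dict = {}

    def gamma_of(values, name):
        try:
            return gamma_method_of_moments(values)
        except ParameterError:
            unestimable.append(name)
            return None

    apm = frame[frame.arm == "APM"]
    pt = frame[frame.arm == "PT"]
    for key, sub, col in (
        ("apm_post_healthcare", apm, "quarterly_cost_healthcare"),
        ("apm_rehab", apm, "quarterly_cost_rehab"),
        ("pt_healthcare", pt, "quarterly_cost_healthcare"),
        ("pt_rehab", pt, "quarterly_cost_rehab"),
    ):
        spec = gamma_of(sub[col].to_numpy(), f"costs.{key}")
        if spec is not None:
            costs[key] = spec
    for key, sub, col in (
        ("apm_q1", apm, "hours_lost_q1"),
        ("pt_q1", pt, "hours_lost_q1"),
        ("q2_moderate", frame[frame.pain_6mo == MODERATE], "hours_lost_q2"),
        ("q2_low", frame[frame.pain_6mo == LOW], "hours_lost_q2"),
    ):
        spec = gamma_of(sub[col].to_numpy(), f"time_hours.{key}")
        if spec is not None:
            hours[key] = spec

    return {"treatment_pain": tp, "costs": costs, "time_hours": hours,
            "unestimable": unestimable}


def apply_estimates(ps: ParameterSet, estimates: dict) -> ParameterSet:
    """New ParameterSet with estimated specs substituted for the originals."""
    return ps.replace_specs(
        treatment_pain=estimates.get("treatment_pain"),
        costs=estimates.get("costs"),
        time_hours=estimates.get("time_hours"),
    )
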