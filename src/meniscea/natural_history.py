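"""Per-quarter transition logic for the meniscal tear + knee OA model.

Pain dynamics follow a two-phase structure: during the first six months after
the index treatment the transition probabilities are treatment-specific
(failed relief in months 0-3, incidence/resolution in months 3-6); afterwards
pain incidence and resolution are driven purely by the underlying OA, by KL
grade.  Structural progression (KL grade), OA incidence among KL 0/1 knees,
TKA election and outcomes, adverse events and background mortality complete
the quarterly cycle.

Annual rates are converted to quarterly probabilities assuming a constant
hazard within the year: ``1 - (1 - p)**(1/4)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .params import ParameterSet, ParameterError, KL_GRADES

__all__ = [
    "HealthState",
    "PainLevel",
    "to_quarterly",
    "pain_transition_treatment",
    "pain_transition_oa",
    "kl_transition",
    "tka_gate",
    "tka_outcome",
    "adverse_event_burden",
    "mortality_quarterly",
    "load_life_table",
    "kl_band",
]

LOW, MODERATE = "LOW", "MODERATE"
PainLevel = str


@dataclass
class HealthState:
    """One subject's (or cohort stratum's) state at the start of a quarter."""

    alive: bool = True
    pain: PainLevel = MODERATE  # all subjects enter symptomatic
    kl: str = "KL01"
    tka: bool = False
    quarters_since_tka: int = 0
    consecutive_moderate_quarters: int = 0
    had_apm: bool = False
    had_pt: bool = False
    age: float = 58.0

    def __post_init__(self) -> None:
        if self.kl not in KL_GRADES:
            raise ParameterError(f"unknown KL grade {self.kl!r}")
        if self.quarters_since_tka > 0 and not self.tka:
            raise ParameterError("quarters_since_tka > 0 requires tka")
        if self.consecutive_moderate_quarters < 0:
            raise ParameterError("consecutive_moderate_quarters must be >= 0")


def to_quarterly(p_annual: float) -> float:
    """Annual probability -> quarterly probability under constant hazard."""
    if not (0.0 <= p_annual <= 1.0):
        raise ParameterError(f"annual probability {p_annual} outside [0, 1]")
    return 1.0 - (1.0 - p_annual) ** 0.25


def kl_band(kl: str) -> str:
    """Treatment-efficacy stratum: KL 0-2 versus KL 3-4."""
    return "KL02" if kl in ("KL01", "KL2") else "KL34"


def pain_transition_treatment(
    context: str, band: str, phase: str, pain: PainLevel | None, ps: ParameterSet
) -> float:
    """P(moderate pain next quarter) during the six-month treatment window.

    ``phase='quarter1'`` is the months 0-3 failed-pain-relief draw (the
    current pain level is irrelevant: everyone enters in pain).
    ``phase='quarter2'`` covers months 3-6: incidence if currently LOW,
    1 - resolution if MODERATE.  The crossover context (``APM_after_PT``)
    has no months 3-6 window — its effect is the single failed-relief draw
    in the quarter following surgery.
    """
    if context not in ("APM", "APM_after_PT", "PT"):
        raise ParameterError(f"unknown treatment context {context!r}")
    if band not in ("KL02", "KL34"):
        raise ParameterError(f"unknown KL band {band!r}")
    if phase == "quarter1":
        return ps.treatment_pain[(context, band, "failed_relief")].mean
    if phase != "quarter2":
        raise ParameterError(f"unknown phase {phase!r}")
    if context == "APM_after_PT":
        raise ParameterError("APM_after_PT has no quarter-2 window")
    if pain == LOW:
        return ps.treatment_pain[(context, band, "incidence")].mean
    return 1.0 - ps.treatment_pain[(context, band, "resolution")].mean


def pain_transition_oa(kl: str, pain: PainLevel, ps: ParameterSet) -> float:
    """P(moderate next quarter) once pain is OA-driven (after month 6)."""
    if pain == LOW:
        return to_quarterly(ps.oa_pain_incidence[kl])
    return 1.0 - to_quarterly(ps.oa_pain_resolution[kl])


def kl_transition(
    kl: str,
    age: float,
    ps: ParameterSet,
    apm_progression_multiplier: float = 1.0,
    had_apm: bool = False,
) -> dict[str, float]:
    """Distribution over next-quarter KL grade (at most one step up).

    The progression multiplier models a possible deleterious effect of
    meniscectomy on structural progression and applies only to subjects who
    underwent APM; the base case sets it to 1.
    """
    m = apm_progression_multiplier if had_apm else 1.0
    if m < 1.0:
        raise ParameterError("progression multiplier must be >= 1")
    if kl == "KL4":
        return {"KL4": 1.0}
    if kl == "KL01":
        p = to_quarterly(oa_incidence_annual(age, ps))
        return {"KL01": 1.0 - p, "KL2": p}
    key = "kl2_to_kl3" if kl == "KL2" else "kl3_to_kl4"
    annual = ps.kl_progression[key] * m
    if annual > 1.0:
        import warnings

        warnings.warn("progression probability clamped to 1 after multiplier")
        annual = 1.0
    p = to_quarterly(annual)
    nxt = "KL3" if kl == "KL2" else "KL4"
    return {kl: 1.0 - p, nxt: p}


def _band_lookup(bands, age: float, what: str) -> float:
    for lo, hi, p in bands:
        if lo <= age <= hi:
            return p
    raise ParameterError(f"age {age} outside {what} bands")


def oa_incidence_annual(age: float, ps: ParameterSet) -> float:
    return _band_lookup(ps.oa_incidence_by_age, np.floor(age), "oa_incidence_by_age")


def tka_uptake_annual(age: float, ps: ParameterSet) -> float:
    return _band_lookup(ps.tka_uptake_by_age, np.floor(age), "tka_uptake_by_age")


def tka_gate(state: HealthState, ps: ParameterSet) -> float:
    """Quarterly probability of electing knee replacement.

    Eligibility requires advanced radiographic OA (KL 3 or 4) and moderate
    pain for at least six consecutive months (two quarters) after the initial
    three-month treatment period; the uptake rate is the age-specific annual
    utilisation converted to quarterly.
    """
    if not state.alive or state.tka:
        return 0.0
    if state.kl not in ("KL3", "KL4"):
        return 0.0
    if state.consecutive_moderate_quarters < 2:
        return 0.0
    return to_quarterly(tka_uptake_annual(state.age, ps))


def tka_outcome(quarters_since_tka: int, ps: ParameterSet) -> float:
    """P(low pain this quarter) after knee replacement.

    Interpreted as the per-quarter probability of occupying the low-pain
    state: first-year efficacy during post-operative quarters 1-4, the
    subsequent-year efficacy thereafter.
    """
    if quarters_since_tka < 1:
        raise ParameterError("tka_outcome requires quarters_since_tka >= 1")
    if quarters_since_tka <= 4:
        return ps.tka_efficacy_first_year
    return ps.tka_efficacy_subsequent


def adverse_event_burden(event_source: str, ps: ParameterSet) -> tuple[float, float, float]:
    """(probability, added cost, P(death | event)) for one exposure.

    APM and TKA events are per procedure; pharmacologic events are per year
    of moderate-pain pharmacologic management (convert with
    :func:`to_quarterly` for quarterly exposure).
    """
    cost_key = {
        "APM": "apm_complication",
        "TKA": "tka_complication",
        "pharm": "pain_mgmt_complication",
    }.get(event_source)
    if cost_key is None:
        raise ParameterError(f"unknown adverse event source {event_source!r}")
    ae = ps.adverse_events[event_source]
    return ae.prob, ps.costs[cost_key].mean, ae.mortality


# -- mortality ----------------------------------------------------------------


def load_life_table(path=None) -> pd.DataFrame:
    """Load a life table CSV with columns ``age, annual_death_prob``.

    The packaged default is a synthetic Gompertz approximation to the pooled
    2009 US all-cause table (see the file header for the fit).
    """
    if path is None:
        source = resources.files("meniscea") / "data/life_table_2009_us_synthetic.csv"
        with resources.as_file(source) as fp:
            table = pd.read_csv(fp)
    else:
        table = pd.read_csv(path)
    if list(table.columns) != ["age", "annual_death_prob"]:
        raise ParameterError(
            "life table must have columns 'age,annual_death_prob', "
            f"got {list(table.columns)}"
        )
    if not table["annual_death_prob"].between(0, 1).all():
        raise ParameterError("life table probabilities must lie in [0, 1]")
    return table


def life_table_array(table: pd.DataFrame) -> tuple[int, np.ndarray]:
    """(minimum age, dense annual death probability array) for fast lookup."""
    ages = table["age"].to_numpy()
    lo = int(ages.min())
    dense = np.zeros(int(ages.max()) - lo + 1)
    dense[(ages - lo).astype(int)] = table["annual_death_prob"].to_numpy()
    return lo, dense


def mortality_quarterly(age: float, life_table: pd.DataFrame) -> float:
    """Quarterly all-cause death probability at ``floor(age)``; 1 at 110+."""
    iage = int(np.floor(age))
    lo, dense = life_table_array(life_table)
    if iage < lo:
        raise ParameterError(f"age {age} below life table range (starts at {lo})")
    if iage - lo >= len(dense):
        return 1.0
    return to_quarterly(float(dense[iage - lo]))
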