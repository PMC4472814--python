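"""Model parameters: definition, validation, point estimates and PSA sampling.

The decision model compares three management strategies for symptomatic
meniscal tear in the presence of knee osteoarthritis (OA): physical therapy
alone (``PT``), PT with crossover to arthroscopic partial meniscectomy for
subjects still in pain at three months (``DelayedAPM``), and surgery as
first-line treatment (``ImmediateAPM``).  Every quantity the model consumes
lives in a single validated :class:`ParameterSet`:

* quarterly pain-transition probabilities during the six-month treatment
  window, stratified by treatment context and Kellgren-Lawrence (KL) band,
  each carried as a beta :class:`DistributionSpec` for probabilistic
  sensitivity analysis (PSA);
* annual OA natural-history rates (structural KL progression, OA incidence
  by age, OA-driven pain incidence/resolution by KL grade);
* total knee arthroplasty (TKA) uptake and efficacy, adverse-event rates;
* direct medical costs and productivity hours, gamma-distributed where the
  analysis samples them, in 2013 USD;
* utilities, discounting and horizon.

Point estimates ("base case") use the printed means; PSA draws replace each
beta/gamma spec by an independent sample.  Parameters without a listed
distribution stay fixed in the PSA.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "AdverseEvent",
    "ParameterSet",
    "GammaMeanMismatchWarning",
    "ParameterError",
    "beta_from_counts",
    "gamma_spec",
    "fixed_spec",
    "sample_psa",
    "load_parameters",
    "default_parameters",
    "PAIN_CONTEXTS",
    "KL_BANDS",
    "PAIN_KINDS",
]

PAIN_CONTEXTS = ("APM", "APM_after_PT", "PT")
KL_BANDS = ("KL02", "KL34")
PAIN_KINDS = ("failed_relief", "incidence", "resolution")

#: relative deviation between a gamma's alpha/lambda mean and the printed
#: mean above which a mismatch warning is emitted
GAMMA_MEAN_TOL = 0.05


class GammaMeanMismatchWarning(UserWarning):
    """A gamma spec's alpha/lambda mean disagrees with its printed mean."""


class ParameterError(ValueError):
    """A parameter value or configuration entry violates its invariants."""


@dataclass(frozen=True)
class DistributionSpec:
    """One model parameter: a point estimate plus an optional PSA distribution.

    ``family`` is ``"beta"``, ``"gamma"`` or ``"fixed"``.  For beta, ``a``/``b``
    are the two shape parameters; for gamma, ``a`` is the shape (alpha) and
    ``b`` the rate (lambda).  ``mean`` is the point estimate in native units
    (probability, USD or hours) and is what the base-case analysis uses; PSA
    draws come from the distribution itself.
    """

    family: str
    mean: float
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma"):
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ParameterError(
                    f"{self.family} spec requires positive shape parameters, "
                    f"got a={self.a}, b={self.b}"
                )
        if self.family == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ParameterError(f"beta spec mean {self.mean} outside [0, 1]")
        if not math.isfinite(self.mean):
            raise ParameterError("spec mean must be finite")

    @property
    def is_sampled(self) -> bool:
        return self.family != "fixed"

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value; fixed specs return the point estimate."""
        if self.family == "beta":
            return float(rng.beta(self.a, self.b))
        if self.family == "gamma":
            return float(rng.gamma(self.a, 1.0 / self.b))
        return self.mean


def fixed_spec(mean: float) -> DistributionSpec:
    return DistributionSpec("fixed", float(mean))


def beta_from_counts(successes: float, failures: float) -> DistributionSpec:
    """Beta spec from event counts, mean = successes / (successes + failures).

    The PSA betas for treatment-related pain probabilities are parameterised
    directly by the observed counts in each treatment-by-KL stratum.
    """
    if successes < 0 or failures < 0:
        raise ParameterError("counts must be non-negative")
    total = successes + failures
    if total == 0:
        raise ParameterError("empty stratum: successes + failures must be > 0")
    mean = successes / total
    if successes == 0 or failures == 0:
        # degenerate all-success / all-failure stratum: no spread to sample
        return fixed_spec(mean)
    return DistributionSpec("beta", mean, float(successes), float(failures))


def gamma_spec(alpha: float, lam: float, mean: float | None = None) -> DistributionSpec:
    """Gamma spec with shape ``alpha`` and rate ``lam``.

    If a printed ``mean`` is supplied it becomes the point estimate even when
    it disagrees with alpha/lam (several printed cost rows do); a
    :class:`GammaMeanMismatchWarning` is emitted when the relative deviation
    exceeds ``GAMMA_MEAN_TOL``.  PSA draws always use (alpha, lam).
    """
    if alpha <= 0 or lam <= 0:
        raise ParameterError(f"gamma spec requires alpha, lam > 0, got ({alpha}, {lam})")
    implied = alpha / lam
    if mean is None:
        mean = implied
    elif abs(implied - mean) > GAMMA_MEAN_TOL * max(abs(implied), 1e-12):
        warnings.warn(
            f"gamma({alpha}, {lam}) implies mean {implied:.1f} but printed "
            f"mean is {mean:.1f}; base case uses the printed mean",
            GammaMeanMismatchWarning,
            stacklevel=2,
        )
    return DistributionSpec("gamma", float(mean), float(alpha), float(lam))


@dataclass(frozen=True)
class AdverseEvent:
    """Per-exposure adverse-event probability and case fatality."""

    prob: float
    mortality: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob <= 1.0 and 0.0 <= self.mortality <= 1.0):
            raise ParameterError("adverse event probabilities must lie in [0, 1]")


# cost entries expected in every ParameterSet
COST_KEYS = (
    "apm_procedure",
    "apm_complication",
    "apm_post_healthcare",
    "apm_rehab",
    "pt_healthcare",
    "pt_rehab",
    "pain_mgmt_moderate",
    "pain_mgmt_low",
    "pain_mgmt_complication",
    "tka_procedure",
    "tka_complication",
)

HOUR_KEYS = (
    "apm_q1",
    "pt_q1",
    "q2_moderate",
    "q2_low",
    "later_moderate",
    "later_low",
)

KL_GRADES = ("KL01", "KL2", "KL3", "KL4")


@dataclass(frozen=True)
class ParameterSet:
    """Validated container for every model input.

    Probabilities marked quarterly are quarterly; natural-history rates
    (``kl_progression``, ``oa_incidence_by_age``, ``tka_uptake_by_age``,
    ``oa_pain_*``, pharmacologic adverse events) are annual and converted by
    the transition layer.  Monetary amounts are 2013 USD.
    """

    cohort_mean_age: float
    cohort_sd_age: float
    cohort_age_range: tuple[float, float]
    kl_shares: tuple[float, float, float, float]  # KL0/1, KL2, KL3, KL4
    kl_progression: Mapping[str, float]  # annual: kl2_to_kl3, kl3_to_kl4
    oa_incidence_by_age: tuple[tuple[float, float, float], ...]  # (lo, hi, annual p)
    tka_uptake_by_age: tuple[tuple[float, float, float], ...]
    utilities: Mapping[str, float]  # low, moderate, dead
    treatment_pain: Mapping[tuple[str, str, str], DistributionSpec]
    oa_pain_incidence: Mapping[str, float]  # annual, by KL grade
    oa_pain_resolution: Mapping[str, float]
    tka_efficacy_first_year: float
    tka_efficacy_subsequent: float
    adverse_events: Mapping[str, AdverseEvent]  # APM, TKA, pharm (pharm annual)
    costs: Mapping[str, DistributionSpec]
    time_hours: Mapping[str, DistributionSpec]
    wage_rate: float
    employment_schedule: tuple[tuple[float, float], ...]  # (age, P(employed))
    discount_rate_annual: float = 0.03
    horizon_years: float = 10.0
    life_table_path: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.kl_shares) - 1.0) > 1e-9:
            raise ParameterError(
                f"KL shares must sum to 1, got {sum(self.kl_shares):.6f}"
            )
        if any(s < 0 for s in self.kl_shares):
            raise ParameterError("KL shares must be non-negative")
        for key in ("low", "moderate", "dead"):
            u = self.utilities.get(key)
            if u is None or not (0.0 <= u <= 1.0):
                raise ParameterError(f"utility {key!r} missing or outside [0, 1]")
        for key, p in self.kl_progression.items():
            _check_prob(f"kl_progression.{key}", p)
        for lo, hi, p in self.oa_incidence_by_age:
            _check_prob(f"oa_incidence_by_age[{lo}-{hi}]", p)
        for lo, hi, p in self.tka_uptake_by_age:
            _check_prob(f"tka_uptake_by_age[{lo}-{hi}]", p)
        for grade in KL_GRADES:
            _check_prob(f"oa_pain_incidence.{grade}", self.oa_pain_incidence[grade])
            _check_prob(f"oa_pain_resolution.{grade}", self.oa_pain_resolution[grade])
        _check_prob("tka_efficacy_first_year", self.tka_efficacy_first_year)
        _check_prob("tka_efficacy_subsequent", self.tka_efficacy_subsequent)
        for ctx in PAIN_CONTEXTS:
            for band in KL_BANDS:
                for kind in PAIN_KINDS:
                    spec = self.treatment_pain.get((ctx, band, kind))
                    if spec is None:
                        raise ParameterError(
                            f"treatment_pain missing ({ctx}, {band}, {kind})"
                        )
                    _check_prob(f"treatment_pain[{ctx},{band},{kind}]", spec.mean)
        for key in COST_KEYS:
            spec = self.costs.get(key)
            if spec is None:
                raise ParameterError(f"costs missing key {key!r}")
            if spec.mean < 0:
                raise ParameterError(f"cost {key!r} is negative: {spec.mean}")
        for key in HOUR_KEYS:
            spec = self.time_hours.get(key)
            if spec is None:
                raise ParameterError(f"time_costs.hours missing key {key!r}")
            if spec.mean < 0:
                raise ParameterError(f"hours {key!r} is negative: {spec.mean}")
        for source in ("APM", "TKA", "pharm"):
            if source not in self.adverse_events:
                raise ParameterError(f"adverse_events missing source {source!r}")
        if self.wage_rate < 0:
            raise ParameterError("wage_rate must be non-negative")
        for age, p in self.employment_schedule:
            _check_prob(f"employment_schedule[{age}]", p)
        if not (0.0 <= self.discount_rate_annual < 1.0):
            raise ParameterError("discount_rate_annual must lie in [0, 1)")
        if self.horizon_years < 0:
            raise ParameterError("horizon_years must be non-negative")

    # -- PSA -----------------------------------------------------------------

    def sampled_keys(self) -> list[tuple[str, object]]:
        """Ordered (section, key) pairs of every spec the PSA samples."""
        out: list[tuple[str, object]] = []
        for key in sorted(self.treatment_pain):
            if self.treatment_pain[key].is_sampled:
                out.append(("treatment_pain", key))
        for key in COST_KEYS:
            if self.costs[key].is_sampled:
                out.append(("costs", key))
        for key in HOUR_KEYS:
            if self.time_hours[key].is_sampled:
                out.append(("time_hours", key))
        return out

    def replace_specs(
        self,
        treatment_pain: Mapping | None = None,
        costs: Mapping | None = None,
        time_hours: Mapping | None = None,
    ) -> "ParameterSet":
        """Return a copy with some DistributionSpec entries replaced."""
        tp = dict(self.treatment_pain)
        tp.update(treatment_pain or {})
        c = dict(self.costs)
        c.update(costs or {})
        th = dict(self.time_hours)
        th.update(time_hours or {})
        return dataclasses.replace(self, treatment_pain=tp, costs=c, time_hours=th)

    def employment_prob(self, age: float) -> float:
        xs = [a for a, _ in self.employment_schedule]
        ys = [p for _, p in self.employment_schedule]
        return float(np.interp(age, xs, ys))


def _check_prob(name: str, p: float) -> None:
    if p is None or not (0.0 <= p <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {p}")


def psa_child_seed(master_seed: int, iteration: int) -> np.random.SeedSequence:
    """Deterministic per-iteration seed so any single PSA draw is replayable."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(iteration),))


def sample_psa(
    ps: ParameterSet, seed: int, iteration: int = 0, subset: set | None = None
) -> ParameterSet:
    """One independent PSA draw of every beta/gamma parameter.

    All sampled specs are replaced by fixed specs holding the draw; fixed
    parameters pass through unchanged.  ``subset``, when given, restricts
    sampling to those (section, key) pairs — used by the partial-information
    value analysis.  Reproducible: the generator is seeded from
    ``(seed, iteration)`` and parameters are drawn in a fixed order.
    """
    rng = np.random.Generator(np.random.PCG64(psa_child_seed(seed, iteration)))
    tp: dict = {}
    costs: dict = {}
    hours: dict = {}
    for section, key in ps.sampled_keys():
        if subset is not None and (section, key) not in subset:
            continue
        if section == "treatment_pain":
            tp[key] = fixed_spec(ps.treatment_pain[key].sample(rng))
        elif section == "costs":
            costs[key] = fixed_spec(ps.costs[key].sample(rng))
        else:
            hours[key] = fixed_spec(ps.time_hours[key].sample(rng))
    return ps.replace_specs(tp, costs, hours)


# -- configuration loading ----------------------------------------------------


def _require(mapping: Mapping, key: str, where: str):
    if not isinstance(mapping, Mapping) or key not in mapping:
        raise ParameterError(f"missing configuration key {where}.{key}" if where else
                             f"missing configuration key {key}")
    return mapping[key]


def _parse_spec(node, where: str) -> DistributionSpec:
    if isinstance(node, (int, float)):
        return fixed_spec(float(node))
    if not isinstance(node, Mapping):
        raise ParameterError(f"malformed distribution at {where}: {node!r}")
    if "beta" in node:
        a, b = node["beta"]
        return beta_from_counts(a, b)
    if "gamma" in node:
        a, lam = node["gamma"]
        return gamma_spec(a, lam, mean=node.get("mean"))
    if "fixed" in node:
        return fixed_spec(float(node["fixed"]))
    raise ParameterError(f"malformed distribution at {where}: {node!r}")


def _parse_bands(nodes, where: str) -> tuple:
    out = []
    for i, node in enumerate(nodes):
        lo, hi = _require(node, "ages", f"{where}[{i}]")
        out.append((float(lo), float(hi), float(_require(node, "annual", f"{where}[{i}]"))))
    return tuple(out)


def load_parameters(config_path=None) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML configuration file.

    With no path, the packaged default configuration (the published base-case
    parameter table) is used.  Errors name the offending key.
    """
    if config_path is None:
        text = (resources.files("meniscea") / "data/default_parameters.yaml").read_text()
    else:
        with open(config_path) as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - exercised via malformed file
        raise ParameterError(f"malformed configuration file: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ParameterError("configuration root must be a mapping")

    cohort = _require(raw, "cohort", "")
    shares_node = _require(cohort, "kl_shares", "cohort")
    kl_shares = tuple(float(_require(shares_node, k, "cohort.kl_shares"))
                      for k in ("kl01", "kl2", "kl3", "kl4"))

    tp_node = _require(raw, "treatment_pain", "")
    treatment_pain = {}
    for ctx in PAIN_CONTEXTS:
        ctx_node = _require(tp_node, ctx, "treatment_pain")
        for kind in PAIN_KINDS:
            kind_node = _require(ctx_node, kind, f"treatment_pain.{ctx}")
            for band in KL_BANDS:
                where = f"treatment_pain.{ctx}.{kind}.{band}"
                treatment_pain[(ctx, band, kind)] = _parse_spec(
                    _require(kind_node, band, f"treatment_pain.{ctx}.{kind}"), where
                )

    oa_pain = _require(raw, "oa_pain", "")
    ae_node = _require(raw, "adverse_events", "")
    adverse_events = {}
    for source in ("APM", "TKA", "pharm"):
        node = _require(ae_node, source, "adverse_events")
        prob_key = "prob_annual" if "prob_annual" in node else "prob"
        adverse_events[source] = AdverseEvent(
            float(_require(node, prob_key, f"adverse_events.{source}")),
            float(_require(node, "mortality", f"adverse_events.{source}")),
        )

    costs_node = _require(raw, "costs", "")
    costs = {k: _parse_spec(_require(costs_node, k, "costs"), f"costs.{k}")
             for k in COST_KEYS}
    tc_node = _require(raw, "time_costs", "")
    hours_node = _require(tc_node, "hours", "time_costs")
    time_hours = {k: _parse_spec(_require(hours_node, k, "time_costs.hours"),
                                 f"time_costs.hours.{k}")
                  for k in HOUR_KEYS}

    emp_node = _require(raw, "employment", "")
    schedule = tuple((float(a), float(p)) for a, p in _require(emp_node, "schedule", "employment"))

    util_node = _require(raw, "utilities", "")
    eff_node = _require(raw, "tka_efficacy", "")
    prog_node = _require(raw, "kl_progression", "")

    return ParameterSet(
        cohort_mean_age=float(_require(cohort, "mean_age", "cohort")),
        cohort_sd_age=float(_require(cohort, "sd_age", "cohort")),
        cohort_age_range=tuple(float(x) for x in _require(cohort, "age_range", "cohort")),
        kl_shares=kl_shares,
        kl_progression={
            "kl2_to_kl3": float(_require(prog_node, "kl2_to_kl3", "kl_progression")),
            "kl3_to_kl4": float(_require(prog_node, "kl3_to_kl4", "kl_progression")),
        },
        oa_incidence_by_age=_parse_bands(_require(raw, "oa_incidence_by_age", ""),
                                         "oa_incidence_by_age"),
        tka_uptake_by_age=_parse_bands(_require(raw, "tka_uptake_by_age", ""),
                                       "tka_uptake_by_age"),
        utilities={k: float(_require(util_node, k, "utilities"))
                   for k in ("low", "moderate", "dead")},
        treatment_pain=treatment_pain,
        oa_pain_incidence={g: float(_require(_require(oa_pain, "incidence", "oa_pain"),
                                             g, "oa_pain.incidence"))
                           for g in KL_GRADES},
        oa_pain_resolution={g: float(_require(_require(oa_pain, "resolution", "oa_pain"),
                                              g, "oa_pain.resolution"))
                            for g in KL_GRADES},
        tka_efficacy_first_year=float(_require(eff_node, "first_year", "tka_efficacy")),
        tka_efficacy_subsequent=float(_require(eff_node, "subsequent", "tka_efficacy")),
        adverse_events=adverse_events,
        costs=costs,
        time_hours=time_hours,
        wage_rate=float(_require(tc_node, "wage_rate", "time_costs")),
        employment_schedule=schedule,
        discount_rate_annual=float(_require(raw, "discount_rate_annual", "")),
        horizon_years=float(_require(raw, "horizon_years", "")),
        life_table_path=raw.get("life_table_path"),
    )


def default_parameters() -> ParameterSet:
    """The packaged base-case parameter table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GammaMeanMismatchWarning)
        return load_parameters(None)
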