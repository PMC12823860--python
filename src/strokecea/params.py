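"""Model parameter types, validation, spec-file I/O and PSA samplers.

The model is parameterised by a single structured YAML document (the
"model spec") holding, for each arm of the trial, the 3-month modified
Rankin Scale (mRS) outcome distribution and symptomatic intracranial
haemorrhage (sICH) incidence, together with utilities, costs, an
age-banded life table, mRS-specific death hazard ratios, a recurrent
stroke model, discounting and willingness-to-pay thresholds.

Every uncertain scalar is stored as ``{value, range, dist, provenance}``;
vectors as ``{values, ranges, dist, provenance}``.  ``dist`` names the
probabilistic-sensitivity-analysis family (``beta`` for quantities on
[0,1], ``gamma`` for non-negative costs, ``dirichlet`` for mRS simplex
blocks, ``fixed`` otherwise) and ``provenance`` distinguishes printed
(``PAPER``) from packaged assumed (``ASSUMED``) inputs.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "ParamRange",
    "Uncertain",
    "MRSDistribution",
    "StrategyParams",
    "UtilitySet",
    "CostSet",
    "LifeTable",
    "MortalityModel",
    "RecurrenceModel",
    "DiscountSpec",
    "ModelConfig",
    "CEAThresholds",
    "ModelSpec",
    "load_model_spec",
    "write_model_spec",
    "FixedSampler",
    "BetaSampler",
    "GammaSampler",
    "DirichletSampler",
    "beta_from_mean_ci",
    "gamma_from_mean_range",
    "dirichlet_from_distribution",
    "sampler_for",
]

N_MRS = 7           # mRS 0..6 (6 = dead)
N_ALIVE = 6         # alive states mRS 0..5
DEAD = 6

_SUM_TOL_REJECT = 1e-3   # |sum - 1| beyond this -> reject
_SUM_TOL_EXACT = 1e-9


class ValidationError(ValueError):
    """A model-spec field violates one of its declared constraints."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# small value types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRange:
    """Closed interval [low, high] in the parent parameter's units."""

    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise ValidationError("range", f"low {self.low} > high {self.high}")

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass(frozen=True)
class Uncertain:
    """A scalar parameter with its range, PSA family and provenance."""

    value: float
    range: ParamRange | None = None
    family: str = "fixed"          # beta | gamma | dirichlet_component | fixed
    provenance: str = "ASSUMED"


@dataclass(frozen=True)
class MRSDistribution:
    """Probability vector over mRS 0-6 at a time point."""

    p: tuple[float, ...]

    def __post_init__(self):
        if len(self.p) != N_MRS:
            raise ValidationError("mrs_distribution", f"needs {N_MRS} entries, got {len(self.p)}")
        for i, v in enumerate(self.p):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"mrs_distribution[{i}]", f"probability {v} outside [0,1]")
        if abs(sum(self.p) - 1.0) > _SUM_TOL_EXACT:
            raise ValidationError("mrs_distribution", f"sum {sum(self.p)} != 1")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "MRSDistribution":
        """Build from raw values, renormalising when the sum is within 1e-3 of 1."""
        s = float(sum(values))
        if abs(s - 1.0) > _SUM_TOL_REJECT:
            raise ValidationError("mrs_distribution", f"probabilities sum to {s:.6g}, outside 1 +/- {_SUM_TOL_REJECT}")
        vals = tuple(float(v) / s for v in values)
        return cls(vals)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class StrategyParams:
    """Everything defining one treatment arm."""

    name: str
    mrs_at_3mo: MRSDistribution
    sich_incidence: float
    includes_drug_cost: bool

    def __post_init__(self):
        if not (0.0 <= self.sich_incidence <= 1.0):
            raise ValidationError(f"{self.name}.sich_incidence", f"{self.sich_incidence} outside [0,1]")


@dataclass(frozen=True)
class UtilitySet:
    u_mrs: tuple[float, ...]     # QALY weight per year, mRS 0..6
    u_recurrence: float          # replaces state utility during a recurrence cycle
    d_sich: float                # one-time disutility per sICH event

    def validate(self, strict: bool = True) -> None:
        if len(self.u_mrs) != N_MRS:
            raise ValidationError("utilities.u_mrs", "needs 7 entries")
        for i, u in enumerate(self.u_mrs):
            if not (0.0 <= u <= 1.0):
                raise ValidationError(f"utilities.u_mrs[{i}]", f"{u} outside [0,1]")
        if self.u_mrs[DEAD] != 0.0:
            raise ValidationError("utilities.u_mrs[6]", "death utility must be 0")
        if not (0.0 <= self.u_recurrence <= 1.0):
            raise ValidationError("utilities.u_recurrence", f"{self.u_recurrence} outside [0,1]")
        if not (0.0 <= self.d_sich <= 1.0):
            raise ValidationError("utilities.d_sich", f"{self.d_sich} outside [0,1]")
        if strict:
            for i in range(N_MRS - 1):
                if self.u_mrs[i] < self.u_mrs[i + 1]:
                    raise ValidationError("utilities.u_mrs", "must be non-increasing in mRS level")


@dataclass(frozen=True)
class CostSet:
    """Direct medical costs, 2024 CNY."""

    acute_hosp_by_mrs: tuple[float, ...]   # one-time, decision-tree phase
    annual_care_mrs01: float
    annual_care_mrs25: float
    recurrent_stroke_event: float
    sich_event: float
    alteplase_price_20mg: float
    alteplase_price_50mg: float
    alteplase_base_case: float

    def validate(self, strict: bool = True) -> None:
        if len(self.acute_hosp_by_mrs) != N_MRS:
            raise ValidationError("costs.acute_hosp_by_mrs", "needs 7 entries")
        for name, v in [
            ("annual_care_mrs01", self.annual_care_mrs01),
            ("annual_care_mrs25", self.annual_care_mrs25),
            ("recurrent_stroke_event", self.recurrent_stroke_event),
            ("sich_event", self.sich_event),
            ("alteplase_price_20mg", self.alteplase_price_20mg),
            ("alteplase_price_50mg", self.alteplase_price_50mg),
            ("alteplase_base_case", self.alteplase_base_case),
            *[(f"acute_hosp_by_mrs[{i}]", c) for i, c in enumerate(self.acute_hosp_by_mrs)],
        ]:
            if v < 0:
                raise ValidationError(f"costs.{name}", f"cost {v} < 0")
        if strict:
            mean_price = 0.5 * (self.alteplase_price_20mg + self.alteplase_price_50mg)
            if abs(self.alteplase_base_case - mean_price) > 1e-6:
                raise ValidationError(
                    "costs.alteplase_base_case",
                    f"{self.alteplase_base_case} != mean of unit prices {mean_price}",
                )

    def annual_care_for(self, mrs: int) -> float:
        """Annual post-stroke care cost for an alive mRS state; 0 for dead."""
        if mrs in (0, 1):
            return self.annual_care_mrs01
        if 2 <= mrs <= 5:
            return self.annual_care_mrs25
        return 0.0

    def care_rate_array(self) -> np.ndarray:
        return np.array([self.annual_care_for(i) for i in range(N_MRS)])


@dataclass(frozen=True)
class LifeTable:
    """Age-banded annual background mortality (5-year bands from age 60)."""

    bands: tuple[tuple[float, float], ...]   # (age lower bound, annual mortality)

    def validate(self, strict: bool = True) -> None:
        ages = [a for a, _ in self.bands]
        qs = [q for _, q in self.bands]
        if ages != sorted(ages):
            raise ValidationError("life_table.bands", "band lower bounds must be sorted")
        q_lo_open = strict  # strict: q in (0,1); relaxed: [0,1) for boundary experiments
        for q in qs:
            if not (0.0 <= q < 1.0) or (q_lo_open and q == 0.0):
                raise ValidationError("life_table.bands", f"annual mortality {q} outside (0,1)")
        if strict and any(q2 <= q1 for q1, q2 in zip(qs, qs[1:])):
            raise ValidationError("life_table.bands", "annual mortality must be strictly increasing")

    def annual_mortality(self, age: float) -> float:
        """Band lookup; ages beyond the last band use the last band, below the first use the first."""
        q = self.bands[0][1]
        for lower, qi in self.bands:
            if age >= lower:
                q = qi
            else:
                break
        return q


@dataclass(frozen=True)
class MortalityModel:
    hr_by_mrs: tuple[float, ...]      # death hazard ratios, alive states mRS 0..5
    post_stroke_excess_hr: float = 1.0

    def validate(self, strict: bool = True) -> None:
        if len(self.hr_by_mrs) != N_ALIVE:
            raise ValidationError("mortality.hr_by_mrs", "needs 6 entries")
        for i, h in enumerate(self.hr_by_mrs):
            if h <= 0:
                raise ValidationError(f"mortality.hr_by_mrs[{i}]", f"hazard ratio {h} <= 0")
        if self.post_stroke_excess_hr <= 0:
            raise ValidationError("mortality.post_stroke_excess_hr", "must be > 0")
        if strict:
            for h1, h2 in zip(self.hr_by_mrs, self.hr_by_mrs[1:]):
                if h2 < h1:
                    raise ValidationError("mortality.hr_by_mrs", "must be non-decreasing in mRS")


@dataclass(frozen=True)
class RecurrenceModel:
    annual_recurrence_by_mrs: tuple[float, ...]   # mRS 0..5, per year
    case_fatality: float                          # death probability given recurrence
    p_stay_given_survive: float                   # else shift one mRS level worse (cap 5)

    def validate(self, strict: bool = True) -> None:
        if len(self.annual_recurrence_by_mrs) != N_ALIVE:
            raise ValidationError("recurrence.annual_recurrence_by_mrs", "needs 6 entries")
        for i, r in enumerate(self.annual_recurrence_by_mrs):
            if not (0.0 <= r < 1.0):
                raise ValidationError(f"recurrence.annual_recurrence_by_mrs[{i}]", f"{r} outside [0,1)")
        if not (0.0 <= self.case_fatality <= 1.0):
            raise ValidationError("recurrence.case_fatality", f"{self.case_fatality} outside [0,1]")
        if not (0.0 <= self.p_stay_given_survive <= 1.0):
            raise ValidationError("recurrence.p_stay_given_survive", "outside [0,1]")
        if strict:
            rs = self.annual_recurrence_by_mrs
            for r1, r2 in zip(rs, rs[1:]):
                if r2 < r1:
                    raise ValidationError(
                        "recurrence.annual_recurrence_by_mrs", "must be non-decreasing in mRS"
                    )


@dataclass(frozen=True)
class DiscountSpec:
    annual_rate: float
    range: ParamRange = ParamRange(0.0, 0.08)

    def validate(self, strict: bool = True) -> None:
        lo, hi = (0.0, 0.08) if strict else (0.0, 1.0)
        if not (lo <= self.annual_rate <= hi):
            raise ValidationError("discount.annual_rate", f"{self.annual_rate} outside [{lo},{hi}]")


@dataclass(frozen=True)
class ModelConfig:
    start_age: float = 64.0
    horizon: float = 30.0            # years
    cycle_length: float = 0.25       # years
    half_cycle_correction: bool = True
    rng_seed: int = 20240
    psa_iterations: int = 1000

    def validate(self, strict: bool = True) -> None:
        if self.start_age <= 0 or self.horizon <= 0 or self.cycle_length <= 0:
            raise ValidationError("config", "ages, horizon and cycle length must be positive")
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("config", "horizon must be an integer number of cycles")

    @property
    def n_markov_cycles(self) -> int:
        """Markov cycles after the decision-tree quarter: horizon/cycle - 1."""
        return int(round(self.horizon / self.cycle_length)) - 1


@dataclass(frozen=True)
class CEAThresholds:
    gdp_per_capita: float

    @property
    def wtp_1x(self) -> float:
        return self.gdp_per_capita

    @property
    def wtp_3x(self) -> float:
        return 3.0 * self.gdp_per_capita


# ---------------------------------------------------------------------------
# PSA samplers
# ---------------------------------------------------------------------------

class FixedSampler:
    """Degenerate sampler returning a constant (zero-width range)."""

    def __init__(self, value: float):
        self.value = float(value)

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


class BetaSampler:
    def __init__(self, alpha: float, beta: float):
        self.alpha = float(alpha)
        self.beta = float(beta)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


class GammaSampler:
    def __init__(self, shape: float, scale: float):
        self.shape = float(shape)
        self.scale = float(scale)

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)


class DirichletSampler:
    def __init__(self, alpha: np.ndarray):
        self.alpha = np.asarray(alpha, dtype=float)

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    def sample(self, rng: np.random.Generator, size=None):
        return rng.dirichlet(self.alpha, size=size)


def beta_from_mean_ci(mean: float, rng_: ParamRange) -> FixedSampler | BetaSampler:
    """Beta shape parameters from a mean and a symmetric 95% interval.

    Moment matching with SD = (high - low) / 3.92; the fitted mean is exact.
    When the implied variance reaches the Bernoulli bound mean*(1-mean) a
    two-parameter beta cannot attain it; the variance is then clamped just
    below the bound (documented fallback).
    """
    if not (0.0 < mean < 1.0):
        raise ValidationError("beta_from_mean_ci", f"mean {mean} outside (0,1)")
    sd = rng_.width / 3.92
    if sd == 0.0:
        return FixedSampler(mean)
    var = min(sd * sd, 0.97 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return BetaSampler(mean * nu, (1.0 - mean) * nu)


def gamma_from_mean_range(mean: float, rng_: ParamRange) -> FixedSampler | GammaSampler:
    """Gamma shape/scale from a mean and a symmetric 95% interval (SD = width/3.92)."""
    if mean <= 0.0:
        raise ValidationError("gamma_from_mean_range", f"mean {mean} must be > 0")
    sd = rng_.width / 3.92
    if sd == 0.0:
        return FixedSampler(mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return GammaSampler(shape, scale)


def dirichlet_from_distribution(dist: MRSDistribution, concentration: float) -> DirichletSampler:
    """Dirichlet over the 7-state mRS simplex, alpha = concentration * p.

    Zero components are floored at 1e-6 before scaling so every state keeps
    positive mass; sampled vectors sum to 1 by construction.
    """
    if concentration <= 0:
        raise ValidationError("dirichlet_from_distribution", "concentration must be > 0")
    p = np.maximum(dist.as_array(), 1e-6)
    return DirichletSampler(concentration * p)


def sampler_for(u: Uncertain):
    """Sampler for one scalar registry entry, per its declared PSA family."""
    if u.family == "beta":
        if u.range is None or u.range.width == 0.0:
            return FixedSampler(u.value)
        if not (0.0 < u.value < 1.0):
            return FixedSampler(u.value)
        return beta_from_mean_ci(u.value, u.range)
    if u.family == "gamma":
        if u.range is None or u.range.width == 0.0 or u.value <= 0.0:
            return FixedSampler(u.value)
        return gamma_from_mean_range(u.value, u.range)
    return FixedSampler(u.value)


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

_INDEXED = re.compile(r"^(?P<base>.+)\[(?P<idx>\d+)\]$")


@dataclass(frozen=True)
class ModelSpec:
    """Immutable bundle of every model input plus its uncertainty registry.

    ``uncertainty`` maps dotted parameter paths (e.g.
    ``"intervention.mrs_at_3mo[3]"``, ``"costs.annual_care_mrs25"``) to
    :class:`Uncertain` records; ``dirichlet_blocks`` maps the two mRS
    simplex paths to their Dirichlet concentrations.
    """

    config: ModelConfig
    discount: DiscountSpec
    thresholds: CEAThresholds
    comparator: StrategyParams
    intervention: StrategyParams
    utilities: UtilitySet
    costs: CostSet
    life_table: LifeTable
    mortality: MortalityModel
    recurrence: RecurrenceModel
    uncertainty: Mapping[str, Uncertain] = field(default_factory=dict)
    dirichlet_blocks: Mapping[str, float] = field(default_factory=dict)
    doc: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping, strict: bool = True) -> "ModelSpec":
        d = copy.deepcopy(dict(d))
        registry: dict[str, Uncertain] = {}
        blocks: dict[str, float] = {}

        def scalar(section: Mapping, key: str, path: str, default=None, register=True) -> float:
            if key not in section:
                if default is None:
                    raise ValidationError(path, "missing required field")
                raw: object = default
            else:
                raw = section[key]
            if isinstance(raw, Mapping):
                value = float(raw["value"])
                pr = raw.get("range")
                rng_ = ParamRange(float(pr[0]), float(pr[1])) if pr is not None else None
                fam = raw.get("dist", "fixed")
                prov = raw.get("provenance", "ASSUMED")
            else:
                value = float(raw)
                rng_, fam, prov = None, "fixed", "ASSUMED"
            if register:
                registry[path] = Uncertain(value, rng_, fam, prov)
            return value

        def vector(section: Mapping, key: str, path: str, n: int, family_override=None) -> tuple[float, ...]:
            raw = section[key]
            values = [float(v) for v in raw["values"]]
            if len(values) != n:
                raise ValidationError(path, f"needs {n} entries, got {len(values)}")
            ranges = raw.get("ranges")
            fam = family_override or raw.get("dist", "fixed")
            prov = raw.get("provenance", "ASSUMED")
            for i, v in enumerate(values):
                pr = ranges[i] if ranges is not None else None
                rng_ = ParamRange(float(pr[0]), float(pr[1])) if pr is not None else None
                registry[f"{path}[{i}]"] = Uncertain(v, rng_, fam, prov)
            return tuple(values)

        try:
            cfg_d = d.get("config", {})
            config = ModelConfig(
                start_age=float(cfg_d.get("start_age", 64.0)),
                horizon=float(cfg_d.get("horizon_years", 30.0)),
                cycle_length=float(cfg_d.get("cycle_length_years", 0.25)),
                half_cycle_correction=bool(cfg_d.get("half_cycle_correction", True)),
                rng_seed=int(cfg_d.get("rng_seed", 20240)),
                psa_iterations=int(cfg_d.get("psa_iterations", 1000)),
            )
            config.validate(strict)

            rate = scalar(d["discount"], "annual_rate", "discount.annual_rate")
            discount = DiscountSpec(rate, registry["discount.annual_rate"].range or ParamRange(0.0, 0.08))
            discount.validate(strict)

            thresholds = CEAThresholds(float(d["thresholds"]["gdp_per_capita"]))

            def strategy(key: str) -> StrategyParams:
                s = d[key]
                vals = vector(s, "mrs_at_3mo", f"{key}.mrs_at_3mo", N_MRS, family_override="dirichlet_component")
                blocks[f"{key}.mrs_at_3mo"] = float(s["mrs_at_3mo"].get("concentration", 115.0))
                dist = MRSDistribution.from_values(vals)
                # registry keeps renormalised component values
                for i, v in enumerate(dist.p):
                    old = registry[f"{key}.mrs_at_3mo[{i}]"]
                    registry[f"{key}.mrs_at_3mo[{i}]"] = Uncertain(v, old.range, old.family, old.provenance)
                sich = scalar(s, "sich_incidence", f"{key}.sich_incidence")
                return StrategyParams(
                    name=str(s.get("name", key)),
                    mrs_at_3mo=dist,
                    sich_incidence=sich,
                    includes_drug_cost=bool(s["includes_drug_cost"]),
                )

            comparator = strategy("comparator")
            intervention = strategy("intervention")

            ut = d["utilities"]
            u_mrs = vector(ut, "u_mrs", "utilities.u_mrs", N_MRS)
            utilities = UtilitySet(
                u_mrs=u_mrs,
                u_recurrence=scalar(ut, "u_recurrence", "utilities.u_recurrence"),
                d_sich=scalar(ut, "d_sich", "utilities.d_sich"),
            )
            utilities.validate(strict)

            co = d["costs"]
            costs = CostSet(
                acute_hosp_by_mrs=vector(co, "acute_hosp_by_mrs", "costs.acute_hosp_by_mrs", N_MRS),
                annual_care_mrs01=scalar(co, "annual_care_mrs01", "costs.annual_care_mrs01"),
                annual_care_mrs25=scalar(co, "annual_care_mrs25", "costs.annual_care_mrs25"),
                recurrent_stroke_event=scalar(co, "recurrent_stroke_event", "costs.recurrent_stroke_event"),
                sich_event=scalar(co, "sich_event", "costs.sich_event"),
                alteplase_price_20mg=scalar(co, "alteplase_price_20mg", "costs.alteplase_price_20mg", register=False),
                alteplase_price_50mg=scalar(co, "alteplase_price_50mg", "costs.alteplase_price_50mg", register=False),
                alteplase_base_case=scalar(co, "alteplase_base_case", "costs.alteplase_base_case"),
            )
            costs.validate(strict)

            lt = d["life_table"]
            life_table = LifeTable(tuple((float(a), float(q)) for a, q in lt["bands"]))
            life_table.validate(strict)

            mo = d["mortality"]
            mortality = MortalityModel(
                hr_by_mrs=vector(mo, "hr_by_mrs", "mortality.hr_by_mrs", N_ALIVE),
                post_stroke_excess_hr=scalar(mo, "post_stroke_excess_hr", "mortality.post_stroke_excess_hr", default=1.0),
            )
            mortality.validate(strict)

            re_ = d["recurrence"]
            recurrence = RecurrenceModel(
                annual_recurrence_by_mrs=vector(
                    re_, "annual_recurrence_by_mrs", "recurrence.annual_recurrence_by_mrs", N_ALIVE
                ),
                case_fatality=scalar(re_, "case_fatality", "recurrence.case_fatality"),
                p_stay_given_survive=scalar(re_, "p_stay_given_survive", "recurrence.p_stay_given_survive", default=0.5),
            )
            recurrence.validate(strict)
        except (KeyError, TypeError) as exc:
            raise ValidationError("model_spec", f"malformed document: {exc!r}") from exc

        # normalised document (renormalised mRS vectors written back)
        for key, strat in (("comparator", comparator), ("intervention", intervention)):
            d[key]["mrs_at_3mo"]["values"] = list(strat.mrs_at_3mo.p)

        return cls(
            config=config,
            discount=discount,
            thresholds=thresholds,
            comparator=comparator,
            intervention=intervention,
            utilities=utilities,
            costs=costs,
            life_table=life_table,
            mortality=mortality,
            recurrence=recurrence,
            uncertainty=registry,
            dirichlet_blocks=blocks,
            doc=d,
        )

    def to_dict(self) -> dict:
        return copy.deepcopy(self.doc)

    def strategies(self) -> tuple[StrategyParams, StrategyParams]:
        """(comparator, intervention)."""
        return self.comparator, self.intervention

    # -- perturbation (OWSA / PSA plumbing) ---------------------------------

    def perturbed(self, path: str, value: float, strict: bool = False) -> "ModelSpec":
        """Return a copy with one scalar parameter set to ``value``.

        Components of an mRS distribution are handled on the simplex: the
        varied component is set to ``value`` and the remaining six are
        rescaled proportionally so the vector still sums to 1 (values are
        clipped into [0,1] if the rescaling would leave the unit interval).
        """
        d = self.to_dict()
        m = _INDEXED.match(path)
        base, idx = (m.group("base"), int(m.group("idx"))) if m else (path, None)
        target = d
        parts = base.split(".")
        for part in parts[:-1]:
            target = target[part]
        leaf = parts[-1]
        if leaf not in target:
            raise ValidationError(path, "unknown parameter path")
        entry = target[leaf]
        if idx is not None and base.endswith("mrs_at_3mo"):
            vals = np.asarray(entry["values"], dtype=float)
            v_new = float(np.clip(value, 0.0, 1.0))
            rest = np.delete(vals, idx)
            rest_sum = rest.sum()
            if rest_sum > 0:
                rest = rest * (1.0 - v_new) / rest_sum
            vals_new = np.insert(rest, idx, v_new)
            vals_new = np.clip(vals_new, 0.0, 1.0)
            vals_new = vals_new / vals_new.sum()
            entry["values"] = [float(v) for v in vals_new]
        elif idx is not None:
            entry["values"][idx] = float(value)
        elif isinstance(entry, Mapping):
            entry["value"] = float(value)
        else:
            target[leaf] = float(value)
        return ModelSpec.from_dict(d, strict=strict)

    def swept_parameters(self) -> Iterator[tuple[str, Uncertain]]:
        """Registry entries with a non-degenerate range (the default OWSA list)."""
        for path, u in self.uncertainty.items():
            if u.range is not None and u.range.width > 0.0:
                yield path, u


def _default_path():
    return resources.files("strokecea.data") / "default_model.yaml"


def load_model_spec(path=None, strict: bool = True) -> ModelSpec:
    """Load a model-spec YAML file; ``path=None`` loads the packaged defaults."""
    if path is None:
        text = _default_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValidationError("model_spec", "document is not a mapping")
    return ModelSpec.from_dict(doc, strict=strict)


def write_model_spec(spec: ModelSpec, path) -> None:
    """Write a spec back to YAML; numeric fields round-trip exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
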