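"""Incremental cost-effectiveness outcomes and threshold classification.

The ICER is the incremental cost per QALY gained, dC/dE.  Following the
Chinese pharmacoeconomic guideline convention, an intervention is "highly
cost-effective" below one times per-capita GDP per QALY, "cost-effective"
between one and three times, and "not cost-effective" above three times;
a dominant intervention (cheaper and more effective) is highly
cost-effective regardless of the threshold.  Net monetary benefit at
willingness-to-pay lambda is NMB = lambda * E - C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .markov import StrategyResult, run_strategy
from .params import CEAThresholds, ModelSpec

__all__ = [
    "CEAResult",
    "BaseCaseResult",
    "compute_icer",
    "classify",
    "net_monetary_benefit",
    "base_case",
]

HIGHLY = "highly cost-effective"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not cost-effective"
DOMINATED = "dominated"
SOUTH_WEST = "south-west"


@dataclass(frozen=True)
class CEAResult:
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None            # None when delta_qaly == 0
    dominance: str | None         # "dominant" | "dominated" | None
    classification: str | None = None

    def with_classification(self, label: str) -> "CEAResult":
        return CEAResult(self.delta_cost, self.delta_qaly, self.delta_ly,
                         self.icer, self.dominance, label)


def compute_icer(intervention: StrategyResult, comparator: StrategyResult) -> CEAResult:
    """Incremental outcomes of intervention versus comparator."""
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qaly - comparator.total_qaly
    dl = intervention.total_ly - comparator.total_ly
    icer = dc / de if de != 0.0 else None
    dominance = None
    if de > 0.0 and dc <= 0.0:
        dominance = "dominant"
    elif de < 0.0 and dc >= 0.0:
        dominance = "dominated"
    return CEAResult(dc, de, dl, icer, dominance)


def classify(cea: CEAResult, thresholds: CEAThresholds) -> str:
    """Guideline classification; exactly one label for every input.

    Boundary convention: an ICER exactly at a threshold falls in the less
    favourable adjacent band (icer == 1x GDP -> "cost-effective",
    icer == 3x GDP -> "cost-effective" since the middle band is closed).
    The south-west quadrant (cheaper but less effective) is labelled on
    its own and never auto-classified against the thresholds.
    """
    dc, de = cea.delta_cost, cea.delta_qaly
    if cea.dominance == "dominant":
        return HIGHLY
    if cea.dominance == "dominated":
        return DOMINATED
    if de == 0.0:
        if dc < 0.0:
            return HIGHLY
        if dc > 0.0:
            return DOMINATED
        return COST_EFFECTIVE   # identical strategies: indifferent
    if de < 0.0:
        return SOUTH_WEST       # dc < 0 here (dc >= 0 is "dominated" above)
    icer = cea.icer
    if icer < thresholds.wtp_1x:
        return HIGHLY
    if icer <= thresholds.wtp_3x:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = wtp * total QALYs - total cost (CNY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.total_qaly - result.total_cost


@dataclass(frozen=True)
class BaseCaseResult:
    intervention: StrategyResult
    comparator: StrategyResult
    cea: CEAResult
    thresholds: CEAThresholds

    def to_summary(self) -> dict:
        """JSON-ready summary: per-arm totals, deltas, ICER, classification."""
        def arm(r: StrategyResult) -> dict:
            return {
                "name": r.name,
                "total_cost_cny": r.total_cost,
                "total_qaly": r.total_qaly,
                "total_ly": r.total_ly,
            }
        return {
            "intervention": arm(self.intervention),
            "comparator": arm(self.comparator),
            "delta_cost_cny": self.cea.delta_cost,
            "delta_qaly": self.cea.delta_qaly,
            "delta_ly": self.cea.delta_ly,
            "icer_cny_per_qaly": self.cea.icer,
            "dominance": self.cea.dominance,
            "classification": self.cea.classification,
            "wtp_1x_cny_per_qaly": self.thresholds.wtp_1x,
            "wtp_3x_cny_per_qaly": self.thresholds.wtp_3x,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_summary(), indent=2, **kwargs)


def base_case(spec: ModelSpec, discount_rate: float | None = None) -> BaseCaseResult:
    """Run both arms through the decision tree and Markov model and compare."""
    comp = run_strategy(spec, spec.comparator, discount_rate=discount_rate)
    intv = run_strategy(spec, spec.intervention, discount_rate=discount_rate)
    cea = compute_icer(intv, comp)
    cea = cea.with_classification(classify(cea, spec.thresholds))
    return BaseCaseResult(intervention=intv, comparator=comp, cea=cea, thresholds=spec.thresholds)
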