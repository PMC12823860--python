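"""Three-month decision-tree phase.

Each arm's first quarter is summarised by the trial's 3-month mRS
distribution: survivors are credited the full quarter of life-years and
state utility, decedents none; costs cover acute hospitalisation by mRS
level, one quarter of post-discharge care for survivors, sICH event
management, and (for the thrombolysis arm) drug acquisition.  sICH enters
as a one-time cost plus a one-quarter utility decrement; sICH deaths are
taken to be already reflected in the 3-month mRS distribution, so no extra
mortality is applied here.  The quarter is treated as time zero and left
undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import DEAD, N_MRS, CostSet, MRSDistribution, StrategyParams, UtilitySet

__all__ = ["TreeOutcome", "run_decision_tree"]


@dataclass(frozen=True)
class TreeOutcome:
    """Cycle-0 ledger for one strategy."""

    initial_distribution: MRSDistribution
    cost_3mo: float
    qaly_3mo: float
    ly_3mo: float


def run_decision_tree(
    strategy: StrategyParams,
    costs: CostSet,
    utilities: UtilitySet,
    cycle_length: float = 0.25,
) -> TreeOutcome:
    """Compute the decision-tree (first-quarter) outcomes of one arm."""
    p = strategy.mrs_at_3mo.p
    u = utilities.u_mrs

    ly = (1.0 - p[DEAD]) * cycle_length
    qaly = sum(p[i] * u[i] for i in range(N_MRS)) * cycle_length
    qaly -= strategy.sich_incidence * utilities.d_sich * cycle_length

    cost = sum(p[i] * costs.acute_hosp_by_mrs[i] for i in range(N_MRS))
    cost += sum(p[i] * costs.annual_care_for(i) for i in range(DEAD)) * cycle_length
    cost += strategy.sich_incidence * costs.sich_event
    if strategy.includes_drug_cost:
        cost += costs.alteplase_base_case

    return TreeOutcome(
        initial_distribution=strategy.mrs_at_3mo,
        cost_3mo=cost,
        qaly_3mo=qaly,
        ly_3mo=ly,
    )
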