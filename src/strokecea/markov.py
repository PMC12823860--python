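"""Markov cohort engine and its microsimulation oracle.

States are {mRS 0..5 alive, Dead}.  Each 3-month cycle a patient faces, in
order: background death (age-banded annual mortality converted to a cycle
probability on the hazard scale and scaled by the mRS-specific death
hazard ratio times a global post-stroke excess ratio), then — among
survivors — recurrent stroke, which is fatal with the case-fatality
probability; recurrence survivors stay in their mRS state with probability
``p_stay_given_survive`` and otherwise shift one level worse (capped at
mRS 5).  "No event" patients remain in state.

Payoffs per cycle: life-years and state utilities on the (optionally
half-cycle-corrected) occupancy, the recurrence utility (0.42/year)
replacing the state utility for recurrence survivors during the event
cycle, quarterly shares of the annual care cost by mRS group, and the
recurrent-stroke event cost for all recurrence events (fatal included).
Everything after the decision-tree quarter is discounted at
``(1 + rate)^(-t)`` with t = cycle_length * cycle_index.

The half-cycle correction weights payoffs by the mean of start- and
end-of-cycle occupancy (trapezoidal rule); with the correction off,
end-of-cycle occupancy is used.  ``microsimulate`` replays the identical
event structure and payoff rules for individual patients and serves as an
independent Monte-Carlo check of the cohort arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import TreeOutcome, run_decision_tree
from .params import DEAD, N_ALIVE, N_MRS, ModelConfig, ModelSpec, StrategyParams

__all__ = [
    "CohortTrace",
    "StrategyResult",
    "MicrosimResult",
    "annual_prob_to_cycle",
    "mortality_for",
    "build_cycle_transition",
    "run_cohort",
    "run_strategy",
    "microsimulate",
]


def annual_prob_to_cycle(p_annual: float, cycle_length: float, hr: float = 1.0) -> float:
    """Convert an annual probability to a cycle probability on the hazard scale.

    Returns ``1 - exp(-hr * (-ln(1 - p_annual)) * cycle_length)``; the
    p_annual = 1 limit maps to 1.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability {p_annual} outside [0,1]")
    if hr <= 0.0:
        raise ValueError(f"hazard ratio {hr} must be > 0")
    if p_annual >= 1.0:
        return 1.0
    rate = -math.log1p(-p_annual)
    return -math.expm1(-hr * rate * cycle_length)


def mortality_for(age, mrs, life_table, mortality, cycle_length: float) -> float:
    """Cycle death probability for an alive mRS state at a given age."""
    q = life_table.annual_mortality(age)
    hr = mortality.hr_by_mrs[mrs] * mortality.post_stroke_excess_hr
    return annual_prob_to_cycle(q, cycle_length, hr)


def build_cycle_transition(occupancy: np.ndarray, death_p: np.ndarray, rec_p: np.ndarray,
                           case_fatality: float, p_stay: float):
    """One cycle of cohort flows.

    Parameters are the current occupancy (7,), per-state cycle death and
    recurrence probabilities (6,), the recurrence case fatality and the
    stay-given-survive probability.  Returns ``(next_occupancy,
    rec_events, rec_survivor_stay, rec_survivor_move)`` where the last
    three are per-source-state flow masses used for payoff attribution
    (``rec_survivor_move[i]`` lands in state ``min(i+1, 5)``).
    """
    alive = occupancy[:N_ALIVE]
    deaths = alive * death_p
    surv = alive - deaths
    rec = surv * rec_p
    rec_fatal = rec * case_fatality
    rec_surv = rec - rec_fatal
    stay = rec_surv * p_stay
    move = rec_surv - stay

    moved_to = np.zeros(N_ALIVE)
    moved_to[1:] += move[:-1]
    moved_to[N_ALIVE - 1] += move[N_ALIVE - 1]

    nxt = np.empty(N_MRS)
    nxt[:N_ALIVE] = (surv - rec) + stay + moved_to
    nxt[DEAD] = occupancy[DEAD] + deaths.sum() + rec_fatal.sum()
    return nxt, rec, stay, move


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle ledger; row 0 is the decision-tree quarter."""

    cycle: np.ndarray
    age: np.ndarray
    occupancy: np.ndarray          # (n_rows, 7) end-of-cycle state occupancy
    cost: np.ndarray               # discounted increments
    qaly: np.ndarray
    ly: np.ndarray
    cost_undisc: np.ndarray
    qaly_undisc: np.ndarray
    ly_undisc: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"mrs{i}": self.occupancy[:, i] for i in range(N_ALIVE)}
        cols["dead"] = self.occupancy[:, DEAD]
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "age": self.age,
                **cols,
                "cost": self.cost,
                "qaly": self.qaly,
                "ly": self.ly,
                "cost_undiscounted": self.cost_undisc,
                "qaly_undiscounted": self.qaly_undisc,
                "ly_undiscounted": self.ly_undisc,
            }
        )


@dataclass(frozen=True)
class StrategyResult:
    name: str
    total_cost: float
    total_qaly: float
    total_ly: float
    trace: CohortTrace


def _cycle_inputs(spec: ModelSpec, config: ModelConfig, discount_rate: float):
    """Precompute per-cycle death probabilities and shared arrays."""
    cl = config.cycle_length
    n = config.n_markov_cycles
    hr = np.asarray(spec.mortality.hr_by_mrs) * spec.mortality.post_stroke_excess_hr
    death = np.empty((n, N_ALIVE))
    ages = config.start_age + cl * np.arange(1, n + 1)
    for k, age in enumerate(ages):
        q = spec.life_table.annual_mortality(age)
        rate = -math.log1p(-q)
        death[k] = -np.expm1(-hr * rate * cl)
    rec = np.array([annual_prob_to_cycle(r, cl) for r in spec.recurrence.annual_recurrence_by_mrs])
    disc = (1.0 + discount_rate) ** (-cl * np.arange(1, n + 1))
    return cl, n, ages, death, rec, disc


def run_cohort(
    tree: TreeOutcome,
    spec: ModelSpec,
    config: ModelConfig | None = None,
    discount_rate: float | None = None,
    name: str = "",
) -> StrategyResult:
    """Propagate a cohort from its 3-month distribution over the Markov horizon."""
    config = config or spec.config
    rate = spec.discount.annual_rate if discount_rate is None else discount_rate
    cl, n, ages, death, rec_p, disc = _cycle_inputs(spec, config, rate)
    u = np.asarray(spec.utilities.u_mrs)
    u_rec = spec.utilities.u_recurrence
    care = spec.costs.care_rate_array()[:N_ALIVE]
    cf = spec.recurrence.case_fatality
    p_stay = spec.recurrence.p_stay_given_survive
    hcc = config.half_cycle_correction

    n_rows = n + 1
    occ = np.zeros((n_rows, N_MRS))
    cost_d = np.zeros(n_rows)
    qaly_d = np.zeros(n_rows)
    ly_d = np.zeros(n_rows)
    cost_u = np.zeros(n_rows)
    qaly_u = np.zeros(n_rows)
    ly_u = np.zeros(n_rows)

    x = tree.initial_distribution.as_array()
    occ[0] = x
    cost_u[0] = cost_d[0] = tree.cost_3mo
    qaly_u[0] = qaly_d[0] = tree.qaly_3mo
    ly_u[0] = ly_d[0] = tree.ly_3mo

    dest_idx = np.minimum(np.arange(N_ALIVE) + 1, N_ALIVE - 1)
    for k in range(1, n + 1):
        nxt, rec, stay, move = build_cycle_transition(x, death[k - 1], rec_p, cf, p_stay)
        w = 0.5 * (x[:N_ALIVE] + nxt[:N_ALIVE]) if hcc else nxt[:N_ALIVE]

        q_base = float(w @ u[:N_ALIVE])
        # recurrence survivors spend the event cycle at the recurrence utility
        if hcc:
            adj = float(np.sum(stay * (u_rec - u[:N_ALIVE])))
            adj += float(np.sum(move * (u_rec - 0.5 * (u[:N_ALIVE] + u[dest_idx]))))
        else:
            adj = float(np.sum(stay * (u_rec - u[:N_ALIVE])))
            adj += float(np.sum(move * (u_rec - u[dest_idx])))

        q_inc = cl * (q_base + adj)
        ly_inc = cl * float(w.sum())
        c_inc = cl * float(w @ care) + spec.costs.recurrent_stroke_event * float(rec.sum())

        occ[k] = nxt
        qaly_u[k], ly_u[k], cost_u[k] = q_inc, ly_inc, c_inc
        qaly_d[k], ly_d[k], cost_d[k] = q_inc * disc[k - 1], ly_inc * disc[k - 1], c_inc * disc[k - 1]
        x = nxt

    trace = CohortTrace(
        cycle=np.arange(n_rows),
        age=np.concatenate(([config.start_age], ages)),
        occupancy=occ,
        cost=cost_d, qaly=qaly_d, ly=ly_d,
        cost_undisc=cost_u, qaly_undisc=qaly_u, ly_undisc=ly_u,
    )
    return StrategyResult(
        name=name,
        total_cost=float(cost_d.sum()),
        total_qaly=float(qaly_d.sum()),
        total_ly=float(ly_d.sum()),
        trace=trace,
    )


def run_strategy(spec: ModelSpec, strategy: StrategyParams, config: ModelConfig | None = None,
                 discount_rate: float | None = None) -> StrategyResult:
    """Decision tree + Markov cohort for one arm of the model."""
    config = config or spec.config
    tree = run_decision_tree(strategy, spec.costs, spec.utilities, config.cycle_length)
    return run_cohort(tree, spec, config, discount_rate, name=strategy.name)


@dataclass(frozen=True)
class MicrosimResult:
    """Mean per-patient totals with Monte-Carlo standard errors."""

    name: str
    total_cost: float
    total_qaly: float
    total_ly: float
    se_cost: float
    se_qaly: float
    se_ly: float
    n_individuals: int


def microsimulate(
    tree: TreeOutcome,
    spec: ModelSpec,
    n_individuals: int,
    seed: int,
    config: ModelConfig | None = None,
    discount_rate: float | None = None,
    strategy: StrategyParams | None = None,
    name: str = "microsim",
) -> MicrosimResult:
    """Individual-level replay of the cohort model (validation oracle).

    Each simulated patient draws a 3-month mRS state, an sICH event, and a
    per-cycle event sequence using exactly the probabilities and payoff
    rules of :func:`run_cohort`; by the law of large numbers the mean
    totals converge to the cohort totals.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    config = config or spec.config
    rate = spec.discount.annual_rate if discount_rate is None else discount_rate
    cl, n_cycles, ages, death, rec_p, disc = _cycle_inputs(spec, config, rate)
    rng = np.random.default_rng(seed)

    u = np.asarray(spec.utilities.u_mrs)  # length 7, u[6] = 0
    u_rec = spec.utilities.u_recurrence
    care7 = spec.costs.care_rate_array()
    acute = np.asarray(spec.costs.acute_hosp_by_mrs)
    cf = spec.recurrence.case_fatality
    p_stay = spec.recurrence.p_stay_given_survive
    hcc = config.half_cycle_correction

    init = tree.initial_distribution.as_array()
    state = rng.choice(N_MRS, size=n_individuals, p=init)
    alive0 = state != DEAD

    sich_inc = strategy.sich_incidence if strategy is not None else 0.0
    drug = spec.costs.alteplase_base_case if (strategy is not None and strategy.includes_drug_cost) else 0.0
    sich = rng.random(n_individuals) < sich_inc

    cost = acute[state] + care7[state] * cl + drug + sich * spec.costs.sich_event
    qaly = u[state] * cl - sich * spec.utilities.d_sich * cl
    ly = alive0 * cl
    cost = cost.astype(float)
    qaly = qaly.astype(float)
    ly = ly.astype(float)

    for k in range(1, n_cycles + 1):
        alive = state != DEAD
        if not alive.any():
            break
        s_old = state.copy()
        d_k = death[k - 1]

        u1 = rng.random(n_individuals)
        u2 = rng.random(n_individuals)
        u3 = rng.random(n_individuals)
        u4 = rng.random(n_individuals)

        p_die = np.zeros(n_individuals)
        p_die[alive] = d_k[state[alive]]
        dies = alive & (u1 < p_die)

        p_rec = np.zeros(n_individuals)
        survivors = alive & ~dies
        p_rec[survivors] = rec_p[state[survivors]]
        rec_event = survivors & (u2 < p_rec)
        rec_fatal = rec_event & (u3 < cf)
        rec_surv = rec_event & ~rec_fatal
        rec_move = rec_surv & (u4 >= p_stay)

        new_state = state.copy()
        new_state[dies | rec_fatal] = DEAD
        new_state[rec_move] = np.minimum(state[rec_move] + 1, N_ALIVE - 1)

        alive_old = (s_old != DEAD).astype(float)
        alive_new = (new_state != DEAD).astype(float)
        if hcc:
            ly_inc = cl * 0.5 * (alive_old + alive_new)
            q_inc = cl * 0.5 * (u[s_old] + u[new_state])
            c_care = cl * 0.5 * (care7[s_old] + care7[new_state])
        else:
            ly_inc = cl * alive_new
            q_inc = cl * u[new_state]
            c_care = cl * care7[new_state]
        # recurrence survivors: event-cycle utility replaced by the recurrence utility
        q_inc[rec_surv] = cl * u_rec
        c_inc = c_care + rec_event * spec.costs.recurrent_stroke_event

        df = disc[k - 1]
        cost += c_inc * df
        qaly += q_inc * df
        ly += ly_inc * df
        state = new_state

    sqn = math.sqrt(n_individuals)
    return MicrosimResult(
        name=name,
        total_cost=float(cost.mean()),
        total_qaly=float(qaly.mean()),
        total_ly=float(ly.mean()),
        se_cost=float(cost.std(ddof=1) / sqn) if n_individuals > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / sqn) if n_individuals > 1 else 0.0,
        se_ly=float(ly.std(ddof=1) / sqn) if n_individuals > 1 else 0.0,
        n_individuals=n_individuals,
    )
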