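"""One-way (tornado) and probabilistic sensitivity analysis.

OWSA re-runs the full model with one parameter at a time set to the low
and high end of its declared range, everything else held at base case.
Components of an mRS simplex are swept by fixing the varied component at
its bound and rescaling the remaining six proportionally so the vector
still sums to one.

PSA samples every uncertain parameter independently from its declared
family — Dirichlet over each arm's 7-state mRS block (concentration set
by the source-trial arm size), beta for scalar probabilities and
utilities, gamma for costs; parameters declared ``fixed`` (death hazard
ratios, the discount rate, structural probabilities) are held at base
case — then runs both arms and records the incremental cost and QALY
pair.  The cost-effectiveness acceptability curve is the fraction of
draws with positive incremental net monetary benefit at each
willingness-to-pay grid point.
"""

from __future__ import annotations

import copy
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outcomes import base_case
from .params import (
    DEAD,
    N_ALIVE,
    ModelSpec,
    dirichlet_from_distribution,
    sampler_for,
)

__all__ = [
    "TornadoEntry",
    "one_way_sensitivity",
    "tornado_table",
    "PSAResult",
    "run_psa",
    "CEACCrossing",
    "ceac_crossing",
]

DEFAULT_WTP_GRID = np.arange(0.0, 120001.0, 1000.0)

_INDEXED = re.compile(r"^(?P<base>.+)\[(?P<idx>\d+)\]$")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_value(spec: ModelSpec) -> float:
    cea = base_case(spec).cea
    return cea.icer if cea.icer is not None else float("nan")


def one_way_sensitivity(spec: ModelSpec, params: list[str] | None = None) -> list[TornadoEntry]:
    """Tornado entries, sorted by |ICER(high) - ICER(low)| descending.

    ``params`` defaults to every registry entry with a non-degenerate
    range.  Bounds that would produce an invalid bundle (probabilities
    outside [0,1] after renormalisation) are clipped with a warning.
    """
    if params is None:
        params = [p for p, _ in spec.swept_parameters()]
    entries = []
    for path in params:
        u = spec.uncertainty[path]
        if u.range is None:
            raise ValueError(f"parameter {path} has no range to sweep")
        lo, hi = u.range.low, u.range.high
        if u.family in ("beta", "dirichlet_component") and (lo < 0.0 or hi > 1.0):
            warnings.warn(f"{path}: sweep bounds clipped into [0,1]")
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        icer_lo = _icer_value(spec.perturbed(path, lo))
        icer_hi = _icer_value(spec.perturbed(path, hi))
        entries.append(TornadoEntry(path, lo, hi, icer_lo, icer_hi))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Plot-ready tornado table (parameter, bounds, ICERs, span)."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "span": [e.span for e in entries],
        }
    )


def _set_scalar(doc: dict, path: str, value: float) -> None:
    m = _INDEXED.match(path)
    base, idx = (m.group("base"), int(m.group("idx"))) if m else (path, None)
    target = doc
    parts = base.split(".")
    for part in parts[:-1]:
        target = target[part]
    entry = target[parts[-1]]
    if idx is not None:
        entry["values"][idx] = float(value)
    elif isinstance(entry, dict):
        entry["value"] = float(value)
    else:
        target[parts[-1]] = float(value)


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental outcomes, sampled parameters and the CEAC."""

    draws: pd.DataFrame          # draw, delta_cost, delta_qaly
    sampled: pd.DataFrame        # one column per sampled parameter
    ceac: pd.DataFrame           # wtp, p_intervention, p_comparator
    wtp_grid: np.ndarray
    seed: int
    n_iterations: int


def run_psa(
    spec: ModelSpec,
    n_iterations: int | None = None,
    seed: int | None = None,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis of intervention vs comparator."""
    n = n_iterations if n_iterations is not None else spec.config.psa_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    seed = spec.config.rng_seed if seed is None else seed
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    rng = np.random.default_rng(seed)

    scalar_samplers = {
        path: sampler_for(u)
        for path, u in spec.uncertainty.items()
        if u.family in ("beta", "gamma")
    }
    block_samplers = {}
    for path, conc in spec.dirichlet_blocks.items():
        strat = spec.comparator if path.startswith("comparator") else spec.intervention
        block_samplers[path] = dirichlet_from_distribution(strat.mrs_at_3mo, conc)

    base_doc = spec.to_dict()
    dc = np.empty(n)
    de = np.empty(n)
    records: list[dict] = []
    for it in range(n):
        doc = copy.deepcopy(base_doc)
        rec: dict[str, float] = {}
        for path, sampler in block_samplers.items():
            p = sampler.sample(rng)
            doc_path = path.split(".")
            doc[doc_path[0]][doc_path[1]]["values"] = [float(v) for v in p]
            for i, v in enumerate(p):
                rec[f"{path}[{i}]"] = float(v)
        for path, sampler in scalar_samplers.items():
            v = float(sampler.sample(rng))
            _set_scalar(doc, path, v)
            rec[path] = v
        # utilities must stay monotone in disability: sort sampled alive-state
        # utilities descending (death stays 0)
        uvals = doc["utilities"]["u_mrs"]["values"]
        alive_sorted = sorted((float(v) for v in uvals[:N_ALIVE]), reverse=True)
        doc["utilities"]["u_mrs"]["values"] = alive_sorted + [float(uvals[DEAD])]

        draw_spec = ModelSpec.from_dict(doc, strict=False)
        res = base_case(draw_spec)
        dc[it] = res.cea.delta_cost
        de[it] = res.cea.delta_qaly
        records.append(rec)

    nmb = grid[:, None] * de[None, :] - dc[None, :]
    p_int = (nmb > 0.0).mean(axis=1)
    ceac = pd.DataFrame({"wtp": grid, "p_intervention": p_int, "p_comparator": 1.0 - p_int})
    draws = pd.DataFrame({"draw": np.arange(n), "delta_cost": dc, "delta_qaly": de})
    return PSAResult(
        draws=draws,
        sampled=pd.DataFrame.from_records(records),
        ceac=ceac,
        wtp_grid=grid,
        seed=seed,
        n_iterations=n,
    )


@dataclass(frozen=True)
class CEACCrossing:
    wtp: float
    at_boundary: bool


def ceac_crossing(ceac: pd.DataFrame, threshold: float = 0.5) -> CEACCrossing:
    """WTP at which the intervention's acceptability first reaches ``threshold``.

    Linear interpolation between the grid points bracketing the crossing;
    a curve already above threshold at the grid minimum (or never reaching
    it) returns the corresponding boundary with ``at_boundary=True``.
    """
    wtp = np.asarray(ceac["wtp"], dtype=float)
    p = np.asarray(ceac["p_intervention"], dtype=float)
    if p[0] >= threshold:
        return CEACCrossing(float(wtp[0]), True)
    above = np.nonzero(p >= threshold)[0]
    if len(above) == 0:
        return CEACCrossing(float(wtp[-1]), True)
    j = int(above[0])
    w0, w1, p0, p1 = wtp[j - 1], wtp[j], p[j - 1], p[j]
    if p1 == p0:
        return CEACCrossing(float(w1), False)
    frac = (threshold - p0) / (p1 - p0)
    return CEACCrossing(float(w0 + frac * (w1 - w0)), False)
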