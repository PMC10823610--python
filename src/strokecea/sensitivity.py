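"""One-way deterministic (DSA) and probabilistic (PSA) sensitivity analysis.

DSA reruns both arms with one named parameter pinned at its lower, then its
upper bound, everything else fixed, and reports the resulting ICERs and
incremental net monetary benefits (tornado data, sorted by ICER span).

PSA is a second-order Monte Carlo: each iteration draws one parameter set
from the configured distributions (gamma for costs, beta for utilities and
the stroke disutility, lognormal for mortality hazard ratios), evaluates
both arms under the *same* draw — the arms differ only in their day-90
distributions and drug costs, so parameter uncertainty does not create
spurious between-arm differences — and records the incremental cost and
QALYs.  Cost-effectiveness acceptability is the fraction of iterations with
positive incremental NMB at each willingness-to-pay value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import compare
from .engine import run_arm
from .params import (
    DistributionSpec,
    ModelParams,
    get_param_value,
    set_param_inplace,
    set_param_value,
)

__all__ = [
    "DSAResult",
    "PSAResult",
    "run_dsa",
    "sample_parameter_set",
    "run_psa",
    "default_wtp_grid",
]


@dataclass
class DSAResult:
    base_icer: float
    table: pd.DataFrame   # param, low, high, icer_low, icer_high, inc_nmb_low, inc_nmb_high, span


@dataclass
class PSAResult:
    n_iter: int
    seed: int
    draws: pd.DataFrame          # iteration, inc_cost, inc_qalys, inc_nmb
    ceac: pd.DataFrame           # wtp, p_cost_effective
    p_ce_at_wtp: float
    wtp: float
    mean_inc_cost: float = field(init=False)
    mean_inc_qalys: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_inc_cost = float(self.draws["inc_cost"].mean())
        self.mean_inc_qalys = float(self.draws["inc_qalys"].mean())


def _icer_value(params: ModelParams, reference: str = "edb", comparator: str = "huk"):
    ref = run_arm(reference, params)
    cmp_ = run_arm(comparator, params)
    return compare(ref, cmp_, params.econ.wtp)


def run_dsa(params: ModelParams, reference: str = "edb", comparator: str = "huk") -> DSAResult:
    """One-way deterministic sensitivity analysis over the configured ranges."""
    if not params.dsa_ranges:
        raise ValueError("no DSA ranges configured")
    base = _icer_value(params, reference, comparator)
    rows = []
    for rng in params.dsa_ranges:
        out = {}
        for side, value in (("low", rng.low), ("high", rng.high)):
            varied = set_param_value(params, rng.param, value)
            try:
                varied.validate()
            except Exception:
                continue  # range violates a type invariant: skip side
            out[side] = _icer_value(varied, reference, comparator)
        if len(out) < 2:
            continue
        icer_low = out["low"].icer if out["low"].icer is not None else np.nan
        icer_high = out["high"].icer if out["high"].icer is not None else np.nan
        rows.append({
            "param": rng.param,
            "low": rng.low,
            "high": rng.high,
            "base": get_param_value(params, rng.param),
            "icer_low": icer_low,
            "icer_high": icer_high,
            "inc_nmb_low": out["low"].incremental_nmb,
            "inc_nmb_high": out["high"].incremental_nmb,
            "span": abs(icer_high - icer_low),
        })
    table = pd.DataFrame(rows).sort_values("span", ascending=False).reset_index(drop=True)
    return DSAResult(base_icer=base.icer, table=table)


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "gamma":
        return float(rng.gamma(shape=spec.alpha, scale=spec.beta))
    if spec.family == "beta":
        return float(rng.beta(spec.alpha, spec.beta))
    if spec.family == "lognormal":
        return float(rng.lognormal(mean=spec.alpha, sigma=spec.beta))
    return spec.value


def sample_parameter_set(params: ModelParams, rng: np.random.Generator) -> ModelParams:
    """One second-order draw: every distributed parameter sampled independently."""
    drawn = params.copy()
    for pid, spec in params.psa_specs.items():
        if spec.family == "fixed":
            continue
        set_param_inplace(drawn, pid, _draw(spec, rng))
    return drawn


def default_wtp_grid(wtp: float) -> np.ndarray:
    """0 to 3x the base threshold in 1,000-¥ steps, with the threshold included."""
    grid = np.arange(0.0, 3 * wtp + 1000.0, 1000.0)
    if wtp not in grid:
        grid = np.sort(np.append(grid, wtp))
    return grid


def run_psa(
    params: ModelParams,
    n_iter: int,
    seed: int,
    reference: str = "edb",
    comparator: str = "huk",
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n_iter`` Monte Carlo iterations.

    Each iteration uses an independent, iteration-indexed substream spawned
    from ``seed`` so results are reproducible and insensitive to partial
    re-runs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    wtp = params.econ.wtp
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(wtp)
    seeds = np.random.SeedSequence(seed).spawn(n_iter)
    rows = []
    for i in range(n_iter):
        rng = np.random.default_rng(seeds[i])
        drawn = sample_parameter_set(params, rng)
        res = compare(run_arm(reference, drawn), run_arm(comparator, drawn), wtp)
        rows.append({"iteration": i, "inc_cost": res.incremental_cost,
                     "inc_qalys": res.incremental_qalys, "inc_nmb": res.incremental_nmb})
    draws = pd.DataFrame(rows)
    inc_nmb_at = draws["inc_qalys"].to_numpy()[:, None] * wtp_grid[None, :] \
        - draws["inc_cost"].to_numpy()[:, None]
    ceac = pd.DataFrame({"wtp": wtp_grid, "p_cost_effective": (inc_nmb_at > 0).mean(axis=0)})
    p_at = float((draws["inc_qalys"] * wtp - draws["inc_cost"] > 0).mean())
    return PSAResult(n_iter=n_iter, seed=seed, draws=draws, ceac=ceac,
                     p_ce_at_wtp=p_at, wtp=wtp)
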