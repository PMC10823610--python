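"""Synthetic trial-like inputs.

No patient-level data from either pivotal trial is public, so this module
fabricates an individual-patient-data (IPD) table that *emulates* the
active-arm trial population: 13 baseline covariates whose marginals track
the published baseline table of the edaravone dexborneol trial arm, plus a
day-90 mRS outcome drawn from a proportional-odds model whose marginal
distribution is calibrated to the published (pre-adjustment) day-90
outcome column.  Outcomes depend on NIHSS, age and diabetes through the
latent score, so reweighting the covariates measurably shifts the outcome
distribution — which is what the MAIC stage needs to be testable.

Only medians and proportions of the real baseline table are published; the
distribution families here (truncated normals for age/BMI, a scaled beta
for onset-to-treatment time, a shifted geometric for NIHSS, independent
coin flips for binaries with a mild age–CHD link) are this package's own
choices and are documented in the methods note.

Also provides :func:`perturb_params`, a jittered-parameter factory for
property-based robustness tests of the Markov engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .maic import OUTCOME_COLUMN, AggregateTarget
from .params import ModelParams

__all__ = [
    "IPDGeneratorSpec",
    "generate_ipd",
    "edb_aggregate_marginals",
    "huk_aggregate_targets",
    "perturb_params",
    "COVARIATES",
]

#: the 13 matching covariates, in the order of the published baseline table
COVARIATES = [
    "age", "male", "bmi", "smoker", "time_to_treatment_h", "previous_stroke",
    "baseline_mrs01", "nihss", "cardioembolic", "hypertension", "diabetes",
    "hyperlipidemia", "chd",
]

# published baseline marginals of the EDB trial arm (medians / proportions)
_EDB_MARGINALS = {
    "age": ("median", 62.96),
    "male": ("proportion", 0.6745),
    "bmi": ("median", 24.20),
    "smoker": ("proportion", 0.3890),
    "time_to_treatment_h": ("median", 28.0),
    "previous_stroke": ("proportion", 0.2905),
    "baseline_mrs01": ("proportion", 0.9983),
    "nihss": ("median", 6.00),
    "cardioembolic": ("proportion", 0.0518),
    "hypertension": ("proportion", 0.6511),
    "diabetes": ("proportion", 0.2521),
    "hyperlipidemia": ("proportion", 0.0735),
    "chd": ("proportion", 0.0868),
}

# published pre-adjustment day-90 mRS margins of the EDB arm (mRS 0..6)
_EDB_D90_MARGINS = np.array([0.227, 0.444, 0.128, 0.109, 0.063, 0.027, 0.000])

# aggregate baseline of the HUK trial (the matching targets for MAIC)
_HUK_TARGETS = [
    ("age", "median", 62.00),
    ("male", "proportion", 0.6805),
    ("bmi", "median", 24.01),
    ("smoker", "proportion", 0.4330),
    ("time_to_treatment_h", "median", 30.5),
    ("previous_stroke", "proportion", 0.2712),
    ("baseline_mrs01", "proportion", 0.9206),
    ("nihss", "median", 7.00),
    ("cardioembolic", "proportion", 0.0075),
    ("hypertension", "proportion", 0.6631),
    ("diabetes", "proportion", 0.3053),
    ("hyperlipidemia", "proportion", 0.1489),
    ("chd", "proportion", 0.1120),
]


def edb_aggregate_marginals() -> dict[str, tuple[str, float]]:
    """Published marginals the generator targets (covariate -> (kind, value))."""
    return dict(_EDB_MARGINALS)


def huk_aggregate_targets() -> list[AggregateTarget]:
    """Published aggregate baseline of the comparator trial, as MAIC targets."""
    return [AggregateTarget(c, k, v) for c, k, v in _HUK_TARGETS]


@dataclass
class IPDGeneratorSpec:
    """Configuration of the synthetic IPD generator.

    ``effect_weights`` are the latent proportional-odds slopes linking
    covariates to worse day-90 outcomes (positive = more disability):
    NIHSS per point above 6, age per decade above 62.96, diabetes yes/no.
    They are an arbitrary-but-fixed choice, large enough that reweighting
    the covariates visibly shifts the outcome distribution.
    """

    n: int = 1200
    seed: int = 0
    age_sd: float = 9.0
    bmi_sd: float = 3.0
    time_beta: tuple[float, float] = (2.66, 2.0)   # scaled to (0, 48] h
    nihss_geom_p: float = 0.5                       # NIHSS = 6 + Geom(p) - 1, capped 25
    effect_weights: dict[str, float] = field(
        default_factory=lambda: {"nihss": 0.35, "age_decade": 0.30, "diabetes": 0.40}
    )
    outcome_margins: np.ndarray = field(default_factory=lambda: _EDB_D90_MARGINS.copy())
    marginals: dict[str, tuple[str, float]] = field(default_factory=edb_aggregate_marginals)


def _trunc_normal(rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float):
    out = rng.normal(mean, sd, size=2 * n)
    out = out[(out >= lo) & (out <= hi)]
    while len(out) < n:
        more = rng.normal(mean, sd, size=n)
        out = np.concatenate([out, more[(more >= lo) & (more <= hi)]])
    return out[:n]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_ipd(spec: IPDGeneratorSpec | None = None) -> pd.DataFrame:
    """Generate a complete synthetic IPD table, deterministic given the seed."""
    spec = spec or IPDGeneratorSpec()
    if spec.n < 50:
        raise ValueError("need at least 50 patients for a stable outcome calibration")
    m = spec.marginals
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    age = _trunc_normal(rng, n, m["age"][1], spec.age_sd,
                        m["age"][1] - 2.5 * spec.age_sd, m["age"][1] + 2.5 * spec.age_sd)
    bmi = _trunc_normal(rng, n, m["bmi"][1], spec.bmi_sd,
                        m["bmi"][1] - 3 * spec.bmi_sd, m["bmi"][1] + 3 * spec.bmi_sd)
    a, b = spec.time_beta
    ttt = 48.0 * rng.beta(a, b, size=n)
    nihss = np.minimum(6 + rng.geometric(spec.nihss_geom_p, size=n) - 1, 25)

    def coin(p: float) -> np.ndarray:
        return (rng.random(n) < p).astype(int)

    male = coin(m["male"][1])
    smoker = coin(m["smoker"][1])
    prev = coin(m["previous_stroke"][1])
    mrs01 = coin(m["baseline_mrs01"][1])
    cardio = coin(m["cardioembolic"][1])
    htn = coin(m["hypertension"][1])
    dm = coin(m["diabetes"][1])
    lipid = coin(m["hyperlipidemia"][1])
    # mild age link for coronary heart disease (older patients more likely)
    p0 = m["chd"][1]
    logit = np.log(p0 / (1 - p0)) + 0.04 * (age - m["age"][1])
    chd = (rng.random(n) < _sigmoid(logit)).astype(int)

    # proportional-odds outcome calibrated to the published day-90 margins
    ew = spec.effect_weights
    eta = (ew.get("nihss", 0.0) * (nihss - 6)
           + ew.get("age_decade", 0.0) * (age - m["age"][1]) / 10.0
           + ew.get("diabetes", 0.0) * dm)
    margins = np.asarray(spec.outcome_margins, dtype=float)
    margins = margins / margins.sum()   # printed columns round to 0.1%
    cum_targets = np.cumsum(margins)[:-1]  # cutpoints for mRS <= 0..5
    cuts = []
    for t in cum_targets:
        if t <= 0.0:
            cuts.append(-np.inf)
            continue
        if t >= 1.0:
            cuts.append(np.inf)
            continue
        f = lambda c: _sigmoid(c - eta).mean() - t
        cuts.append(brentq(f, -50, 50))
    cum_p = np.column_stack([_sigmoid(c - eta) if np.isfinite(c)
                             else np.full(n, 1.0 if c > 0 else 0.0) for c in cuts])
    cum_p = np.minimum.accumulate(cum_p[:, ::-1], axis=1)[:, ::-1]  # enforce monotone
    cum_p = np.column_stack([cum_p, np.ones(n)])
    draws = rng.random(n)
    outcome = (draws[:, None] > cum_p).sum(axis=1)

    return pd.DataFrame({
        "age": age, "male": male, "bmi": bmi, "smoker": smoker,
        "time_to_treatment_h": ttt, "previous_stroke": prev,
        "baseline_mrs01": mrs01, "nihss": nihss, "cardioembolic": cardio,
        "hypertension": htn, "diabetes": dm, "hyperlipidemia": lipid,
        "chd": chd, OUTCOME_COLUMN: outcome,
    })


def perturb_params(params: ModelParams, relative_scale: float, seed: int) -> ModelParams:
    """Multiplicative jitter on costs, utilities and hazard ratios.

    Each scalar is multiplied by ``1 + relative_scale * u`` with
    ``u ~ Uniform(-1, 1)``, then clipped back to its type invariant
    (utilities to [0, 1], costs to >= 0, hazard ratios to >= 1).  Used for
    property-based robustness sweeps of the engine.
    """
    if not 0.0 <= relative_scale <= 0.5:
        raise ValueError("relative_scale must be in [0, 0.5]")
    out = params.copy()
    if relative_scale == 0.0:
        return out
    rng = np.random.default_rng(seed)

    def jit(x: float) -> float:
        return x * (1.0 + relative_scale * rng.uniform(-1, 1))

    for key in out.costs.hosp_cost_by_group:
        out.costs.hosp_cost_by_group[key] = max(jit(out.costs.hosp_cost_by_group[key]), 0.0)
    for key in out.costs.annual_post_stroke_cost_by_group:
        out.costs.annual_post_stroke_cost_by_group[key] = max(
            jit(out.costs.annual_post_stroke_cost_by_group[key]), 0.0)
    out.utilities.u = np.clip([jit(v) for v in out.utilities.u], 0.0, 1.0)
    out.utilities.stroke_disutility = float(np.clip(jit(out.utilities.stroke_disutility), 0.0, 1.0))
    out.mortality.hr = np.maximum([jit(v) for v in out.mortality.hr], 1.0)
    for arm in out.arms.values():
        arm.drug_price_per_unit = max(jit(arm.drug_price_per_unit), 0.0)
    # keep the one-way ranges consistent with the jittered base values
    from .params import get_param_value
    for rng_ in out.dsa_ranges:
        base = get_param_value(out, rng_.param)
        rng_.low = min(rng_.low, base)
        rng_.high = max(rng_.high, base)
    out.validate()
    return out
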