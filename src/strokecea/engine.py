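"""Decision-tree + Markov cohort engine.

Short-term stage: the trial-derived (MAIC-adjusted) day-90 mRS distribution
is the decision-tree endpoint for each arm; that distribution is held for
the whole first model year ("cycle 0") and seeds the long-term Markov chain.

Long-term stage: annual cycles over a 40-year horizon.  Each cycle, patients
in an alive mRS state either

* die (life-table mortality adjusted by an mRS-specific hazard ratio),
* survive and suffer a recurrent ischemic stroke — then either die of it
  (case fatality) or move to an equal-or-worse mRS state per the
  redistribution matrix, or
* survive and remain in their current state.

Costs (drug course, one-time hospitalization per stroke event, annual
secondary-prevention cost in stroke years) and QALYs (state utilities minus
a stroke-year disutility) are accrued per cycle with half-cycle correction
and discounted at the configured annual rates.

The hazard ratio is applied on the rate scale by default,
``p = 1 - (1 - q)^HR``, which keeps probabilities in (0, 1) even at the
oldest ages where the naive product ``q * HR`` exceeds 1.  The naive
product (capped at 1) is available as ``hr_mode="probability"`` for
convention calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DEATH_STATE, ModelParams, MRSDistribution

__all__ = [
    "CohortTrace",
    "ArmOutcome",
    "decision_tree_stage",
    "natural_mortality",
    "death_probability",
    "recurrence_probability",
    "build_transition_matrix",
    "run_cohort",
    "accrue",
    "run_arm",
    "microsimulate",
]

#: alive mRS states grouped the way the cost inputs are stratified
GROUP_MILD = (0, 1, 2)     # mrs0_2
GROUP_SEVERE = (3, 4, 5)   # mrs3_5


def _group_key(state: int) -> str:
    if state in GROUP_MILD:
        return "mrs0_2"
    if state in GROUP_SEVERE:
        return "mrs3_5"
    return "mrs6"


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of the simulated cohort.

    ``occupancy[k, s]`` is the probability of being in mRS state ``s`` at
    cycle ``k`` (k = 0 .. horizon).  Derived per-cycle event flows needed by
    the accrual stage are carried alongside: the mass that suffered a
    recurrent stroke during the transition into cycle ``k``, split into
    survivors by post-recurrence state and recurrence deaths.
    """

    occupancy: np.ndarray           # (horizon+1, 7)
    age_at_cycle: np.ndarray        # (horizon+1,)
    recurrence_survivors: np.ndarray  # (horizon+1, 6): post-recurrence state mass
    recurrence_deaths: np.ndarray     # (horizon+1,)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cumulative_death(self) -> np.ndarray:
        return self.occupancy[:, DEATH_STATE]

    @property
    def life_years(self) -> float:
        """Undiscounted, half-cycle-corrected life years."""
        alive = 1.0 - self.occupancy[:, DEATH_STATE]
        w = np.ones(len(alive))
        w[0] = w[-1] = 0.5
        return float((alive * w).sum())


@dataclass
class ArmOutcome:
    arm: str
    discounted_cost: float
    cost_drug: float
    cost_hospitalization: float
    cost_post_stroke: float
    discounted_qalys: float
    life_years: float
    trace: CohortTrace


def decision_tree_stage(arm: str, params: ModelParams) -> tuple[MRSDistribution, float, float]:
    """Short-term stage: day-90 distribution, acute cost and first-year QALYs.

    Returns the arm's day-90 mRS distribution (the Markov initial state),
    the acute-phase cost (drug course plus one-time hospitalization cost
    weighted over the day-90 mRS groups), and the first-year QALY accrual
    (one year of day-90-state utility minus the index-stroke disutility for
    survivors), before discounting or half-cycle weighting.
    """
    if arm not in params.arms:
        raise ValueError(f"unknown arm {arm!r}; expected one of {list(params.arms)}")
    armp = params.arms[arm]
    d90 = armp.d90
    hosp = params.costs.hosp_cost_by_group
    hosp_cost = sum(float(d90.p[s]) * hosp[_group_key(s)] for s in range(7))
    acute_cost = armp.drug_cost + hosp_cost
    u = params.utilities.u
    first_year_qalys = float(d90.p[:6] @ u) - d90.alive_mass * params.utilities.stroke_disutility
    return d90, acute_cost, first_year_qalys


def natural_mortality(age: float, params: ModelParams) -> float:
    """Annual all-cause mortality probability from the life table."""
    if age < params.econ.start_age:
        raise ValueError(f"age {age} below model start age {params.econ.start_age}")
    for lo, hi, q in params.mortality.life_table:
        if age >= lo and (hi is None or age <= hi):
            return q
    raise ValueError(f"age {age} not covered by the life table")


def death_probability(age: float, mrs_state: int, params: ModelParams, hr_mode: str = "rate") -> float:
    """Annual death probability for an alive mRS state.

    ``hr_mode="rate"`` applies the hazard ratio on the rate scale,
    ``1 - (1 - q)**HR``; ``"probability"`` uses ``min(q * HR, 1)``.
    """
    if not 0 <= mrs_state <= 5:
        raise ValueError(f"mrs_state {mrs_state} is not an alive state")
    q = natural_mortality(age, params)
    h = float(params.mortality.hr[mrs_state])
    if hr_mode == "rate":
        return 1.0 - (1.0 - q) ** h
    if hr_mode == "probability":
        return min(q * h, 1.0)
    raise ValueError(f"unknown hr_mode {hr_mode!r}")


def recurrence_probability(cycle_index: int, params: ModelParams) -> float:
    """Annual recurrent-stroke probability in Markov year ``cycle_index``."""
    if cycle_index < 1:
        raise ValueError("recurrence is defined from the first Markov year on")
    rp = params.recurrence.annual_recurrence_prob
    if cycle_index <= len(rp):
        return float(rp[cycle_index - 1])
    return params.recurrence.late_recurrence_prob


def build_transition_matrix(cycle_index: int, params: ModelParams, hr_mode: str = "rate") -> np.ndarray:
    """Row-stochastic 7x7 transition matrix for the given Markov year.

    Row = origin state, column = destination.  Death is absorbing.  Event
    ordering within a cycle: death first, recurrence conditional on
    survival, redistribution (or recurrence fatality) conditional on
    recurrence.
    """
    if cycle_index < 1:
        raise ValueError("transitions start at cycle 1")
    age = params.econ.start_age + cycle_index - 1
    r = recurrence_probability(cycle_index, params)
    redis = params.recurrence.redistribution
    fatality = params.recurrence.case_fatality
    m = np.zeros((7, 7))
    for s in range(6):
        p_d = death_probability(age, s, params, hr_mode=hr_mode)
        surv = 1.0 - p_d
        m[s, :6] = surv * r * redis[:, s]
        m[s, s] += surv * (1.0 - r)
        m[s, DEATH_STATE] = p_d + surv * r * fatality[s]
    m[DEATH_STATE, DEATH_STATE] = 1.0
    if np.any(m < -1e-12):
        raise ValueError("negative transition probability; check parameter values")
    np.clip(m, 0.0, None, out=m)
    return m


def run_cohort(arm: str, params: ModelParams, hr_mode: str = "rate") -> CohortTrace:
    """Propagate the day-90 distribution through the full Markov horizon."""
    d90, _, _ = decision_tree_stage(arm, params)
    n = params.econ.horizon_cycles
    occ = np.zeros((n + 1, 7))
    occ[0] = d90.p
    rec_surv = np.zeros((n + 1, 6))
    rec_dead = np.zeros(n + 1)
    redis = params.recurrence.redistribution
    fatality = params.recurrence.case_fatality
    for k in range(1, n + 1):
        m = build_transition_matrix(k, params, hr_mode=hr_mode)
        prev = occ[k - 1]
        occ[k] = prev @ m
        age = params.econ.start_age + k - 1
        r = recurrence_probability(k, params)
        p_d = np.array([death_probability(age, s, params, hr_mode=hr_mode) for s in range(6)])
        entering = prev[:6] * (1.0 - p_d) * r        # recurrence events by pre-state
        rec_surv[k] = redis @ entering
        rec_dead[k] = float(entering @ fatality)
    ages = params.econ.start_age + np.arange(n + 1)
    return CohortTrace(occupancy=occ, age_at_cycle=ages, recurrence_survivors=rec_surv,
                       recurrence_deaths=rec_dead)


def accrue(arm: str, trace: CohortTrace, params: ModelParams, half_cycle: bool = True) -> ArmOutcome:
    """Discounted cost and QALY accrual over a cohort trace.

    Half-cycle correction weights state-membership accruals (utilities,
    stroke-year secondary-prevention costs) by 1/2 at cycle 0 and the final
    cycle.  One-time event costs (drug course, hospitalization per stroke
    event) are charged in full in the cycle of the event.  Secondary-
    prevention ("post-stroke") annual costs are charged in stroke years:
    cycle 0 for all day-90 survivors, and each recurrence year for the mass
    that survived that recurrence, grouped by post-recurrence mRS.
    """
    _, acute_cost, _ = decision_tree_stage(arm, params)
    n = trace.n_cycles
    occ = trace.occupancy
    u = params.utilities.u
    disu = params.utilities.stroke_disutility
    hosp = params.costs.hosp_cost_by_group
    post = params.costs.annual_post_stroke_cost_by_group
    r_out = params.econ.discount_rate_outcome
    r_cost = params.econ.discount_rate_cost

    w = np.ones(n + 1)
    if half_cycle:
        w[0] = w[-1] = 0.5
    d_out = (1.0 + r_out) ** -np.arange(n + 1)
    d_cost = (1.0 + r_cost) ** -np.arange(n + 1)

    mild = list(GROUP_MILD)
    severe = list(GROUP_SEVERE)

    # --- QALYs ---------------------------------------------------------
    state_utility = occ[:, :6] @ u
    rec_surv_mass = trace.recurrence_survivors.sum(axis=1)
    index_disu = np.zeros(n + 1)
    index_disu[0] = (1.0 - occ[0, DEATH_STATE]) * disu
    qalys = float((d_out * w * (state_utility - rec_surv_mass * disu - index_disu)).sum())

    # --- costs ---------------------------------------------------------
    cost_drug = params.arms[arm].drug_cost
    # one-time hospitalization: index event (cycle 0, undiscounted) ...
    cost_hosp = sum(float(occ[0, s]) * hosp[_group_key(s)] for s in range(7))
    # ... plus each recurrent event, by post-recurrence group
    rec_mild = trace.recurrence_survivors[:, mild].sum(axis=1)
    rec_severe = trace.recurrence_survivors[:, severe].sum(axis=1)
    cost_hosp += float(
        (d_cost * (rec_mild * hosp["mrs0_2"] + rec_severe * hosp["mrs3_5"]
                   + trace.recurrence_deaths * hosp["mrs6"])).sum()
    )
    # secondary prevention, charged in stroke years
    post_cycle0 = (occ[0, mild].sum() * post["mrs0_2"] + occ[0, severe].sum() * post["mrs3_5"]) * w[0]
    post_rec = float((d_cost * (rec_mild * post["mrs0_2"] + rec_severe * post["mrs3_5"])).sum())
    cost_post = post_cycle0 + post_rec

    total = cost_drug + cost_hosp + cost_post
    return ArmOutcome(
        arm=arm,
        discounted_cost=total,
        cost_drug=cost_drug,
        cost_hospitalization=cost_hosp,
        cost_post_stroke=cost_post,
        discounted_qalys=qalys,
        life_years=trace.life_years,
        trace=trace,
    )


def run_arm(arm: str, params: ModelParams, hr_mode: str = "rate", half_cycle: bool = True) -> ArmOutcome:
    """Convenience: cohort propagation followed by accrual for one arm."""
    trace = run_cohort(arm, params, hr_mode=hr_mode)
    return accrue(arm, trace, params, half_cycle=half_cycle)


def microsimulate(arm: str, params: ModelParams, n_walkers: int, seed: int,
                  hr_mode: str = "rate") -> np.ndarray:
    """Individual-level Monte Carlo oracle for the cohort trace.

    Simulates ``n_walkers`` independent patients through the same per-cycle
    transition matrices and returns the (horizon+1, 7) occupancy-fraction
    matrix.  Used in tests to cross-check :func:`run_cohort`; it is not a
    production mode.
    """
    rng = np.random.default_rng(seed)
    d90, _, _ = decision_tree_stage(arm, params)
    n = params.econ.horizon_cycles
    states = rng.choice(7, size=n_walkers, p=d90.p / d90.p.sum())
    occ = np.zeros((n + 1, 7))
    occ[0] = np.bincount(states, minlength=7) / n_walkers
    for k in range(1, n + 1):
        m = build_transition_matrix(k, params, hr_mode=hr_mode)
        cum = np.cumsum(m, axis=1)
        draws = rng.random(n_walkers)
        new_states = np.empty_like(states)
        for s in range(7):
            mask = states == s
            if mask.any():
                new_states[mask] = np.searchsorted(cum[s], draws[mask], side="right")
        states = np.minimum(new_states, 6)
        occ[k] = np.bincount(states, minlength=7) / n_walkers
    return occ
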