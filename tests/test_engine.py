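import numpy as np
import pytest

from strokecea.engine import (
    accrue,
    build_transition_matrix,
    death_probability,
    decision_tree_stage,
    microsimulate,
    natural_mortality,
    recurrence_probability,
    run_arm,
    run_cohort,
)


def _no_event_params(params):
    """Variant with (numerically) no mortality and no recurrence."""
    p = params.copy()
    p.mortality.life_table = [(lo, hi, 1e-12) for lo, hi, _ in p.mortality.life_table]
    p.mortality.hr = np.ones(6)
    p.recurrence.annual_recurrence_prob = np.zeros(9)
    p.recurrence.late_recurrence_prob = 0.0
    return p


class TestMortalityLookups:
    @pytest.mark.parametrize("age, q", [(60, 0.0075), (64, 0.0075), (65, 0.0117), (95, 0.1617)])
    def test_band_lookup(self, params, age, q):
        assert natural_mortality(age, params) == pytest.approx(q)

    def test_age_below_model_start_raises(self, params):
        with pytest.raises(ValueError):
            natural_mortality(40, params)

    def test_identity_hazard_recovers_life_table(self, params):
        p = params.copy()
        p.mortality.hr = np.ones(6)
        assert death_probability(60, 3, p) == pytest.approx(0.0075)

    def test_rate_scale_closed_forms(self, params):
        # 1 - (1 - q)^HR stays a probability even where q * HR would not
        assert death_probability(60, 5, params) == pytest.approx(1 - 0.9925 ** 6.55, abs=1e-12)
        p95 = death_probability(95, 5, params)
        assert p95 == pytest.approx(1 - 0.8383 ** 6.55, abs=1e-12)
        assert p95 < 1.0 < 0.1617 * 6.55  # the naive product exceeds 1 here

    def test_probability_mode_is_capped_product(self, params):
        assert death_probability(60, 5, params, hr_mode="probability") == \
            pytest.approx(min(0.0075 * 6.55, 1.0))
        assert death_probability(95, 5, params, hr_mode="probability") == 1.0


class TestRecurrenceSchedule:
    @pytest.mark.parametrize("year, rate", [(1, 0.059), (2, 0.036), (9, 0.028), (10, 0.016), (25, 0.016)])
    def test_year_lookup(self, params, year, rate):
        assert recurrence_probability(year, params) == pytest.approx(rate)

    def test_year_zero_raises(self, params):
        with pytest.raises(ValueError):
            recurrence_probability(0, params)


class TestTransitionMatrix:
    def test_rows_stochastic_across_horizon(self, params):
        for k in range(1, 41):
            m = build_transition_matrix(k, params)
            assert m.sum(axis=1) == pytest.approx(np.ones(7), abs=1e-9)
            assert (m >= 0).all()

    def test_death_is_absorbing(self, params):
        m = build_transition_matrix(1, params)
        assert m[6] == pytest.approx([0, 0, 0, 0, 0, 0, 1])

    def test_no_recurrence_identity_hazard_limit(self, params):
        p = params.copy()
        p.mortality.hr = np.ones(6)
        p.recurrence.annual_recurrence_prob = np.zeros(9)
        p.recurrence.late_recurrence_prob = 0.0
        m = build_transition_matrix(1, p)
        q = natural_mortality(60, p)
        for s in range(6):
            assert m[s, s] == pytest.approx(1 - q)
            assert m[s, 6] == pytest.approx(q)

    def test_recurrence_branch_split_for_mrs2_at_cycle_one(self, params):
        """Recurrence from mRS2 redistributes 49.50/11.88/13.86/6.93 to states
        2..5 with the 17.83% remainder dying of the recurrence."""
        m = build_transition_matrix(1, params)
        pd2 = death_probability(60, 2, params)
        r = recurrence_probability(1, params)
        branch = (1 - pd2) * r
        assert m[2, 3] == pytest.approx(branch * 0.1188)
        assert m[2, 4] == pytest.approx(branch * 0.1386)
        assert m[2, 5] == pytest.approx(branch * 0.0693)
        assert m[2, 2] == pytest.approx(branch * 0.4950 + (1 - pd2) * (1 - r))
        assert m[2, 6] == pytest.approx(pd2 + branch * 0.1783, abs=1e-6)

    def test_no_improvement_transitions(self, params):
        m = build_transition_matrix(1, params)
        for s in range(6):
            assert m[s, :s] == pytest.approx(np.zeros(s), abs=1e-15)


class TestCohortTrace:
    @pytest.mark.parametrize("arm", ["edb", "huk"])
    def test_trace_invariants(self, params, arm):
        t = run_cohort(arm, params)
        assert t.occupancy.sum(axis=1) == pytest.approx(np.ones(41), abs=1e-9)
        assert np.all(np.diff(t.occupancy[:, 6]) >= -1e-12)      # monotone death
        assert np.all(np.diff(t.occupancy[:, 0]) <= 1e-12)       # mRS0 never replenished
        assert t.occupancy[0] == pytest.approx(params.arms[arm].d90.p)

    @pytest.mark.parametrize("arm", ["edb", "huk"])
    def test_cohort_nearly_extinct_at_horizon(self, params, arm):
        t = run_cohort(arm, params)
        assert t.occupancy[-1, 6] > 0.99

    def test_no_event_chain_is_constant(self, params):
        p = _no_event_params(params)
        t = run_cohort("edb", p)
        assert t.occupancy[-1] == pytest.approx(t.occupancy[0], abs=1e-9)

    def test_matches_microsimulation_oracle(self, params):
        occ = microsimulate("edb", params, n_walkers=200_000, seed=11)
        t = run_cohort("edb", params)
        assert np.abs(occ - t.occupancy).max() < 0.005


class TestDecisionTree:
    def test_drug_cost_components(self, params):
        _, acute_huk, _ = decision_tree_stage("huk", params)
        hosp = params.costs.hosp_cost_by_group
        d = params.arms["huk"].d90.p
        hosp_part = (d[:3].sum() * hosp["mrs0_2"] + d[3:6].sum() * hosp["mrs3_5"]
                     + d[6] * hosp["mrs6"])
        assert acute_huk == pytest.approx(2100.0 + hosp_part)

    def test_edb_hospitalization_weighted_sum(self, params):
        _, acute, _ = decision_tree_stage("edb", params)
        assert acute - 2772.0 == pytest.approx(0.728 * 12614 + 0.272 * 17223, abs=0.5)

    def test_all_dead_cohort_accrues_nothing(self, params):
        p = params.copy()
        p.arms["edb"].d90.p = np.array([0, 0, 0, 0, 0, 0, 1.0])
        _, _, q1 = decision_tree_stage("edb", p)
        assert q1 == pytest.approx(0.0)

    def test_unknown_arm_raises(self, params):
        with pytest.raises(ValueError, match="unknown arm"):
            decision_tree_stage("placebo", params)


class TestAccrual:
    def test_discounting_monotone(self, params):
        base = run_arm("edb", params)
        p0 = params.copy()
        p0.econ.discount_rate_cost = 0.0
        p0.econ.discount_rate_outcome = 0.0
        undisc = run_arm("edb", p0)
        assert undisc.discounted_qalys > base.discounted_qalys
        assert undisc.discounted_cost > base.discounted_cost

    def test_zero_discount_recovers_raw_sums(self, params):
        p0 = params.copy()
        p0.econ.discount_rate_cost = 0.0
        p0.econ.discount_rate_outcome = 0.0
        out = run_arm("edb", p0)
        t = out.trace
        w = np.ones(41)
        w[0] = w[-1] = 0.5
        su = t.occupancy[:, :6] @ p0.utilities.u
        disu = p0.utilities.stroke_disutility
        raw = (w * su).sum() - w[0] * (1 - t.occupancy[0, 6]) * disu \
            - (w * t.recurrence_survivors.sum(axis=1) * disu).sum()
        assert out.discounted_qalys == pytest.approx(raw)

    def test_components_sum_to_total(self, params):
        out = run_arm("edb", params)
        assert out.cost_drug + out.cost_hospitalization + out.cost_post_stroke == \
            pytest.approx(out.discounted_cost)

    def test_no_treatment_difference_limit(self, params):
        """Identical day-90 distributions leave only the drug-cost gap."""
        p = params.copy()
        p.arms["huk"].d90.p = p.arms["edb"].d90.p.copy()
        e = run_arm("edb", p)
        h = run_arm("huk", p)
        assert e.discounted_qalys == pytest.approx(h.discounted_qalys, abs=1e-12)
        assert e.discounted_cost - h.discounted_cost == pytest.approx(2772.0 - 2100.0)

    def test_life_years_fall_when_any_hazard_rises(self, params):
        base = run_arm("edb", params)
        for s in range(6):
            p = params.copy()
            p.mortality.hr[s] *= 1.5
            worse = run_arm("edb", p)
            assert worse.life_years < base.life_years

    def test_half_cycle_correction_reduces_accrual(self, params):
        full = accrue("edb", run_cohort("edb", params), params, half_cycle=False)
        half = run_arm("edb", params)
        assert half.discounted_qalys < full.discounted_qalys
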