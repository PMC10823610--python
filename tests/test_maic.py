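import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from strokecea.maic import (
    AggregateTarget,
    MAICError,
    effective_sample_size,
    fit_maic_weights,
    prepare_matching_matrix,
    run_maic,
    weighted_outcome_distribution,
)
from strokecea.synthetic import IPDGeneratorSpec, generate_ipd, huk_aggregate_targets


class TestPrepareMatchingMatrix:
    def test_proportion_target_centers_column(self):
        ipd = pd.DataFrame({"male": [1, 1, 0, 1]})
        z, names = prepare_matching_matrix(ipd, [AggregateTarget("male", "proportion", 0.6805)])
        assert names == ["male"]
        assert z[:, 0] == pytest.approx(np.array([1, 1, 0, 1]) - 0.6805)

    def test_covariate_already_on_target_has_zero_mean(self):
        ipd = pd.DataFrame({"x": [1.0, 3.0]})
        z, _ = prepare_matching_matrix(ipd, [AggregateTarget("x", "mean", 2.0)])
        assert z.mean() == pytest.approx(0.0)

    def test_median_target_uses_below_indicator(self):
        ipd = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        z, _ = prepare_matching_matrix(ipd, [AggregateTarget("x", "median", 2.5)])
        assert z[:, 0] == pytest.approx([0.5, 0.5, -0.5, -0.5])

    def test_absent_covariate_raises(self):
        with pytest.raises(MAICError, match="not found"):
            prepare_matching_matrix(pd.DataFrame({"a": [1]}), [AggregateTarget("b", "mean", 0)])

    def test_constant_off_target_covariate_raises(self):
        ipd = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(MAICError, match="unmatchable"):
            prepare_matching_matrix(ipd, [AggregateTarget("x", "mean", 5.0)])


class TestFitWeights:
    def test_targets_at_sample_means_give_uniform_weights(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3))
        z = x - x.mean(axis=0)
        w, b = fit_maic_weights(z)
        assert b == pytest.approx(np.zeros(3), abs=1e-6)
        assert w == pytest.approx(np.ones(40), abs=1e-6)

    def test_two_patient_closed_form(self):
        """Matching a mean of 0.75 on {0, 1} forces a 3:1 weight ratio."""
        z = np.array([[0.0], [1.0]]) - 0.75
        w, _ = fit_maic_weights(z)
        assert w[1] / w[0] == pytest.approx(3.0, rel=1e-8)

    def test_matches_derivative_free_optimizer(self):
        """The Newton solution agrees with an independent minimisation of
        Q(b) = sum exp(z.b) on a small instance."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 2))
        z = x - x.mean(axis=0) + np.array([0.15, -0.1])
        _, b = fit_maic_weights(z)
        obj = lambda bb: np.exp(z @ bb).sum()
        ref = minimize(obj, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        assert b == pytest.approx(ref.x, abs=1e-6)

    def test_separation_is_diagnosed(self):
        # target beyond the support of a binary covariate: unattainable moment
        z = (np.array([[0.0]] * 10 + [[1.0]] * 10)) - 1.5
        with pytest.raises(MAICError):
            fit_maic_weights(z)

    def test_all_thirteen_moments_match_on_synthetic_ipd(self, ipd):
        res = run_maic(ipd, huk_aggregate_targets())
        assert res.balance["gap"].abs().max() < 1e-6
        assert (res.weights >= 0).all()
        assert res.weights.mean() == pytest.approx(1.0)
        assert res.ess <= len(ipd)


class TestESS:
    @pytest.mark.parametrize("weights, expected", [
        (np.ones(10), 10.0),
        (np.array([1.0, 0.0, 0.0, 0.0]), 1.0),
        (np.array([0.5, 1.5]), 1.6),
    ])
    def test_known_values(self, weights, expected):
        assert effective_sample_size(weights) == pytest.approx(expected)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.zeros(5))

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_by_n_with_equality_iff_uniform(self, ws):
        w = np.asarray(ws)
        if w.sum() == 0:
            return
        ess = effective_sample_size(w)
        assert ess <= len(w) + 1e-9
        positive = w[w > 0]
        if len(positive) == len(w) and np.allclose(w, w[0]):
            assert ess == pytest.approx(len(w))


class TestWeightedOutcome:
    def test_uniform_weights_recover_empirical_distribution(self, ipd):
        d = weighted_outcome_distribution(ipd, np.ones(len(ipd)))
        emp = np.bincount(ipd["mrs_d90"], minlength=7) / len(ipd)
        assert d.p == pytest.approx(emp)

    def test_single_patient_concentration(self, ipd):
        w = np.zeros(len(ipd))
        w[5] = 1.0
        d = weighted_outcome_distribution(ipd, w)
        assert d.p[ipd["mrs_d90"].iloc[5]] == pytest.approx(1.0)

    def test_length_mismatch_raises(self, ipd):
        with pytest.raises(ValueError):
            weighted_outcome_distribution(ipd, np.ones(3))

    def test_reweighting_toward_worse_covariates_shifts_outcome_worse(self, ipd):
        """The comparator trial's higher NIHSS/diabetes burden must pull the
        reweighted day-90 distribution toward higher mRS."""
        res = run_maic(ipd, huk_aggregate_targets())
        unweighted = weighted_outcome_distribution(ipd, np.ones(len(ipd)))
        # brute-force oracle: expected mRS must increase under the weights
        mean_w = (res.weighted_outcome.p * np.arange(7)).sum()
        mean_u = (unweighted.p * np.arange(7)).sum()
        assert mean_w > mean_u

    def test_reweighting_to_own_means_is_a_noop(self, ipd):
        targets = []
        for t in huk_aggregate_targets():
            x = ipd[t.covariate].to_numpy(dtype=float)
            if t.kind == "median":
                targets.append(AggregateTarget(t.covariate, "median", float(np.median(x))))
            else:
                targets.append(AggregateTarget(t.covariate, t.kind, float(x.mean())))
        # medians of discrete covariates may not split the sample exactly in
        # half; match the continuous ones only for a clean identity check
        targets = [t for t in targets if t.kind != "median"]
        res = run_maic(ipd, targets)
        unweighted = weighted_outcome_distribution(ipd, np.ones(len(ipd)))
        assert res.weighted_outcome.p == pytest.approx(unweighted.p, abs=1e-9)
        assert res.ess == pytest.approx(len(ipd), rel=1e-6)
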