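"""Semi-Markov engine oracles: closed forms, engine agreement, reweighting."""

import numpy as np
import pandas as pd
import pytest

from cpfextrap.semimarkov import (
    WEEKS_PER_MONTH,
    TransitionModel,
    bias_adjust,
    remission_table,
    simulate_cohort,
    solve_renewal,
)

from conftest import exponential_fit, make_fit


def _exp_model(rate_rem=0.1, rate_rel=0.1, lead_in=0.0):
    return TransitionModel(
        to_remission=exponential_fit(rate_rem, lead_in),
        to_relapse=exponential_fit(rate_rel),
        lead_in_weeks=lead_in,
    )


class TestClosedFormOracle:
    def test_month_zero_remission_is_zero(self):
        tr = simulate_cohort(_exp_model(), n_sim=500, horizon_months=12, seed=1)
        assert tr.proportion_remission[0] == 0.0

    def test_two_state_markov_closed_form_microsim(self):
        """lambda = mu = 0.1/week: p_R(t) = 0.5 (1 - e^{-0.2 t})."""
        tr = simulate_cohort(_exp_model(), n_sim=20000, horizon_months=48, seed=2)
        tw = tr.months * WEEKS_PER_MONTH
        closed = 0.5 * (1 - np.exp(-0.2 * tw))
        se = np.sqrt(np.maximum(closed * (1 - closed), 1e-12) / 20000)
        assert np.all(np.abs(tr.proportion_remission - closed) <= 3 * se + 1e-9)

    def test_two_state_markov_closed_form_renewal(self):
        tr = solve_renewal(_exp_model(), horizon_months=48, grid_step=0.25)
        tw = tr.months * WEEKS_PER_MONTH
        closed = 0.5 * (1 - np.exp(-0.2 * tw))
        assert np.max(np.abs(tr.proportion_remission - closed)) < 5e-4

    def test_absorbing_remission_equals_one_minus_survival(self):
        """Relapse hazard ~ 0: occupancy converges to 1 - S_remission(t)."""
        model = TransitionModel(
            to_remission=exponential_fit(0.05),
            to_relapse=exponential_fit(1e-9),
        )
        tr = simulate_cohort(model, n_sim=20000, horizon_months=24, seed=3)
        tw = tr.months * WEEKS_PER_MONTH
        target = 1 - np.exp(-0.05 * tw)
        se = np.sqrt(np.maximum(target * (1 - target), 1e-12) / 20000)
        assert np.all(np.abs(tr.proportion_remission - target) <= 4 * se + 1e-9)

    def test_renewal_degenerate_relapse_identical_to_remission_cdf(self):
        model = TransitionModel(
            to_remission=exponential_fit(0.05),
            to_relapse=exponential_fit(1e-12),
        )
        tr = solve_renewal(model, horizon_months=24, grid_step=0.25)
        tw = tr.months * WEEKS_PER_MONTH
        np.testing.assert_allclose(tr.proportion_remission, 1 - np.exp(-0.05 * tw), atol=1e-3)


class TestEngineAgreement:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_microsim_and_renewal_agree(self, seed):
        rng = np.random.default_rng(seed)
        fam = rng.choice(["weibull", "loglogistic", "lognormal"])
        rem = make_fit(fam, {"intercept": rng.uniform(2.5, 4.0)},
                       {"intercept": rng.uniform(-0.3, 0.4)})
        rel = make_fit("weibull", {"intercept": rng.uniform(3.0, 4.5)},
                       {"intercept": rng.uniform(-0.3, 0.3)})
        model = TransitionModel(rem, rel, lead_in_weeks=4.0)
        n = 30000
        sim = simulate_cohort(model, n_sim=n, horizon_months=36, seed=seed + 100)
        det = solve_renewal(model, horizon_months=36, grid_step=0.25)
        p = det.proportion_remission
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        assert np.all(np.abs(sim.proportion_remission - p) <= 3 * se + 2e-3)


class TestLeadIn:
    def test_no_remission_before_lead_in(self):
        model = _exp_model(rate_rem=0.5, lead_in=4.0)
        tr = solve_renewal(model, horizon_months=6, grid_step=0.25)
        tw = tr.months * WEEKS_PER_MONTH
        assert np.all(tr.proportion_remission[tw < 4.0] == 0.0)
        assert tr.proportion_remission[-1] > 0.1


class TestStochasticOrdering:
    def test_faster_remission_never_hurts_occupancy(self):
        slow = _exp_model(rate_rem=0.05)
        fast = _exp_model(rate_rem=0.10)
        t_slow = solve_renewal(slow, horizon_months=48, grid_step=0.5)
        t_fast = solve_renewal(fast, horizon_months=48, grid_step=0.5)
        assert np.all(t_fast.proportion_remission >= t_slow.proportion_remission - 1e-9)


class TestCovariates:
    def test_population_mixture_matches_weighted_profiles(self):
        rem = make_fit("weibull", {"intercept": 3.0, "x": 0.8}, {"intercept": 0.0},
                       loc_cov=("x",))
        rel = make_fit("weibull", {"intercept": 3.5}, {"intercept": 0.0})
        table = pd.DataFrame({"x": [-1.0, 1.0]})
        model = TransitionModel(rem, rel, covariate_table=table)
        mix = solve_renewal(model, horizon_months=24, grid_step=0.25)
        singles = []
        for x in (-1.0, 1.0):
            m = TransitionModel(rem, rel, covariate_table=pd.DataFrame({"x": [x]}))
            singles.append(solve_renewal(m, horizon_months=24, grid_step=0.25).proportion_remission)
        np.testing.assert_allclose(mix.proportion_remission, np.mean(singles, axis=0), atol=1e-10)


class TestBiasAdjust:
    def test_identical_tables_give_uniform_weights(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]})
        out = bias_adjust(t, t.copy())
        np.testing.assert_allclose(out["weight"], 1 / 3, atol=1e-9)

    def test_weighted_means_match_reference(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame({"a": rng.normal(0, 1, 200), "b": rng.binomial(1, 0.4, 200).astype(float)})
        ref = pd.DataFrame({"a": rng.normal(0.3, 1, 100), "b": rng.binomial(1, 0.6, 100).astype(float)})
        out = bias_adjust(t, ref, ["a", "b"])
        w = out["weight"].to_numpy()
        assert abs(np.sum(w * t["a"]) - ref["a"].mean()) < 1e-6
        assert abs(np.sum(w * t["b"]) - ref["b"].mean()) < 1e-6

    def test_infeasible_targets_listed(self):
        t = pd.DataFrame({"a": [0.0, 1.0]})
        ref = pd.DataFrame({"a": [5.0]})
        with pytest.raises(ValueError, match="a"):
            bias_adjust(t, ref, ["a"])

    def test_reweighted_trace_matches_resampled_population(self):
        """Weights in the microsim equal explicit resampling of the table."""
        rem = make_fit("weibull", {"intercept": 3.0, "x": 0.6}, {"intercept": 0.0},
                       loc_cov=("x",))
        rel = make_fit("weibull", {"intercept": 3.5}, {"intercept": 0.0})
        table = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
        w = np.array([0.6, 0.3, 0.1])
        model_w = TransitionModel(rem, rel, covariate_table=table, weights=w)
        det_w = solve_renewal(model_w, horizon_months=24, grid_step=0.5)
        # explicit mixture
        singles = []
        for x in table["x"]:
            m = TransitionModel(rem, rel, covariate_table=pd.DataFrame({"x": [x]}))
            singles.append(solve_renewal(m, horizon_months=24, grid_step=0.5).proportion_remission)
        np.testing.assert_allclose(det_w.proportion_remission,
                                   np.tensordot(w, np.array(singles), axes=1), atol=1e-10)


class TestReporting:
    def test_partition_of_unity_and_table(self):
        tr = simulate_cohort(_exp_model(), n_sim=5000, horizon_months=48, seed=5)
        np.testing.assert_allclose(tr.proportion_remission + tr.proportion_csf, 1.0)
        table = remission_table({"DVS": tr, "SOC": tr}, months=(0, 8, 24, 48))
        assert list(table["month"]) == [0, 8, 24, 48]
        np.testing.assert_allclose(table["difference_pct"], 0.0)

    def test_month_beyond_horizon_rejected(self):
        tr = simulate_cohort(_exp_model(), n_sim=100, horizon_months=12, seed=6)
        with pytest.raises(ValueError, match="beyond"):
            remission_table({"DVS": tr}, months=(24,))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_cohort(_exp_model(), n_sim=0, horizon_months=12, seed=1)
        with pytest.raises(ValueError):
            simulate_cohort(_exp_model(), n_sim=10, horizon_months=0, seed=1)
        with pytest.raises(ValueError):
            solve_renewal(_exp_model(), horizon_months=12, grid_step=2.0)
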