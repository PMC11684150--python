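"""Likelihood exactness, MLE recovery, model comparison, curve prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import cpfextrap as cx
from cpfextrap import FamilySpec, compare_models, fit_mle, log_likelihood, predict_curve
from cpfextrap.families import get_family


def _simulate(family, n, rng, beta, gamma, q=None, cens_scale=60.0, x=None):
    fam = get_family(family)
    if x is None:
        x = rng.normal(size=n)
    mu = beta[0] + beta[1] * x if len(beta) > 1 else np.full(n, beta[0])
    eta = gamma[0] + (gamma[1] * x if len(gamma) > 1 else 0.0)
    a0 = np.exp(eta) if fam.anc_links[0] == "log" else eta
    anc = (np.broadcast_to(a0, (n,)),) if fam.n_anc == 1 else (
        np.broadcast_to(a0, (n,)), np.full(n, q))
    t = fam.sample(rng.uniform(size=n), mu, anc)
    c = rng.exponential(cens_scale, n)
    obs = np.minimum(t, c)
    d = (t <= c).astype(int)
    return pd.DataFrame({"time": obs, "event": d, "x": x})


class TestLogLikelihood:
    def test_censored_only_is_sum_log_survival(self):
        df = pd.DataFrame({"time": [2.0, 5.0, 9.0], "event": [0, 0, 0]})
        spec = FamilySpec("weibull")
        ll = log_likelihood(df, spec, [np.log(10.0)], [0.0])
        expected = np.sum(-(df["time"] / 10.0) ** 1.0)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_exponential_single_observation_closed_form(self):
        """Weibull with shape 1, rate 0.5, one event at t=2: log(0.5) - 1."""
        df = pd.DataFrame({"time": [2.0], "event": [1]})
        ll = log_likelihood(df, FamilySpec("weibull"), [np.log(2.0)], [0.0])
        assert ll == pytest.approx(np.log(0.5) - 1.0, abs=1e-12)

    def test_zero_time_rejected_with_sample_name(self):
        df = pd.DataFrame({"time": [0.0], "event": [1]})
        with pytest.raises(ValueError, match="lead-in"):
            log_likelihood(df, FamilySpec("weibull"), [1.0], [0.0])

    @pytest.mark.parametrize("family", ["weibull", "gompertz", "loglogistic", "lognormal", "gengamma"])
    def test_matches_per_term_hazard_survival_decomposition(self, family):
        """d*log h + log S per observation, against independently evaluated
        h = f/S with S from quadrature of the density."""
        from scipy.integrate import quad

        rng = np.random.default_rng(13)
        fam = get_family(family)
        for _ in range(3):
            mu = rng.uniform(1.0, 3.0)
            if family == "gompertz":
                anc_val = (rng.uniform(0.0, 0.05),)
                q = None
            elif family == "gengamma":
                anc_val = (rng.uniform(0.5, 1.2),)
                q = rng.uniform(-1.0, 1.5)
            else:
                anc_val = (rng.uniform(0.6, 1.8),)
                q = None

            def pdf(u):
                uu = np.array([u])
                anc = (np.full(1, anc_val[0]),) if fam.n_anc == 1 else (
                    np.full(1, anc_val[0]), np.full(1, q))
                return float(np.exp(fam.log_hazard(uu, mu, anc) + fam.log_surv(uu, mu, anc))[0])

            anc_full = (np.full(1, anc_val[0]),) if fam.n_anc == 1 else (
                np.full(1, anc_val[0]), np.full(1, q))
            t0 = float(fam.sample(np.array([0.5]), mu, anc_full)[0])  # median
            t_hi = float(fam.sample(np.array([1e-13]), mu, anc_full)[0])
            # integrate in log-time between the median and the 1e-13
            # survival quantile (finite for every family/parameter draw)
            S_quad, _ = quad(lambda y: pdf(np.exp(y)) * np.exp(y), np.log(t0), np.log(t_hi),
                             epsabs=1e-13, limit=500)
            f0 = pdf(t0)
            df = pd.DataFrame({"time": [t0], "event": [1]})
            eta = np.log(anc_val[0]) if fam.anc_links[0] == "log" else anc_val[0]
            ll = log_likelihood(df, FamilySpec(family), [mu], [eta], q=q)
            oracle = np.log(f0 / S_quad) + np.log(S_quad)
            assert ll == pytest.approx(oracle, abs=1e-8)


class TestFitMLE:
    def test_exponential_rate_mle_is_events_over_time(self):
        """With the shape pinned to 1 (exponential), the profile MLE of the
        rate is events / total time — checked by 1-d optimization of the
        model's own likelihood."""
        rng = np.random.default_rng(3)
        t = rng.exponential(8.0, 400)
        c = rng.exponential(20.0, 400)
        df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)})
        spec = FamilySpec("weibull")

        res = minimize_scalar(
            lambda mu: -log_likelihood(df, spec, [mu], [0.0]), bounds=(-3, 6), method="bounded",
            options={"xatol": 1e-10},
        )
        rate_hat = np.exp(-res.x)
        assert rate_hat == pytest.approx(df["event"].sum() / df["time"].sum(), rel=1e-6)

    def test_weibull_location_and_shape_recovery(self):
        rng = np.random.default_rng(7)
        df = _simulate("weibull", 2000, rng, beta=[3.0, 0.5], gamma=[0.2, -0.3])
        fit = fit_mle(df, FamilySpec("weibull", ("x",), ("x",)))
        assert fit.converged
        se = fit.se
        assert abs(fit.beta["intercept"] - 3.0) < 3 * se["mu.intercept"]
        assert abs(fit.beta["x"] - 0.5) < 3 * se["mu.x"]
        assert abs(fit.gamma_shape["intercept"] - 0.2) < 3 * se["shape.intercept"]
        assert abs(fit.gamma_shape["x"] + 0.3) < 3 * se["shape.x"]

    def test_deterministic_given_same_data(self):
        rng = np.random.default_rng(8)
        df = _simulate("loglogistic", 300, rng, beta=[2.5], gamma=[0.3])
        f1 = fit_mle(df, FamilySpec("loglogistic"))
        f2 = fit_mle(df, FamilySpec("loglogistic"))
        assert f1.beta == f2.beta and f1.loglik == f2.loglik

    def test_matches_r_flexsurv_on_small_fixture(self, tmp_path):
        """Independent cross-check: same Weibull AFT fit in R's flexsurv."""
        import subprocess

        rng = np.random.default_rng(15)
        df = _simulate("weibull", 200, rng, beta=[3.0, 0.4], gamma=[0.1])
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(flexsurv))
            d <- read.csv("{csv}")
            f <- flexsurvreg(Surv(time, event) ~ x, data = d, dist = "weibullPH")
            g <- flexsurvreg(Surv(time, event) ~ x, data = d, dist = "weibull")
            cat(coef(g)[["scale"]], coef(g)[["x"]], log(f$res[["shape","est"]]), f$loglik, sep = ",")
            """
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        mu_r, beta_x_r, log_shape_r, loglik_r = map(float, out.stdout.strip().split(","))
        fit = fit_mle(df, FamilySpec("weibull", ("x",)))
        assert fit.beta["intercept"] == pytest.approx(mu_r, abs=1e-3)
        assert fit.beta["x"] == pytest.approx(beta_x_r, abs=1e-3)
        assert fit.gamma_shape["intercept"] == pytest.approx(log_shape_r, abs=1e-3)
        assert fit.loglik == pytest.approx(loglik_r, abs=1e-4)

    def test_aic_bic_identities(self):
        rng = np.random.default_rng(10)
        df = _simulate("lognormal", 150, rng, beta=[2.0], gamma=[0.0])
        fit = fit_mle(df, FamilySpec("lognormal"))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-10)
        assert fit.bic == pytest.approx(-2 * fit.loglik + fit.k * np.log(fit.n), abs=1e-10)


class TestCompareModels:
    def test_sorted_by_aic_with_delta(self):
        rng = np.random.default_rng(11)
        df = _simulate("weibull", 400, rng, beta=[3.0], gamma=[0.5])
        fits = [fit_mle(df, FamilySpec(f)) for f in ("weibull", "lognormal", "gompertz")]
        table = compare_models(fits)
        assert list(table["aic"]) == sorted(table["aic"])
        assert table["delta_aic"].iloc[0] == 0.0

    def test_mixed_datasets_rejected(self):
        rng = np.random.default_rng(12)
        d1 = _simulate("weibull", 100, rng, beta=[3.0], gamma=[0.0])
        d2 = _simulate("weibull", 120, rng, beta=[3.0], gamma=[0.0])
        with pytest.raises(ValueError, match="same samples"):
            compare_models([fit_mle(d1, FamilySpec("weibull")), fit_mle(d2, FamilySpec("weibull"))])


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(14)
    df = _simulate("weibull", 500, rng, beta=[3.0, 0.5], gamma=[0.2])
    df.attrs["lead_in_weeks"] = 4.0
    return fit_mle(df, FamilySpec("weibull", ("x",)))


class TestPredictCurve:

    def test_horizon_zero_single_unit_point(self, fit):
        curve = predict_curve(fit, {"x": 0.0}, horizon_weeks=0.0)
        assert len(curve) == 1 and curve["survival"].iloc[0] == 1.0

    def test_lead_in_plateau(self, fit):
        curve = predict_curve(fit, {"x": 0.0}, horizon_weeks=30.0)
        assert (curve.loc[curve["week"] <= 4.0, "survival"] == 1.0).all()
        assert curve["survival"].iloc[-1] < 1.0

    def test_one_row_average_equals_single_profile(self, fit):
        single = predict_curve(fit, {"x": 0.7}, 20.0)
        table = predict_curve(fit, pd.DataFrame([{"x": 0.7}]), 20.0)
        np.testing.assert_array_equal(single["survival"], table["survival"])

    def test_population_average_is_mean_of_per_row_curves(self, fit):
        rows = pd.DataFrame({"x": [-1.0, 0.0, 0.5, 2.0]})
        pop = predict_curve(fit, rows, 40.0)
        per_row = np.mean(
            [predict_curve(fit, {"x": v}, 40.0)["survival"].to_numpy() for v in rows["x"]], axis=0
        )
        np.testing.assert_allclose(pop["survival"], per_row, atol=1e-12)

    def test_missing_covariate_rejected(self, fit):
        with pytest.raises(ValueError, match="x"):
            predict_curve(fit, {"y": 1.0}, 10.0)
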