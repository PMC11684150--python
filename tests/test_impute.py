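"""Hierarchical multiple imputation: identity, recovery, and variability."""

import numpy as np
import pytest

from cpfextrap import (
    CohortConfig,
    fit_imputation_model,
    generate_cohort,
    impute,
    inject_missingness,
)
from cpfextrap.records import records_to_frames


def _clean_cohort(n_rwe=2000, seed=31):
    cfg = CohortConfig(n_trial=200, n_rwe=n_rwe, n_trial_unassessed=0,
                       n_rwe_unassessed=0, trial_dvs_retained=100,
                       missingness={}, seed=seed)
    return generate_cohort(cfg)


def _pain_dist(records, study="RWE"):
    counts = np.zeros(4)
    for r in records:
        if r.study != study:
            continue
        for v in r.visits:
            if v.eo_all_closed is not None and v.pdai_pain is not None:
                counts[v.pdai_pain] += 1
    return counts / counts.sum()


class TestIdentity:
    def test_no_missing_data_returns_input_unchanged(self):
        recs = _clean_cohort(n_rwe=100)
        model = fit_imputation_model(recs)
        res = impute(model, recs, m=3, seed=1)
        b0, v0 = records_to_frames(recs)
        for comp in res.completed:
            b1, v1 = records_to_frames(comp)
            assert b0.equals(b1) and v0.equals(v1)

    def test_m_below_one_rejected(self):
        recs = _clean_cohort(n_rwe=50)
        model = fit_imputation_model(recs)
        with pytest.raises(ValueError):
            impute(model, recs, m=0, seed=1)

    def test_entirely_missing_variable_rejected(self):
        recs = _clean_cohort(n_rwe=50)
        for r in recs:
            r.covariates["weight"] = None
        with pytest.raises(ValueError, match="weight"):
            fit_imputation_model(recs, target_variables=["weight"])


class TestRecovery:
    def test_binary_covariate_mcar_recovery(self):
        """30% MCAR on a binary covariate: pooled imputed prevalence within
        0.05 of the complete-data prevalence (n = 2000, m = 20)."""
        recs = _clean_cohort()
        rwe = [r for r in recs if r.study == "RWE"]
        truth = np.mean([r.covariates["prior_biologic"] for r in rwe])
        masked = inject_missingness(recs, {"prior_biologic": {"RWE": 0.30}}, seed=5)
        model = fit_imputation_model(masked)
        res = impute(model, masked, m=20, seed=6)
        prev = np.mean([
            np.mean([r.covariates["prior_biologic"] for r in comp if r.study == "RWE"])
            for comp in res.completed
        ])
        assert abs(prev - truth) < 0.05

    def test_pdai_category_recovery_at_heavy_missingness(self):
        """73.5% MCAR on RWE PDAI pain: every imputed category proportion
        within 0.05 of the complete-data distribution."""
        recs = _clean_cohort(seed=32)
        truth = _pain_dist(recs)
        masked = inject_missingness(recs, {"pdai_pain": {"RWE": 0.735}}, seed=7)
        model = fit_imputation_model(masked)
        res = impute(model, masked, m=10, seed=8)
        dists = np.array([_pain_dist(comp) for comp in res.completed])
        assert np.all(np.abs(dists.mean(axis=0) - truth) < 0.05)

    def test_observed_values_identical_across_completions(self):
        recs = _clean_cohort(n_rwe=300, seed=33)
        masked = inject_missingness(recs, {"weight": {"RWE": 0.4}}, seed=9)
        model = fit_imputation_model(masked)
        res = impute(model, masked, m=4, seed=10)
        for orig in masked:
            if orig.covariates["weight"] is None:
                continue
            for comp in res.completed:
                match = next(r for r in comp if r.patient_id == orig.patient_id)
                assert match.covariates["weight"] == orig.covariates["weight"]

    def test_between_imputation_variance_positive(self):
        recs = _clean_cohort(n_rwe=300, seed=34)
        masked = inject_missingness(recs, {"weight": {"RWE": 0.4}}, seed=11)
        model = fit_imputation_model(masked)
        res = impute(model, masked, m=8, seed=12)
        means = [
            np.mean([r.covariates["weight"] for r in comp if r.study == "RWE"])
            for comp in res.completed
        ]
        assert np.var(means, ddof=1) > 0

    def test_no_missing_left_in_targets(self):
        recs = generate_cohort(CohortConfig(n_trial=100, n_rwe=150,
                                            n_trial_unassessed=0, n_rwe_unassessed=0,
                                            trial_dvs_retained=50, seed=35))
        model = fit_imputation_model(recs)
        res = impute(model, recs, m=2, seed=13)
        for comp in res.completed:
            for r in comp:
                for var in model.targets:
                    if var in ("pdai_pain", "pdai_discharge"):
                        for v in r.visits:
                            if v.eo_all_closed is not None:
                                assert getattr(v, var) is not None
                    else:
                        assert r.covariates.get(var) is not None

    def test_downstream_fit_coefficients_recovered_under_mcar(self):
        """20% MCAR on a fit covariate: Weibull coefficients pooled over
        completions stay within Monte-Carlo error of the complete-data fit."""
        from cpfextrap import FamilySpec, derive_remission, fit_mle

        recs = _clean_cohort(seed=37)
        complete = fit_mle(
            derive_remission(recs, "cpc"),
            FamilySpec("weibull", ("luminal_active", "age_c")),
        )
        masked = inject_missingness(recs, {"luminal_severity": {"TRIAL": 0.2, "RWE": 0.2}}, seed=16)
        model = fit_imputation_model(masked)
        res = impute(model, masked, m=10, seed=17)
        pooled = {}
        for comp in res.completed:
            f = fit_mle(derive_remission(comp, "cpc"),
                        FamilySpec("weibull", ("luminal_active", "age_c")))
            for k, v in f.beta.items():
                pooled.setdefault(k, []).append(v)
        for k, se in complete.se.items():
            if not k.startswith("mu."):
                continue
            name = k.removeprefix("mu.")
            assert abs(np.mean(pooled[name]) - complete.beta[name]) < 3 * se, k

    def test_reproducible_given_seed(self):
        recs = _clean_cohort(n_rwe=200, seed=36)
        masked = inject_missingness(recs, {"weight": {"RWE": 0.3}}, seed=14)
        model = fit_imputation_model(masked)
        r1 = impute(model, masked, m=2, seed=15)
        r2 = impute(model, masked, m=2, seed=15)
        for c1, c2 in zip(r1.completed, r2.completed):
            b1, v1 = records_to_frames(c1)
            b2, v2 = records_to_frames(c2)
            assert b1.equals(b2) and v1.equals(v2)
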