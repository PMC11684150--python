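"""Synthetic registry generator: determinism, counts, oracles, missingness."""

import numpy as np
import pytest

from cpfextrap import CohortConfig, generate_cohort, inject_missingness, km_estimate
from cpfextrap.events import derive_remission
from cpfextrap.records import records_to_frames

from conftest import flat_true_models


def test_deterministic_under_fixed_seed():
    cfg = CohortConfig(n_trial=60, n_rwe=40, n_trial_unassessed=4, n_rwe_unassessed=3,
                       trial_dvs_retained=30, seed=42)
    b1, v1 = records_to_frames(generate_cohort(cfg))
    b2, v2 = records_to_frames(generate_cohort(CohortConfig(
        n_trial=60, n_rwe=40, n_trial_unassessed=4, n_rwe_unassessed=3,
        trial_dvs_retained=30, seed=42)))
    assert b1.equals(b2) and v1.equals(v2)


def test_record_counts_match_config(default_cohort):
    assert len(default_cohort) == 212 + 386
    trial = [r for r in default_cohort if r.study == "TRIAL"]
    rwe = [r for r in default_cohort if r.study == "RWE"]
    assert len(trial) == 212 and len(rwe) == 386


@pytest.mark.parametrize(
    "field, value",
    [("n_trial", 0), ("lead_in_weeks", -1.0), ("n_trial_unassessed", 500)],
)
def test_invalid_config_raises_naming_field(field, value):
    cfg = CohortConfig(**{field: value})
    with pytest.raises(ValueError, match=field):
        cfg.validate()


def test_unknown_outcome_in_true_models_rejected():
    cfg = CohortConfig(true_models={"NOT_AN_OUTCOME": {}})
    with pytest.raises(ValueError, match="NOT_AN_OUTCOME"):
        cfg.validate()


def test_exponential_truth_km_median_oracle():
    """Constant hazard 0.05/week, dense twice-weekly visits: the KM median of
    the derived remission times sits within 5% of log(2)/0.05 ~ 13.9 weeks.

    (The assessment grid must be finer than 5% of the median, or the
    interval-observation rounding alone exhausts the tolerance.)"""
    cfg = CohortConfig(
        n_trial=10000, n_rwe=1, n_trial_unassessed=0, n_rwe_unassessed=0,
        trial_dvs_retained=5000, n_followup=0,
        trial_visit_weeks=tuple(np.arange(0.5, 40.1, 0.5)),
        true_models=flat_true_models(scale=1 / 0.05),
        missingness={}, censoring_rates={}, lead_in_weeks=0.0, seed=5,
    )
    recs = [r for r in generate_cohort(cfg) if r.study == "TRIAL"]
    samples = derive_remission(recs, "cpc")
    est = km_estimate(samples["time"], samples["event"])
    assert est.median == pytest.approx(np.log(2) / 0.05, rel=0.05)


def test_covariate_moments_match_config():
    cfg = CohortConfig(n_trial=10000, n_rwe=10, n_trial_unassessed=0,
                       n_rwe_unassessed=0, trial_dvs_retained=5000,
                       missingness={}, seed=8)
    recs = [r for r in generate_cohort(cfg) if r.study == "TRIAL"]
    age = np.array([r.covariates["age"] for r in recs])
    dur = np.array([r.covariates["cd_duration"] for r in recs])
    male = np.mean([r.covariates["gender"] == "male" for r in recs])
    assert age.mean() == pytest.approx(38.2, abs=3 * 13.2 / np.sqrt(len(recs)) + 0.05)
    assert age.std() == pytest.approx(13.2, rel=0.05)
    assert dur.mean() == pytest.approx(11.4, rel=0.03)  # gamma matched to mean/SD
    assert male == pytest.approx(0.54, abs=0.02)


def test_latent_ordering_invariants(latent_cohort):
    """Clinical remission never after CPC remission; loss of closure never
    before PDAI recurrence; relapse clocks start at CPC remission."""
    for r in latent_cohort:
        lat = r.latent
        assert lat["t_clin_rem"] <= lat["t_cpc_rem"]
        assert lat["t_pdai_recur"] <= lat["t_reopen"]
        assert lat["t_pdai_recur"] >= lat["t_cpc_rem"]


def test_inject_missingness_identity_and_boundary(latent_cohort):
    recs = latent_cohort[:50]
    same = inject_missingness(recs, {"pdai_pain": {"TRIAL": 0.0, "RWE": 0.0}}, seed=1)
    _, v0 = records_to_frames(recs)
    _, v1 = records_to_frames(same)
    assert v0.equals(v1)

    allmiss = inject_missingness(recs, {"pdai_pain": {"TRIAL": 1.0, "RWE": 1.0}}, seed=1)
    for r in allmiss:
        assert all(v.pdai_pain is None for v in r.visits)


def test_inject_missingness_unknown_variable():
    with pytest.raises(ValueError, match="not_a_var"):
        inject_missingness([], {"not_a_var": {"TRIAL": 0.5}}, seed=0)


def test_missing_fraction_converges():
    """73.5% masking of RWE PDAI reproduces the target rate within 3 SE."""
    cfg = CohortConfig(n_trial=10, n_rwe=1500, n_trial_unassessed=0,
                       n_rwe_unassessed=0, trial_dvs_retained=5,
                       missingness={}, seed=21)
    recs = generate_cohort(cfg)
    masked = inject_missingness(recs, {"pdai_pain": {"RWE": 0.735}}, seed=3)
    tot = obs = 0
    for r in masked:
        if r.study != "RWE":
            continue
        for v in r.visits:
            if v.eo_all_closed is not None:
                tot += 1
                obs += v.pdai_pain is not None
    frac = 1 - obs / tot
    se = np.sqrt(0.735 * 0.265 / tot)
    assert abs(frac - 0.735) < 3 * se


def test_mar_mode_depends_on_observed_covariate():
    cfg = CohortConfig(n_trial=10, n_rwe=3000, n_trial_unassessed=0,
                       n_rwe_unassessed=0, trial_dvs_retained=5,
                       missingness={}, seed=22)
    recs = generate_cohort(cfg)
    masked = inject_missingness(recs, {"pdai_pain": {"RWE": 0.5}}, seed=4, mode="MAR")
    rates = {True: [0, 0], False: [0, 0]}
    for r in masked:
        if r.study != "RWE":
            continue
        active = r.covariates.get("luminal_severity") in ("moderate", "severe")
        for v in r.visits:
            if v.eo_all_closed is not None:
                rates[active][0] += v.pdai_pain is None
                rates[active][1] += 1
    assert rates[True][0] / rates[True][1] > rates[False][0] / rates[False][1]
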