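"""Synthetic two-study CPF registry generator.

Emulates the data structures the downstream analysis assumes: a randomized
trial (``TRIAL``: DVS vs SoC arms, fixed visit grid, near-complete PDAI) and
a retrospective chart-review study (``RWE``: SoC only, irregular routine-care
visits, heavy PDAI missingness), each with the shared baseline-covariate
schema.

Latent event structure per patient (all clocks in weeks from treatment
initiation, which is week 0):

* ``t_cpc_rem``   — time to CPC remission (closure of all external openings
  AND PDAI pain = 0 AND discharge = 0), drawn from the configured family for
  the ``CPC_REMISSION`` outcome with location/shape linear predictors.
* ``t_clin_rem``  — time to clinical remission (closure only); drawn from
  the ``CLIN_REMISSION`` model and coerced to ``min(draw, t_cpc_rem)`` so
  that clinical remission never happens after CPC remission.
* relapse clocks start at ``t_cpc_rem`` (semi-Markov clock reset by
  construction): ``t_cpc_rel`` from the ``CPC_RELAPSE_FROM_CPC`` model and
  ``t_clin_rel = max(draw, t_cpc_rel)`` from ``CLIN_RELAPSE_FROM_CPC`` (loss
  of closure implies loss of CPC status, so CPC relapse is never later).

Observation is interval-censored at the visit schedule: a state change is
seen at the first visit at or after its latent time. A config switch keeps
the latent times on the record for oracle tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import (
    ARMS,
    CATEGORICAL_COVARIATES,
    COVARIATE_SCHEMA,
    PatientRecord,
    Visit,
    encode_covariates,
    records_to_frames,
)
from .families import get_family

logger = logging.getLogger(__name__)

OUTCOME_NAMES = (
    "CLIN_REMISSION",
    "CPC_REMISSION",
    "CLIN_RELAPSE_FROM_CPC",
    "CPC_RELAPSE_FROM_CPC",
)


@dataclass
class TrueEventModel:
    """True data-generating distribution for one outcome in one arm.

    ``beta`` maps encoded-covariate names to location effects (plus
    ``intercept``); ``gamma`` likewise for the shape linear predictor, mapped
    through the family's ancillary link. For the generalized gamma, ``q``
    supplies the second ancillary parameter.
    """

    family: str
    beta: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)
    q: float = 1.0

    def draw(self, rng: np.random.Generator, enc: dict) -> float:
        fam = get_family(self.family)
        mu = self.beta.get("intercept", 0.0) + sum(
            v * enc[k] for k, v in self.beta.items() if k != "intercept"
        )
        eta = self.gamma.get("intercept", 0.0) + sum(
            v * enc[k] for k, v in self.gamma.items() if k != "intercept"
        )
        a0 = np.exp(eta) if fam.anc_links[0] == "log" else eta
        anc = (a0,) if fam.n_anc == 1 else (a0, self.q)
        u = rng.uniform()
        return float(np.atleast_1d(fam.sample(np.atleast_1d(u), mu, tuple(np.atleast_1d(a) for a in anc)))[0])


def _default_covariate_model() -> dict:
    """Marginal covariate distributions per study.

    Numeric means/SDs and category proportions follow the published baseline
    tables of the two source populations (trial vs chart review). Duration
    of disease and CDAI are right-skewed non-negative scores and are drawn
    from gamma distributions matched to the stated mean/SD; age and weight
    are approximately symmetric and drawn normal.
    """
    return {
        "age": {"kind": "normal", "mean": {"TRIAL": 38.2, "RWE": 37.9}, "sd": {"TRIAL": 13.2, "RWE": 13.4}},
        "weight": {"kind": "normal", "mean": {"TRIAL": 72.2, "RWE": 66.1}, "sd": {"TRIAL": 14.8, "RWE": 14.3}},
        "cd_duration": {"kind": "gamma", "mean": {"TRIAL": 11.4, "RWE": 9.4}, "sd": {"TRIAL": 9.2, "RWE": 8.9}},
        "cdai": {"kind": "gamma", "mean": {"TRIAL": 90.7, "RWE": 172.9}, "sd": {"TRIAL": 52.0, "RWE": 90.0}},
        "gender": {"kind": "categorical", "levels": ["male", "female"],
                   "probs": {"TRIAL": [0.54, 0.46], "RWE": [0.52, 0.48]}},
        "ethnicity": {"kind": "categorical", "levels": ["caucasian", "other"],
                      "probs": {"TRIAL": [0.92, 0.08], "RWE": [0.98, 0.02]}},
        "smoking": {"kind": "categorical", "levels": ["current", "former", "never"],
                    "probs": {"TRIAL": [0.44, 0.15, 0.41], "RWE": [0.34, 0.17, 0.49]}},
        "luminal_severity": {"kind": "categorical", "levels": ["mild_inactive", "moderate", "severe"],
                             "probs": {"TRIAL": [1.0, 0.0, 0.0], "RWE": [0.58, 0.36, 0.06]}},
        "n_io": {"kind": "categorical", "levels": [1, 2, 3],
                 "probs": {"TRIAL": [0.85, 0.12, 0.03], "RWE": [0.78, 0.16, 0.06]}},
        "n_eo": {"kind": "categorical", "levels": [1, 2, 3, 4],
                 "probs": {"TRIAL": [0.62, 0.28, 0.08, 0.02], "RWE": [0.62, 0.28, 0.08, 0.02]}},
        "prior_antibiotic": {"kind": "categorical", "levels": [0, 1],
                             "probs": {"TRIAL": [0.255, 0.745], "RWE": [0.77, 0.23]}},
        "prior_biologic": {"kind": "categorical", "levels": [0, 1],
                           "probs": {"TRIAL": [0.205, 0.795], "RWE": [0.54, 0.46]}},
        "prior_immunomod": {"kind": "categorical", "levels": [0, 1],
                            "probs": {"TRIAL": [0.225, 0.775], "RWE": [0.32, 0.68]}},
        "pdai_pain_base": {"kind": "categorical", "levels": [0, 1, 2, 3],
                           "probs": {"TRIAL": [0.25, 0.40, 0.25, 0.10], "RWE": [0.10, 0.25, 0.40, 0.25]}},
        "pdai_discharge_base": {"kind": "categorical", "levels": [0, 1, 2, 3],
                                "probs": {"TRIAL": [0.15, 0.35, 0.35, 0.15], "RWE": [0.08, 0.22, 0.42, 0.28]}},
    }


def _default_true_models() -> dict:
    """True event-time models per outcome and arm.

    Weibull throughout by default, with the active arm faster to remission
    and slower to relapse, a penalty on remission for active luminal disease
    and a mild age effect. Scales are in weeks.
    """
    def w(mu0, shape, beta=None, gamma=None):
        b = {"intercept": mu0}
        b.update(beta or {})
        return TrueEventModel("weibull", beta=b, gamma={"intercept": np.log(shape), **(gamma or {})})

    cov_rem = {"luminal_active": 0.35, "age_c": 0.05}
    cov_rel = {"prior_biologic": -0.20, "luminal_active": -0.25}
    return {
        "CLIN_REMISSION": {
            "DVS": w(np.log(25.0), 1.2, cov_rem),
            "SOC": w(np.log(45.0), 1.2, cov_rem),
        },
        "CPC_REMISSION": {
            "DVS": w(np.log(32.0), 1.2, cov_rem),
            "SOC": w(np.log(60.0), 1.2, cov_rem),
        },
        "CLIN_RELAPSE_FROM_CPC": {
            "DVS": w(np.log(150.0), 0.9, cov_rel),
            "SOC": w(np.log(75.0), 0.9, cov_rel),
        },
        "CPC_RELAPSE_FROM_CPC": {
            "DVS": w(np.log(110.0), 0.9, cov_rel),
            "SOC": w(np.log(55.0), 0.9, cov_rel),
        },
    }


def _default_missingness() -> dict:
    """Per-variable missing probability per study.

    Baseline rates mirror the per-variable Ns of the published baseline
    table (e.g. smoking status recorded for only 39/200 trial patients;
    CDAI and baseline PDAI missing for ~3/4 of the chart-review cohort);
    visit-level PDAI missingness is 0.5% in the trial versus 73.5% in the
    chart review.
    """
    return {
        "weight": {"TRIAL": 0.010, "RWE": 0.070},
        "cd_duration": {"TRIAL": 0.005, "RWE": 0.016},
        "smoking": {"TRIAL": 0.805, "RWE": 0.006},
        "luminal_severity": {"TRIAL": 0.0, "RWE": 0.064},
        "n_io": {"TRIAL": 0.0, "RWE": 0.061},
        "n_eo": {"TRIAL": 0.015, "RWE": 0.026},
        "cdai": {"TRIAL": 0.010, "RWE": 0.757},
        "pdai_pain_base": {"TRIAL": 0.005, "RWE": 0.744},
        "pdai_discharge_base": {"TRIAL": 0.005, "RWE": 0.728},
        "pdai_pain": {"TRIAL": 0.005, "RWE": 0.735},
        "pdai_discharge": {"TRIAL": 0.005, "RWE": 0.735},
    }


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic two-study registry.

    Defaults reproduce the published patient flow exactly (212 trial
    patients of whom 12 lack a completed post-index assessment, leaving
    101 DVS + 99 SoC; 386 chart-review patients of whom 73 lack one,
    leaving 313 SoC) and the published baseline marginals and missingness
    levels.
    """

    n_trial: int = 212
    n_rwe: int = 386
    n_trial_unassessed: int = 12
    n_rwe_unassessed: int = 73
    trial_dvs_retained: int = 101  # DVS count among assessed trial patients
    n_followup: int = 89  # trial patients with a chart-review follow-up extension
    covariate_model: dict = field(default_factory=_default_covariate_model)
    true_models: dict = field(default_factory=_default_true_models)
    trial_visit_weeks: tuple = (6.0, 12.0, 18.0, 24.0, 36.0, 52.0, 78.0, 104.0)
    followup_visit_weeks: tuple = (130.0, 156.0)
    rwe_first_visit_median: float = 8.0
    rwe_gap_median: float = 10.0
    rwe_gap_log_sd: float = 0.45
    rwe_followup_range: tuple = (52.0, 156.0)
    missingness: dict = field(default_factory=_default_missingness)
    censoring_rates: dict = field(
        default_factory=lambda: {"lost": 0.0030, "proctectomy": 0.0010, "death": 0.0004}
    )
    lead_in_weeks: float = 4.0
    keep_latent: bool = False
    seed: int = 20240101

    def validate(self) -> None:
        for name in ("n_trial", "n_rwe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CohortConfig.{name} must be > 0")
        if not 0 <= self.n_trial_unassessed < self.n_trial:
            raise ValueError("CohortConfig.n_trial_unassessed out of range")
        if not 0 <= self.n_rwe_unassessed < self.n_rwe:
            raise ValueError("CohortConfig.n_rwe_unassessed out of range")
        n_assessed = self.n_trial - self.n_trial_unassessed
        if not 0 <= self.trial_dvs_retained <= n_assessed:
            raise ValueError("CohortConfig.trial_dvs_retained out of range")
        if self.lead_in_weeks < 0:
            raise ValueError("CohortConfig.lead_in_weeks must be >= 0")
        for outcome in self.true_models:
            if outcome not in OUTCOME_NAMES:
                raise ValueError(
                    f"CohortConfig.true_models has unknown outcome {outcome!r}; "
                    f"expected one of {OUTCOME_NAMES}"
                )
            for arm in self.true_models[outcome]:
                if arm not in ARMS:
                    raise ValueError(f"CohortConfig.true_models[{outcome}] has unknown arm {arm!r}")
        for var, spec in self.covariate_model.items():
            if spec["kind"] == "categorical":
                for study, p in spec["probs"].items():
                    p = np.asarray(p, dtype=float)
                    if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
                        raise ValueError(
                            f"CohortConfig.covariate_model[{var!r}] probs for {study} "
                            "must be in [0,1] and sum to 1"
                        )
        for var, per_study in self.missingness.items():
            for study, p in per_study.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"CohortConfig.missingness[{var!r}][{study!r}] must be in [0,1]"
                    )
        for reason, rate in self.censoring_rates.items():
            if rate < 0:
                raise ValueError(f"CohortConfig.censoring_rates[{reason!r}] must be >= 0")


def _draw_covariates(rng: np.random.Generator, model: dict, study: str) -> dict:
    cov = {}
    for var, spec in model.items():
        if spec["kind"] == "normal":
            val = rng.normal(spec["mean"][study], spec["sd"][study])
            cov[var] = max(val, 0.0)
        elif spec["kind"] == "gamma":
            m, s = spec["mean"][study], spec["sd"][study]
            shape = (m / s) ** 2
            cov[var] = rng.gamma(shape, s ** 2 / m)
        elif spec["kind"] == "categorical":
            idx = rng.choice(len(spec["levels"]), p=spec["probs"][study])
            cov[var] = spec["levels"][idx]
        else:
            raise ValueError(f"unknown covariate kind {spec['kind']!r} for {var!r}")
    return cov


def _latent_times(rng: np.random.Generator, cfg: CohortConfig, arm: str, enc: dict) -> dict:
    tm = cfg.true_models
    t_cpc = tm["CPC_REMISSION"][arm].draw(rng, enc)
    t_clin = min(tm["CLIN_REMISSION"][arm].draw(rng, enc), t_cpc)
    # relapse clocks start at CPC remission (clock reset)
    s_cpc_rel = tm["CPC_RELAPSE_FROM_CPC"][arm].draw(rng, enc)
    s_clin_rel = max(tm["CLIN_RELAPSE_FROM_CPC"][arm].draw(rng, enc), s_cpc_rel)
    # remission events are structurally absent during the lead-in window
    t_clin += cfg.lead_in_weeks
    t_cpc += cfg.lead_in_weeks
    return {
        "t_clin_rem": t_clin,
        "t_cpc_rem": t_cpc,
        "t_reopen": t_cpc + s_clin_rel,  # loss of closure
        "t_pdai_recur": t_cpc + s_cpc_rel,  # pain/discharge recurrence
    }


def _observe_visit(rng: np.random.Generator, week: float, lat: dict) -> Visit:
    closed = lat["t_clin_rem"] <= week < lat["t_reopen"]
    # PDAI pain & discharge are 0 exactly while CPC remission holds
    in_cpc = lat["t_cpc_rem"] <= week < lat["t_pdai_recur"]
    if in_cpc:
        pain, disch = 0, 0
    else:
        # symptomatic: at least one of pain/discharge positive
        pain = int(rng.integers(0, 4))
        disch = int(rng.integers(1, 4)) if pain == 0 else int(rng.integers(0, 4))
    return Visit(week=week, eo_all_closed=bool(closed), pdai_pain=pain, pdai_discharge=disch)


def _rwe_schedule(rng: np.random.Generator, cfg: CohortConfig) -> list:
    """Irregular routine-care visit weeks, log-normal inter-visit gaps."""
    end = rng.uniform(*cfg.rwe_followup_range)
    weeks, w = [], 0.0
    w = rng.lognormal(np.log(cfg.rwe_first_visit_median), cfg.rwe_gap_log_sd)
    while w < end and len(weeks) < 60:
        weeks.append(round(w, 1))
        w += max(rng.lognormal(np.log(cfg.rwe_gap_median), cfg.rwe_gap_log_sd), 0.5)
    if not weeks:
        weeks = [round(max(end / 2.0, 1.0), 1)]
    return sorted(set(weeks))


def _censor_draw(rng: np.random.Generator, rates: dict):
    best = None
    for reason, rate in rates.items():
        if rate <= 0:
            continue
        t = rng.exponential(1.0 / rate)
        if best is None or t < best[0]:
            best = (t, reason)
    return best


def _make_patient(rng, cfg, pid, study, arm, assessed, followup=False):
    cov = _draw_covariates(rng, cfg.covariate_model, study)
    enc = encode_covariates(cov)
    lat = _latent_times(rng, cfg, arm, enc)

    if study == "TRIAL":
        schedule = list(cfg.trial_visit_weeks)
        if followup:
            schedule += list(cfg.followup_visit_weeks)
    else:
        schedule = _rwe_schedule(rng, cfg)

    censor = _censor_draw(rng, cfg.censoring_rates)
    censor_week = censor[0] if censor else np.inf
    if assessed and schedule and censor is not None:
        # censoring clock starts at the first completed assessment
        # (memoryless rates, so this is a clean conditioning): patients in
        # the assessed stratum have, by definition, at least one assessment
        censor_week = schedule[0] + censor[0]

    visits = []
    for w in schedule:
        if w > censor_week:
            break
        if assessed:
            visits.append(_observe_visit(rng, w, lat))
        else:
            # enrolled but never completed a clinical assessment
            visits.append(Visit(week=w, eo_all_closed=None, pdai_pain=None, pdai_discharge=None))
    if not assessed:
        visits = visits[: int(rng.integers(0, 3))]

    censor_event = None
    if censor is not None and (visits == [] or censor_week <= (schedule[-1] if schedule else 0.0)):
        censor_event = (round(censor_week, 1), censor[1])
        visits = [v for v in visits if v.week <= censor_event[0]]

    return PatientRecord(
        patient_id=pid,
        study=study,
        arm=arm,
        covariates=cov,
        visits=visits,
        censor_event=censor_event,
        has_post_index_assessment=assessed and any(v.eo_all_closed is not None for v in visits),
        latent=dict(lat) if cfg.keep_latent else None,
        source=study,
    )


def generate_cohort(config: CohortConfig) -> list:
    """Generate the two-study registry; deterministic given ``config.seed``.

    Returns ``n_trial + n_rwe`` :class:`PatientRecord` objects. Trial arms
    are assigned with exact quotas among assessed patients (randomized
    block), matching the published disposition; chart-review patients are
    all SoC.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    records = []
    n_assessed = config.n_trial - config.n_trial_unassessed
    arms = ["DVS"] * config.trial_dvs_retained + ["SOC"] * (n_assessed - config.trial_dvs_retained)
    rng.shuffle(arms)
    # unassessed trial patients: arms split near-evenly (their arm never
    # enters the analysis sets)
    n_un_dvs = config.n_trial_unassessed // 2
    arms += ["DVS"] * n_un_dvs + ["SOC"] * (config.n_trial_unassessed - n_un_dvs)
    followup_ids = set(rng.choice(n_assessed, size=min(config.n_followup, n_assessed), replace=False))
    for i, arm in enumerate(arms):
        assessed = i < n_assessed
        records.append(
            _make_patient(
                rng, config, f"T{i + 1:04d}", "TRIAL", arm, assessed, followup=i in followup_ids
            )
        )
    for j in range(config.n_rwe):
        assessed = j < config.n_rwe - config.n_rwe_unassessed
        records.append(_make_patient(rng, config, f"R{j + 1:04d}", "RWE", "SOC", assessed))

    records = inject_missingness(records, config.missingness, seed=int(rng.integers(2 ** 31)))
    return records


def inject_missingness(records, missingness_spec, seed, mode="MCAR"):
    """Set targeted values to missing per the per-study probabilities.

    ``mode="MCAR"`` (default) masks each value independently with its
    configured probability. ``mode="MAR"`` makes the masking probability
    depend on an observed covariate: the configured probability is tilted
    up for patients with active luminal disease and down otherwise, keeping
    the marginal rate approximately equal.
    """
    if mode not in ("MCAR", "MAR"):
        raise ValueError("mode must be 'MCAR' or 'MAR'")
    known = set(COVARIATE_SCHEMA) | {"pdai_pain", "pdai_discharge", "eo_all_closed"}
    for var in missingness_spec:
        if var not in known:
            raise ValueError(f"unknown variable {var!r} in missingness spec")
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        r = r.copy()
        for var, per_study in missingness_spec.items():
            p = per_study.get(r.study, 0.0)
            if p <= 0:
                continue
            if mode == "MAR":
                active = r.covariates.get("luminal_severity") in ("moderate", "severe")
                p = min(p * (1.3 if active else 0.85), 1.0)
            if var in COVARIATE_SCHEMA:
                if p >= 1.0 or rng.uniform() < p:
                    r.covariates[var] = None
            else:
                for v in r.visits:
                    if getattr(v, var) is not None and (p >= 1.0 or rng.uniform() < p):
                        setattr(v, var, None)
        out.append(r)
    return out


def write_cohort(records, outdir, config: CohortConfig | None = None) -> None:
    """Write baseline.csv + visits.csv and a JSON sidecar echoing the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    baseline, visits = records_to_frames(records)
    baseline.to_csv(outdir / "baseline.csv", index=False)
    visits.to_csv(outdir / "visits.csv", index=False)
    if config is not None:
        sidecar = {
            k: v
            for k, v in config.__dict__.items()
            if k not in ("covariate_model", "true_models", "missingness")
        }
        sidecar["covariate_model"] = config.covariate_model
        sidecar["missingness"] = config.missingness
        sidecar["true_models"] = {
            o: {a: {"family": m.family, "beta": m.beta, "gamma": m.gamma, "q": m.q}
                for a, m in per_arm.items()}
            for o, per_arm in config.true_models.items()
        }
        (outdir / "cohort_config.json").write_text(json.dumps(sidecar, indent=2, default=float))
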