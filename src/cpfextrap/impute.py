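"""Multiple imputation of baseline covariates and PDAI categories.

The model is hierarchical over studies and conjugate-style throughout, so
completed data sets are drawn from closed-form approximate posteriors:

* categorical variables (including the 0–3 PDAI items): per-study
  multinomial with Dirichlet partial pooling toward the pooled category
  proportions (empirical-Bayes global mean, prior strength ``tau``);
* numeric variables: normal regression on a small set of always-observed
  predictors with a study offset shrunk by a normal (ridge) prior —
  i.e. a study-level random intercept — with coefficient and residual
  variance drawn from their normal / scaled-inverse-chi-square posterior;
* visit-level PDAI items are fitted over the instrument categories plus an
  explicit dummy "missing-pattern" category; at imputation the dummy mass
  is renormalized away so draws land on real categories. Fitting with the
  dummy keeps the observed-category counts honest in the presence of very
  high missingness rather than silently treating missing as informative.

Each of the ``m`` completions uses independent posterior parameter draws,
so between-imputation variance is real; observed values are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import (
    CATEGORICAL_COVARIATES,
    NONNEGATIVE_COVARIATES,
    NUMERIC_COVARIATES,
)

logger = logging.getLogger(__name__)

#: Visit-level imputation targets (PDAI instrument items).
VISIT_TARGETS = ("pdai_pain", "pdai_discharge")

#: Predictors for the numeric regressions; always observed in the generator
#: defaults and imputed first when categorical.
_NUMERIC_PREDICTORS = ("age", "gender")


@dataclass
class ImputationModel:
    """Fitted per-variable hierarchical models (sufficient statistics)."""

    categorical: dict = field(default_factory=dict)  # var -> per-study Dirichlet params
    numeric: dict = field(default_factory=dict)  # var -> regression posterior
    visit: dict = field(default_factory=dict)  # pdai item -> per-study Dirichlet params
    targets: tuple = ()
    tau: float = 5.0


@dataclass
class ImputationResult:
    completed: list  # m lists of PatientRecord
    m: int
    diagnostics: dict
    seed: int


def _levels(var):
    if var in CATEGORICAL_COVARIATES:
        return list(CATEGORICAL_COVARIATES[var])
    return [0, 1, 2, 3]  # PDAI items


def _fit_categorical(values_by_study, levels, tau, dummy_missing=False):
    """Dirichlet posteriors with partial pooling toward the pooled mean.

    Returns ``{study: alpha}`` over ``levels`` (the dummy category, when
    fitted, is recorded separately and renormalized away at draw time).
    """
    idx = {v: i for i, v in enumerate(levels)}
    counts = {}
    n_missing = {}
    for study, vals in values_by_study.items():
        c = np.zeros(len(levels))
        miss = 0
        for v in vals:
            if v is None:
                miss += 1
            else:
                c[idx[v]] += 1
        counts[study] = c
        n_missing[study] = miss
    pooled = sum(counts.values()) + 0.5
    global_p = pooled / pooled.sum()
    post = {}
    for study, c in counts.items():
        post[study] = c + tau * global_p
    return {
        "levels": levels,
        "alpha": post,
        "global_p": global_p,
        "n_missing": n_missing,
        "dummy_missing_count": n_missing if dummy_missing else None,
    }


def _fit_numeric(rows, var):
    """Bayesian linear model y ~ predictors + ridge-shrunk study offset."""
    y, X, ok = [], [], []
    for row in rows:
        if row[var] is None:
            continue
        y.append(float(row[var]))
        X.append(_numeric_design(row))
    if not y:
        raise ValueError(f"variable {var!r} entirely missing in all studies; cannot impute")
    X = np.asarray(X)
    y = np.asarray(y)
    lam = np.zeros(X.shape[1])
    lam[-1] = 1.0  # ridge prior on the study offset only (partial pooling)
    A = X.T @ X + np.diag(lam)
    beta_hat = np.linalg.solve(A, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(len(y) - X.shape[1], 2)
    s2 = float(resid @ resid) / dof
    return {"beta": beta_hat, "A_inv": np.linalg.inv(A), "s2": s2, "dof": dof}


def _numeric_design(row):
    age = row.get("age")
    male = 1.0 if row.get("gender") == "male" else 0.0
    return [
        1.0,
        0.0 if age is None else (float(age) - 38.0) / 10.0,
        male,
        1.0 if row["study"] == "RWE" else 0.0,  # shrunk study offset
    ]


def fit_imputation_model(records, target_variables=None, tau: float = 5.0) -> ImputationModel:
    """Fit the hierarchical imputation models from the observed data.

    ``target_variables`` defaults to every baseline covariate with at least
    one missing value plus the visit-level PDAI items. Raises if a target
    is entirely unobserved in every study.
    """
    baseline_rows = [
        {"study": r.study, **{k: r.covariates.get(k) for k in r.covariates}} for r in records
    ]
    all_baseline_vars = set().union(*(r.covariates.keys() for r in records)) if records else set()
    if target_variables is None:
        target_variables = [
            v
            for v in sorted(all_baseline_vars)
            if any(row.get(v) is None for row in baseline_rows)
        ] + [t for t in VISIT_TARGETS]

    model = ImputationModel(targets=tuple(target_variables), tau=tau)
    studies = sorted({r.study for r in records})

    for var in target_variables:
        if var in VISIT_TARGETS:
            vals_by_study = {s: [] for s in studies}
            for r in records:
                for v in r.visits:
                    if v.eo_all_closed is not None:
                        vals_by_study[r.study].append(getattr(v, var))
            if all(all(x is None for x in vals) for vals in vals_by_study.values()):
                raise ValueError(f"variable {var!r} entirely missing in all studies; cannot impute")
            model.visit[var] = _fit_categorical(vals_by_study, _levels(var), tau, dummy_missing=True)
        elif var in CATEGORICAL_COVARIATES:
            vals_by_study = {s: [] for s in studies}
            for row in baseline_rows:
                vals_by_study[row["study"]].append(row.get(var))
            if all(all(x is None for x in vals) for vals in vals_by_study.values()):
                raise ValueError(f"variable {var!r} entirely missing in all studies; cannot impute")
            model.categorical[var] = _fit_categorical(vals_by_study, _levels(var), tau)
        elif var in NUMERIC_COVARIATES:
            model.numeric[var] = _fit_numeric(baseline_rows, var)
        else:
            raise ValueError(f"unknown imputation target {var!r}")
    return model


def _draw_fill_categorical(rng, fit, study, n):
    alpha = fit["alpha"].get(study)
    if alpha is None:
        alpha = fit["global_p"] * 10.0
    p = rng.dirichlet(alpha)
    idx = rng.choice(len(fit["levels"]), size=n, p=p)
    return [fit["levels"][i] for i in idx]


def impute(model: ImputationModel, records, m: int = 20, seed: int = 0) -> ImputationResult:
    """Produce ``m`` completed record sets by posterior-draw imputation."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    completed = []
    imputed_fraction: dict = {}

    for _ in range(m):
        recs = [r.copy() for r in records]
        # categorical baseline targets first (gender may feed the regressions)
        for var, fit in model.categorical.items():
            for study in {r.study for r in recs}:
                missing = [r for r in recs if r.study == study and r.covariates.get(var) is None]
                if not missing:
                    continue
                fills = _draw_fill_categorical(rng, fit, study, len(missing))
                for r, v in zip(missing, fills):
                    r.covariates[var] = v
        for var, fit in model.numeric.items():
            L = np.linalg.cholesky(fit["A_inv"] + 1e-12 * np.eye(len(fit["beta"])))
            s2 = fit["s2"] * fit["dof"] / rng.chisquare(fit["dof"])
            beta = fit["beta"] + np.sqrt(s2) * (L @ rng.standard_normal(len(fit["beta"])))
            for r in recs:
                if r.covariates.get(var) is None:
                    x = np.asarray(_numeric_design({"study": r.study, **r.covariates}))
                    val = float(x @ beta + np.sqrt(s2) * rng.standard_normal())
                    if var in NONNEGATIVE_COVARIATES:
                        val = max(val, 0.0)
                    r.covariates[var] = val
        for var, fit in model.visit.items():
            for study in {r.study for r in recs}:
                p = rng.dirichlet(fit["alpha"].get(study, fit["global_p"] * 10.0))
                for r in recs:
                    if r.study != study:
                        continue
                    for v in r.visits:
                        if v.eo_all_closed is not None and getattr(v, var) is None:
                            setattr(v, var, int(fit["levels"][rng.choice(len(p), p=p)]))
        completed.append(recs)

    # diagnostics: imputed fractions per target
    n_records = max(len(records), 1)
    for var in model.targets:
        if var in VISIT_TARGETS:
            tot = obs = 0
            for r in records:
                for v in r.visits:
                    if v.eo_all_closed is not None:
                        tot += 1
                        obs += getattr(v, var) is not None
            imputed_fraction[var] = 0.0 if tot == 0 else 1.0 - obs / tot
        else:
            n_miss = sum(1 for r in records if r.covariates.get(var) is None)
            imputed_fraction[var] = n_miss / n_records

    return ImputationResult(
        completed=completed,
        m=m,
        diagnostics={"imputed_fraction": imputed_fraction, "tau": model.tau},
        seed=seed,
    )
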