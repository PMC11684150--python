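"""Maximum-likelihood fitting of covariate-adjusted parametric survival models.

The model: event time T_i follows one of five parametric families with a
per-subject location parameter given by a linear predictor, mu_i = x_i' beta,
and a per-subject ancillary (shape) parameter given by a second linear
predictor z_i' gamma mapped through the family's link (log for positive
shapes, identity for the Gompertz shape and the generalized-gamma Q). With
censoring indicator d_i, the log-likelihood is the exact sum of

    d_i * log h(t_i; mu_i, alpha_i) + log S(t_i; mu_i, alpha_i)

over subjects. Fitting maximizes this by multi-start quasi-Newton on the
(already unconstrained) coefficient vector; the variance-covariance matrix
comes from the numerical Hessian at the optimum. AIC = -2 loglik + 2k and
BIC = -2 loglik + k ln n compare families on the same samples.

Times are weeks since the outcome baseline, already lead-in shifted for
fitting (see :func:`cpfextrap.events.apply_lead_in`); reported curves
re-apply the lead-in plateau, so S(t) = 1 for t below the lead-in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .families import get_family

logger = logging.getLogger(__name__)


@dataclass
class FamilySpec:
    """Which family to fit and which covariates enter each linear predictor.

    ``shape_covariates`` must be a subset of ``location_covariates`` (or
    empty for an intercept-only shape), mirroring the usual hierarchy of a
    location-and-shape regression.
    """

    family: str
    location_covariates: tuple = ()
    shape_covariates: tuple = ()

    def __post_init__(self) -> None:
        get_family(self.family)  # validates the name
        self.location_covariates = tuple(self.location_covariates)
        self.shape_covariates = tuple(self.shape_covariates)
        extra = set(self.shape_covariates) - set(self.location_covariates)
        if extra:
            raise ValueError(
                f"shape covariates must be a subset of location covariates; extra: {sorted(extra)}"
            )


@dataclass
class ParamFit:
    spec: FamilySpec
    beta: dict  # location coefficients (includes "intercept")
    gamma_shape: dict  # shape linear predictor (includes "intercept")
    q: Optional[float]  # generalized-gamma second ancillary, else None
    loglik: float
    n: int
    k: int
    aic: float
    bic: float
    vcov: Optional[np.ndarray] = None
    param_names: tuple = ()
    converged: bool = True
    lead_in_weeks: float = 0.0
    messages: tuple = ()
    dataset_token: Optional[str] = None  # identifies the samples fitted on

    @property
    def se(self) -> dict:
        if self.vcov is None:
            return {}
        s = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        return dict(zip(self.param_names, s))

    def to_json_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "location_covariates": list(self.spec.location_covariates),
            "shape_covariates": list(self.spec.shape_covariates),
            "beta": self.beta,
            "gamma_shape": self.gamma_shape,
            "q": self.q,
            "loglik": self.loglik,
            "n": self.n,
            "k": self.k,
            "aic": self.aic,
            "bic": self.bic,
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "param_names": list(self.param_names),
            "converged": self.converged,
            "lead_in_weeks": self.lead_in_weeks,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ParamFit":
        spec = FamilySpec(d["family"], tuple(d["location_covariates"]), tuple(d["shape_covariates"]))
        return cls(
            spec=spec,
            beta=d["beta"],
            gamma_shape=d["gamma_shape"],
            q=d.get("q"),
            loglik=d["loglik"],
            n=d["n"],
            k=d["k"],
            aic=d["aic"],
            bic=d["bic"],
            vcov=None if d.get("vcov") is None else np.asarray(d["vcov"]),
            param_names=tuple(d.get("param_names", ())),
            converged=d.get("converged", True),
            lead_in_weeks=d.get("lead_in_weeks", 0.0),
        )


def _design(samples: pd.DataFrame, names) -> np.ndarray:
    cols = [np.ones(len(samples))]
    for c in names:
        if c not in samples.columns:
            raise ValueError(f"covariate {c!r} not present in samples")
        cols.append(samples[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _anc_from_eta(fam, eta, q=None):
    a0 = np.exp(eta) if fam.anc_links[0] == "log" else eta
    if fam.n_anc == 1:
        return (a0,)
    return (a0, np.broadcast_to(q, np.shape(a0)))


def log_likelihood(samples: pd.DataFrame, spec: FamilySpec, beta, gamma_shape, q=None) -> float:
    """Exact log-likelihood sum d*log h + log S at given coefficients.

    ``beta``/``gamma_shape`` are sequences ordered (intercept, then the
    spec's covariates). Raises if any per-observation contribution is
    non-finite (e.g. t = 0).
    """
    fam = get_family(spec.family)
    t = samples["time"].to_numpy(dtype=float)
    d = samples["event"].to_numpy(dtype=int)
    if np.any(t <= 0):
        bad = samples.index[t <= 0][0]
        raise ValueError(f"non-positive time at sample {bad}; shift with the lead-in first")
    X = _design(samples, spec.location_covariates)
    Z = _design(samples, spec.shape_covariates)
    mu = X @ np.asarray(beta, dtype=float)
    eta = Z @ np.asarray(gamma_shape, dtype=float)
    anc = _anc_from_eta(fam, eta, q)
    ls = fam.log_surv(t, mu, anc)
    contrib = np.where(d == 1, fam.log_hazard(t, mu, anc), 0.0) + ls
    if not np.all(np.isfinite(contrib)):
        bad = samples.index[~np.isfinite(contrib)][0]
        raise ValueError(f"non-finite log-likelihood contribution at sample {bad}")
    return float(contrib.sum())


def _nll_factory(samples, spec, p, s):
    fam = get_family(spec.family)
    t = samples["time"].to_numpy(dtype=float)
    d = samples["event"].to_numpy(dtype=int)
    X = _design(samples, spec.location_covariates)
    Z = _design(samples, spec.shape_covariates)
    is_gg = fam.n_anc == 2
    dmask = d == 1

    def nll(theta):
        beta = theta[:p]
        gamma = theta[p : p + s]
        q = theta[p + s] if is_gg else None
        mu = X @ beta
        eta = np.clip(Z @ gamma, -30.0, 30.0)
        anc = _anc_from_eta(fam, eta, q)
        with np.errstate(all="ignore"):
            ls = fam.log_surv(t, mu, anc)
            lh = fam.log_hazard(t, mu, anc)
        contrib = np.where(dmask, lh, 0.0) + ls
        if not np.all(np.isfinite(contrib)):
            return 1e12
        return -float(contrib.sum())

    return nll


def _numerical_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


def _starts(samples, spec, p, s):
    """Start points on the coefficient scale; family-aware."""
    t = samples["time"].to_numpy(dtype=float)
    d = samples["event"].to_numpy(dtype=int)
    total_time = t.sum()
    n_events = max(d.sum(), 1)
    rate = n_events / total_time  # exponential MLE as anchor
    fam = get_family(spec.family)
    starts = []

    def make(mu0, eta0, q=None):
        th = np.zeros(p + s + (1 if fam.n_anc == 2 else 0))
        th[0] = mu0
        th[p] = eta0
        if fam.n_anc == 2:
            th[-1] = q
        return th

    if spec.family == "gompertz":
        starts.append(make(np.log(rate), 0.0))
        starts.append(make(np.log(rate), 0.005))
        starts.append(make(np.log(rate) - 0.5, -0.005))
    elif spec.family == "gengamma":
        # nested Weibull and near-log-normal solutions tame the likelihood ridge
        mu0 = -np.log(rate)
        starts.append(make(mu0, 0.0, q=1.0))
        starts.append(make(np.log(np.median(t)), np.log(max(np.std(np.log(t)), 0.2)), q=1e-3))
        starts.append(make(mu0, 0.3, q=-0.5))
    elif spec.family == "lognormal":
        lt = np.log(t)
        starts.append(make(float(np.mean(lt)), float(np.log(max(np.std(lt), 0.2)))))
        starts.append(make(float(np.median(lt)), 0.0))
    else:  # weibull, loglogistic: scale anchored at 1/rate
        starts.append(make(-np.log(rate), 0.0))
        starts.append(make(-np.log(rate), 0.3))
        starts.append(make(float(np.log(np.median(t))), -0.3))
    return starts


def fit_mle(samples: pd.DataFrame, spec: FamilySpec, auto_drop_shape: bool = False) -> ParamFit:
    """Multi-start maximum-likelihood fit of one family spec.

    Deterministic (the start set is fixed given the data). Non-convergence
    of every start yields a fit flagged ``converged=False`` rather than an
    exception. With ``auto_drop_shape=True``, shape covariates whose
    inclusion prevents convergence are dropped one at a time (greedily) and
    the drops are logged.
    """
    n_events = int(samples["event"].sum())
    p = 1 + len(spec.location_covariates)
    s = 1 + len(spec.shape_covariates)
    fam = get_family(spec.family)
    k = p + s + (1 if fam.n_anc == 2 else 0)
    if n_events < k + 1:
        logger.warning(
            "only %d events for %d parameters (%s); estimates may be unstable",
            n_events, k, spec.family,
        )

    nll = _nll_factory(samples, spec, p, s)
    best = None
    messages = []
    for x0 in _starts(samples, spec, p, s):
        try:
            res = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
        except Exception as e:  # noqa: BLE001 - flagged, not raised
            messages.append(str(e))
            continue
        if best is None or res.fun < best.fun:
            best = res
    converged = best is not None and np.isfinite(best.fun) and best.fun < 1e11
    if converged:
        # polish with Nelder-Mead if BFGS stopped on a rough gradient
        res2 = optimize.minimize(nll, best.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
        if res2.fun < best.fun:
            best = res2

    if not converged and auto_drop_shape and spec.shape_covariates:
        dropped = spec.shape_covariates[-1]
        logger.warning("dropping shape covariate %r (fit did not converge)", dropped)
        sub = FamilySpec(spec.family, spec.location_covariates, spec.shape_covariates[:-1])
        fit = fit_mle(samples, sub, auto_drop_shape=True)
        fit.messages = tuple(list(fit.messages) + [f"shape covariate {dropped!r} dropped"])
        return fit

    param_names = (
        ["mu.intercept"] + [f"mu.{c}" for c in spec.location_covariates]
        + ["shape.intercept"] + [f"shape.{c}" for c in spec.shape_covariates]
        + (["Q"] if fam.n_anc == 2 else [])
    )
    if best is None:
        theta = np.zeros(k)
        ll = -np.inf
    else:
        theta = best.x
        ll = -float(best.fun)

    vcov = None
    if converged:
        try:
            H = _numerical_hessian(nll, theta)
            vcov = np.linalg.inv(H)
            if np.any(np.diag(vcov) < 0):
                messages.append("Hessian not positive definite at optimum")
        except np.linalg.LinAlgError:
            messages.append("singular Hessian; no vcov")

    n = len(samples)
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * np.log(n)
    beta = dict(zip(["intercept"] + list(spec.location_covariates), theta[:p]))
    gamma = dict(zip(["intercept"] + list(spec.shape_covariates), theta[p : p + s]))
    q = float(theta[p + s]) if fam.n_anc == 2 else None
    token = f"n={n};events={n_events};tsum={samples['time'].sum():.6g}"
    lead_in = float(samples.attrs.get("lead_in_weeks", 0.0)) if hasattr(samples, "attrs") else 0.0
    return ParamFit(
        spec=spec,
        beta={k_: float(v) for k_, v in beta.items()},
        gamma_shape={k_: float(v) for k_, v in gamma.items()},
        q=q,
        loglik=ll,
        n=n,
        k=k,
        aic=float(aic),
        bic=float(bic),
        vcov=vcov,
        param_names=tuple(param_names),
        converged=bool(converged),
        lead_in_weeks=lead_in,
        messages=tuple(messages),
        dataset_token=token,
    )


def compare_models(fits) -> pd.DataFrame:
    """AIC-sorted comparison table (with BIC and delta-AIC) for one dataset."""
    fits = list(fits)
    tokens = {f.dataset_token for f in fits if f.dataset_token is not None}
    if len(tokens) > 1:
        raise ValueError("compare_models requires fits on the same samples")
    rows = [
        {
            "family": f.spec.family,
            "k": f.k,
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "converged": f.converged,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df


def _profile_params(fit: ParamFit, profile: pd.DataFrame):
    fam = get_family(fit.spec.family)
    for c in fit.spec.location_covariates:
        if c not in profile.columns:
            raise ValueError(f"covariate {c!r} missing from profile")
    X = _design(profile, fit.spec.location_covariates)
    Z = _design(profile, fit.spec.shape_covariates)
    beta = np.array([fit.beta["intercept"]] + [fit.beta[c] for c in fit.spec.location_covariates])
    gamma = np.array(
        [fit.gamma_shape["intercept"]] + [fit.gamma_shape[c] for c in fit.spec.shape_covariates]
    )
    mu = X @ beta
    eta = Z @ gamma
    anc = _anc_from_eta(fam, eta, fit.q)
    return fam, mu, anc


def predict_curve(
    fit: ParamFit,
    covariate_profile,
    horizon_weeks: float,
    weights=None,
    grid_step: float = 1.0,
) -> pd.DataFrame:
    """Survival curve S(t) on a weekly grid, with the lead-in plateau.

    ``covariate_profile`` is a one-row mapping or a DataFrame; with several
    rows the curve is the (weight-)averaged population curve. Returns a
    DataFrame with columns ``week`` and ``survival``; S(t) = 1 for
    t < lead-in and S(t) = S_fit(t - lead-in) beyond.
    """
    if isinstance(covariate_profile, dict):
        covariate_profile = pd.DataFrame([covariate_profile])
    fam, mu, anc = _profile_params(fit, covariate_profile)
    grid = np.arange(0.0, horizon_weeks + grid_step / 2.0, grid_step)
    L = fit.lead_in_weeks
    shifted = np.clip(grid - L, 0.0, None)
    tt = shifted[None, :].repeat(len(mu), axis=0)
    anc_cols = tuple(np.asarray(a)[:, None] for a in anc)
    with np.errstate(all="ignore"):
        S = np.exp(fam.log_surv(tt, np.asarray(mu)[:, None], anc_cols))
    S = np.where(tt <= 0, 1.0, S)
    if weights is None:
        w = np.full(len(mu), 1.0 / len(mu))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    pop = w @ S
    return pd.DataFrame({"week": grid, "survival": pop})


def rubin_pool(fits) -> pd.DataFrame:
    """Rubin's rules across imputation-completed fits of one spec.

    Returns per-parameter pooled estimates, total SE (within + between),
    and the between/within split.
    """
    fits = list(fits)
    names = fits[0].param_names
    est = np.array([[dict(zip(f.param_names, _theta(f)))[nm] for nm in names] for f in fits])
    within = np.array(
        [[f.se.get(nm, np.nan) ** 2 for nm in names] for f in fits]
    )
    m = len(fits)
    qbar = est.mean(axis=0)
    ubar = np.nanmean(within, axis=0)
    b = est.var(axis=0, ddof=1) if m > 1 else np.zeros(len(names))
    total = ubar + (1 + 1 / m) * b
    return pd.DataFrame(
        {"param": names, "estimate": qbar, "se": np.sqrt(total), "within_var": ubar, "between_var": b}
    )


def _theta(fit: ParamFit) -> np.ndarray:
    vals = [fit.beta["intercept"]] + [fit.beta[c] for c in fit.spec.location_covariates]
    vals += [fit.gamma_shape["intercept"]] + [fit.gamma_shape[c] for c in fit.spec.shape_covariates]
    if fit.q is not None:
        vals.append(fit.q)
    return np.asarray(vals)


def save_fits(fits: dict, path) -> None:
    """Serialize a {label: ParamFit} map to JSON."""
    payload = {label: f.to_json_dict() for label, f in fits.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_fits(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    return {label: ParamFit.from_json_dict(d) for label, d in payload.items()}
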