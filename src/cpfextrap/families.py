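"""The five parametric survival families, in flexsurv-style parameterizations.

Every family exposes the survivor function S(t), hazard h(t), their logs,
and inverse-survival sampling, all vectorized over observations with a
per-observation location parameter ``mu`` and ancillary (shape) parameters.
Conventions:

* Weibull (AFT form):   S(t) = exp(-(t/b)^s),           b = exp(mu), s > 0
* Gompertz:             h(t) = exp(mu) * exp(a t),      a real (identity link)
* log-logistic:         S(t) = 1 / (1 + (t/b)^s),       b = exp(mu), s > 0
* log-normal:           S(t) = 1 - Phi((ln t - mu)/sigma), sigma > 0
* generalized gamma (Prentice mu, sigma, Q): nests Weibull at Q = 1 and
  log-normal at Q = 0; sigma > 0, Q real.

Positive ancillary parameters are reached from a linear predictor through a
log link; the Gompertz shape ``a`` and the generalized-gamma ``Q`` use an
identity link (both may legitimately be negative).
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import norm

_EPS_GOMPERTZ = 1e-9
_EPS_Q = 1e-6


class Family:
    """Base class; subclasses implement logs of h and S plus sampling.

    ``anc`` is a tuple of ancillary-parameter arrays on the natural scale
    (already back-transformed from any linear predictor).
    """

    name: str = ""
    n_anc: int = 1
    #: link per ancillary parameter: "log" or "identity"
    anc_links: tuple = ("log",)

    def log_surv(self, t, mu, anc):  # pragma: no cover - abstract
        raise NotImplementedError

    def log_hazard(self, t, mu, anc):  # pragma: no cover - abstract
        raise NotImplementedError

    def surv(self, t, mu, anc):
        return np.exp(self.log_surv(t, mu, anc))

    def hazard(self, t, mu, anc):
        return np.exp(self.log_hazard(t, mu, anc))

    def sample(self, u, mu, anc):
        """Event time t with S(t) = u (inverse-survival sampling)."""
        raise NotImplementedError


class Weibull(Family):
    name = "weibull"

    def log_surv(self, t, mu, anc):
        (s,) = anc
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            return -np.exp(s * (np.log(t) - mu))

    def log_hazard(self, t, mu, anc):
        (s,) = anc
        t = np.asarray(t, dtype=float)
        return np.log(s) - mu + (s - 1.0) * (np.log(t) - mu)

    def sample(self, u, mu, anc):
        (s,) = anc
        return np.exp(mu) * (-np.log(u)) ** (1.0 / s)


class Gompertz(Family):
    name = "gompertz"
    anc_links = ("identity",)

    def log_surv(self, t, mu, anc):
        (a,) = anc
        t = np.asarray(t, dtype=float)
        rate = np.exp(mu)
        a = np.broadcast_to(np.asarray(a, dtype=float), np.broadcast_shapes(np.shape(a), t.shape)).copy()
        small = np.abs(a) < _EPS_GOMPERTZ
        # -(r/a)(e^{at}-1); a->0 limit gives the exponential -r t
        with np.errstate(over="ignore"):
            out = np.where(
                small,
                -rate * t * (1.0 + a * t / 2.0),
                -(rate / np.where(small, 1.0, a)) * np.expm1(np.where(small, 0.0, a) * t),
            )
        return out

    def log_hazard(self, t, mu, anc):
        (a,) = anc
        return mu + a * np.asarray(t, dtype=float)

    def sample(self, u, mu, anc):
        (a,) = anc
        u = np.asarray(u, dtype=float)
        rate = np.exp(mu)
        a = np.broadcast_to(np.asarray(a, dtype=float), np.broadcast_shapes(np.shape(a), u.shape))
        small = np.abs(a) < _EPS_GOMPERTZ
        a_safe = np.where(small, 1.0, a)
        arg = 1.0 - (a_safe / rate) * np.log(u)
        t = np.where(
            small,
            -np.log(u) / rate,
            np.where(arg > 0, np.log(np.where(arg > 0, arg, 1.0)) / a_safe, np.inf),
        )
        return t


class LogLogistic(Family):
    name = "loglogistic"

    def log_surv(self, t, mu, anc):
        (s,) = anc
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            z = s * (np.log(t) - mu)
        return -np.logaddexp(0.0, z)

    def log_hazard(self, t, mu, anc):
        (s,) = anc
        t = np.asarray(t, dtype=float)
        z = s * (np.log(t) - mu)
        return np.log(s) - mu + (s - 1.0) * (np.log(t) - mu) - np.logaddexp(0.0, z)

    def sample(self, u, mu, anc):
        (s,) = anc
        return np.exp(mu) * ((1.0 - u) / u) ** (1.0 / s)


class LogNormal(Family):
    name = "lognormal"

    def log_surv(self, t, mu, anc):
        (sigma,) = anc
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            z = (np.log(t) - mu) / sigma
        return norm.logsf(z)

    def log_hazard(self, t, mu, anc):
        (sigma,) = anc
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            z = (np.log(t) - mu) / sigma
        log_f = norm.logpdf(z) - np.log(t) - np.log(sigma)
        return log_f - norm.logsf(z)

    def sample(self, u, mu, anc):
        (sigma,) = anc
        return np.exp(mu + sigma * norm.isf(u))


class GenGamma(Family):
    """Generalized gamma in the Prentice (mu, sigma, Q) parameterization.

    Q = 1 reduces to Weibull with shape 1/sigma and scale exp(mu); Q -> 0
    reduces to log-normal(mu, sigma). |Q| below 1e-6 is evaluated on the
    log-normal branch.
    """

    name = "gengamma"
    n_anc = 2
    anc_links = ("log", "identity")

    def _wz(self, t, mu, sigma):
        with np.errstate(divide="ignore"):
            return (np.log(np.asarray(t, dtype=float)) - mu) / sigma

    def log_surv(self, t, mu, anc):
        sigma, Q = anc
        t = np.asarray(t, dtype=float)
        sigma = np.broadcast_to(np.asarray(sigma, float), np.broadcast_shapes(np.shape(sigma), t.shape))
        Q = np.broadcast_to(np.asarray(Q, float), np.broadcast_shapes(np.shape(Q), t.shape))
        w = self._wz(t, mu, sigma)
        out = np.empty(np.broadcast_shapes(w.shape), dtype=float)
        ln_branch = np.abs(Q) < _EPS_Q
        if np.any(ln_branch):
            out[ln_branch] = norm.logsf(w[ln_branch])
        rest = ~ln_branch
        if np.any(rest):
            q = Q[rest]
            k = q ** -2.0
            ug = k * np.exp(np.clip(q * w[rest], -700, 700))
            with np.errstate(divide="ignore"):
                upper = np.log(special.gammaincc(k, ug))
                lower = np.log(special.gammainc(k, ug))
            out[rest] = np.where(q > 0, upper, lower)
        return out

    def _log_pdf(self, t, mu, anc):
        sigma, Q = anc
        t = np.asarray(t, dtype=float)
        sigma = np.broadcast_to(np.asarray(sigma, float), np.broadcast_shapes(np.shape(sigma), t.shape))
        Q = np.broadcast_to(np.asarray(Q, float), np.broadcast_shapes(np.shape(Q), t.shape))
        w = self._wz(t, mu, sigma)
        out = np.empty(w.shape, dtype=float)
        ln_branch = np.abs(Q) < _EPS_Q
        if np.any(ln_branch):
            out[ln_branch] = (
                norm.logpdf(w[ln_branch]) - np.log(t if np.ndim(t) == 0 else t[ln_branch]) - np.log(sigma[ln_branch])
            )
        rest = ~ln_branch
        if np.any(rest):
            q = Q[rest]
            k = q ** -2.0
            qw = q * w[rest]
            out[rest] = (
                np.log(np.abs(q))
                + k * np.log(k)
                - special.gammaln(k)
                + k * (qw - np.exp(np.clip(qw, -700, 700)))
                - np.log(sigma[rest])
                - np.log(t if np.ndim(t) == 0 else t[rest])
            )
        return out

    def log_hazard(self, t, mu, anc):
        return self._log_pdf(t, mu, anc) - self.log_surv(t, mu, anc)

    def sample(self, u, mu, anc):
        sigma, Q = anc
        u = np.asarray(u, dtype=float)
        sigma = np.broadcast_to(np.asarray(sigma, float), np.broadcast_shapes(np.shape(sigma), u.shape))
        Q = np.broadcast_to(np.asarray(Q, float), np.broadcast_shapes(np.shape(Q), u.shape))
        w = np.empty(u.shape, dtype=float)
        ln_branch = np.abs(Q) < _EPS_Q
        if np.any(ln_branch):
            w[ln_branch] = norm.isf(u[ln_branch])
        rest = ~ln_branch
        if np.any(rest):
            q = Q[rest]
            k = q ** -2.0
            ug = np.where(q > 0, special.gammainccinv(k, u[rest]), special.gammaincinv(k, u[rest]))
            w[rest] = np.log(ug / k) / q
        return np.exp(mu + sigma * w)


FAMILIES: dict[str, Family] = {
    f.name: f for f in (Weibull(), Gompertz(), LogLogistic(), LogNormal(), GenGamma())
}

#: Canonical spelling accepted from configs.
_ALIASES = {
    "weibull": "weibull",
    "gompertz": "gompertz",
    "loglogistic": "loglogistic",
    "log-logistic": "loglogistic",
    "log_logistic": "loglogistic",
    "lognormal": "lognormal",
    "log-normal": "lognormal",
    "log_normal": "lognormal",
    "gengamma": "gengamma",
    "generalized_gamma": "gengamma",
    "generalised_gamma": "gengamma",
}


def get_family(name: str) -> Family:
    key = _ALIASES.get(str(name).strip().lower().replace(" ", "_"))
    if key is None:
        raise ValueError(
            f"unknown survival family {name!r}; choose from {sorted(set(_ALIASES.values()))}"
        )
    return FAMILIES[key]
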