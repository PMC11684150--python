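import numpy as np
import pytest

from cpfextrap import CohortConfig, FamilySpec, generate_cohort
from cpfextrap.cohort import TrueEventModel
from cpfextrap.paramfit import ParamFit


def exponential_fit(rate: float, lead_in: float = 0.0) -> ParamFit:
    """A Weibull ParamFit pinned to an exponential with the given weekly rate."""
    return ParamFit(
        spec=FamilySpec("weibull"),
        beta={"intercept": float(np.log(1.0 / rate))},
        gamma_shape={"intercept": 0.0},
        q=None,
        loglik=0.0,
        n=1,
        k=2,
        aic=0.0,
        bic=0.0,
        lead_in_weeks=lead_in,
    )


def make_fit(family, beta, gamma, q=None, lead_in=0.0, loc_cov=(), shape_cov=()):
    spec = FamilySpec(family, loc_cov, shape_cov)
    return ParamFit(
        spec=spec,
        beta=beta,
        gamma_shape=gamma,
        q=q,
        loglik=0.0,
        n=1,
        k=2,
        aic=0.0,
        bic=0.0,
        lead_in_weeks=lead_in,
    )


def flat_true_models(family="weibull", scale=20.0, shape=1.0):
    """All four outcomes share one covariate-free true model."""
    m = TrueEventModel(family, beta={"intercept": float(np.log(scale))},
                       gamma={"intercept": float(np.log(shape))})
    return {o: {a: m for a in ("DVS", "SOC")}
            for o in ("CLIN_REMISSION", "CPC_REMISSION",
                      "CLIN_RELAPSE_FROM_CPC", "CPC_RELAPSE_FROM_CPC")}


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-study registry (one generation per session)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def latent_cohort():
    """A moderate cohort with latent event times retained, for oracle checks."""
    cfg = CohortConfig(n_trial=300, n_rwe=300, n_trial_unassessed=0,
                       n_rwe_unassessed=0, trial_dvs_retained=150,
                       keep_latent=True, seed=99)
    return generate_cohort(cfg)
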