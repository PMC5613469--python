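"""Shared fixtures: small simulated cohorts and fitted posteriors.

Expensive fits are session-scoped so many tests can share them.
"""

import numpy as np
import pandas as pd
import pytest

from mvglmm.cohort import CohortDataset, split_train_test
from mvglmm.model import MCMCConfig, ModelSpec, PosteriorSamples, fit_mglmm, fit_univariate_set
from mvglmm.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, 3 visits, no dropout."""
    return simulate_cohort(SimulationConfig(n_subjects=40, seed=7))


@pytest.fixture(scope="session")
def split_cohort(small_cohort):
    return split_train_test(small_cohort, n_test=5, seed=3)


@pytest.fixture(scope="session")
def small_post(split_cohort):
    """Quick multivariate fit (shared; not used for precision assertions)."""
    return fit_mglmm(split_cohort, ModelSpec(),
                     MCMCConfig(n_burnin=300, n_keep=250, thin=1, n_chains=2, seed=11))


@pytest.fixture(scope="session")
def small_post_uni(split_cohort):
    """Quick univariate (diagonal-Sigma) fit on the same data."""
    return fit_univariate_set(split_cohort, ModelSpec(),
                              MCMCConfig(n_burnin=300, n_keep=250, thin=1, n_chains=2, seed=12))


def make_degenerate_posterior(beta, mu, Sigma, sigma2, n_draws,
                              outcomes=(("Y1", "gaussian"),),
                              covariates=("visit_time",),
                              subject_ids=("T001",)):
    """A PosteriorSamples whose draws are M copies of one fixed theta.

    With the parameters held fixed, external prediction reduces to a pure
    random-effects integral, which closed forms / grid integration can
    check exactly.
    """
    beta = np.asarray(beta, float)
    mu = np.asarray(mu, float)
    Sigma = np.asarray(Sigma, float)
    sigma2 = np.asarray(sigma2, float)
    K, p = beta.shape
    M = int(n_draws)
    N = len(subject_ids)
    return PosteriorSamples(
        beta=np.broadcast_to(beta, (M, K, p)).copy(),
        mu=np.broadcast_to(mu, (M, K)).copy(),
        Sigma=np.broadcast_to(Sigma, (M, K, K)).copy(),
        sigma2=np.broadcast_to(sigma2, (M, K)).copy(),
        gamma=np.broadcast_to(mu, (M, N, K)).copy(),
        chain=np.repeat(np.arange(2), M - M // 2)[:M],
        subject_ids=list(subject_ids),
        outcomes=tuple(tuple(o) for o in outcomes),
        covariates=tuple(covariates),
        correlation_mode="multivariate",
        shift=np.zeros(K),
        scale=np.ones(K),
    )


def make_k1_dataset(n_subjects=80, n_visits=4, beta=(0.4, -1.0), mu=5.0,
                    tau=2.0, sigma=1.5, seed=0):
    """Hand-built K=1 Gaussian random-intercept dataset (covariates t, x1)."""
    rng = np.random.default_rng(seed)
    rows, subs = [], []
    for i in range(n_subjects):
        sid = f"U{i:03d}"
        subs.append({"subject_id": sid})
        g = mu + tau * rng.standard_normal()
        for j in range(n_visits):
            t = float(j)
            x1 = rng.standard_normal()
            y = beta[0] * t + beta[1] * x1 + g + sigma * rng.standard_normal()
            rows.append({"subject_id": sid, "visit_time": t, "x1": x1, "Y1": y})
    return CohortDataset(subjects=pd.DataFrame(subs), visits=pd.DataFrame(rows))
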