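"""Model specification, fitting mechanics, posterior store and summaries."""

import numpy as np
import pandas as pd
import pytest

from mvglmm.cohort import CohortDataset, ConfigurationError, DataError
from mvglmm.model import (
    BayesianMGLMM, MCMCConfig, ModelSpec, PosteriorSamples,
    cross_outcome_correlation, fit_mglmm, log_likelihood_terms,
    summarize_posterior,
)

from conftest import make_k1_dataset


def test_modelspec_validation():
    with pytest.raises(ConfigurationError):
        ModelSpec(outcomes=())
    with pytest.raises(ConfigurationError):
        ModelSpec(outcomes=(("Y1", "poisson"),))
    with pytest.raises(ConfigurationError):
        ModelSpec(correlation_mode="mixed")


def test_mcmcconfig_validation():
    with pytest.raises(ConfigurationError):
        MCMCConfig(n_keep=0)
    with pytest.raises(ConfigurationError):
        MCMCConfig(n_burnin=-1)
    MCMCConfig(n_burnin=0)     # zero burn-in is legal


def test_estimator_is_sklearn_compatible(small_post):
    est = BayesianMGLMM(n_burnin=5, n_keep=5, thin=1, seed=1)
    params = est.get_params()
    assert params["n_keep"] == 5
    est.set_params(n_keep=7)
    assert est.get_params()["n_keep"] == 7
    assert not hasattr(est, "posterior_")      # unfitted


def test_posterior_shapes(small_post, split_cohort):
    n_train = len(split_cohort.subject_ids("train"))
    M = small_post.n_draws
    assert small_post.beta.shape == (M, 3, 8)
    assert small_post.mu.shape == (M, 3)
    assert small_post.Sigma.shape == (M, 3, 3)
    assert small_post.gamma.shape == (M, n_train, 3)
    assert small_post.n_chains == 2
    assert M == 500
    # sigma2 defined for the two Gaussian outcomes, NaN for the Bernoulli
    assert np.all(np.isfinite(small_post.sigma2[:, :2]))
    assert np.all(np.isnan(small_post.sigma2[:, 2]))


def test_posterior_save_load_roundtrip(small_post, tmp_path):
    path = tmp_path / "post.npz"
    small_post.save(path)
    back = PosteriorSamples.load(path)
    assert np.allclose(back.beta, small_post.beta)
    assert np.allclose(back.gamma, small_post.gamma)
    assert np.allclose(back.sigma2, small_post.sigma2, equal_nan=True)
    assert back.outcomes == small_post.outcomes
    assert back.subject_ids == [str(s) for s in small_post.subject_ids]
    assert back.correlation_mode == "multivariate"


def test_unknown_subject_raises_helpfully(small_post):
    with pytest.raises(KeyError, match="external"):
        small_post.subject_index("NOT_A_SUBJECT")


def test_outcome_index(small_post):
    assert small_post.outcome_index("Y2") == 1
    assert small_post.outcome_index(0) == 0


def test_fit_only_uses_training_rows(small_post, split_cohort):
    train = set(split_cohort.subject_ids("train"))
    assert set(small_post.subject_ids) == {str(s) for s in train}


def test_missing_outcome_terms_tolerated(split_cohort):
    # blank out some outcome cells; fit must drop only those terms
    visits = split_cohort.visits.copy()
    visits.loc[visits.index[:5], "Y1"] = np.nan
    visits.loc[visits.index[5:8], "Y3"] = np.nan
    ds = CohortDataset(subjects=split_cohort.subjects, visits=visits,
                       constants=split_cohort.constants)
    post = fit_mglmm(ds, ModelSpec(),
                     MCMCConfig(n_burnin=20, n_keep=10, thin=1, n_chains=1, seed=0))
    assert post.n_draws == 10


def test_binary_outcome_validation(split_cohort):
    visits = split_cohort.visits.copy()
    visits["Y3"] = 2.0 * visits["Y3"] + 1.0      # values outside {0,1}
    ds = CohortDataset(subjects=split_cohort.subjects, visits=visits)
    with pytest.raises(DataError):
        fit_mglmm(ds, ModelSpec(), MCMCConfig(n_burnin=5, n_keep=5, thin=1,
                                              n_chains=1, seed=0))
    visits2 = split_cohort.visits.copy()
    visits2["Y3"] = 0.0                          # single class
    ds2 = CohortDataset(subjects=split_cohort.subjects, visits=visits2)
    with pytest.raises(DataError):
        fit_mglmm(ds2, ModelSpec(), MCMCConfig(n_burnin=5, n_keep=5, thin=1,
                                               n_chains=1, seed=0))


def test_missing_covariate_column(split_cohort):
    spec = ModelSpec(covariates=("visit_time", "no_such_column"))
    with pytest.raises(ConfigurationError, match="no_such_column"):
        fit_mglmm(split_cohort, spec, MCMCConfig(n_burnin=5, n_keep=5, thin=1,
                                                 n_chains=1, seed=0))


def test_fit_deterministic_given_seed(split_cohort):
    mcmc = MCMCConfig(n_burnin=30, n_keep=20, thin=1, n_chains=2, seed=99)
    a = fit_mglmm(split_cohort, ModelSpec(), mcmc)
    b = fit_mglmm(split_cohort, ModelSpec(), mcmc)
    assert np.allclose(a.beta, b.beta)
    assert np.allclose(a.Sigma, b.Sigma)


def test_k1_gaussian_fit_runs():
    ds = make_k1_dataset(n_subjects=30, seed=2)
    spec = ModelSpec(outcomes=(("Y1", "gaussian"),), covariates=("visit_time", "x1"))
    post = fit_mglmm(ds, spec, MCMCConfig(n_burnin=200, n_keep=200, thin=1,
                                          n_chains=2, seed=0))
    assert post.beta.shape == (400, 1, 2)
    assert np.all(np.isfinite(post.sigma2))


def test_summary_structure(small_post):
    s = summarize_posterior(small_post, force=True)
    assert {"outcome", "parameter", "median", "q2.5", "q97.5",
            "significant", "rhat", "ess"} <= set(s.columns)
    # per Gaussian outcome: intercept + 8 betas + sigma2 + Sigma_kk = 11
    assert (s["outcome"] == "Y1").sum() == 11
    assert (s["outcome"] == "Y3").sum() == 10       # no sigma2 row
    assert (s.loc[s["parameter"] == "sigma2", "median"] > 0).all()


def test_summary_significance_matches_interval(small_post):
    s = summarize_posterior(small_post, force=True)
    expect = (s["q2.5"] > 0) | (s["q97.5"] < 0)
    assert (s["significant"].astype(bool) == expect).all()


def test_psrf_gate_withholds_significance(small_post):
    # sabotage the chains so split-Rhat explodes
    bad = PosteriorSamples(
        beta=small_post.beta.copy(), mu=small_post.mu.copy(),
        Sigma=small_post.Sigma, sigma2=small_post.sigma2,
        gamma=small_post.gamma, chain=small_post.chain,
        subject_ids=small_post.subject_ids, outcomes=small_post.outcomes,
        covariates=small_post.covariates,
        correlation_mode=small_post.correlation_mode,
        shift=small_post.shift, scale=small_post.scale)
    bad.beta[bad.chain == 1] += 50.0
    with pytest.warns(UserWarning, match="PSRF"):
        s = summarize_posterior(bad)
    assert s["significant"].isna().all()
    s2 = summarize_posterior(bad, force=True)
    assert s2["significant"].notna().all()


def test_cross_outcome_correlation(small_post, small_post_uni):
    cc = cross_outcome_correlation(small_post)
    assert -1 <= cc["q2.5"] <= cc["median"] <= cc["q97.5"] <= 1
    assert not cc["degenerate"]
    with pytest.warns(UserWarning, match="univariate"):
        cu = cross_outcome_correlation(small_post_uni)
    assert cu == {"median": 0.0, "q2.5": 0.0, "q97.5": 0.0, "degenerate": True}


def test_log_likelihood_terms(small_post, split_cohort):
    theta = small_post.theta_draw(0)
    ll = log_likelihood_terms(split_cohort, ModelSpec(), theta["beta"],
                              small_post.gamma[0], theta["sigma2"],
                              subject_ids=small_post.subject_ids, role="train")
    assert set(ll["outcome"]) == {"Y1", "Y2", "Y3"}
    assert np.all(np.isfinite(ll["loglik"]))
    assert (ll["loglik"] <= 0).sum() > 0.9 * len(ll)    # densities mostly < 1

    # hand-check one Gaussian term
    frame = split_cohort.frame(role="train")
    row = frame.dropna(subset=["Y1"] + list(small_post.covariates)).iloc[0]
    x = np.array([row[c] for c in small_post.covariates], float)
    i = small_post.subject_ids.index(str(row["subject_id"]))
    lin = theta["beta"][0] @ x + small_post.gamma[0, i, 0]
    from scipy.stats import norm
    expect = norm.logpdf(row["Y1"], lin, np.sqrt(theta["sigma2"][0]))
    got = ll[(ll["subject_id"] == row["subject_id"]) & (ll["outcome"] == "Y1")]
    assert np.any(np.isclose(got["loglik"], expect, atol=1e-9))


def test_log_likelihood_nonfinite_guard(small_post, split_cohort):
    theta = small_post.theta_draw(0)
    bad_beta = theta["beta"].copy()
    bad_beta[0, 0] = np.inf
    with pytest.raises(FloatingPointError):
        log_likelihood_terms(split_cohort, ModelSpec(), bad_beta,
                             small_post.gamma[0], theta["sigma2"],
                             subject_ids=small_post.subject_ids, role="train")
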