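"""Dynamic prediction: internal/external machinery, exact conjugate math,
history handling, sequential tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mvglmm.cohort import ConfigurationError
from mvglmm.predict import (
    PredictionRequest, external_gamma_draws, predict_external,
    predict_internal, sample_new_subject_raneff, sequential_prediction_table,
)

from conftest import make_degenerate_posterior


def _gauss_post(M=40_000):
    return make_degenerate_posterior(
        beta=[[0.5]], mu=[10.0], Sigma=[[9.0]], sigma2=[4.0], n_draws=M)


def _hist(times, ys):
    return pd.DataFrame({"visit_time": times, "Y1": ys})


def _exact_gamma_posterior(theta_beta, mu, tau2, sigma2, times, ys):
    """Closed-form N(m, v) for gamma | Gaussian history at fixed theta."""
    times = np.asarray(times, float); ys = np.asarray(ys, float)
    resid = ys - theta_beta * times
    v = 1.0 / (1.0 / tau2 + len(ys) / sigma2)
    m = v * (mu / tau2 + resid.sum() / sigma2)
    return m, v


# -- internal mode -----------------------------------------------------------

def test_internal_gaussian_matches_hand_computation():
    post = _gauss_post(M=200_000)
    req = PredictionRequest("T001", "Y1", 12.0, {"visit_time": 12.0})
    res = predict_internal(post, req, seed=0)
    # degenerate posterior: lin = 0.5*12 + gamma(=mu=10) = 16, noise sd 2
    assert res.point == pytest.approx(16.0, abs=0.03)
    assert res.lo95 == pytest.approx(16.0 - 1.96 * 2.0, abs=0.05)
    assert res.hi95 == pytest.approx(16.0 + 1.96 * 2.0, abs=0.05)


def test_internal_unknown_subject(small_post):
    req = PredictionRequest("GHOST", "Y1", 36.0,
                            {c: 0.0 for c in small_post.covariates})
    with pytest.raises(KeyError):
        predict_internal(small_post, req)


def test_internal_missing_covariate(small_post):
    sid = small_post.subject_ids[0]
    with pytest.raises(ConfigurationError, match="covariate"):
        predict_internal(small_post, PredictionRequest(sid, "Y1", 36.0,
                                                       {"visit_time": 36.0}))


def test_internal_real_fit_draws(small_post, split_cohort):
    sid = small_post.subject_ids[0]
    frame = split_cohort.frame()
    row = frame[frame["subject_id"] == sid].iloc[0]
    cov = {c: float(row[c]) for c in small_post.covariates}
    res = predict_internal(small_post, PredictionRequest(sid, "Y1", 36.0, cov), seed=1)
    assert len(res.draws) == small_post.n_draws
    assert res.lo95 < res.point < res.hi95
    res3 = predict_internal(small_post, PredictionRequest(sid, "Y3", 36.0, cov), seed=1)
    assert 0.0 <= res3.lo95 <= res3.point <= res3.hi95 <= 1.0
    assert set(np.unique(res3.draws)) <= {0.0, 1.0}
    assert "bernoulli_lo95" in res3.extra


# -- external mode: exact conjugate updating ---------------------------------

def test_external_gaussian_conjugate_closed_form():
    post = _gauss_post(M=400_000)
    times, ys = [0.0, 6.0], [12.0, 14.0]
    m, v = _exact_gamma_posterior(0.5, 10.0, 9.0, 4.0, times, ys)
    g = external_gamma_draws(post, _hist(times, ys), target_time=12.0, seed=3)
    assert g.shape == (post.n_draws, 1)
    assert g.mean() == pytest.approx(m, abs=0.01)
    assert g.var() == pytest.approx(v, rel=0.02)


def test_external_history_strictly_before_target():
    post = _gauss_post(M=150_000)
    # third visit sits exactly at the target time; it must be ignored
    with_at = external_gamma_draws(post, _hist([0.0, 6.0, 12.0], [12.0, 14.0, 99.0]),
                                   target_time=12.0, seed=4)
    without = external_gamma_draws(post, _hist([0.0, 6.0], [12.0, 14.0]),
                                   target_time=12.0, seed=4)
    assert with_at.mean() == pytest.approx(without.mean(), abs=0.02)
    m, _ = _exact_gamma_posterior(0.5, 10.0, 9.0, 4.0, [0.0, 6.0], [12.0, 14.0])
    assert with_at.mean() == pytest.approx(m, abs=0.02)


def test_external_more_history_shrinks_gamma_spread():
    post = _gauss_post(M=100_000)
    g1 = external_gamma_draws(post, _hist([0.0], [12.0]), target_time=40.0, seed=5)
    g2 = external_gamma_draws(post, _hist([0.0, 6.0, 12.0], [12.0, 14.0, 15.0]),
                              target_time=40.0, seed=5)
    assert g2.var() < g1.var()


def test_external_empty_history_prior_fallback():
    post = _gauss_post(M=100_000)
    with pytest.warns(UserWarning, match="empty"):
        g = external_gamma_draws(post, _hist([], []), target_time=12.0, seed=6)
    assert g.mean() == pytest.approx(10.0, abs=0.05)
    assert g.var() == pytest.approx(9.0, rel=0.03)


def test_external_missing_history_raises():
    post = _gauss_post(M=100)
    req = PredictionRequest("X", "Y1", 12.0, {"visit_time": 12.0}, mode="external")
    with pytest.raises(ConfigurationError, match="history"):
        predict_external(post, req)


def test_external_mixed_binary_history_moves_gamma():
    # bernoulli-only history: observing y=1 at every visit must pull the
    # random effect above its prior mean
    post = make_degenerate_posterior(
        beta=[[0.0]], mu=[0.0], Sigma=[[4.0]], sigma2=[np.nan],
        outcomes=(("Y3", "bernoulli"),), n_draws=3000)
    hist = pd.DataFrame({"visit_time": [0.0, 6.0, 12.0], "Y3": [1.0, 1.0, 1.0]})
    g = external_gamma_draws(post, hist, target_time=24.0, seed=7)
    assert g.mean() > 0.5
    hist0 = pd.DataFrame({"visit_time": [0.0, 6.0, 12.0], "Y3": [0.0, 0.0, 0.0]})
    g0 = external_gamma_draws(post, hist0, target_time=24.0, seed=7)
    assert g0.mean() < -0.5


def test_sample_new_subject_raneff_single_draw():
    post = _gauss_post(M=10)
    theta = post.theta_draw(0)
    g = sample_new_subject_raneff(post, theta, _hist([0.0], [12.0]),
                                  rng=np.random.default_rng(0), target_time=6.0)
    assert g.shape == (1,)
    assert np.isfinite(g).all()


def test_gamma_draw_reuse(small_post, split_cohort):
    sid = split_cohort.subject_ids("test")[0]
    frame = split_cohort.frame()
    sub = frame[frame["subject_id"] == sid]
    hist = sub[sub["visit_time"] <= 0.0]
    cov = {c: float(sub.iloc[0][c]) for c in small_post.covariates}
    cov["visit_time"] = 18.0
    g = external_gamma_draws(small_post, hist, target_time=0.5, seed=8)
    req = PredictionRequest(sid, "Y1", 18.0, cov, mode="external", history=hist)
    a = predict_external(small_post, req, seed=9, gamma_draws=g)
    b = predict_external(small_post, req, seed=9, gamma_draws=g)
    assert np.allclose(a.draws, b.draws)


# -- sequential tables -------------------------------------------------------

@pytest.fixture(scope="module")
def seq_table(small_post, split_cohort):
    return sequential_prediction_table(small_post, split_cohort, seed=21)


def test_sequential_table_structure(seq_table, split_cohort):
    t = seq_table
    assert {"subject_id", "outcome", "horizon_months", "history_window",
            "predicted", "lo95", "hi95", "observed", "covered"} <= set(t.columns)
    test_ids = set(map(str, split_cohort.subject_ids("test")))
    assert set(t["subject_id"].astype(str)) <= test_ids
    # 18-month horizon: baseline window only; 36-month: baseline and
    # baseline+18 windows; 3 outcomes each
    per_subj = t.groupby("subject_id").size().unique()
    assert list(per_subj) == [9]
    assert set(t["history_window"]) == {"baseline", "baseline+18"}
    h36 = t[t["horizon_months"] == 36.0]
    assert set(h36["history_window"]) == {"baseline", "baseline+18"}


def test_sequential_table_intervals_and_coverage_flags(seq_table):
    t = seq_table
    assert (t["lo95"] <= t["hi95"]).all()
    y3 = t[t["outcome"] == "Y3"]
    assert y3["predicted"].between(0, 1).all()
    obs = t.dropna(subset=["observed"])
    assert set(obs["covered"].astype(float).unique()) <= {0.0, 1.0}


def test_sequential_table_deterministic(small_post, split_cohort, seq_table):
    again = sequential_prediction_table(small_post, split_cohort, seed=21)
    pd.testing.assert_frame_equal(seq_table, again)


def test_sequential_table_horizon_validation(small_post, split_cohort):
    with pytest.raises(ConfigurationError):
        sequential_prediction_table(small_post, split_cohort,
                                    horizons=[36.0, 18.0], seed=0)
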