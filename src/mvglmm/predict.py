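"""Dynamic prediction of future visits from a fitted multivariate GLMM.

Two regimes:

* **internal** — the subject was in the training set, so their random
  intercepts ``gamma_i^(m)`` are already part of the posterior draws; each
  retained draw is plugged into the mean model and, for Gaussian outcomes,
  residual noise is added.
* **external** — a new subject: for each retained parameter draw
  ``Theta^(m)`` the random intercepts are drawn from their conditional
  posterior ``f(gamma | history, Theta^(m))`` — exact conjugate normal when
  the outcome history is Gaussian-only; with binary history terms the draw
  is still exact, via rejection sampling: propose from the Gaussian-part
  conditional and accept with the Bernoulli likelihood product (which is
  bounded by 1, so no envelope constant is needed).  Rare stubborn draws
  fall back to Polya-Gamma Gibbs sweeps.

Outcome values observed strictly before the target time form the history;
covariates at the target time are taken as known.  Intervals are
equal-tailed 2.5%/97.5% quantiles of the predictive draws.  For binary
outcomes the headline point value and interval summarize the predictive
probabilities ``logit^-1(eta^(m))``; the Bernoulli 0/1 draws are also kept.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit

from ._polyagamma import sample_pg1
from .cohort import CohortDataset, ConfigurationError
from .model import PosteriorSamples

__all__ = [
    "PredictionRequest", "PredictionResult", "predict_internal",
    "predict_external", "sample_new_subject_raneff",
    "sequential_prediction_table",
]


@dataclass
class PredictionRequest:
    """What to predict: subject, outcome, target time and covariates there.

    ``history`` (external mode) is a long-format frame of this subject's
    visits: ``visit_time``, outcome columns, covariate columns.  Outcome
    values at or after ``target_time`` are ignored (strictly-before rule).
    """

    subject_id: str
    outcome: str | int
    target_time: float
    covariates: dict
    mode: str = "internal"
    history: pd.DataFrame | None = None


@dataclass
class PredictionResult:
    """Posterior predictive draws and their equal-tailed 95% summary."""

    outcome: str
    target_time: float
    draws: np.ndarray                    # predicted values Y^(m)(t')
    point: float                         # mean of draws (probability for binary)
    lo95: float
    hi95: float
    prob_draws: np.ndarray | None = None  # binary only: p^(m)
    extra: dict = field(default_factory=dict)


def _x_vector(samples: PosteriorSamples, covariates: dict) -> np.ndarray:
    try:
        return np.array([float(covariates[c]) for c in samples.covariates])
    except KeyError as e:
        raise ConfigurationError(f"covariate {e.args[0]!r} missing from request") from None


def _summarize(samples, k, lin, rng, clamp, target_time) -> PredictionResult:
    name, fam = samples.outcomes[k]
    if fam == "gaussian":
        eps = rng.standard_normal(len(lin)) * np.sqrt(samples.sigma2[:, k])
        draws = lin + eps
        if clamp:
            draws = np.clip(np.round(draws), 0, 52)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        return PredictionResult(name, target_time, draws, float(draws.mean()),
                                float(lo), float(hi))
    prob = expit(lin)
    draws = (rng.random(len(lin)) < prob).astype(float)
    lo, hi = np.quantile(prob, [0.025, 0.975])
    blo, bhi = np.quantile(draws, [0.025, 0.975])
    return PredictionResult(
        name, target_time, draws, float(prob.mean()), float(lo), float(hi),
        prob_draws=prob,
        extra={"bernoulli_mean": float(draws.mean()),
               "bernoulli_lo95": float(blo), "bernoulli_hi95": float(bhi)},
    )


def predict_internal(samples: PosteriorSamples, request: PredictionRequest,
                     seed: int = 0, clamp: bool = False) -> PredictionResult:
    """Procedure I: plug each draw's ``beta^(m)`` and stored ``gamma^(m)``
    into the mean model at the target time."""
    k = samples.outcome_index(request.outcome)
    i = samples.subject_index(request.subject_id)   # raises for unknown subject
    x = _x_vector(samples, request.covariates)
    rng = np.random.default_rng(seed)
    lin = samples.beta[:, k, :] @ x + samples.gamma[:, i, k]
    return _summarize(samples, k, lin, rng, clamp, request.target_time)


# ---------------------------------------------------------------------------
# external mode: random effects for a new subject
# ---------------------------------------------------------------------------

def _history_design(samples: PosteriorSamples, history: pd.DataFrame,
                    target_time: float | None):
    """Per-outcome (y, X) arrays from a subject's history (strictly before
    the target time), visit-level complete-case in the covariates."""
    hist = history.copy()
    if target_time is not None:
        hist = hist[hist["visit_time"].astype(float) < float(target_time)]
    if len(hist) == 0:
        return {}
    X = np.column_stack([hist[c].to_numpy(float) for c in samples.covariates])
    cov_ok = ~np.isnan(X).any(axis=1)
    design = {}
    for k, (name, fam) in enumerate(samples.outcomes):
        if name not in hist.columns:
            continue
        y = hist[name].to_numpy(float)
        mask = cov_ok & ~np.isnan(y)
        if mask.any():
            design[k] = (y[mask], X[mask])
    return design


def _gamma_sweep(theta, design, families, gamma, rng):
    """One Gibbs sweep of gamma | history, Theta (Polya-Gamma for logits)."""
    K = len(theta["mu"])
    Siginv = np.linalg.inv(theta["Sigma"])
    d = np.zeros(K)
    b = np.zeros(K)
    for k, (y, X) in design.items():
        lin = X @ theta["beta"][k]
        if families[k] == "gaussian":
            d[k] += len(y) / theta["sigma2"][k]
            b[k] += np.sum(y - lin) / theta["sigma2"][k]
        else:
            psi = lin + gamma[k]
            om = sample_pg1(rng, psi)
            d[k] += om.sum()
            b[k] += np.sum(y - 0.5 - om * lin)
    prec = Siginv + np.diag(d)
    rhs = Siginv @ theta["mu"] + b
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(K)
    return mean + solve_triangular(L, z, lower=True, trans="T")


def sample_new_subject_raneff(samples: PosteriorSamples, theta_draw: dict,
                              history: pd.DataFrame, rng=None,
                              target_time: float | None = None,
                              n_sweeps: int = 10,
                              gamma_init: np.ndarray | None = None) -> np.ndarray:
    """One draw from ``f(gamma_l | history, Theta^(m))``.

    Exact conjugate normal for Gaussian-only histories; with binary history
    terms, exact rejection sampling (Gaussian-part proposal, Bernoulli
    likelihood acceptance) with a Polya-Gamma Gibbs fallback of
    ``n_sweeps`` sweeps from ``gamma_init`` (defaults to mu) if rejection
    stalls.  With an empty history the draw falls back to the prior
    ``MVN(mu^(m), Sigma^(m))``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    design = _history_design(samples, history, target_time)
    families = samples.families
    theta = theta_draw
    if not design:
        warnings.warn("empty outcome history; drawing random effects from the prior")
        return rng.multivariate_normal(theta["mu"], theta["Sigma"], method="svd")
    K = len(theta["mu"])
    gauss_design = {k: v for k, v in design.items() if families[k] == "gaussian"}
    bern_design = {k: v for k, v in design.items() if families[k] == "bernoulli"}

    # Gaussian-part conjugate conditional N(mean, prec^-1)
    Siginv = np.linalg.inv(theta["Sigma"])
    d = np.zeros(K)
    b = np.zeros(K)
    for k, (y, X) in gauss_design.items():
        lin = X @ theta["beta"][k]
        d[k] += len(y) / theta["sigma2"][k]
        b[k] += np.sum(y - lin) / theta["sigma2"][k]
    prec = Siginv + np.diag(d)
    rhs = Siginv @ theta["mu"] + b
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)

    def _propose(n):
        z = rng.standard_normal((K, n))
        return mean[:, None] + solve_triangular(L, z, lower=True, trans="T")

    if not bern_design:
        return _propose(1)[:, 0]

    # rejection: accept with the Bernoulli likelihood product (<= 1)
    for _ in range(200):
        prop = _propose(64)                             # (K, 64)
        logacc = np.zeros(64)
        for k, (y, X) in bern_design.items():
            psi = (X @ theta["beta"][k])[:, None] + prop[k][None, :]
            logacc += (y[:, None] * psi - np.logaddexp(0.0, psi)).sum(axis=0)
        hit = np.log(rng.random(64)) < logacc
        if hit.any():
            return prop[:, int(np.argmax(hit))]

    # extremely unlikely binary history: Polya-Gamma Gibbs fallback
    gamma = np.array(theta["mu"], float) if gamma_init is None else np.array(gamma_init, float)
    for _ in range(max(1, n_sweeps)):
        gamma = _gamma_sweep(theta, design, families, gamma, rng)
    return gamma


def _external_gamma_draws(samples: PosteriorSamples, history: pd.DataFrame,
                          target_time: float | None, rng,
                          max_rounds: int = 500) -> np.ndarray:
    """gamma_l^(m) for every retained draw m -> (M, K)."""
    design = _history_design(samples, history, target_time)
    M = samples.n_draws
    K = samples.mu.shape[1]
    families = samples.families
    if not design:
        warnings.warn("empty outcome history; drawing random effects from the prior")
        L = np.linalg.cholesky(samples.Sigma + 1e-12 * np.eye(K)[None])
        z = rng.standard_normal((M, K, 1))
        return samples.mu + (L @ z)[..., 0]

    gauss_design = {k: v for k, v in design.items() if families[k] == "gaussian"}
    bern_design = {k: v for k, v in design.items() if families[k] == "bernoulli"}

    # Gaussian-part conditional N(mean_m, prec_m^-1), vectorized over draws
    Siginv = np.linalg.inv(samples.Sigma)                # (M,K,K)
    D = np.zeros((M, K))
    B = np.zeros((M, K))
    for k, (y, X) in gauss_design.items():
        lin = samples.beta[:, k, :] @ X.T                # (M, n)
        s2 = samples.sigma2[:, k]
        D[:, k] += len(y) / s2
        B[:, k] += (y[None, :] - lin).sum(axis=1) / s2
    prec = Siginv.copy()
    idx = np.arange(K)
    prec[:, idx, idx] += D
    rhs = (Siginv @ samples.mu[..., None])[..., 0] + B
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    Lt = np.swapaxes(L, -1, -2)

    if not bern_design:
        z = rng.standard_normal((M, K, 1))
        return mean + np.linalg.solve(Lt, z)[..., 0]

    # exact rejection sampling per draw, vectorized over the still-active set
    lin_b = {k: samples.beta[:, k, :] @ X.T for k, (y, X) in bern_design.items()}
    out = np.empty((M, K))
    active = np.ones(M, dtype=bool)
    for _ in range(max_rounds):
        a = np.nonzero(active)[0]
        z = rng.standard_normal((len(a), K, 1))
        prop = mean[a] + np.linalg.solve(Lt[a], z)[..., 0]
        logacc = np.zeros(len(a))
        for k, (y, X) in bern_design.items():
            psi = lin_b[k][a] + prop[:, k][:, None]      # (n_active, n_obs)
            logacc += (y[None, :] * psi - np.logaddexp(0.0, psi)).sum(axis=1)
        hit = np.log(rng.random(len(a))) < logacc
        out[a[hit]] = prop[hit]
        active[a[hit]] = False
        if not active.any():
            break
    # any stragglers (pathologically unlikely binary history for that draw):
    # fall back to Polya-Gamma Gibbs sweeps
    for m in np.nonzero(active)[0]:
        out[m] = sample_new_subject_raneff(
            samples, samples.theta_draw(m), history, rng,
            target_time=target_time, n_sweeps=20)
    return out


def predict_external(samples: PosteriorSamples, request: PredictionRequest,
                     seed: int = 0, clamp: bool = False,
                     gamma_draws: np.ndarray | None = None) -> PredictionResult:
    """Procedure II: draw random effects from their conditional posterior
    given the subject's history, then predict as in internal mode.

    ``gamma_draws`` allows reuse of the (M, K) random-effect draws across
    outcomes/horizons sharing one history.
    """
    if request.history is None:
        raise ConfigurationError("external prediction needs a history frame")
    k = samples.outcome_index(request.outcome)
    x = _x_vector(samples, request.covariates)
    rng = np.random.default_rng(seed)
    if gamma_draws is None:
        gamma_draws = _external_gamma_draws(samples, request.history,
                                            request.target_time, rng)
    lin = samples.beta[:, k, :] @ x + gamma_draws[:, k]
    return _summarize(samples, k, lin, rng, clamp, request.target_time)


def external_gamma_draws(samples: PosteriorSamples, history: pd.DataFrame,
                         target_time: float | None = None, seed: int = 0) -> np.ndarray:
    """Public handle on the per-draw external random effects (M, K)."""
    rng = np.random.default_rng(seed)
    return _external_gamma_draws(samples, history, target_time, rng)


# ---------------------------------------------------------------------------
# sequential prediction tables (Table-3 style)
# ---------------------------------------------------------------------------

def _covariates_at(sub_frame: pd.DataFrame, covariates, t: float) -> dict:
    """Covariate vector at time t: the observed row there, else last
    observation carried forward with visit_time reset to t."""
    rows = sub_frame[sub_frame["visit_time"] == t]
    if len(rows) == 0:
        before = sub_frame[sub_frame["visit_time"] < t]
        if len(before) == 0:
            raise ConfigurationError(f"no covariates available at or before t={t}")
        rows = before.sort_values("visit_time").iloc[[-1]]
    row = rows.iloc[0]
    cov = {c: row[c] for c in covariates if c != "visit_time"}
    cov["visit_time"] = float(t)
    return cov


def sequential_prediction_table(samples: PosteriorSamples,
                                dataset: CohortDataset,
                                subject_ids=None,
                                horizons=None,
                                seed: int = 0,
                                clamp: bool = False) -> pd.DataFrame:
    """External predictions for each subject x outcome x horizon x history
    window, with observed values and interval-coverage flags.

    History windows are cumulative: for a horizon ``h`` every visit time
    ``c < h`` defines a window of visits at times ``<= c`` (e.g., at 36
    months: baseline-only, then baseline+18-month).
    """
    if subject_ids is None:
        subject_ids = dataset.subject_ids("test")
    frame = dataset.frame()
    times = np.sort(frame["visit_time"].unique())
    if horizons is None:
        horizons = [t for t in times if t > times[0]]
    if np.any(np.diff(np.asarray(horizons, float)) <= 0):
        raise ConfigurationError("horizons must strictly increase")

    rows = []
    rng_master = np.random.SeedSequence(seed)
    for sid, ss in zip(subject_ids, rng_master.spawn(len(subject_ids))):
        sub = frame[frame["subject_id"] == sid]
        child = ss.spawn(len(times) + 1)
        gamma_cache = {}
        for h in horizons:
            cuts = [t for t in times if t < h]
            for cut in cuts:
                if cut not in gamma_cache:
                    ci = int(np.searchsorted(times, cut))
                    hist = sub[sub["visit_time"] <= cut]
                    rng = np.random.default_rng(child[ci])
                    gamma_cache[cut] = _external_gamma_draws(
                        samples, hist, target_time=cut + 1e-9, rng=rng)
                label = ("baseline" if cut == times[0] else
                         "baseline+" + "+".join(str(int(t)) for t in times
                                                if times[0] < t <= cut))
                cov = _covariates_at(sub, samples.covariates, h)
                for name, fam in samples.outcomes:
                    req = PredictionRequest(sid, name, float(h), cov,
                                            mode="external",
                                            history=sub[sub["visit_time"] <= cut])
                    sid_key = zlib.crc32(str(sid).encode()) % (2 ** 31)
                    res = predict_external(
                        samples, req,
                        seed=np.random.SeedSequence(
                            [seed, sid_key, int(h), int(cut)]).generate_state(1)[0],
                        clamp=clamp, gamma_draws=gamma_cache[cut])
                    obs_rows = sub[sub["visit_time"] == h]
                    obs = float(obs_rows[name].iloc[0]) if len(obs_rows) and not np.isnan(
                        obs_rows[name].iloc[0]) else np.nan
                    # binary outcomes: coverage of the 0/1 observation is
                    # judged against the Bernoulli predictive interval, not
                    # the probability interval reported in lo95/hi95
                    if fam == "bernoulli":
                        c_lo = res.extra["bernoulli_lo95"]
                        c_hi = res.extra["bernoulli_hi95"]
                    else:
                        c_lo, c_hi = res.lo95, res.hi95
                    covered = (c_lo <= obs <= c_hi) if np.isfinite(obs) else np.nan
                    rows.append({
                        "subject_id": sid, "outcome": name,
                        "horizon_months": float(h), "history_window": label,
                        "predicted": res.point, "lo95": res.lo95,
                        "hi95": res.hi95, "observed": obs, "covered": covered,
                    })
    return pd.DataFrame(rows)
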