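"""Gibbs sampler core for the hierarchically centered multivariate GLMM.

Model (per outcome k, subject i, visit j), on the internally shifted/scaled
outcome scale:

    gaussian :  y_ikj = x_ikj' beta_k + gamma_ik + eps,  eps ~ N(0, sigma2_k)
    bernoulli:  logit P(y_ikj = 1) = x_ikj' beta_k + gamma_ik

    gamma_i = (gamma_i1..gamma_iK)' ~ MVN(mu, Sigma)

The fixed design ``x`` carries no constant column; the population intercept
is mu_k (hierarchical centering).

Blocking.  Covariates with little or no within-subject variation (age at
baseline, gender, subject-stable clinical scores) are near-confounded with
the random intercepts, so the naive one-block-at-a-time scheme mixes
catastrophically slowly.  Conditional on the Polya-Gamma latents the whole
model is linear-Gaussian, which allows a collapsed update: each sweep draws

    1. omega | beta, gamma                (Polya-Gamma, logistic terms)
    2. (beta_1..beta_K, mu) | omega, sigma2, Sigma   -- gamma integrated
       out analytically via a per-subject Woodbury correction
    3. gamma | beta, mu, omega, sigma2, Sigma        (conjugate MVN)
    4. sigma2 | beta, gamma               (conjugate gamma on precisions)
    5. Sigma^-1 | gamma, mu               (Wishart; diagonal-constrained
                                           per-block gammas in univariate mode)

Steps 2-3 jointly draw (theta, gamma) from their exact conditional, so the
scheme targets the exact posterior while mixing essentially like the
marginal sampler.  In univariate mode Sigma is constrained diagonal (zero
cross-outcome correlation), which factorizes the model into K separate
fits while sharing this code path.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ._polyagamma import sample_pg1

__all__ = ["run_gibbs", "sample_wishart", "default_prior"]


def default_prior(K: int) -> dict:
    """Vague conjugate priors on the shifted-scaled parameterization."""
    return {
        "beta_var": 1e4,          # beta_k ~ N(0, beta_var I)
        "mu_var": 1e4,            # mu ~ N(0, mu_var I)
        "wishart_df": K + 1,      # Sigma^-1 ~ Wishart(df, scale)
        "wishart_scale": np.eye(K),
        "sigma2_shape": 1.0,      # sigma_k^-2 ~ Gamma(shape, rate)
        "sigma2_rate": 0.005,
    }


def sample_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """One Wishart(df, scale) draw via the Bartlett decomposition."""
    K = scale.shape[0]
    L = np.linalg.cholesky(scale)
    A = np.zeros((K, K))
    for i in range(K):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    T = L @ A
    return T @ T.T


def _sample_mvn_prec(rng, prec: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Draw from MVN with given precision matrix and precision*mean = rhs."""
    c, low = cho_factor(prec, lower=True)
    mean = cho_solve((c, low), rhs)
    z = rng.standard_normal(len(rhs))
    return mean + solve_triangular(c, z, lower=True, trans="T")


def _sample_mvn_prec_batch(rng, prec: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Batched version: prec (N,K,K), rhs (N,K) -> draws (N,K)."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    z = rng.standard_normal(rhs.shape)
    x = np.linalg.solve(np.swapaxes(L, -1, -2), z[..., None])[..., 0]
    return mean + x


def run_gibbs(ys, Xs, subjs, families, N, *, n_burnin, n_keep, thin,
              rng, prior, init, univariate=False):
    """Run one MCMC chain; return retained (thinned) draws.

    Parameters
    ----------
    ys, Xs, subjs
        Per-outcome observed values, fixed designs (no constant column),
        and subject indices in ``0..N-1``; missing terms simply absent.
    families
        ``"gaussian"`` or ``"bernoulli"`` per outcome.
    init
        Starting state: ``beta`` (K,p), ``mu`` (K,), ``gamma`` (N,K),
        ``Sigma`` (K,K), ``sigma2`` (K,).
    univariate
        Constrain Sigma to be diagonal (zero cross-outcome correlation).

    Returns
    -------
    dict with stacked arrays ``beta`` (M,K,p), ``mu`` (M,K), ``Sigma``
    (M,K,K), ``sigma2`` (M,K), ``gamma`` (M,N,K); M = ``n_keep``.
    """
    K = len(ys)
    p = Xs[0].shape[1]
    P = K * p + K                      # theta = (beta_1..beta_K, mu)
    gauss = [k for k in range(K) if families[k] == "gaussian"]
    bern = [k for k in range(K) if families[k] == "bernoulli"]

    beta = np.array(init["beta"], dtype=float)
    mu = np.array(init["mu"], dtype=float)
    gamma = np.array(init["gamma"], dtype=float)
    Sigma = np.array(init["Sigma"], dtype=float)
    sigma2 = np.array(init["sigma2"], dtype=float)
    Siginv = np.linalg.inv(Sigma)
    if univariate:
        Siginv = np.diag(np.diag(Siginv))

    theta_prior_prec = np.concatenate([
        np.full(K * p, 1.0 / prior["beta_var"]),
        np.full(K, 1.0 / prior["mu_var"]),
    ])
    df_post = prior["wishart_df"] + N
    S0inv = np.linalg.inv(prior["wishart_scale"])
    idxK = np.arange(K)

    n_total = n_burnin + n_keep * thin
    out = {
        "beta": np.empty((n_keep, K, p)),
        "mu": np.empty((n_keep, K)),
        "Sigma": np.empty((n_keep, K, K)),
        "sigma2": np.full((n_keep, K), np.nan),
        "gamma": np.empty((n_keep, N, K)),
    }
    kept = 0

    def _refresh(beta, mu, gamma, sigma2, Siginv):
        """Steps 1-3: omega | state, then the collapsed (theta, gamma)."""
        # -- 1. Polya-Gamma latents for logistic outcomes ------------------
        omegas = {}
        for k in bern:
            psi = Xs[k] @ beta[k] + gamma[subjs[k], k]
            omegas[k] = sample_pg1(rng, psi)

        # working weights w and weighted pseudo-responses w*ytilde per term:
        # gaussian: w = 1/sigma2, w*ytilde = y/sigma2
        # bernoulli (given omega): w = omega, w*ytilde = y - 1/2
        wts, wy = [], []
        for k in range(K):
            if families[k] == "gaussian":
                wts.append(np.full(len(ys[k]), 1.0 / sigma2[k]))
                wy.append(ys[k] / sigma2[k])
            else:
                wts.append(omegas[k])
                wy.append(ys[k] - 0.5)

        # per-subject sufficient statistics
        D = np.zeros((N, K))               # sum of weights
        U = np.zeros((N, K))               # sum of w*ytilde
        G = np.zeros((N, K, p))            # sum of w*x
        for k in range(K):
            D[:, k] = np.bincount(subjs[k], weights=wts[k], minlength=N)
            U[:, k] = np.bincount(subjs[k], weights=wy[k], minlength=N)
            np.add.at(G[:, k, :], subjs[k], Xs[k] * wts[k][:, None])

        # -- 2. theta = (beta, mu) with gamma integrated out ---------------
        # Marginal precision: full-data GLS blocks minus the Woodbury
        # correction J_i M_i J_i', with M_i = (Sigma^-1 + diag(D_i))^-1.
        Pm = np.diag(theta_prior_prec.copy())
        rhs = np.zeros(P)
        for k in range(K):
            sl = slice(k * p, (k + 1) * p)
            Pm[sl, sl] += (Xs[k] * wts[k][:, None]).T @ Xs[k]
            gk = G[:, k, :].sum(axis=0)
            Pm[sl, K * p + k] += gk
            Pm[K * p + k, sl] += gk
            Pm[K * p + k, K * p + k] += D[:, k].sum()
            rhs[sl] += Xs[k].T @ wy[k]
            rhs[K * p + k] += wy[k].sum()
        M = np.linalg.inv(np.broadcast_to(Siginv, (N, K, K))
                          + D[:, None, :] * np.eye(K)[None])     # (N,K,K)
        J = np.zeros((N, P, K))
        for k in range(K):
            J[:, k * p:(k + 1) * p, k] = G[:, k, :]
            J[:, K * p + k, k] = D[:, k]
        Pm -= np.einsum("npk,nkl,nql->pq", J, M, J, optimize=True)
        rhs -= np.einsum("npk,nkl,nl->p", J, M, U, optimize=True)
        theta = _sample_mvn_prec(rng, Pm, rhs)
        beta = theta[:K * p].reshape(K, p)
        mu = theta[K * p:]

        # -- 3. random intercepts gamma_i | theta --------------------------
        B = U - np.einsum("nkp,kp->nk", G, beta)
        prec = np.broadcast_to(Siginv, (N, K, K)).copy()
        prec[:, idxK, idxK] += D
        rhs_g = (Siginv @ mu)[None, :] + B
        gamma = _sample_mvn_prec_batch(rng, prec, rhs_g)
        return beta, mu, gamma

    # With logistic outcomes the Polya-Gamma layer dominates the
    # autocorrelation, so the (omega, theta, gamma) blocks are refreshed
    # twice per sweep.
    n_refresh = 2 if bern else 1

    for it in range(n_total):
        for _ in range(n_refresh):
            beta, mu, gamma = _refresh(beta, mu, gamma, sigma2, Siginv)

        # -- 4. residual variances -----------------------------------------
        for k in gauss:
            resid = ys[k] - Xs[k] @ beta[k] - gamma[subjs[k], k]
            shape = prior["sigma2_shape"] + 0.5 * len(resid)
            rate = prior["sigma2_rate"] + 0.5 * resid @ resid
            sigma2[k] = 1.0 / rng.gamma(shape, 1.0 / rate)

        # -- 5. random-intercept covariance --------------------------------
        dev = gamma - mu
        S = dev.T @ dev
        if univariate:
            Siginv = np.zeros((K, K))
            for k in range(K):
                shape = (2.0 + N) / 2.0       # per-block Wishart df = 2
                rate = (S0inv[k, k] + S[k, k]) / 2.0
                Siginv[k, k] = rng.gamma(shape, 1.0 / rate)
            Sigma = np.diag(1.0 / np.diag(Siginv))
        else:
            Siginv = sample_wishart(rng, df_post, np.linalg.inv(S0inv + S))
            Sigma = np.linalg.inv(Siginv)

        # -- retention ------------------------------------------------------
        if it >= n_burnin and (it - n_burnin) % thin == thin - 1:
            out["beta"][kept] = beta
            out["mu"][kept] = mu
            out["Sigma"][kept] = Sigma
            for k in gauss:
                out["sigma2"][kept, k] = sigma2[k]
            out["gamma"][kept] = gamma
            kept += 1

    assert kept == n_keep
    return out
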