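"""Bayesian multivariate GLMM: specification, fitting and posterior summary.

The estimator :class:`BayesianMGLMM` jointly fits K longitudinal outcomes
(Gaussian-identity and Bernoulli-logit families) with correlated
subject-level random intercepts ``gamma_i ~ MVN(mu, Sigma)`` under
hierarchical centering: the fixed design has no constant column and the
population intercept of outcome k is ``mu_k``.  Sampling is blocked Gibbs
with Polya-Gamma augmentation for logistic outcomes; continuous outcomes
are internally shifted and scaled to their training mean/SD (priors are
placed on that scale, draws are mapped back before storage).

``correlation_mode="univariate"`` constrains Sigma to be diagonal — the
zero-cross-correlation comparator in which each outcome is effectively fit
on its own.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._gibbs import default_prior, run_gibbs
from .cohort import CohortDataset, ConfigurationError, DataError
from .simulate import COVARIATES

__all__ = [
    "ModelSpec", "MCMCConfig", "PosteriorSamples", "BayesianMGLMM",
    "fit_mglmm", "fit_univariate_set", "summarize_posterior",
    "cross_outcome_correlation", "log_likelihood_terms",
]

DEFAULT_OUTCOMES = (("Y1", "gaussian"), ("Y2", "gaussian"), ("Y3", "bernoulli"))


@dataclass
class ModelSpec:
    """Outcome families, fixed covariates and prior hyperparameters."""

    outcomes: tuple = DEFAULT_OUTCOMES
    covariates: tuple = tuple(COVARIATES)
    correlation_mode: str = "multivariate"
    beta_prior_var: float = 1e4
    mu_prior_var: float = 1e4
    wishart_df: float | None = None     # defaults to K + 1
    sigma2_gamma_shape: float = 1.0
    sigma2_gamma_rate: float = 0.005

    def __post_init__(self) -> None:
        self.outcomes = tuple((str(n), str(f)) for n, f in self.outcomes)
        if not self.outcomes:
            raise ConfigurationError("need at least one outcome")
        for _, fam in self.outcomes:
            if fam not in ("gaussian", "bernoulli"):
                raise ConfigurationError(f"unsupported family {fam!r}")
        if self.correlation_mode not in ("multivariate", "univariate"):
            raise ConfigurationError(f"unknown correlation_mode {self.correlation_mode!r}")


@dataclass
class MCMCConfig:
    """Chain schedule: burn-in, retained draws, thinning, chains, seed."""

    n_burnin: int = 4000
    n_keep: int = 2000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_burnin", "n_keep", "thin", "n_chains"):
            if getattr(self, f) < 1 and f != "n_burnin":
                raise ConfigurationError(f"{f} must be positive")
        if self.n_burnin < 0:
            raise ConfigurationError("n_burnin must be nonnegative")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws on the natural outcome scale.

    Arrays are stacked over chains: the first ``n_keep`` rows are chain 0,
    and so on (``chain`` labels each draw).  ``sigma2`` is NaN for
    non-Gaussian outcomes.
    """

    beta: np.ndarray          # (M, K, p)
    mu: np.ndarray            # (M, K)
    Sigma: np.ndarray         # (M, K, K)
    sigma2: np.ndarray        # (M, K)
    gamma: np.ndarray         # (M, N, K)
    chain: np.ndarray         # (M,)
    subject_ids: list
    outcomes: tuple           # ((name, family), ...)
    covariates: tuple
    correlation_mode: str
    shift: np.ndarray         # (K,) internal outcome shift (0 for bernoulli)
    scale: np.ndarray         # (K,) internal outcome scale (1 for bernoulli)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1

    @property
    def outcome_names(self) -> list:
        return [n for n, _ in self.outcomes]

    @property
    def families(self) -> list:
        return [f for _, f in self.outcomes]

    def outcome_index(self, outcome) -> int:
        if isinstance(outcome, (int, np.integer)):
            return int(outcome)
        return self.outcome_names.index(outcome)

    def subject_index(self, subject_id) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(
                f"subject {subject_id!r} was not in the training set; "
                "use external prediction"
            ) from None

    def theta_draw(self, m: int) -> dict:
        """One complete parameter draw Theta^(m)."""
        return {"beta": self.beta[m], "mu": self.mu[m],
                "Sigma": self.Sigma[m], "sigma2": self.sigma2[m]}

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "subject_ids": list(map(str, self.subject_ids)),
            "outcomes": [list(o) for o in self.outcomes],
            "covariates": list(self.covariates),
            "correlation_mode": self.correlation_mode,
            "meta": self.meta,
        }
        np.savez_compressed(
            path, beta=self.beta, mu=self.mu, Sigma=self.Sigma,
            sigma2=self.sigma2, gamma=self.gamma, chain=self.chain,
            shift=self.shift, scale=self.scale,
            meta_json=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            return cls(
                beta=z["beta"], mu=z["mu"], Sigma=z["Sigma"],
                sigma2=z["sigma2"], gamma=z["gamma"], chain=z["chain"],
                subject_ids=meta["subject_ids"],
                outcomes=tuple(tuple(o) for o in meta["outcomes"]),
                covariates=tuple(meta["covariates"]),
                correlation_mode=meta["correlation_mode"],
                shift=z["shift"], scale=z["scale"], meta=meta["meta"],
            )


def _build_design(frame: pd.DataFrame, spec: ModelSpec):
    """Per-outcome (y, X, subject-index) arrays with visit-level
    complete-case handling of covariates and term-level outcome missingness."""
    cov = list(spec.covariates)
    missing = [c for c in cov if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"covariates not in dataset: {missing}")
    sids = sorted(frame["subject_id"].unique())
    sidx = {s: i for i, s in enumerate(sids)}
    Xall = frame[cov].to_numpy(float)
    cov_ok = ~np.isnan(Xall).any(axis=1)
    subj_all = frame["subject_id"].map(sidx).to_numpy()

    ys, Xs, subjs = [], [], []
    for name, fam in spec.outcomes:
        if name not in frame.columns:
            raise ConfigurationError(f"outcome column {name!r} not in dataset")
        y = frame[name].to_numpy(float)
        mask = cov_ok & ~np.isnan(y)
        if mask.sum() == 0:
            raise DataError(f"no usable rows for outcome {name}")
        if fam == "bernoulli":
            vals = set(np.unique(y[mask]))
            if not vals <= {0.0, 1.0}:
                raise DataError(f"binary outcome {name} has values outside {{0,1}}")
            if len(vals) < 2:
                raise DataError(f"binary outcome {name} has a single class")
        ys.append(y[mask])
        Xs.append(Xall[mask])
        subjs.append(subj_all[mask])
    return sids, ys, Xs, subjs


def _initial_state(ys, Xs, subjs, families, N, p, rng, disperse: bool):
    """Chain start: single-outcome least-squares fits (logit-approximate for
    binary outcomes); optionally dispersed by +2 rough SDs for a second chain."""
    K = len(ys)
    beta = np.zeros((K, p))
    mu = np.zeros(K)
    sigma2 = np.ones(K)
    for k in range(K):
        y = ys[k] if families[k] == "gaussian" else 4.0 * (ys[k] - 0.5)
        X1 = np.column_stack([np.ones(len(y)), Xs[k]])
        coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
        mu[k] = coef[0]
        beta[k] = coef[1:]
        resid = y - X1 @ coef
        sigma2[k] = max(np.var(resid), 1e-4)
    if disperse:
        scale_b = np.abs(beta) + 0.25
        beta = beta + 2.0 * scale_b * rng.standard_normal(beta.shape)
        mu = mu + 2.0 * (np.abs(mu) + 0.25) * rng.standard_normal(K)
        sigma2 = sigma2 * np.exp(rng.standard_normal(K))
        Sigma = 2.0 * np.eye(K)
    else:
        Sigma = np.eye(K)
    gamma = np.tile(mu, (N, 1))
    return {"beta": beta, "mu": mu, "gamma": gamma, "Sigma": Sigma,
            "sigma2": sigma2}


class BayesianMGLMM(BaseEstimator):
    """Multivariate Bayesian GLMM with correlated random intercepts.

    Parameters mirror :class:`ModelSpec` and :class:`MCMCConfig`; see the
    module docstring for the model.  After :meth:`fit`, the retained draws
    live in ``posterior_`` (a :class:`PosteriorSamples`).

    Examples
    --------
    >>> est = BayesianMGLMM(n_burnin=200, n_keep=100, thin=1, seed=1)
    >>> est.fit(train_dataset)                          # doctest: +SKIP
    >>> est.posterior_.n_draws                          # doctest: +SKIP
    200
    """

    def __init__(self, outcomes=DEFAULT_OUTCOMES, covariates=tuple(COVARIATES),
                 correlation_mode="multivariate", n_burnin=4000, n_keep=2000,
                 thin=10, n_chains=2, seed=0, beta_prior_var=1e4,
                 mu_prior_var=1e4, wishart_df=None, sigma2_gamma_shape=1.0,
                 sigma2_gamma_rate=0.005):
        self.outcomes = outcomes
        self.covariates = covariates
        self.correlation_mode = correlation_mode
        self.n_burnin = n_burnin
        self.n_keep = n_keep
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed
        self.beta_prior_var = beta_prior_var
        self.mu_prior_var = mu_prior_var
        self.wishart_df = wishart_df
        self.sigma2_gamma_shape = sigma2_gamma_shape
        self.sigma2_gamma_rate = sigma2_gamma_rate

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            outcomes=tuple(tuple(o) for o in self.outcomes),
            covariates=tuple(self.covariates),
            correlation_mode=self.correlation_mode,
            beta_prior_var=self.beta_prior_var,
            mu_prior_var=self.mu_prior_var,
            wishart_df=self.wishart_df,
            sigma2_gamma_shape=self.sigma2_gamma_shape,
            sigma2_gamma_rate=self.sigma2_gamma_rate,
        )

    def fit(self, dataset: CohortDataset, role: str | None = None) -> "BayesianMGLMM":
        """Fit on the dataset's training subjects (or all, if no split)."""
        spec = self._spec()
        if role is None:
            role = "train" if "role" in dataset.subjects.columns else None
        frame = dataset.frame(role=role)
        if len(frame) == 0:
            raise DataError("empty training set")
        sids, ys, Xs, subjs = _build_design(frame, spec)
        families = [f for _, f in spec.outcomes]
        K, p, N = len(ys), len(spec.covariates), len(sids)

        # internal shift/scale of continuous outcomes
        shift = np.zeros(K)
        scale = np.ones(K)
        ys_s = []
        for k, fam in enumerate(families):
            if fam == "gaussian":
                shift[k] = float(np.mean(ys[k]))
                sd = float(np.std(ys[k]))
                scale[k] = sd if sd > 0 else 1.0
                ys_s.append((ys[k] - shift[k]) / scale[k])
            else:
                ys_s.append(ys[k])

        prior = default_prior(K)
        prior["beta_var"] = spec.beta_prior_var
        prior["mu_var"] = spec.mu_prior_var
        prior["wishart_df"] = spec.wishart_df if spec.wishart_df is not None else K + 1
        prior["sigma2_shape"] = spec.sigma2_gamma_shape
        prior["sigma2_rate"] = spec.sigma2_gamma_rate

        univariate = spec.correlation_mode == "univariate"
        chains = []
        chain_seeds = np.random.SeedSequence(self.seed).spawn(self.n_chains)
        for c, ss in enumerate(chain_seeds):
            rng = np.random.default_rng(ss)
            init = _initial_state(ys_s, Xs, subjs, families, N, p, rng,
                                  disperse=(c % 2 == 1))
            draws = run_gibbs(
                ys_s, Xs, subjs, families, N,
                n_burnin=self.n_burnin, n_keep=self.n_keep, thin=self.thin,
                rng=rng, prior=prior, init=init, univariate=univariate,
            )
            chains.append(draws)

        def stack(key):
            return np.concatenate([c[key] for c in chains], axis=0)

        beta = stack("beta")
        mu = stack("mu")
        Sigma = stack("Sigma")
        sigma2 = stack("sigma2")
        gamma = stack("gamma")
        chain = np.repeat(np.arange(self.n_chains), self.n_keep)

        # back-transform to the natural outcome scale
        beta = beta * scale[None, :, None]
        mu = mu * scale[None, :] + shift[None, :]
        gamma = gamma * scale[None, None, :] + shift[None, None, :]
        Sigma = Sigma * np.outer(scale, scale)[None, :, :]
        sigma2 = sigma2 * (scale ** 2)[None, :]

        self.posterior_ = PosteriorSamples(
            beta=beta, mu=mu, Sigma=Sigma, sigma2=sigma2, gamma=gamma,
            chain=chain, subject_ids=list(sids),
            outcomes=spec.outcomes, covariates=spec.covariates,
            correlation_mode=spec.correlation_mode, shift=shift, scale=scale,
            meta={"n_burnin": self.n_burnin, "n_keep": self.n_keep,
                  "thin": self.thin, "n_chains": self.n_chains,
                  "seed": self.seed},
        )
        return self

    def predict(self, dataset_or_requests, **kwargs):
        """Internal prediction; see :mod:`mvglmm.predict` for full control."""
        from .predict import predict_internal
        return predict_internal(self.posterior_, dataset_or_requests, **kwargs)


def fit_mglmm(dataset: CohortDataset, spec: ModelSpec | None = None,
              mcmc: MCMCConfig | None = None) -> PosteriorSamples:
    """Functional wrapper: fit the model and return the posterior draws."""
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    est = BayesianMGLMM(
        outcomes=spec.outcomes, covariates=spec.covariates,
        correlation_mode=spec.correlation_mode,
        n_burnin=mcmc.n_burnin, n_keep=mcmc.n_keep, thin=mcmc.thin,
        n_chains=mcmc.n_chains, seed=mcmc.seed,
        beta_prior_var=spec.beta_prior_var, mu_prior_var=spec.mu_prior_var,
        wishart_df=spec.wishart_df,
        sigma2_gamma_shape=spec.sigma2_gamma_shape,
        sigma2_gamma_rate=spec.sigma2_gamma_rate,
    )
    return est.fit(dataset).posterior_


def fit_univariate_set(dataset: CohortDataset, spec: ModelSpec | None = None,
                       mcmc: MCMCConfig | None = None) -> PosteriorSamples:
    """Zero-cross-correlation comparator: Sigma constrained diagonal."""
    spec = spec or ModelSpec()
    spec = ModelSpec(**{**asdict(spec), "correlation_mode": "univariate"})
    return fit_mglmm(dataset, spec, mcmc)


def log_likelihood_terms(dataset: CohortDataset, spec: ModelSpec,
                         beta, gamma, sigma2, subject_ids=None,
                         role: str | None = None) -> pd.DataFrame:
    """Per-(subject, outcome, visit) log-density at one parameter value.

    ``beta`` is (K, p); ``gamma`` is (N, K) aligned with ``subject_ids``
    (defaults to sorted subjects in the dataset); ``sigma2`` length K
    (ignored for Bernoulli outcomes).  Missing outcome terms are absent
    from the result, as they contribute nothing to the likelihood.
    """
    beta = np.asarray(beta, float)
    gamma = np.asarray(gamma, float)
    sigma2 = np.asarray(sigma2, float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(gamma))):
        raise FloatingPointError("non-finite parameters")
    frame = dataset.frame(role=role)
    sids, ys, Xs, subjs = _build_design(frame, spec)
    if subject_ids is not None:
        order = {s: i for i, s in enumerate(subject_ids)}
        remap = np.array([order[s] for s in sids])
    else:
        remap = np.arange(len(sids))
    rows = []
    for k, (name, fam) in enumerate(spec.outcomes):
        g = gamma[remap[subjs[k]], k]
        lin = Xs[k] @ beta[k] + g
        if fam == "gaussian":
            if not np.isfinite(sigma2[k]) or sigma2[k] <= 0:
                raise FloatingPointError(f"invalid sigma2 for outcome {name}")
            ll = norm.logpdf(ys[k], loc=lin, scale=np.sqrt(sigma2[k]))
        else:
            # log Bernoulli(y | logit^-1(lin)) in a numerically stable form
            ll = ys[k] * lin - np.logaddexp(0.0, lin)
        for s, val in zip(subjs[k], ll):
            rows.append({"subject_id": sids[s], "outcome": name, "loglik": float(val)})
    return pd.DataFrame(rows)


def _rhat_ess(draws: np.ndarray, chain: np.ndarray):
    """Split-Rhat and bulk ESS via arviz for a 1-D parameter."""
    import arviz as az
    n_chains = int(chain.max()) + 1
    if n_chains < 2:
        return np.nan, np.nan
    per = draws.reshape(n_chains, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(np.asarray(az.rhat(az.convert_to_dataset(per))["x"]).item())
        ess = float(np.asarray(az.ess(az.convert_to_dataset(per))["x"]).item())
    return rhat, ess


def summarize_posterior(samples: PosteriorSamples, force: bool = False) -> pd.DataFrame:
    """Posterior medians, equal-tailed 95% credible intervals, significance
    flags (interval excludes 0) and convergence diagnostics per parameter.

    If any fixed-effect/intercept PSRF exceeds 1.2 the significance flags
    are withheld (set to NA) unless ``force`` is given.
    """
    if samples.n_draws < 2:
        raise ConfigurationError("need at least 2 retained draws")
    rows = []
    names = samples.outcome_names
    p = samples.beta.shape[2]
    for k, name in enumerate(names):
        entries = [("Intercept", samples.mu[:, k])]
        entries += [(samples.covariates[j], samples.beta[:, k, j]) for j in range(p)]
        if samples.families[k] == "gaussian":
            entries.append(("sigma2", samples.sigma2[:, k]))
        entries.append((f"Sigma[{name},{name}]", samples.Sigma[:, k, k]))
        for label, draws in entries:
            med = float(np.median(draws))
            lo, hi = np.quantile(draws, [0.025, 0.975])
            rhat, ess = _rhat_ess(draws, samples.chain)
            rows.append({
                "outcome": name, "parameter": label, "median": med,
                "q2.5": float(lo), "q97.5": float(hi),
                "significant": bool(lo > 0 or hi < 0),
                "rhat": rhat, "ess": ess,
            })
    out = pd.DataFrame(rows)
    core = out["parameter"].isin(["Intercept", *samples.covariates])
    worst = out.loc[core, "rhat"].max()
    if not force and np.isfinite(worst) and worst > 1.2:
        warnings.warn(
            f"max PSRF {worst:.3f} > 1.2; significance flags withheld "
            "(pass force=True to emit them anyway)"
        )
        out["significant"] = pd.NA
    return out


def cross_outcome_correlation(samples: PosteriorSamples, i: int = 0, j: int = 1) -> dict:
    """Posterior summary of corr(gamma_i, gamma_j) across retained draws."""
    if samples.correlation_mode == "univariate":
        warnings.warn("univariate mode constrains cross-outcome correlation to 0")
        return {"median": 0.0, "q2.5": 0.0, "q97.5": 0.0, "degenerate": True}
    S = samples.Sigma
    corr = S[:, i, j] / np.sqrt(S[:, i, i] * S[:, j, j])
    lo, hi = np.quantile(corr, [0.025, 0.975])
    return {"median": float(np.median(corr)), "q2.5": float(lo),
            "q97.5": float(hi), "degenerate": False, "draws": corr}
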