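# Methods

This note documents the statistical model, the sampler, the prediction
procedures and the evaluation conventions implemented in `mvglmm`.

## Model

For subject $i = 1,\dots,N$ at visit time $t_{ij}$ we jointly model three
outcomes: two continuous instrument totals
$Y_{1ij}$ (MDS-UPDRS part II, motor aspects of daily living) and
$Y_{2ij}$ (MDS-UPDRS part I, non-motor aspects of daily living), and a
binary imbalance indicator $Y_{3ij}$ (1 when the Hoehn & Yahr stage or
MDS-UPDRS item 2.12 reaches 3):

$$
\begin{aligned}
Y_{kij} &= \mathbf{x}_{ij}^\top \boldsymbol\beta_k + \gamma_{ik} + \varepsilon_{kij},
  \qquad \varepsilon_{kij} \sim N(0, \sigma_k^2), \qquad k = 1, 2,\\
\operatorname{logit} \Pr(Y_{3ij} = 1) &= \mathbf{x}_{ij}^\top \boldsymbol\beta_3 + \gamma_{i3},
\end{aligned}
$$

with a shared covariate vector
$\mathbf{x}_{ij} = (\text{visit time}, \text{age at baseline}, \text{gender},
\text{education}, \text{disease duration}, \text{HAMD}_z, \text{MoCA}_{adj},
\text{LEDD}_z)$ and **correlated subject-level random intercepts**

$$
\boldsymbol\gamma_i = (\gamma_{i1}, \gamma_{i2}, \gamma_{i3})^\top
  \sim \mathrm{MVN}(\boldsymbol\mu, \Sigma).
$$

The model is *hierarchically centered*: the fixed design carries no constant
column, and the population intercept of outcome $k$ is $\mu_k$, the mean of
the random intercepts. Off-diagonal elements of $\Sigma$ link the outcomes;
$\Sigma_{12}/\sqrt{\Sigma_{11}\Sigma_{22}}$ is the cross-outcome correlation
reported as the model's headline coupling parameter. Setting
`correlation_mode="univariate"` constrains $\Sigma$ to be diagonal, which
factorizes the model into three independent univariate GLMMs — the
comparator used to quantify the value of joint modelling.

Missing outcome values contribute nothing to the likelihood (term-level
missingness); a visit with a missing covariate is dropped for all outcomes
at that visit (visit-level complete case). Dropout is assumed missing at
random, so the monotone dropout process is ignorable for likelihood-based
inference.

## Priors

* $\boldsymbol\beta_k \sim N(0, 10^4 I)$ and $\mu_k \sim N(0, 10^4)$, placed on
  internally standardized outcomes (see below);
* $\sigma_k^{-2} \sim \mathrm{Gamma}(1, 0.005)$;
* $\Sigma^{-1} \sim \mathrm{Wishart}(K + 1, I_K)$ (in univariate mode, an
  independent $\mathrm{Gamma}$ prior on each diagonal precision, equivalent
  to the $K=1$ Wishart per block).

Continuous outcomes are shifted and scaled to their training mean/SD before
sampling and all draws are mapped back afterwards
($\beta \mapsto c\beta$, $\mu \mapsto c\mu + s$, $\Sigma \mapsto c c^\top \odot \Sigma$,
$\sigma^2 \mapsto c^2 \sigma^2$), so the vague priors above are expressed on
a scale-free parameterization.

## Posterior sampling

Conditional on Pólya-Gamma latent variables $\omega_{3ij} \sim \mathrm{PG}(1,
\psi_{3ij})$ for the logistic terms, the whole model is linear-Gaussian
(Polson, Scott & Windle's augmentation). Each Gibbs sweep draws:

1. $\omega \mid \boldsymbol\beta, \boldsymbol\gamma$ — Pólya-Gamma;
2. $(\boldsymbol\beta_1, \dots, \boldsymbol\beta_K, \boldsymbol\mu) \mid \omega,
   \sigma^2, \Sigma$ — a **collapsed update** with
   $\boldsymbol\gamma$ integrated out analytically. The marginal Gaussian
   precision of the stacked fixed effects is the full-data GLS precision
   minus a per-subject Woodbury correction
   $J_i (\Sigma^{-1} + D_i)^{-1} J_i^\top$, where $D_i$ is the diagonal of
   per-subject weight totals — a $K \times K$ solve per subject, vectorized
   over subjects;
3. $\boldsymbol\gamma_i \mid \cdot$ — conjugate MVN, batched over subjects;
4. $\sigma_k^{-2} \mid \cdot$ — conjugate Gamma;
5. $\Sigma^{-1} \mid \boldsymbol\gamma, \boldsymbol\mu$ — Wishart via Bartlett
   decomposition (independent per-block Gammas in univariate mode).

Steps 2–3 jointly draw $(\boldsymbol\theta, \boldsymbol\gamma)$ from their exact
conditional, so the chain targets the exact posterior. The collapsed step
is essential: covariates with little or no within-subject variation (age,
gender, education, disease duration; MoCA in practice) are near-confounded
with the random intercepts, and the naive one-block-at-a-time scheme
produces effectively non-converging chains for those coefficients
($\hat R > 2$). With the collapsed update the only remaining source of
autocorrelation is the Pólya-Gamma layer, so steps 1–3 are refreshed twice
per sweep when a logistic outcome is present.

$\mathrm{PG}(1, z)$ is sampled from its infinite convolution-of-gammas
representation truncated at 200 terms with a deterministic mean correction
for the dropped tail, validated against the closed-form moments
$E[\omega] = \tanh(z/2)/(2z)$.

Two chains are run by default, the second from a deliberately over-dispersed
start; convergence is monitored by split-$\hat R$ and bulk effective sample
size. Posterior summaries withhold significance flags when any
fixed-effect $\hat R$ exceeds 1.2 unless explicitly forced.

## Dynamic prediction

Let $\Theta^{(m)}$ be the $m$-th retained draw. To predict outcome $k$ of
subject $\ell$ at a future time $t'$ (covariates at $t'$ treated as known,
outcome history strictly before $t'$):

* **Internal** (training subject): plug $\boldsymbol\beta_k^{(m)}$ and the
  stored $\gamma_{\ell k}^{(m)}$ into the mean model; add
  $N(0, \sigma_k^{2(m)})$ noise for continuous outcomes; draw Bernoulli
  variables for the binary outcome.
* **External** (new subject): draw
  $\boldsymbol\gamma_\ell^{(m)} \sim f(\boldsymbol\gamma \mid \text{history},
  \Theta^{(m)})$ for each $m$. With a Gaussian-only history this
  conditional is exactly normal and is computed in closed form, vectorized
  over all draws. With binary history terms the draw is still **exact**, by
  rejection sampling: propose from the Gaussian-part conditional and accept
  with probability equal to the Bernoulli likelihood product (bounded by 1,
  so no envelope constant is needed); the rare stubborn draw falls back to
  Pólya-Gamma Gibbs sweeps. An empty history falls back to the prior
  $\mathrm{MVN}(\boldsymbol\mu^{(m)}, \Sigma^{(m)})$, with a warning.

Point predictions are means over the $M$ predictive draws; 95% intervals
are equal-tailed 2.5%/97.5% quantiles. For the binary outcome the headline
point/interval summarize the predictive probabilities; the 0/1 Bernoulli
draws and their interval are also reported, and observed-value coverage is
judged against the Bernoulli interval.

Sequential prediction tables rebuild the random-effect posterior under
growing history windows (baseline only; baseline + 18 months; …) for each
horizon, mirroring the dynamic-prediction workflow of a clinic revisit.

## Evaluation

* RMSE and mean absolute error (AB) pool all subject-visit terms of a
  continuous outcome.
* The binary outcome is scored by the empirical ROC over all distinct
  predicted probabilities; the trapezoidal AUC equals the ties-½
  pair-counting estimator. Two fits scored on the same labels are compared
  with DeLong's nonparametric paired test on placement values.
* Interval coverage is the fraction of observations inside their closed
  95% interval.

Fitted values for training-data accuracy are posterior means of the
subject-conditional mean (probability for the binary outcome); a marginal
variant integrates the random intercept out by Gauss–Hermite quadrature.

## Synthetic cohorts

The generator emulates an early-PD longitudinal study: visits at 0/18/36
months; baseline age $\sim N(63.2, 8.4^2)$, education $\sim N(14.9, 2.7^2)$
years (rounded), 61.8% male, disease duration lognormal moment-matched to
mean 5.1 / SD 5.5 years; HAMD, MoCA and LEDD drift across visits around
published per-visit means/SDs with intra-subject correlation 0.5. Default
effect sizes are the reference fit's posterior medians, with
$\mathrm{corr}(\gamma_1, \gamma_2) = 0.55$, random-intercept SDs
$(5.5, 5.5, 2.0)$ and residual SDs $(5, 5)$. Dropout is monotone,
gender-differential and missing-at-random, calibrated so a 76-subject
cohort retains $\approx 65$ subjects at 18 months and $\approx 52$ at 36
months (male 36-month retention 57.4% vs female 86.2%).

The generator writes both raw clinical columns and the exact standardized
covariates used during generation (z-scored with *population* moments).
Re-standardizing empirically from a finite training sample therefore
reproduces those columns only up to sampling noise in the constants — a
deliberate, documented mismatch: parameter-recovery experiments fit on the
generation-exact columns, while the preprocessing path is exercised on the
raw columns.

Known limitations: covariate trajectories are exchangeable around their
drift (no autoregression); the binary outcome's raw components
(H&Y / item 2.12) are generated only up to the imbalance indicator they
imply; dropout depends on gender alone, not on outcome history (MAR by
construction, not MNAR).
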