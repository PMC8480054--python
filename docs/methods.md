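# Methods

## Model

Feeding-study data consist of administered doses $x_{d(i)}$ (the $D$
distinct quantities of the study design, all strictly positive) and a
biomarker matrix $y \in \mathbb R^{n\times P}$. The measurement model is a
one-factor model in the unobserved continuous intake $z_i > 0$,

$$y_{ip} = \alpha_p + \beta_p z_i + \varepsilon_{ip},\qquad
\varepsilon_{ip}\sim\mathcal N(0,\sigma_p^2),$$

with the intake prior a zero-truncated Gaussian mixture anchored at the
doses, $z_i \sim \sum_d \pi_d(\mathbf y_i)\,\mathcal
N_{(0,\infty)}(x_d,\theta_d^2)$, and observation-specific weights from a
Cauchit cumulative-link ordinal regression on the standardized biomarkers.

Assumptions worth stating explicitly:

- **Positive loadings.** $\beta_p > 0$ (prior truncated at zero). This
  resolves the sign/reflection non-identifiability of one-factor models and
  assumes each biomarker increases with intake; biomarkers known to
  decrease with intake should be negated before fitting.
- **Homoscedastic Gaussian errors** per biomarker, no missing values.
  Missing biomarkers are rejected with an explicit error rather than
  imputed. The matrix is modelled as supplied — any transformation
  (e.g. log) is the user's choice upstream.
- **Intakes near doses.** The mixture components sit at the administered
  quantities; the model is designed for interpolation within the dose
  range, not extrapolation far outside it.
- No participant covariates (age, sex, ...) enter the model.

## Default priors (data-driven, user-overridable)

For each biomarker, $y_p$ is regressed on the assigned dose by least
squares. The prior for $(\alpha_p, \beta_p)$ is Gaussian (truncated to
$(0,\infty)$ for $\beta_p$) centered at the fitted intercept/slope (slope
floored at $10^{-6}$), with variance $\max(10\,\hat s_p^2, 1)$ where
$\hat s_p^2$ is the residual variance — weakly informative on the data's
own scale. $\sigma_p^2 \sim \mathrm{IG}(2, \hat s_p^2)$, and
$\theta_d^2 \sim \mathrm{IG}(2, (x_d/D)^2)$: the component spread is given
a prior scale that grows with the dose, reflecting that absolute intake
variability is larger at larger portions. The gating ridge penalty defaults
to 0.1 on standardized biomarkers (unit-free); the Cauchit link is the
default because its heavy tails keep outlying biomarker profiles from
collapsing the gating weights, with logit/probit available.

## Posterior computation

One Gibbs sweep updates, in order: component labels (exact categorical
conditional, computed in log space); the gating model (penalized refit on
current labels every `gating_refit_every` = 10 sweeps — a modularized "cut"
update rather than a full Bayesian gating posterior, mirroring the use of a
penalized ordinal fitter); latent intakes (truncated-normal conditional
with precision $\sum_p \beta_p^2/\sigma_p^2 + 1/\theta_{c_i}^2$);
measurement parameters (exact bivariate-normal conditional, $\beta_p$ drawn
from its truncated marginal, then $\alpha_p \mid \beta_p$; conjugate
inverse-gamma for $\sigma_p^2$); component variances (conjugate
inverse-gamma proposal corrected by an independence-Metropolis step for the
truncation normalizer $\Phi(x_d/\theta_d)^{-n_d}$, which is negligible
whenever $x_d \gg \theta_d$). Empty components draw $\theta_d^2$ from the
prior. Initialization is deterministic (intakes at the assigned dose,
labels at the dose index, least-squares measurement parameters, gating fit
on initial labels), and a seed makes the whole fit bit-reproducible.
Components are anchored at fixed, ordered doses, so label switching cannot
occur and no relabelling step exists. Burn-in is an iteration count at the
API level, with a fraction-based convenience flag on the command line;
thinning is off by default with an optional factor to bound memory.

The ordinal gating fit reparameterizes cutpoints as $\zeta_1$ plus positive
log-increments (monotone at every iterate), uses an analytic gradient with
L-BFGS-B, and always starts from the null model (cutpoints at Cauchy
quantiles of the empirical label frequencies), so refits are deterministic
given the labels.

## Prediction

For a biomarker-only observation, the predictive intake distribution
integrates over parameter uncertainty by cycling deterministically through
the stored post-burn-in draws (fit once, predict cheaply and often). For
each stored draw, the mixture component is sampled from its **exact
marginal**: the intake is integrated out of
$\pi_d(\mathbf y^*)\int_0^\infty \mathcal
N_{(0,\infty)}(z;x_d,\theta_d^2)\prod_p \mathcal N(y^*_p;\alpha_p+\beta_p
z,\sigma_p^2)\,dz$ in closed form (completing the square leaves a Gaussian
normalizer times the half-line mass $\Phi(m_d\sqrt{A_d})$). The intake is
then drawn from its truncated-normal conditional given the component.

A conditional alternative — sampling the component given the previous
intake draw — was considered and rejected: when the dose components are far
apart relative to $\theta_d$, that chain is metastable (switching modes
requires a many-sigma excursion of $z^*$), which distorts multi-modal
predictive distributions at practical iteration counts. The collapsed
weights were verified against per-component numerical integration at
$10^{-15}$ accuracy. The predictive burn-in simply discards the first
parameter draws consumed.

## Synthetic data generator

The generator emulates a dose-controlled intervention study: actual intake
deviates from the administered portion as $z_i \sim \mathcal
N_{(0,\infty)}(x_{d(i)}, \text{intake\_sd}^2)$ (compliance and absorption
variability), and biomarkers respond linearly with additive Gaussian noise.
Defaults represent a three-arm citrus-type study — groups of 24/22/24 at
80/160/320 g (n = 70), three biomarkers with loadings (0.5, 1.0, 1.5),
intercepts (10, 20, 5) and error SDs (17, 34, 51). With a population intake
SD of about 101 g, those error SDs put the per-biomarker signal-to-noise
ratio at about 3: dose-group biomarker distributions overlap moderately, so
recovery is nontrivial but reliable. `intake_sd` defaults to 10 g, roughly
3–12% of the administered portions. True gating is implicit (intakes are
drawn per assigned group): the gating model is an inferential device, not a
generative claim, and is evaluated through recovery behavior only.

What the generator does **not** emulate: metabolite kinetics (half-lives,
time since intake), between-subject response heterogeneity (loadings are
shared), skewed or heteroscedastic measurement error, and correlated
biomarker errors. Passing tests on these data therefore demonstrate the
correctness and calibration of the inference machinery under the model's
own assumptions, not robustness to real-world violations of them.

## Numerical choices

- **Zero-truncated normal sampling**: inverse-CDF through the survival
  function, $-\Phi^{-1}(\Phi(-a)(1-u))$, which is accurate deep into both
  tails; when the truncation point is more than 5 SDs above the mean the
  survival mass is too small to resolve and sampling falls back to
  rejection from a shifted exponential (Robert's method). Draws are floored
  at the smallest positive normal so the support stays open.
- Mixture log-densities and label probabilities are computed in log space
  with max-subtraction; the truncation normalizer uses `log_ndtr`.
- Gating category probabilities take the last category as the complement of
  the cumulative link (rows sum to one exactly) and are floored at
  $10^{-300}$ against floating-point zeros at extreme linear predictors.
- Degenerate inputs: a single dose level ($D=1$) yields a degenerate gating
  model with weight 1; constant biomarker columns get unit standardization
  scale; empty gating categories are handled by the ridge penalty; a single
  biomarker ($P=1$) warns but proceeds.
- Posterior summaries are the sample median, SD (ddof = 1) and equal-tailed
  95% interval with linear quantile interpolation.

## Problem sizes used in the validation suite

The test suite and `scripts/acceptance.py` validate: half-normal moments of
the truncated sampler at $10^6$ draws; gating simplexes over $10^4$ random
inputs; conditional-moment agreement with quadrature on 100 random
configurations; a Geweke-style successive-conditional vs forward check of
the Gibbs transitions at $n=20, P=2, D=2$ (gating held fixed at zero
coefficients so the joint model is properly generative); parameter recovery
at $n=210$ with 5000/1500 iterations plus slope-interval coverage across 20
replicate studies at 1500/500 iterations each (coverage is insensitive to
longer chains at this size); and predictive calibration for 50
biomarker-only observations. These sizes are the package's own choices for
a thorough desk-scale validation.

## Limitations

- The gating update is modularized (periodic penalized refit), not a full
  Bayesian posterior over gating parameters; gating uncertainty enters the
  predictive only through the between-sweep variability of the refits.
- $D$ is fixed by the study design; there is no model selection over the
  number of components, no parallel chains, and no adaptive tuning.
- Prediction assumes the new biomarkers come from the population the model
  was calibrated on; no covariate adjustment or drift correction exists.
- Intakes far outside the administered dose range are supported only
  through the tails of the dose-anchored mixture and will be shrunk toward
  the nearest component.
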