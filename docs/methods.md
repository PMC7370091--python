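# Methods

## The model

Each cardioventilatory variable is analysed separately.  Observations are
per-(subject, condition) series on a common equally spaced grid
t_1 < ... < t_n (seconds).  The likelihood is

    y_ij(t_k) | mu, alpha_i, tau  ~  N( mu(t_k) + alpha_i(t_k), 1/tau ),

independently across subjects j, conditions i in {ONB, FB} and times k,
with `alpha_ONB = 0` for identifiability.  `tau` is the residual
*precision*; where the literature writes the Gaussian's second argument as
a variance sigma^2, we read tau = 1/sigma^2 (the precision
parameterization of latent Gaussian inference engines).  The model
deliberately contains **no subject term**, matching the printed analysis
model of the motivating trial; an iid subject-intercept extension exists
behind `fit(..., subject_intercept=True)` for sensitivity checks only (its
intercept precision is empirical-Bayes-optimized jointly but held at the
mode rather than grid-mixed).

Both functional parameters carry intrinsic second-order random-walk (RW2)
priors for equally spaced locations: precision structure Q = D2' D2 with
D2 the (n-2) x n second-difference operator.  Q has rank n-2 and null
space spanned by constant and linear trends, i.e. straight lines are free
and curvature is penalized.  By default the structure is *scaled*: Q is
multiplied by the geometric mean of its reference marginal variances (the
diagonal of the Moore-Penrose pseudo-inverse), so the scaled prior has
geometric-mean reference variance 1 and the precision hyperparameters
theta_mu, theta_alpha have comparable meaning across grid sizes.

No sum-to-zero constraints are imposed on the intrinsic priors.  The
posterior is nevertheless proper because both conditions are observed at
every grid point, making A'A strictly positive on every latent coordinate.
Pseudo-determinants (products of the n-2 nonzero eigenvalues) are used
wherever the improper priors enter the evidence; only differences across
hyperparameter nodes matter for the mixture weights, so the convention is
harmless as long as it is fixed, which it is.

## Hyperparameter handling

The three log-precisions theta = (theta_mu, theta_alpha, theta_tau) get
independent log-gamma(1, 5e-5) hyperpriors (the conventional weak default
of latent Gaussian engines; the trial reports none).  Given theta the
latent posterior is Gaussian with precision

    Q_post = blockdiag(e^theta_mu Q, e^theta_alpha Q) + tau A'A,

and the evidence log p(y | theta) is closed-form.  Inference over theta
uses an empirical-Bayes mode search (Nelder-Mead on the log hyperposterior)
followed by a 7-point-per-axis grid spanning +/-3 log-precision units
around the mode (grid resolution and span are `HyperGridConfig` options; a
1-point grid with a pinned center reduces the fit to one conditional
Gaussian, which the oracle tests exploit).  Posterior summary curves and
joint samples are mixtures over the grid nodes with softmax-normalized
weights.  All dense linear algebra is Cholesky-based on the 2n x 2n
posterior precision; at the default n = 121 a full fit takes about 1.5 s.

## Excursion sets

"Where is the effect significant?" is answered simultaneously, not
pointwise.  For a direction d (positive, negative, or two-sided via
sign-matching to the posterior mean), grid points are ordered by decreasing
marginal posterior probability of the directional event (ties broken by
earlier time).  The candidate sets are the prefixes of this ordering; the
joint probability that the event holds everywhere on a prefix is computed
by numerical integration over the Gaussian mixture — scrambled-Sobol
quasi-random draws by default (32768; configurable, minimum 10^4, plain
Monte Carlo available), allocated to hyperparameter nodes proportionally
to their weights (law of total probability) — and the excursion set at
level alpha is the largest prefix with joint probability >= 1 - alpha.
The excursion function F(t) records each point's entry level, is clipped
by the analytic bound "joint <= every member's marginal", and membership
F(t) >= 1 - alpha makes sets nested across levels by construction.
Integration standard errors are reported alongside the joint probability.
Intervals are formatted in minutes at 5-s resolution ("minute 2:50 to 11").

## Synthetic generator

The generator mirrors the analysis model.  Mean curves are mono-exponential
on-kinetics b + A(1 - e^-(t-t0)/tau_c) — the canonical shape of a
constant-load cardiopulmonary response — with tau_c = 60 s by default;
condition effects delta(t) are constant or Gaussian-bump curves signed by
each variable's hypothesized direction; noise is iid Gaussian on the
analysis scale (log scale for VO2 and VCO2, which are generated as
log-normal and analysed after natural-log transform).  Defaults emulate the
motivating trial's published summaries: 18 subjects, grid 60-660 s in 5-s
steps (121 points; the trial reports breath-by-breath acquisition but not
its analysis grid, so the 5-s grid is this package's choice), steady states
at the ONB condition means, constant effects equal to the FB-ONB mean
differences, and noise SDs equal to the average of the two reported SDs.
The published summary table prints the Tex/Tot SDs in fractional units
against percentage means; the values are kept as printed.

What the generator does **not** emulate: irregular breath-by-breath
sampling, missing breaths, autocorrelated physiological noise, and —
importantly for the responder analysis — between-subject heterogeneity of
the condition effect.  Every simulated subject shares the same delta(t)
(the optional subject intercept shifts both conditions equally and cancels
in the within-subject change), so simulated responder counts concentrate
near 0 or n rather than spreading across subjects as real trials do.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not physiological realism.

## Responder analysis

Per subject, pct_change = 100 (mean_FB - mean_ONB)/mean_ONB over the grid
on the untransformed scale.  The typical error is the between-subject SD
of these changes divided by sqrt(2) — the paired-trial typical error of
the standard reliability framework, computed in-sample per variable (the
formula is isolated in `typical_error` precisely because the upstream
description is terse).  Responders must exceed 1 TE *in the hypothesized
direction* (a two-sided mode exists but is not default).  The proportion
test is the exact binomial tail P(X >= k | n, 0.5) by default; a
normal-approximation variant with continuity correction is provided
because "one-sample proportion test" is ambiguous between the two.

## Classical statistics

Paired t-tests raise on zero-variance differences rather than returning
infinite statistics.  Cohen's d defaults to the pooled-SD form
(m2 - m1)/sqrt((s1^2 + s2^2)/2); on the trial's exertion summaries this
gives 0.617 where 0.61 was printed — the original formula is unknown, so
the value is reported, not forced.  Repeated-measures interaction power
uses the noncentral F with df1 = (g-1)(m-1)eps, df2 = (N-g)(m-1)eps and
noncentrality lambda = f^2 N m eps / (1 - rho).  Under this convention the
trial's stated inputs (f = 0.25, alpha = 0.05, power = 0.80, g = 2,
m = 10, rho = 0.5, eps = 1) yield a minimal N of 14, not the 20 the trial
reports; power-software noncentrality conventions differ and the one used
originally could not be pinned down, so the package documents its
convention and reports its own number.

## Numerical choices and known limitations

- Linear interpolation (`resample_to_grid`) with a hard no-extrapolation
  rule; exact on affine series.
- Natural log (not log10) for the log-scale variables; applied exactly
  once, guarded by a per-variable flag.
- Ties in the excursion ordering break toward earlier times; weights are
  invariant to additive shifts of the log-evidence.
- Grid mixing, not nested Laplace approximations: exact for this Gaussian
  likelihood up to grid resolution, but not applicable to non-Gaussian
  responses.
- **Null-set calibration.**  Because the RW2 null space is unpenalized,
  the constant and linear components of alpha are informed by the data
  alone; under a true null the posterior z-score of alpha carries roughly
  two free degrees of freedom, so the probability that the level-0.05
  two-sided excursion set is non-empty on null data is the familywise
  pointwise rate (~0.2 in the package's own 200-replicate calibration
  runs), not the nominal 0.05.  A singleton excursion set needs only one
  marginal probability >= 0.95 — joint control kicks in for the *extent*
  of the set, not its existence.  Consumers who need family-wise control
  of set existence should screen with a max-|z| criterion or constrain the
  null space, at the cost of no longer representing constant condition
  shifts.  This behaviour is intrinsic to the unconstrained model, and the
  package reports it rather than hiding it.
- Scalar trial statistics (ratios, effect sizes, proportion tests on
  printed counts) operate on rounded published summaries and inherit their
  rounding.
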