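# Methods

## Model and estimators

`coxband` works in the counting-process formulation of the Cox proportional
hazards model.  Subject *i* carries a counting process N_i(t) (0/1, its event
by time t), an at-risk indicator Y_i(t) and a covariate vector X_i(t), and
has intensity

    lambda_i(t) = Y_i(t) lambda_0(t) exp{X_i(t)' beta_0}.

Data are one or more rows per subject, each an at-risk interval (entry, exit]
with fixed covariates; right-censoring, left-truncation (delayed entry) and
time-dependent covariates are all expressed this way.  The at-risk convention
is the half-open one, Y_i(t) = 1{entry < t <= exit}: a subject is not at risk
at its own entry time, which is what makes left-truncation exact.

With risk-set sums S_k(t, beta) = sum_i X_i(t)^{(k)} Y_i(t) e^{X_i(t)'beta}
(k = 0, 1, 2), E = S1/S0 and V = S2/S0 - E E', the estimators are

* beta_hat: the root of the partial-likelihood score
  U_tau(beta) = sum_events {X_e - E(t_e, beta)}, found by Newton-Raphson
  from 0 with step-halving on the log partial likelihood
  (tol 1e-9 on ||U||_inf, max 50 iterations);
* Lambda_hat: the Breslow estimator, jump (number of tied events)/S0(u, beta_hat)
  at each unique event time u.  Ties follow the Breslow convention
  throughout (tied events share one risk set), which is the convention the
  score equation above already embodies; at beta = 0 the estimator reduces
  exactly to Nelson-Aalen.

The plug-in variance of sqrt(n){Lambda_hat(t) - Lambda_0(t)} is

    sigma^2(t) = n sum_{u<=t} d_u / S0(u)^2
               + q(t)' {I_tau(beta_hat)/n}^{-1} q(t),
    q(t) = sum_{u<=t} E(u, beta_hat) dLambda_hat(u),

the first term being the baseline (martingale) variance and the second the
contribution of estimating beta; the two cross-terms vanish asymptotically
by martingale orthogonality.  The estimator is validated in the tests against
the empirical variance of the Breslow estimator over 1000 simulated datasets.

Degenerate inputs: data without events raise `NoEventsError`; a Newton step
that would invert a singular information matrix while the score is nonzero
(collinear covariates) raises `SingularInformationError`.  If the score
already vanishes at the start (all covariates identical, or zero), the fit is
returned with `degenerate=True` -- its Breslow estimator is valid but
standard errors are unavailable.

## The two multiplier-bootstrap schemes

Both schemes perturb the data with i.i.d. multipliers G_1..G_n with mean 0
and variance 1; three laws are provided: N(0,1) (skewness 0), centered unit
Poisson (skewness 1) and centered unit exponential (skewness 2).

**Direct resampling** perturbs the asymptotic linearization: with

    U* = sum_i G_i  int (X_i - E) dW_i,
    I* = sum_i G_i^2 int (X_i - E)(X_i - E)' dW_i,

the replicate is beta* = beta_hat + (I*)^{-1} U*, and the bootstrap Breslow
process adds -(beta* - beta_hat)' int E dLambda_hat plus the reweighted
baseline increments sum_i G_i int dW_i / S0.  It is closed-form, hence fast.

**Estimating-equation resampling** rewrites the score equations themselves:
with dW_i = dN_i the reweighted score is
sum_i (G_i + 1) int {X_i - E(., beta)} dN_i = 0, solved for beta* by the same
batch Newton iteration, and the bootstrap Breslow estimator is the
(G_i + 1)-reweighted Breslow formula evaluated at beta*.  Because weights
G_i + 1 can be negative (normal multipliers), a replicate may fail to
converge; such replicates are flagged, dropped from all downstream
quantities, and counted (an ensemble with more than 20% dropped raises).
In practice the drop rate under the simulation design is zero to a fraction
of a percent.  Replicate Newton steps are clipped to a unit trust radius and
iterates confined to beta_hat +/- 5, so divergent replicates are detected by
their final score norm rather than by overflow.

The increment measure dW_i is either the counting-process increment dN_i or
the estimated martingale increment dM_i = dN_i - Y_i e^{X_i'beta_hat}
dLambda_hat.  For the estimating-equation scheme the dM variant is obtained
by carrying G_i dM_i through the same derivation, which yields baseline
increments {d_u + sum_i G_i dM_i(u)}/S0(u, beta) and the score

    U*(beta) = sum_i G_i int {X_i - E(., beta)} dM_i
             + int {E(., beta_hat) - E(., beta)} dN.

At beta = beta_hat both schemes' bootstrap scores coincide (a property the
tests pin to machine precision), and G = 0 reproduces the original
estimators exactly in both schemes.

Ensembles are vectorized across replicates: the (n, B) multiplier matrix is
drawn in one call (column b is replicate b, so ensembles are bitwise
reproducible under a seed), and each Newton sweep evaluates the risk-set
sums for all replicate betas at once via suffix cumulative sums over
exit-/entry-sorted rows.  One B=500 ensemble on an n=400 dataset takes on
the order of 30 ms.

## Simultaneous confidence bands

A level 1-alpha band for Lambda_0 on [t1, t2] is
phi^{-1}[phi(Lambda_hat) -+ c*/g_n] with phi the identity or log transform
and g_n an equal-precision (EP) or Hall-Wellner (HW) weight; see the module
docstring of `coxband.bands` for the four weight formulas.  Choices made
where the construction is genuinely open:

* The variance entering the weights is the ensemble's empirical variance of
  sqrt(n)(Lambda* - Lambda_hat), used both inside the sup statistic and in
  the assembled band (one shared variance function, in the spirit of
  bootstrap studentization).  The plug-in sigma^2 can be substituted by
  passing the fit as the weight source; the two agree closely.
* The critical value is the empirical (1-alpha) quantile -- order statistic
  ceil((1-alpha) B), i.e. the right-continuous inverted ECDF, so results are
  bitwise reproducible -- of sup over the grid of g*(t)|Lambda*(t) -
  Lambda_hat(t)|, with the *untransformed* weight.  The same critical value
  is reused for the log band: the naive log-scale sup statistic is
  numerically unstable (log of nonpositive replicate values) and the two are
  asymptotically equivalent.
* The sup grid is the set of event times inside [t1, t2] plus the two
  endpoints; the deviation process is a step function, so the supremum is
  attained there.
* The identity-transform lower limit is clipped at 0 (cumulative hazards are
  nonnegative); the log band is positive by construction.

Band containment (`contains`) means lower(t) <= target(t) <= upper(t) at
every grid point, endpoints included.  Note the right endpoint is the
stringent one in small samples: the Breslow estimate plateaus after the last
observed event while a growing target keeps rising, and only the band's
width there can absorb the gap.  This makes equal-precision bands (width
proportional to sigma) noticeably more fragile at the interval's right edge
than Hall-Wellner bands (width proportional to 1 + sigma^2) when the risk
set nearly empties, which is visible in the small-sample coverage numbers.

## Synthetic-data generator and the coverage experiment

`generate_dataset` draws from the study design used throughout the package's
validation: one covariate X ~ N(0, 16) (sd 4), unit baseline hazard so that
Lambda_0(t) = t and event times are exponential with rate e^{0.3 X},
independent censoring C = min(Exp(1), 3) -- the truncation at tau = 3 is read
as administrative censoring, i.e. everyone still under observation at 3 is
censored there, which keeps tau = 3 usable as the terminal evaluation time --
and bands built on [0.5, 3] at the 95% level.  The start point 0.5 avoids
the region near 0 where sup-statistic approximations are poor.

What the generator does *not* emulate: covariate measurement error, model
misspecification (nonproportional hazards), dependent censoring, and
left-truncation (entry is 0 for all subjects; truncation is exercised by
dedicated unit tests instead).  Passing coverage tests therefore demonstrate
the calibration of the resampling machinery under a correctly specified
model, not robustness to violations of it.

`run_coverage` simulates `reps` datasets (seeded substreams: dataset r uses
spawn key (r, 0), its bootstrap uses (r, 1, j)), builds each configured band,
and reports the fraction containing Lambda_0(t) = t on the whole grid,
together with the binomial Monte Carlo standard error; fit and band
failures are counted and excluded.  The desk-scale defaults are reps = 1000
and B = 500 (bumped to reps = 2000 for n = 100 runs in the acceptance
script, where datasets are cheap); MC standard errors are always reported so
comparisons remain calibrated at any scale.

## Functionals

Plug-in functionals of (beta_hat, Lambda_hat) are bootstrapped by applying
the functional to each replicate (beta*, Lambda*), justified by Hadamard
differentiability:

* survival S(t|X) = exp{-Lambda_hat(t) e^{X'beta_hat}};
* restricted mean life Psi = int_0^tau S(s|X) ds, integrated exactly over
  the survival step function, with symmetric CIs
  estimate -+ (1-alpha)-quantile of |Psi* - Psi_hat|, and differences of
  restricted means handled by applying the difference per replicate;
* two-cause cumulative incidence
  F1(t|X) = sum_{u<=t} exp{-Lambda_1(u-) e^{X'b1} - Lambda_2(u-) e^{X'b2}}
  e^{X'b1} dLambda_1(u), built from two cause-specific Cox fits whose
  bootstraps use independent multiplier streams.  Left limits are used for
  the survival factor (survival "just before" each jump), which keeps
  F1 <= 1 and matches product-integral logic; the overall survival uses the
  exponential form exp(-Lambda_1 - Lambda_2).

Bands for trajectories (survival curves, F1) reuse the cumulative-hazard
band machinery with the functional's replicate paths and variance.

## Numerical notes and limitations

* All risk-set computations clip the linear predictor at +/-700 before
  exponentiation; with the Newton box of beta_hat +/- 5 this prevents
  overflow without affecting any converged result.
* Quantiles are order statistics (no interpolation) for reproducibility.
* Problem sizes in the test suite (reps of 150-1000, B of 200-500,
  n of 100-400) are the package's desk-scale validation profile; they keep
  Monte Carlo standard errors near or below one percentage point, which is
  the resolution at which the published coverage probabilities are compared.
* Equal-precision band coverage in small samples (n = 100) runs a few
  percentage points below its large-sample target at the right edge of the
  band interval, for the plateau reason described above; Hall-Wellner and
  log-transformed variants are markedly better calibrated there, matching
  the usual recommendation of log-transformed bands.
* Efron or exact tie corrections, stratification, time-varying coefficients
  and penalized estimation are out of scope, as are more than two competing
  causes and multistate extensions.
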