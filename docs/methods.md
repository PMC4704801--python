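# Methods

## Model and assumptions

One latent trait per subject, observed through p continuous measures at
visit times t_1 < t_2 < ... (years):

    y_ij = f u_ij + e_ij,        e_ij ~ N(0, diag(d)),
    u_i,j+1 = u_ij + η_ij,       η_ij ~ N(0, τ_ij),   τ_ij = t_{i,j+1} − t_ij.

Assumptions that make the model identified and the scores comparable
across subjects: the loading vector f and the idiosyncratic variances d
are shared by all subjects; subjects are independent; the transition is
a pure random walk (no mean reversion), which is reasonable for slowly
drifting traits sampled roughly annually; and the state innovation
variance is pinned to the raw visit gap τ, which fixes the scale of the
latent trait (so f is identified in scale, not only direction — the
likelihood is *not* invariant to rescaling f). The sign indeterminacy is
resolved by the convention sum(f) > 0.

Missing data: a missing cell removes that measure from the measurement
update of that visit; a visit with every measure missing cannot appear
in the input (it is indistinguishable from a longer gap, which is the
supported representation).

## Likelihood and filtering

Subjects are independent with shared parameters, so the stacked
np-dimensional filter factorizes into n scalar-state filters; the
implementation exploits this everywhere (O(n·p) per visit instead of
O((np)³)). The measurement update uses the rank-one Woodbury identities,
and the exact log-likelihood accumulates by the prediction-error
decomposition with the standard Gaussian constant −(m/2)·log 2π, m = the
number of observed measures at the visit. A vectorized path handles the
regular case (shared visit times, complete data); a per-subject path
handles ragged times and missing cells. Factor scores are fixed-interval
(RTS) smoothed means with their variances; the non-dynamic model scores
each visit by the cross-sectional regression rule γ'y,
γ = (ff' + diag d)⁻¹ f.

### Initial state

Two prior policies for the state at the first visit:

* `"simulation"` (default for estimation): proper prior N(0, 1 + g),
  where g is the presample gap (default 1 year). This matches the
  synthetic generator (below) and is the right order of magnitude for
  standardized measures.
* `"diffuse"`: a proper prior with variance 1e7, for filtering and
  scoring at **fixed** parameters.

The diffuse proxy must not be used while estimating the loadings: with
free f the term f f'·κ acts as an unconstrained rank-one level
component, and the maximizer drives f → 0 while κf² absorbs the entire
between-subject level variance, degenerating the dynamics. This was
observed empirically (collapsed fits with extreme scores); exact-diffuse
initialization à la Koopman is out of scope, hence the proper-prior
default.

## Two-cycle ECME estimation

Each outer iteration:

1. **Cycle 1 (closed form).** The Rubin–Thayer EM update of classical
   factor analysis applied to the pooled second-moment matrix C_yy of
   all subject-visit observation vectors (missing cells: pairwise-
   complete accumulation rescaled to the pooled visit count N):
   γ = (ff'+D)⁻¹f, ω = 1 − γ'f, B½ = C_yy γ (γ'C_yy γ + Nω)⁻¹,
   D_new = diag(C_yy − C_yy γ B½')/N. This updates the variances and
   provides an intermediate loading estimate.
2. **Cycle 2 (conditional maximization of the actual likelihood).**
   L-BFGS-B (numeric gradient) over the p shared loadings jointly, with
   d fixed, started from the better of B½ and the current f; the
   returned point never has lower likelihood than its start.

Because cycle 1 targets the pooled covariance rather than the dynamic
likelihood, its raw D step can reduce the panel log-likelihood. Two
safeguards keep the iteration a true ascent algorithm with a stationary
limit: the D step is damped toward the previous value (halving) until
it does not decrease the likelihood, and if no damping level ascends,
D is updated by a numerical conditional maximization over log-variances
— a proper ECME "either" step. Consequences verified in the tests: the
log-likelihood trace is non-decreasing, and on tiny instances the
converged likelihood matches a direct numerical maximization of the
exact joint-Gaussian likelihood to 1e-4.

Defaults: convergence when the relative log-likelihood change is below
1e-6, at most 200 outer iterations, inner optimizer capped at 40
iterations per cycle (ascent holds regardless of the cap), variance
floor 1e-6 (Heywood protection). Starting values: a principal-axis
solution of C_yy/N refined by cycle-1-only EM (i.e. the CFM fit).

The CFM comparator iterates only cycle 1 to convergence of the
implied-covariance likelihood (classical ML factor analysis on pooled
visits; cross-checked against scikit-learn's `FactorAnalysis` in the
tests).

## Synthetic generator

The generator emulates a large observational cognition panel:

* loadings f_k ~ U(0,1) i.i.d., rescaled to sum to 1;
* noise-to-total-variance ratios β_k ~ U(0.1, 0.9) i.i.d. (endpoints
  avoid the boundary of the parameter space), giving
  d_k = f_k β_k/(1−β_k); both are redrawn per replicate;
* latent start u₀ ~ N(0,1) one presample gap (1 year) before the first
  visit, then a random-walk step onto every visit with variance equal
  to the elapsed gap; the first-visit state therefore has variance 2;
* default spacing: unit gaps (annual visits); a random-gap policy draws
  gaps from {0.5, 1, 1.5, 2} years for unequal-spacing tests;
* two-group extension: a deterministic drift δ·τ added to the latent
  increments of group-1 subjects (a difference in annual rate of
  change), with balanced groups matched in pairs exactly on a
  baseline-age covariate (age ~ N(75.7, 7.5), no age effect on the
  latent path — age enters only as a regression covariate).

What the generator does **not** emulate: non-Gaussian noise, floor and
ceiling effects of real neuropsychological tests, informative
missingness or dropout, practice effects, and covariate effects on the
trait. Passing tests therefore demonstrate correctness of the
estimator and its Monte-Carlo behavior under the stated model, not
robustness to those real-data features.

## Evaluation

The trace statistic — the multivariate R² of regressing true on
estimated factor paths — is computed on the paths stacked over all
subjects and visits, where for one factor per subject it reduces to the
squared uncentered correlation (u'û)²/((u'u)(û'û)). Stacking is the
only arrangement that is well defined for every grid cell (a T×n or
n×T matrix form has a singular cross-product whenever min(n,T) is
exceeded). The statistic is invariant to scaling and sign of the
estimate; û ≡ 0 scores 0 by convention. Smoothed scores enter for the
dynamic model and regression scores for the non-dynamic model, matching
how each would be used for retrospective trajectory estimation.

Monte-Carlo grid: per replicate a fresh (f, β, d) draw and panel, both
models fitted on the same draw (paired design, which lowers the
Monte-Carlo variance of the ratio), estimation with the
simulation-matching initial prior. The per-replicate ratio
TR_DFM/TR_CFM is averaged; the ratio of means is reported alongside
because at very small n·T an occasional non-dynamic fit latches onto a
noise direction (trace statistic near zero), making the mean of ratios
heavy-tailed. Replicate r of cell (n,p,T) uses the sub-seed
(master, n, p, T, r), so every cell is independently reproducible.

Two measured regularities worth recording: at these study conditions
the dynamic model's advantage in the trace ratio is largest at T=3 and
shrinks as T grows (both estimators approach 1 as the pooled factor
variance grows, and the cross-sectional scores catch up), and the
non-dynamic trace statistic improves slightly with p (the information
h = Σ f_k²/d_k concentrates). Residual diagnostics: the normality check
is the skewness/kurtosis χ²(2) statistic (Bowman–Shenton, identical in
form to Jarque–Bera) and the lag-1 portmanteau is a Box–Ljung χ²(1)
computed within subjects and pooled — cross-subject boundary products
are excluded, which matters for many short series.

## Power analysis

The bootstrap scheme: for each total sample size n, B times resample
n/2 matched pairs with replacement from a synthetic two-group source
panel, re-standardize, refit both factor models on the resample, and
test the time×group interaction per outcome (each raw measure, the CFM
score, the DFM score) in a linear mixed model with fixed effects
intercept, time, group, time×group, baseline age (uncentered) and
correlated random intercept and slope per subject. The interaction
p-value uses the normal reference for the Wald statistic. Power is the
rejection proportion; fit failures count conservatively as
non-rejections and are tallied.

Mixed-model fitting detail: quasi-Newton REML (statsmodels `MixedLM`,
L-BFGS) can report convergence at a poor point when variance ratios are
extreme (e.g. near-zero residual variance); every fit is therefore
polished by a derivative-free (Powell) pass from the quasi-Newton
solution and the higher restricted likelihood is kept — this reproduces
`lme4` standard errors on a stiff test case. A documented fallback with
independent random intercept and slope engages if the correlated-effects
model fails outright.

Required sample size: the power curve over the n grid is made monotone
by isotonic regression and linearly interpolated at the target (default
80%); values outside the grid are returned with an explicit
extrapolation flag.

On this synthetic generator the dynamic and non-dynamic factor scores
(and the best single indicators) have similar power: the effect is a
drift common to the whole latent path, and slope testing gains little
from temporal smoothing beyond what the random-slope model already
pools. Null calibration (rejection ≈ α at δ=0) and monotonicity of
power in n hold and are tested; no ordering between DFM and CFM power
is asserted.

## Problem sizes used in the shipped experiments

The packaged acceptance run uses 200 replicates per grid cell (100 for
the two largest cells, n=300 with p=10 and p=15 at T=15) — at these
sizes the Monte-Carlo standard error of a cell mean is about
0.005–0.01. The power checks use 150 null replicates at n=200 subjects
and a two-point size grid with B=80 bootstrap replicates. These are the
package's default desk-scale settings; all replicate counts are
parameters.

## Known limitations

* One factor per subject (q=1); multi-factor and cross-loading
  extensions are out of scope, as are stationary (mean-reverting)
  transitions.
* No standard errors for the loadings; the likelihood trace and
  parameter-recovery simulations are the accuracy evidence.
* The cycle-1 closed form assumes an i.i.d. unit-variance factor, so it
  serves only as a fast proposal; the ascent safeguards (not the raw
  update) carry the convergence guarantee.
* Exact-diffuse initialization is not implemented; the diffuse proxy is
  for scoring at fixed parameters only.
* The mixed-model p-values use the normal reference (no small-sample
  degrees-of-freedom correction), adequate at the sample sizes used
  here.
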