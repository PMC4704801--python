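# dynfactor

Dynamic factor models for panels with **many subjects and short,
possibly unequally spaced time series** — the situation typical of
longitudinal epidemiological studies such as cognitive-aging cohorts,
where a battery of p neuropsychological tests is observed on n hundreds
of participants at 2–15 roughly annual visits, and the goal is a single
smooth latent index (overall cognition, memory, attention, ...) per
person per visit that is comparable across people and over time.

## Model

For subject i at visit time t the p standardized measures load on one
latent trait that evolves as a Gaussian random walk:

    y_it = f u_it + e_it,          e_it ~ N(0, diag(d))
    u_i,t+τ = u_it + η_it,         η_it ~ N(0, τ)

* `f` — loading vector, shared by all subjects (this is what makes the
  estimated trait comparable across people);
* `d` — idiosyncratic (test-specific) error variances;
* `τ` — the raw gap in years between consecutive visits, so unequally
  spaced and missing visits are handled by the state equation itself.

Subjects are independent and share `(f, d)`, so the stacked
np-dimensional filter factorizes exactly into n scalar-state Kalman
filters — estimation scales linearly in the number of subjects instead
of cubically.

**Estimation** is a two-cycle ECME iteration: cycle 1 applies the
closed-form EM update of classical factor analysis to the pooled
second-moment matrix of all subject-visits (updating `d` and giving an
intermediate `f`); cycle 2 maximizes the exact Kalman prediction-error
log-likelihood over `f` with `d` fixed. Safeguards (step damping plus a
numerical conditional-maximization fallback for `d`) make every
iteration ascend the true likelihood, so the fit converges to a
stationary point of the exact likelihood. The non-dynamic comparator
(CFM: classical confirmatory factor analysis, the same observation
equation with an i.i.d. factor) is fitted by cycle 1 alone and scored
cross-sectionally; the dynamic model is scored by fixed-interval
smoothing.

Also included: a synthetic panel generator with known latent paths, the
trace statistic `(u'û)² / ((u'u)(û'û))` (a multivariate R² of true on
estimated factor paths), residual diagnostics (Bowman–Shenton
normality, lag-1 Box–Ljung on filter-standardized innovations), and a
matched-pair bootstrap power analysis for group differences in the
annual rate of change, with required-sample-size inversion.

## Worked example

```
$ dynfactor simulate --n 40 --p 4 --t 5 --seed 2 --out demo/
wrote demo/panel.csv (200 visit rows)

$ dynfactor fit --model dfm --in demo/panel.csv --out demo/fit.json --no-standardize --seed 2
dfm fit: iterations=7 loglik=-452.5584 converged=True
wrote demo/fit.json
```

`demo/fit.json` holds the fitted loadings and variances, the smoothed
factor score (with variance) for every subject-visit, and the
log-likelihood trace. On this run the estimated factor paths explain
about 93% of the variance of the simulated true paths (trace statistic
0.928 against `demo/truth.csv`); the log-likelihood trace is
non-decreasing and the fit converged in 7 iterations.

The simulation grid and the power study are available both from Python
(`dynfactor.run_grid`, `dynfactor.bootstrap_power`) and from the CLI
(`dynfactor table1 ...`, `dynfactor power ...`); `dynfactor diagnose`
reports the residual diagnostics of a fitted model per variable.

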