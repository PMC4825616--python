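# Methods

## Forward model

A session delivers K bolus doses; dose k raises plasma concentration by its
peak increment D_k (arbitrary concentration units) at time t_k (minutes)
and decays exponentially with elimination half-life t_half. Tissue effect
lags concentration by a fixed delay t_shift and follows the sigmoid Emax
(Hill) model; the measured signal adds a quadratic baseline drift:

    C(t) = sum_k D_k * u(t - t_shift - t_k) * 2^(-(t - t_shift - t_k)/t_half)
    E(C) = e_max * C^n / (ec50^n + C^n)
    y(t) = a0 + a1*t + a2*t^2 + E(C(t)) + noise

The unit step uses u(0) = 1: a dose takes effect exactly at t_k + t_shift,
so the peak concentration D_k is attained at a sample that coincides with
an onset. Concentration is piecewise monotone, so the maximum of E(C(t))
over a window lies at a dose onset; `peak_effect` nevertheless searches a
dense grid (0.01 min) augmented with the exact onset times, which also
covers future non-monotone extensions. SNR of a (condition, noise) cell is
defined as that peak noise-free effect divided by the noise SD.

## The standard simulation study

`SimulationDesign` defaults encode the validation study the method is
intended for: four unit-peak doses at 0/10/20/30 min over a 40-min session
sampled every 0.25 min (161 points); t_half = 41 min, t_shift = 0.5 min,
Hill n = 1; baseline 1000 + 0.05 t; six conditions — a null tissue
(e_max = 0) and five responsive ones with EC50 in {0.25, 0.6, 2, pi, 7.5}
at e_max = 10; eight noise SDs {0.1, 0.2, 0.5, 1, 2, 5, 10, 20}
(log-spaced between 1% and 200% of e_max); 1000 Gaussian-noise replicates
per (condition, noise) cell: 48,000 noisy curves plus 6 clean ones. The
resulting peak effects range from 2.96 (EC50 = 7.5) to 9.27 (EC50 = 0.25).

Noise is independent per time point and replicate. Each curve draws from
its own RNG substream keyed by (condition index, noise index, replicate)
spawned from one master seed, so datasets are reproducible regardless of
generation order or parallel partitioning.

What the generator does *not* emulate: temporally autocorrelated or
heteroscedastic noise, scanner drifts beyond a quadratic, BOLD
nonlinearity, motion. Passing the simulation study therefore demonstrates
correctness of the estimator under its own assumptions and its noise
robustness — not performance on arbitrary real fMRI data.

## Inference

For fixed nonlinear parameters (q = log10 EC50, t_shift, optionally
t_half) every candidate model is linear in its remaining coefficients, with
basis columns [1], [1, t, t^2], or [1, t, t^2, E_unit] where
E_unit = C^n/(ec50^n + C^n); the e_max coefficient is unconstrained in
sign, accommodating drugs that suppress the signal.

Marginalization of the linear coefficients and noise SD is analytic:

- intercept: flat (improper) prior — present in all three models, its
  arbitrary constant cancels exactly from every model comparison;
- remaining (centered) coefficients: Zellner g-prior
  N(0, g * sigma^2 * (Xc' Xc)^-1), default g = 1e8;
- noise SD: Jeffreys prior.

This yields, for a model with k non-intercept columns,

    log m(y) = const - (1/2) log N - (k/2) log(1+g)
               - ((N-1)/2) log(RSS + ESS/(1+g))

which depends on the design only through its column span, and is invariant
under rescaling of the data — so model probabilities are scale-free. The
g-prior provides the Occam factor sqrt(1+g) per extra linear dimension
that a truly flat prior cannot (flat priors leave Bayes factors between
models of different dimension ill-defined). g = 1e8 says a signal
component may be up to ~10^4 times the noise SD, an order of magnitude
beyond the largest component-to-noise ratio the standard study contains
(baseline ~10^3 x the smallest noise SD), and implies an effective
detection threshold near 4.3 sigma for the drug-effect component.

Uniform priors on the nonlinear parameters follow the method's standard
ranges: q in [-3, 1.3] (EC50 from 0.001 to 20), t_shift in [0, 1] min;
t_half is fixed (41 min) in simulation mode or uniform on [2, 60] min for
in-vivo-style fits. Hill n is fixed at 1. Posterior model probabilities
use equal model priors. A curve is reported as containing signal when
prob(full) exceeds a configurable threshold (default 0.5); only then are
parameters returned, both as the maximum-likelihood values and as posterior
means (linear coefficients: least-squares solution at the
maximum-likelihood nonlinear point). The residual SD is computed from the
preferred model's maximum-likelihood fit with N - m denominator.

### Quadrature engine

The 2-3 remaining dimensions are integrated over the prior box by
composite trapezoid quadrature on a tensor grid (defaults: 0.025 in q,
0.05 min in t_shift, 25 nodes in t_half when free). One subtlety: the
marginal likelihood is *discontinuous* in t_shift wherever a dose onset
crosses a sample time (the u(0)=1 step flips one sample in or out), so the
t_shift axis is split at those boundaries and integrated bin-wise, with
left bin edges evaluated just inside each bin; evidence then converges to
~1e-6 at the default grid (verified by grid-doubling). For curve batches
sharing a sampling grid the fitter precomputes, per node, the orthonormal
extension of the drift basis by the unit effect shape; a fit then costs a
few matrix-vector products (~1 ms per curve), making the full-size study
tractable on one CPU. The maximum-likelihood nonlinear point is polished
off-grid by bounded Nelder–Mead.

### MCMC engine

The sampling engine mirrors the method's original description: an ensemble
sampler (emcee stretch moves, 50 walkers) is annealed up a ladder of 30
geometrically spaced inverse temperatures from 1e-4 to 1, with 100 sweeps
per rung of which the first half is discarded as equilibration — 2500
retained samples per annealing step. Evidence is estimated by
stepping-stone along the ladder (each temperature ratio estimated from the
colder rung's samples), which has far lower discretization bias than
trapezoid thermodynamic integration at the same cost. Runs are exactly
reproducible given a seed. On a 20-curve reference suite the two engines
agree within |delta log evidence| ~ 0.15 (bound tested: 0.5). The
maximum-likelihood sample is the first occurrence of the best sampled
point. Models without nonlinear parameters are evaluated in closed form.

## Evaluation harness

`run_study` fits every curve of a design (checkpointable, deterministic);
summaries mirror the method's standard validation surfaces: per-cell
sensitivity (fraction with prob(full) > threshold), mean probability vs
SNR, false-positive count over the null condition, and EC50 accuracy —
arithmetic means of estimates and of estimated/input ratios over accepted
curves only; cells with no accepted curve contribute no accuracy point
(NaN, not zero). The default scaled-down replication for routine checks is
25 replicates per cell (binomial error ~10%); the full 1000 is a config
change. `accuracy_snr_threshold` reports the smallest cell SNR above which
every cell's mean ratio stays within 1.5-fold of unity; at 25 reps/cell
this lands between ~4 and ~6 depending on seed, always below 6.5.

## Voxelwise fitting

Each in-mask voxel of a 4D NIfTI volume is fitted independently with the
same engine as single-curve fits (bitwise-identical results regardless of
partitioning). Frame times come from a sidecar JSON because a NIfTI TR
cannot express shifted or variable sampling. Output maps (prob, EC50,
e_max, t_shift, t_half, residual SD) use NaN as the missing value. Region
analyses are the user's extraction of a mean time course followed by a
single-curve fit.

## Design choices, degenerate inputs, limitations

- Curves need at least 8 points and nonzero variance; rank-deficient
  designs (degenerate grids) raise errors before fitting.
- The "no signal" model is a constant-mean model — a literal zero-mean
  model would be absurd against ~1000-unit baselines.
- t_shift is structurally identified only to within one sampling interval:
  between sample points, a shift is absorbed by a 2^(t_shift/t_half)
  rescaling of the effect column, i.e. by e_max. At 0.25-min sampling,
  expect t_shift estimates within a bin of the truth, not better.
- With the default g the detection boundary sits at cell SNR ~4-6. This is
  deliberately conservative: over the full null study the maximal spurious
  effect t-statistic across the (q, t_shift) prior box reaches ~3.5, so a
  laxer prior would begin to admit false positives, and the package
  prioritizes the method's no-false-positive character. Users who prefer
  more sensitivity at low SNR can lower g (the threshold scales as
  sqrt(log g)).
- EC50 estimates near the upper prior bound (EC50 -> 20) are compressed by
  the prior box; with weak signal the estimate distribution is skewed high
  (conservative: sensitivity to drug is understated, not overstated).
- Emax=0-condition noise uses the same absolute SD ladder as responsive
  conditions (one ladder for all six curves).
- Accuracy aggregation uses arithmetic means (matching "mean estimated
  EC50"); a geometric alternative is a one-line change on the summary
  table but is not the default.
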