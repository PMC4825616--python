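# quantpd

Bayesian model selection and EC50 estimation for multi-dose pharmacodynamic
imaging time courses.

## The problem

Estimating how sensitive a tissue is to a drug — its EC50, the plasma
concentration producing half the maximum effect — classically requires many
subjects and many dose levels. An alternative is to give several small
doses within a *single* imaging session (e.g. pharmacological fMRI) and fit
a pharmacokinetic–pharmacodynamic (PKPD) model to each region's or voxel's
time–signal curve. The catch: imaging signals drift, are noisy, and often
contain no drug response at all, so a fitting procedure must first decide
*whether* there is a dose-locked signal before quantifying it.

`quantpd` implements this workflow for scientists running multi-dose
pharmacodynamic imaging experiments: a forward simulator, a Bayesian
model-selection and estimation engine, a simulation-study harness for
validating operating characteristics, and voxelwise fitting of 4D NIfTI
images.

## The model

Plasma concentration from K bolus doses with peaks $D_k$ at times $t_k$,
eliminated with half-life $t_{1/2}$ and acting after a delay $t_s$:

$$C(t) = \sum_{k=1}^{K} D_k\, u(t - t_s - t_k)\, 2^{-(t - t_s - t_k)/t_{1/2}}$$

Sigmoid (Hill) concentration–effect relation and quadratic baseline drift:

$$E(C) = \frac{E_{max} C^n}{EC_{50}^n + C^n}, \qquad
  B(t) = a_0 + a_1 t + a_2 t^2, \qquad y(t) = B(t) + E(C(t)) + \varepsilon$$

Three nested models compete for each curve: **full** ($B + E$), **baseline**
($B$ only), and **no-signal** (constant). Their posterior probabilities are
computed under equal model priors; the linear parameters
($E_{max}, a_0, a_1, a_2$) and the noise SD are marginalized analytically
(flat intercept + Zellner g-prior + Jeffreys $\sigma$), leaving only
$q = \log_{10} EC_{50}$, $t_s$ (and optionally $t_{1/2}$) to integrate over
their uniform priors — by deterministic quadrature or by annealed ensemble
MCMC with stepping-stone evidence estimates. A curve "contains signal" when
prob(full) > 0.5; only then are parameters reported.

## Worked example

Fit one noisy simulated curve (true EC50 = 2, Gaussian noise SD = 1):

```python
import numpy as np
from quantpd import (SimulationDesign, EffectParams, QuadratureFitter,
                     generate_clean_curve, TimeCourse)

design = SimulationDesign(seed=7)               # the standard 6-condition study
curve = generate_clean_curve(EffectParams.from_ec50(10, 2.0), design)
noisy = TimeCourse(curve.times,
                   curve.values + np.random.default_rng(7).normal(0, 1.0, len(curve)))

fitter = QuadratureFitter(curve.times, design.schedule)
result = fitter.fit(noisy)
print(f"prob(full)     = {result.prob_full:.3f}")
est = result.estimates
print(f"EC50 (max-lik) = {est['ec50']['ml']:.2f}")
print(f"e_max          = {est['e_max']['ml']:.1f}")
print(f"residual SD    = {result.residual_sd:.2f}")
```

prints

```
prob(full)     = 1.000
EC50 (max-lik) = 2.43
e_max          = 10.6
residual SD    = 0.88
```

The full PKPD model is selected with certainty, the maximum-likelihood EC50
(2.43) lands within the expected scatter of the true value 2 at this
signal-to-noise ratio (~6), the effect amplitude is recovered (true 10),
and the residual SD estimates the injected noise. On a noise-only curve the
same call returns prob(full) ≈ 0 and no parameter estimates.

## Command line

```sh
quantpd simulate --config design.yaml --seed 1 --out curves.csv
quantpd fit curves.csv --engine quadrature --out results.csv
quantpd evaluate results.csv curves.json --out report/
quantpd voxelwise img.nii mask.nii --frame-times frames.json \
        --config cfg.yaml --out maps/
```

`simulate` writes a long-format CSV plus a JSON manifest; `fit` produces
one row per curve (model probabilities, $E_{max}$, EC50, $t_{1/2}$, $t_s$,
residual SD; parameters blank when prob(full) ≤ threshold); `evaluate`
summarizes a study into per-cell sensitivity/accuracy surfaces and figures;
`voxelwise` writes NIfTI parameter maps (NaN outside the mask).

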