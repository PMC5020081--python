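# ddm-recovery

Simulation–recovery toolkit for the Ratcliff diffusion model: how well can
the parameters of a two-choice decision process be re-estimated from
finite, possibly contaminated response-time data, and does *fixing* the
intertrial-variability parameters (a deliberately too-simple model) help
rather than hurt?

## Who this is for

Researchers fitting diffusion models to binary-decision RT data face two
practical choices: the optimization criterion — maximum likelihood (ML),
Kolmogorov–Smirnov (KS), or a binned chi-square (CS) — and the model
complexity, from the 4-parameter basic model up to the full 7-parameter
model with intertrial variabilities. This package simulates ground-truth
data, refits it under every combination of those choices, and scores the
result, so that such recommendations can be derived (and re-derived)
instead of assumed.

## The model

Evidence accumulates as a Wiener process with drift ν between absorbing
boundaries 0 and *a* (diffusion coefficient 1), starting at *z·a* with
relative start *z_r*; the response time is the boundary first-passage time
plus a non-decision time *t₀*. Across trials ν ~ N(ν, s_ν), *z_r* ~
U(z_r ± s_zr/2) and *t₀* ~ U(t₀ ± s_t0/2). Nested specifications fix
subsets of the variabilities: the 5-parameter model sets s_ν = s_zr = 0,
the 4-parameter model additionally s_t0 = 0, the 3-parameter model
additionally z_r = 0.5.

The numerical engine evaluates first-passage densities by the standard
small-time/large-time series (truncated for absolute error ≤ 1e-7), with
the normal drift variability integrated in closed form and the uniform
variabilities by Gauss–Legendre quadrature; CDFs use exact series sums
for models without drift variability and cached graded-grid integration
otherwise. Trials are sampled exactly by inverse-CDF on the trial-level
first-passage distribution — no Euler discretization anywhere.

Recovery is scored by (1) Pearson correlations between true and
re-estimated parameters, averaged over (a, ν, t₀, z_r) via Fisher's
Z-transform, (2) mean signed bias, and (3) the 95% quantile of the mean
estimation precision, `(1/4) Σ_k ((est_k − true_k)/w_k)²`, where the
weights are "best possible accuracy" scales (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from ddm_recovery import DiffusionParams, DiffusionFitter, simulate_trials

truth = DiffusionParams(a=1.2, v=1.0, t0=0.30, zr=0.50, sv=0.8, st0=0.15, szr=0.3)
data = simulate_trials(truth, 500, seed=11)

for n_free in (5, 7):
    est = DiffusionFitter(n_free=n_free, criterion="ml", random_state=0).fit(data)
    p = est.params_
    print(f"{n_free}-parameter ML fit: a={p.a:.3f} v={p.v:.3f} t0={p.t0:.3f} "
          f"zr={p.zr:.3f} sv={p.sv:.3f} st0={p.st0:.3f} szr={p.szr:.3f} "
          f"(NLL={est.objective_:.1f}, converged={est.converged_})")
```

prints

```
5-parameter ML fit: a=1.183 v=0.661 t0=0.283 zr=0.541 sv=0.000 st0=0.113 szr=0.000 (NLL=199.0, converged=True)
7-parameter ML fit: a=1.227 v=0.811 t0=0.306 zr=0.544 sv=0.751 st0=0.120 szr=0.493 (NLL=198.6, converged=False)
```

Both fits land close to the generating truth for the four main
parameters; the 7-parameter model buys a negligible likelihood gain
(ΔNLL ≈ 0.4) at the price of two extra poorly constrained variability
parameters — at 500 trials their estimates (s_ν = 0.75, s_zr = 0.49
vs. true 0.8 and 0.3) are mostly noise, which is exactly the trade-off
the recovery studies quantify.

Full factorial studies run from YAML configs:

```bash
ddm-recovery run-study  --config study.yaml   # recovery grid -> CSV tables
ddm-recovery run-retest --config retest.yaml  # reliability-ceiling simulation
ddm-recovery fit --data trials.dat --model 5 --criterion ks
```

`DiffusionFitter` follows scikit-learn conventions (`get_params`,
`set_params`, `fit`, fitted attributes with trailing underscores), so it
composes with sklearn tooling; `ddm_recovery.fit()` is the functional
shortcut.

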