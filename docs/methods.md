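# Methods

This note documents the model, the numerics, the synthetic-data
conditions, and the design choices behind `ddm_recovery`, in the spirit
of the methods documentation of simulation-heavy scientific packages.

## Model and first-passage numerics

The diffusion model describes a two-choice decision as a Wiener process
with drift ν and unit diffusion coefficient between absorbing boundaries
at 0 and *a* (all evidence quantities are on this σ = 1 scale; ranges
below assume it). The process starts at *z_r·a* and the observed RT is
the first-passage time plus the non-decision time *t₀*. Intertrial
distributions: drift normal with SD *s_ν*; relative start and
non-decision time uniform with widths *s_zr*, *s_t0* centred on *z_r*
and *t₀*. These trial-level distributional conventions follow common
practice in diffusion-model software; nothing in the package depends on
them beyond the generator and the variability integrals.

Density. The lower-boundary density factorizes into a driftless
unit-interval kernel and a drift factor. The kernel uses the small-time
reflection series or the large-time eigenfunction series, switching by
the usual term-count bounds with truncation chosen for absolute error
≤ 1e-7. The drift factor integrates the normal drift distribution in
closed form (a Gaussian integral), so drift variability costs nothing;
the two uniform variabilities use Gauss–Legendre quadrature (11 nodes
each by default, configurable) — the integrands are smooth, so the
quadrature error is far below the series tolerance. Upper-boundary
quantities come from the reflection (ν, z_r) → (−ν, 1−z_r).

CDF. For parameter sets without drift variability the CDF is evaluated
by exact series as well: a large-time tail sum, or for small normalized
times a sum of Gaussian-CDF terms obtained by integrating each
reflection term analytically (evaluated in log space to stay stable at
|ν·a| up to ~10). With drift variability there is no closed form; the
CDF is then the cumulative trapezoid of the closed-form-s_ν density on a
cached graded grid (points quadratically concentrated near the support
edge; 385 grid points inside the optimizer, 513+ for standalone
evaluation), with the *s_t0* uniform applied afterwards as a mixture of
time shifts. Grid-path and series-path agree to ~1e-4 in the tests, and
marginal probabilities of both boundaries sum to 1 within 1e-4.

Sampling. Trials are drawn exactly: per trial, (ν, z_r, t₀) from their
intertrial distributions, the boundary from the closed-form absorption
probability, and the decision time by bisection on the exact basic-model
CDF (inverse-CDF sampling). The suite cross-validates simulator against
density: the sup distance between the empirical CDF of 1e6 samples and
the quadrature CDF stays below 0.005 for random parameter sets — this is
the load-bearing consistency check between the two independent routes.

## Synthetic-data conditions

The generator reproduces the two study designs this package targets:

- *Uniform recovery population* (`study1_population`): a ∈ [0.5, 2.0],
  ν ∈ [−4, 4], t₀ ∈ [0.2, 0.5] s, z_r ∈ [0.3, 0.7], s_ν ∈ [0, 1],
  s_t0 ∈ [0, 0.2] s, s_zr ∈ [0, 0.5]. The two-drift variant replaces ν
  by stimulus-specific drifts ν₀ ~ N(−2.35, 1.0), ν₁ ~ N(2.00, 1.0)
  (mean magnitude difference 0.35); two-drift data interleave the two
  stimulus types in equal numbers, a choice the package makes since only
  joint estimation is specified.
- *Empirical-moment populations* (`study2_population`): multivariate
  normals matching the means/SDs of lexical-decision and
  recognition-memory fits (e.g. LDT: a 1.42(0.32), ν₀ −4.01(1.13),
  ν₁ 3.10(1.11), t₀ 0.48(0.04), z_r 0.53(0.06), s_ν 1.34(0.64),
  s_t0 0.15(0.05), s_zr 0.37(0.25)). The correlation matrix defaults to
  identity and is configurable; the empirical correlations are not
  published. Draws violating the parameter domain are redrawn.

Contamination replaces round(rate·n) randomly chosen trials (default
4%): *fast* contaminants get Bernoulli(0.5) responses and RTs uniform in
t_min ± 100 ms with t_min = t₀ − s_t0/2 (truncated at zero), emulating
guesses at the lower edge; *slow* contaminants replace only the RT with
values uniform in [Q3 + 1.5·IQR, Q3 + 5·IQR] of the pre-replacement
distribution, emulating lapses. Within-range distributions are uniform —
only the ranges are prescribed, uniformity is the package's choice.
Datasets with fewer than 4% of trials at either boundary are flagged by
the threshold-balance filter; summaries exclude them, record tables keep
them.

What the generator does **not** emulate: sequential dependencies,
practice/fatigue drifts, real contaminant structure, or between-session
state changes (the retest simulation deliberately assumes equal
parameters in both sessions, which is what makes it a reliability
*ceiling*). Passing tests therefore certify the estimation machinery
under the model's own assumptions, not robustness to every real-data
pathology.

## Estimation

Objectives. ML is the summed negative log density per trial with a
per-trial floor of 1e-10 — the floor keeps the objective finite when
trials fall outside the predicted support, and its harshness (−log floor
≈ 23 per trial) is precisely why ML is sensitive to fast contaminants,
an effect the studies measure rather than suppress. KS is the sup
distance between empirical and model joint CDFs on a signed-RT axis
(lower-boundary RTs negated). CS is Pearson's chi-square over response ×
RT-bin cells with edges at the 0.1/0.3/0.5/0.7/0.9 quantiles of each
response's RTs; responses with fewer than 12 trials collapse to one
pooled bin (flagged). For two-drift data ML and CS sum over stimulus
types and KS takes the maximum of the per-stimulus statistics.

Optimization. Nelder–Mead on a transformed unconstrained space (log for
a, t₀, s_ν, s_t0; logit for z_r and for s_zr as a fraction of its
feasible width, which enforces the start-point domain by construction;
the t₀ ≥ s_t0/2 constraint is handled by clipping plus a linear
penalty). Starts are data-driven — EZ-style moment inversion for
(a, ν, t₀) from accuracy, RT mean and RT variance, z_r at 0.5 — plus a
variability-start series: the default (s_ν = 0.5, s_zr = 0.3,
s_t0 = 0.2), or zeros / half-maxima / maxima for robustness analyses.
Three starts per fit (data-driven plus two perturbed restarts);
evaluation budgets of 150·d (first start) and 80·d (restarts) function
evaluations for d free parameters, tolerance 1e-4. These budgets were
chosen so a full desk-scale study grid completes in minutes; the
convergence flag records when the optimizer stopped on tolerance rather
than budget. Fixed parameters are pinned exactly (the 5-parameter model
returns s_ν = s_zr = 0 identically, etc.).

Inside the optimizer the ML density switches automatically from
trial-wise quadrature to interpolation on the cached graded grid when
trials × quadrature nodes exceeds ~4000; the two paths agree to well
under 0.01 in total log-likelihood on moderate datasets (tested), and
the switch only trades constant-factor speed.

## Evaluation

Mean estimation precision weights squared deviations by a per-parameter
"best possible accuracy". Those constants are not published anywhere, so
the package operationalizes them as the SD of (est − true) achieved by
the *generating* 7-parameter model fitted with ML at 5000 trials on the
uniform recovery population — the best accuracy reachable in practice.
The shipped defaults (a 0.0456, ν 0.1774, t₀ 0.0161, z_r 0.0218) come
from exactly that calibration with 100 parameter sets;
`PrecisionWeights.calibrate` recomputes them for any other population,
and all ranking-style conclusions are invariant to any fixed positive
choice of weights. Quantiles use linear interpolation
("type 7"). Fisher-Z averaging clamps |r| = 1 to 1 − 1e-12; parameters
with fuzz-level variance (< 1e-10 relative) are reported as NaN rather
than spurious correlations. Model-superiority tables report *all* tied
winners, since several models often perform near-identically.

For two-drift designs the drift measure everywhere is ν_total = ν₁ − ν₀
(upper-stimulus minus lower-stimulus drift), the same quantity used for
retest reliability; this keeps one-drift and two-drift cells comparable
on a single drift axis.

## Study runner

Per-cell seeds derive from the master seed and the cell labels through
CRC-hashed `SeedSequence` spawning, so any cell can be reproduced in
isolation and reruns are byte-identical. The same simulated dataset is
fitted by all criteria and model specifications of a cell — model
comparisons are within-data. Failed or filtered cells stay in the record
table with status flags; summaries exclude filtered datasets and the
manifest reports both tallies. RTs are stored in seconds throughout;
millisecond constants (the ±100 ms fast-contaminant window) are
converted at the contamination boundary only.

## Problem sizes

The test suite exercises the pipeline at desk scale, chosen as the
package's own verification conditions: 10 parameter sets × 1e6 trials
for the simulator/density cross-check; 100 parameter sets at 5000 trials
for true-model recovery (r > 0.95 per parameter); 100 sets × 200
contaminated trials for the 5-vs-7-parameter comparison under ML and KS;
100 sets across trial numbers {48, 200, 1000} for precision
monotonicity; and 100 simulated subjects × two sessions at {32, 1000}
trials for the reliability ceiling. Full-scale grids (1000 sets, seven
trial numbers, all three criteria, all four models) run through the same
`run_recovery_study` code path from a YAML config.

## Known limitations

- No intertrial variability of threshold separation, and none of the
  model extensions (Lévy noise, collapsing bounds, leakage).
- CS binning and KS tie-handling conventions are declared (quantile
  edges, pooling below 12 trials, sup over both step sides); other
  software may bin differently, so CS values are comparable within the
  package, not across programs.
- The optimizer is a budgeted local search with restarts; pathological
  datasets (tiny n, extreme drifts) can end at the budget with the
  convergence flag unset, and such fits are kept, flagged, in the
  records — mirroring how unsupervised batch fitting behaves in
  practice.
- Hierarchical/Bayesian estimation and closed-form EZ estimation are out
  of scope (EZ appears only as a starting-value heuristic).
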