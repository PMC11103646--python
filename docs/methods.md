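# Methods

This note documents the models, numerical choices and design decisions behind
`choicedyn`, and what the synthetic-cohort validation does and does not
establish about real data.

## Task and data model

A trial is one self-paced episode of a 2AFC choice-learning task: the animal
initiates at a center port; either one luminance cue (single offer, 2/3 of
trials) or both cues (dual offer, 1/3) appear over the side ports; the
response latency is the time from initiation to the side poke.  The high
offer is 8 illuminated LEDs paired with the high-value reward, the low offer
2 LEDs.  Errors — pokes at a non-illuminated port — can occur only on
single-offer trials; they are analyzed as rates and their latencies are never
entered into latency analyses.  The canonical interchange format is a flat
UTF-8 CSV, one row per trial, with 1-based session/trial indices and all
times in seconds; validation checks every record-level invariant (offer
consistency, choice domain, monotone trial onsets, key uniqueness) and
reports violations as data rather than exceptions.

## Screening and descriptive measures

Latencies above 3 s are screened out as task disengagement before any latency
analysis, and removal counts are preserved so that screened + removed equals
the original count.  Medians use the linear-interpolation definition; a
rat×session×trial-type×value cell with fewer than 5 trials reports a missing
median (small dual-offer low-value cells are otherwise unstable).
Cohort-level latency summaries are means of per-rat medians, matching how the
repeated-measures tests operate on per-rat values; pooling trials across rats
first would weight fast rats more heavily, and with per-rat trial counts this
choice shifts cohort medians by a few milliseconds at most.

Within-session slowing is a robust linear regression of latency on trial
onset time: an M-estimator with the Huber norm at k = 1.345 standardized
residuals, MAD scale, iterated to a coefficient change below 1e-8 or 200
iterations (statsmodels RLM).  Without outliers this reduces exactly to least
squares; with a few percent of gross outliers it recovers slopes of the
order 5e-5 s/s that OLS misses.

## Ex-Gaussian latency model

The latency density is the convolution of Normal(μ, σ) and Exponential(τ):

    f(t) = (1/τ) exp(μ/τ + σ²/(2τ²) − t/τ) Φ((t−μ)/σ − σ/τ)

with mean μ+τ, variance σ²+τ², skewness 2τ³/(σ²+τ²)^{3/2}.  The density is
evaluated in log space (`scipy.special.log_ndtr`) so the near-Gaussian regime
τ ≪ σ stays finite.  Fitting is maximum likelihood (L-BFGS-B, σ and τ bounded
positive) from a moment start: τ₀ = sd·(skew/2)^{1/3} clipped into the
feasible cone, μ₀ = mean − τ₀, σ₀² = max(var − τ₀², ε).  A fit requires at
least 40 latencies.

Adequacy is checked by the simulate-from-fit procedure: a synthetic sample of
the same size as the raw data is drawn from the fitted parameters and
compared with the raw sample by a two-sample KS test; if that rejects at
α = 0.05 a rank-sum test is run, and the fit is accepted when either test
fails to distinguish the samples.  Matching the synthetic sample size to the
raw n keeps the KS comparison calibrated.  On data truly generated from the
fitted parameters this accepts ≈95% of validation seeds (the KS type-I
rate), which the acceptance suite verifies.

## Generalized drift-diffusion model

Evidence x(t) accumulates between absorbing boundaries 0 (low choice) and a
(high choice), from z = a/2 + z₀, with drift v = k (ln L_high − ln L_low) and
diffusion SD s.  Observed latency = decision time + t₀.  A lapse mixture with
weight λ contributes stimulus-independent responses (uniform choice,
exponential timing with rate r).  Free parameters: k, a, t₀.  Fixed
constants: s = 1.5, z₀ = 0.1 (absolute evidence units toward the high
boundary; a > 0.2 is enforced so the start stays interior), λ = 0.2, r = 1/s.
The λ = 0.2 constant is interpreted as the *mixture weight* of the lapse
process with the lapse density's mass split evenly over the two choices; the
alternative reading (0.2 as the exponential's rate) is available by setting
the exposed `lapse_rate` constant.  Fixing s resolves the diffusion scale
degeneracy — scaling (k, a, z₀, s) by a common factor leaves all choice
probabilities unchanged, which the tests verify numerically.  Natural
logarithms of the LED counts (8, 2) stand in for measured luminances, giving
a fixed contrast of ln 4.

### First-passage solvers

Two independent routes compute the boundary-resolved first-passage density:

* **Analytic series** (default, used for likelihoods).  In normalized time
  u = t s²/a² the lower-boundary density uses the spectral (large-u)
  expansion for u ≥ 0.12 and the image-sum (small-u) expansion below, with
  24 spectral terms / 6 image pairs — truncation error far below 1e-6 over
  the fitted parameter range.
* **Crank–Nicolson Fokker–Planck** (cross-check).  p_t = −v p_x + (s²/2)p_xx
  on ≥200 interior nodes with absorbing ends; absorption densities are the
  boundary fluxes from one-sided second-order derivatives.  The delta initial
  condition is replaced by the exact free-space Gaussian a few steps in
  (boundary mass < 1e-14 at that horizon), which removes the slowly-converging
  grid-scale transient; when a barrier is too close for the Gaussian start
  the solver falls back to a node-split delta with Rannacher (backward-Euler)
  startup steps.  The steep early flux transient (before u ≈ 1) can be
  integrated with substeps.  A mass defect above 1e-3 raises a
  numerical-accuracy error rather than returning a bad solution.

At dt = 5e-4, nx = 1000, 8 early substeps, the two routes agree to better
than 1e-3 in density sup-norm and 1e-4 in choice probability across a
3×3 (k, a) grid, and both match the closed-form absorption probability
P = (1 − e^{−2vz/s²})/(1 − e^{−2va/s²}).

### Simulator

Euler–Maruyama with a Brownian-bridge correction: after each step the
probability that the within-step excursion touched a barrier,
exp(−2(a−x_t)(a−x_{t+dt})/(s² dt)), is sampled, which removes most of the
discretization bias of plain Euler.  At dt = 1–2 ms the simulated choice
fractions and latency distributions match the analytic solutions to
Monte-Carlo error, so the simulator serves as a third independent check and
as the generative engine of the synthetic cohorts.

### Fitting

The trial likelihood is (1−λ) f_boundary(t − t₀) + λ·½ r e^{−rt}, floored at
1e-12.  All trials in a fit share one condition, so each objective evaluation
needs a single series solve plus interpolation.  The global optimizer is
differential evolution (rand/1/bin, population 45 = 15 per dimension,
crossover 0.7, F ∈ [0.5, 1), box k ∈ [0, 6], a ∈ [0.3, 6], t₀ ∈ [0, 1])
followed by an L-BFGS-B polish; a fit landing on a box edge is flagged.  The
default budget (80 generations, tol 0.01) fits ~100-trial per-rat sessions in
a couple of seconds; the acceptance suite uses a larger budget (150
generations) for the n = 2,000 recovery benchmark, which recovers k and a
within a few percent and t₀ within ~10 ms.  Only dual-offer trials enter DDM
fits by default (`ddm_dual_only` exposes the all-trials variant), optionally
after trimming to the 95th latency percentile.

## Resampling statistics

* **Paired permutation test**: statistic = mean(y−x); null by sign-flipping
  each pair's difference.  With 2ⁿ ≤ n_perm the sign space is enumerated and
  p is exact; otherwise p = (1 + #{|stat*| ≥ |stat|})/(n_perm + 1)
  (Phipson–Smyth add-one, keeping p valid and never zero).  Effect sizes get
  a 95% BCa interval from 5,000 paired bootstrap resamples, with the bias
  correction from the bootstrap distribution's position and acceleration from
  the jackknife; a BCa interval that fails to cover the point estimate (rare,
  pathological resamples) is flagged.
* **Bonferroni**: p_adj = min(1, m·p), with m = number of sessions per value
  (5) for the offer-effect family, applied separately per value.
* **Repeated-measures ANOVA**: balanced complete within-subject designs only,
  one or two factors, each effect tested against its own subject interaction
  (F = MS_effect / MS_effect×subject); replicates within a subject×cell are
  averaged first; no sphericity correction.  Unbalanced input is an error
  naming the offending subjects.
* **Repeated-measures correlation**: common-slope ANCOVA with subject
  intercepts, computed on within-subject-centered variables;
  r = sign(b)·√(SS_slope/(SS_slope+SS_res)), df = n_obs − n_subjects − 1,
  p from the slope's F test, CI by Fisher z with the ANCOVA dof.  Verified
  against pingouin and against direct normal-equations solutions.
* KS and rank-sum tests wrap scipy (asymptotic rank-sum with tie
  correction); Spearman matrices are pairwise-complete with constant columns
  flagged.

## Synthetic cohort: what it emulates

Defaults encode the study conditions: 15 rats × 5 sessions × 300 trials, 1/3
dual-offer, 8 vs 2 LEDs, 5% single-offer errors.  Dual-offer (choice,
latency) pairs come from the DDM simulator with k = 0.83 (chosen so the
lapse-mixed high-choice probability is ≈72%), t₀ = 0.30 s, and a boundary
declining 2.4 → 2.1 → 2.0 → 1.9 → 1.85 across sessions — the learning effect,
steepest after the first session, with drift and nondecision time held
constant.  Single-offer latencies are ex-Gaussian: (μ, σ, τ) =
(0.40, 0.05, 0.12) s for high value and (0.44, 0.06, 0.14) s for low,
putting single-offer medians near 0.51/0.55 s and dual-offer slowing at
~0.07–0.21 s, shrinking over sessions as the boundary comes down.  All
latencies gain a linear within-session drift of 0.003 s per minute of session
time (5e-5 s/s), and trial onsets accumulate latency plus an inter-trial
interval of 2 s + Exp(mean 2 s).  Per-rat heterogeneity is log-normal
multiplicative jitter (SD 0.1) on k, a, t₀, μ and τ — multiplicative so every
parameter stays positive.  Child seeds are derived from the cohort seed via
`SeedSequence`, making cohorts byte-reproducible.

What the generator does **not** emulate: side biases and spatial strategies,
the pre-choice training stages, reward-magnitude sensitivity beyond the two
fixed values, sequential (win-stay/lose-shift) dependencies, and any
non-stationarity beyond the linear slowing term.  Passing the end-to-end
tests therefore shows that the pipeline *recovers the effects it assumes*
(offer-effect slowing, threshold decline, drift–preference coupling) at
realistic sample sizes and noise levels — it does not by itself validate the
model against animal behavior; for that, the `replicate` path runs the same
pipeline on converted MedPC data.

The inter-trial interval makes a 300-trial session span ~20–25 minutes; only
the per-minute slowing slope, never the absolute session length, enters any
analysis.

## Problem sizes

The test suite exercises the engine cross-checks on a 3×3 (k, a) grid at
dt = 5e-4; recovery benchmarks at n = 2,000 (DDM) and n = 5,000 (ex-Gauss);
permutation calibration over 1,000 null simulations at n = 10 pairs; and the
end-to-end stage on the full default cohort (22,500 trials, 80 DDM fits, 300
ex-Gaussian cells).  The complete suite runs in a few minutes on one CPU;
`scripts/acceptance.py` reruns the cohort analysis in about two.

## Known limitations

* The DDM omits across-trial drift/start variability and collapsing bounds;
  with heavy contamination beyond the lapse mixture, the 95th-percentile trim
  is the only defense.
* Pooled fits average over rat heterogeneity, so a pooled boundary is mildly
  compressed relative to the mean of per-rat boundaries.
* rm-ANOVA requires complete balanced designs by construction; rats missing
  cells are dropped (and named) rather than imputed.
* The BCa acceleration uses the jackknife; for n < ~8 pairs the interval can
  be unstable (the permutation p, exact in that regime, is the primary
  inference).
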