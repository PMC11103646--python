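# choicedyn

Behavioral dynamics of early choice learning in rodents: an analysis pipeline
for two-alternative forced-choice (2AFC) tasks in which animals first learn
the reward values of single stimuli and only later learn to choose between
them.

## The problem

When a rat that knows the value of two visual cues (a bright, high-value
stimulus and a dim, low-value one) is first offered both at once, does it
deliberate?  Behaviorally, deliberation shows up as *dual-offer slowing*: the
latency from trial initiation to the nosepoke response is longer when both
cues are present than when only one is.  This package implements the three
layers of analysis needed to characterize that effect and how it changes over
the first few sessions of choice learning:

1. **Descriptive measures** — per-rat median latencies (after screening out
   responses > 3 s), high-value choice percentages on dual-offer trials,
   single-offer error percentages, the *offer effect* (dual − single median
   latency at matched value), and robust (Huber) regression of within-session
   slowing.

2. **Ex-Gaussian decomposition** — each latency distribution is modelled as
   Normal(μ, σ) + Exponential(τ): μ indexes the sensorimotor peak of the
   distribution, τ its long right tail, which is read as variability in the
   decision process.  Fits are maximum likelihood and validated by
   regenerating data from the fitted parameters and testing it against the
   raw sample (Kolmogorov–Smirnov, with a rank-sum fallback).

3. **Generalized drift-diffusion modelling (DDM)** — dual-offer choices and
   latencies are jointly modelled as evidence accumulation between two
   absorbing boundaries 0 and *a*, starting at *a*/2 + *z₀*, with drift
   *v* = *k*·(ln L_high − ln L_low) tied to the luminance contrast of the two
   offers, diffusion noise *s*, nondecision time *t₀*, and a lapse mixture
   (weight λ, exponential timing).  Three parameters are free — *k*, *a*,
   *t₀* — while *s* = 1.5, *z₀* = 0.1 and λ = 0.2 are fixed constants.  The
   trial likelihood is the boundary-resolved first-passage density, computed
   two independent ways (an analytic series expansion and a Crank–Nicolson
   Fokker–Planck solver) and maximized by differential evolution.

Inference uses paired permutation tests (sign-flip null, 5,000 reshuffles)
with BCa bootstrap confidence intervals (5,000 resamples) and Bonferroni
correction, balanced repeated-measures ANOVA, and repeated-measures
correlation (common-slope ANCOVA) to relate the DDM parameters to choice
preference and the ex-Gaussian components.

Because the interesting scientific claims concern *changes over learning*, the
package ships a synthetic-cohort generator whose defaults encode the study
conditions (15 rats × five 300-trial sessions, 1/3 dual-offer trials, ~72%
high-value choices, <10% single-offer errors, right-skewed latencies with
~0.1–0.2 s dual-offer slowing, and a decision boundary that declines across
sessions).  Every stage of the pipeline is validated end-to-end against this
generator.

## Worked example

```python
from choicedyn import PipelineConfig, default_config, run_pipeline

report = run_pipeline(PipelineConfig(simulate=default_config(seed=1), seed=1))

perm = report.stats["offer_effect_permutation"]["high"]
s1 = next(d for d in perm if d["session_index"] == 1)
print(f"session-1 offer effect (high value): {s1['mean_diff']:.3f} s, "
      f"p = {s1['p_value']:.4f}")

pooled = report.ddm_fits.query("scope == 'pooled'").set_index("session_index")
print(f"boundary separation, session 1 -> 5: "
      f"{pooled.loc[1, 'a']:.2f} -> {pooled.loc[5, 'a']:.2f}")

rc = report.stats["rm_corr"]["k"]["choice_pct"]
print(f"drift vs choice-preference rm-corr: r = {rc['r']:.3f}, df = {rc['df']}")
```

prints

```
session-1 offer effect (high value): 0.177 s, p = 0.0002
boundary separation, session 1 -> 5: 2.12 -> 1.87
drift vs choice-preference rm-corr: r = 0.887, df = 59
```

Rats slow by ~0.18 s when given a choice in their first choice session (the
permutation test rejects the no-slowing null), the fitted decision threshold
declines with experience, and the drift coefficient tracks how strongly each
animal prefers the high-value stimulus, session by session.

A command-line interface mirrors the library:

```bash
choicedyn simulate --seed 7 --out trials.csv
choicedyn metrics  --in trials.csv --out metrics.csv
choicedyn run      --out report_dir --seed 7
```

## Replicating on real data

`choicedyn replicate --data converted.csv --out report_dir` runs the same
pipeline on a trial table converted from MedPC session files.  The canonical
CSV dialect (one row per trial) is documented in `choicedyn.task_model`;
converting the raw MedPC files is left to the user, since their layout is
apparatus-specific.
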