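"""Simulated cohorts of rats performing the choice-learning task.

The generator mirrors the analysis's own generative assumptions so that every
downstream stage can be exercised and validated without animal data:

* sessions mix ~2/3 single-offer and ~1/3 dual-offer trials, randomized by
  side; the high offer is 8 illuminated LEDs, the low offer 2;
* dual-offer (choice, latency) pairs are drawn from the lapse-mixed
  drift-diffusion simulator, with the decision boundary declining over the
  five choice-learning sessions (the learning effect under study) while drift
  and nondecision time stay constant;
* single-offer latencies are ex-Gaussian draws, value-specific, and slower
  for the low-value stimulus; single-offer errors are Bernoulli;
* all latencies gain a slow linear within-session drift (gradual task
  disengagement), implemented as extra nondecision time proportional to the
  trial's onset time;
* per-rat heterogeneity is multiplicative log-normal jitter on the drift
  coefficient, boundary, nondecision time and the ex-Gaussian mu/tau.

Defaults emulate the study conditions: 15 rats, five 300-trial sessions,
~72% high-value choices on dual offers, <10% single-offer errors, right-skewed
latencies with single-offer medians near 0.5 s and dual-offer slowing of
roughly 0.1-0.2 s that shrinks as the boundary comes down.

Determinism: every random stream is keyed off ``cfg.seed`` through
``numpy.random.SeedSequence`` child keys, so a config reproduces its cohort
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .ddm import Condition, DDMParams, simulate_ddm
from .exgauss import ExGaussParams, exgauss_sample
from .task_model import TrialDataset, TrialRecord

__all__ = ["CohortConfig", "RatParams", "default_config", "generate_session", "generate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    n_rats: int = 15
    n_sessions: int = 5
    trials_per_session: int = 300
    dual_fraction: float = 1.0 / 3.0
    luminance_high: float = 8.0
    luminance_low: float = 2.0
    single_error_rate: float = 0.05
    ddm_by_session: tuple[DDMParams, ...] = ()
    single_offer_exgauss: dict = field(default_factory=dict)  # value -> ExGaussParams
    slowing_slope_s_per_min: float = 0.003
    iti_fixed_s: float = 2.0
    iti_exp_mean_s: float = 2.0
    rat_heterogeneity_sd: float = 0.1
    seed: int = 20240517

    def validate(self) -> None:
        if not 0 <= self.dual_fraction < 1:
            raise ValueError(f"dual_fraction must be in [0,1), got {self.dual_fraction}")
        if self.trials_per_session <= 0:
            raise ValueError("trials_per_session must be > 0")
        if self.n_rats < 0 or self.n_sessions <= 0:
            raise ValueError("n_rats must be >= 0 and n_sessions > 0")
        if not self.luminance_high > self.luminance_low > 0:
            raise ValueError("need luminance_high > luminance_low > 0")
        if not 0 <= self.single_error_rate < 1:
            raise ValueError("single_error_rate must be in [0,1)")
        if len(self.ddm_by_session) != self.n_sessions:
            raise ValueError(
                f"ddm_by_session has {len(self.ddm_by_session)} entries "
                f"for {self.n_sessions} sessions"
            )
        for v in ("high", "low"):
            if v not in self.single_offer_exgauss:
                raise ValueError(f"single_offer_exgauss missing value {v!r}")

    @property
    def condition(self) -> Condition:
        return Condition(self.luminance_high, self.luminance_low)


def default_config(seed: int = 20240517) -> CohortConfig:
    """The study conditions: 15 rats x 5 sessions x 300 trials, 1/3 dual.

    The boundary separation declines over sessions (2.4 -> 1.85, steepest
    after the first session) while drift coefficient and nondecision time are
    constant — the generative analogue of the threshold-decline learning
    effect the analysis is built to detect.
    """
    boundaries = (2.4, 2.1, 2.0, 1.9, 1.85)
    ddm = tuple(
        DDMParams(drift_coef=0.83, boundary_sep=a, nondecision_t=0.30)
        for a in boundaries
    )
    cfg = CohortConfig(
        ddm_by_session=ddm,
        single_offer_exgauss={
            "high": ExGaussParams(mu=0.40, sigma=0.05, tau=0.12),
            "low": ExGaussParams(mu=0.44, sigma=0.06, tau=0.14),
        },
        seed=seed,
    )
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class RatParams:
    """Per-rat parameter bundle after heterogeneity jitter."""

    rat_id: str
    ddm_by_session: tuple[DDMParams, ...]
    single_offer_exgauss: dict


def _jitter_rat(cfg: CohortConfig, rat_index: int) -> RatParams:
    """Log-normal multiplicative jitter keeps every parameter positive."""
    ss = np.random.SeedSequence([cfg.seed, 1000 + rat_index])
    rng = np.random.default_rng(ss)
    sd = cfg.rat_heterogeneity_sd
    f_k, f_a, f_t0, f_mu, f_tau = np.exp(rng.normal(0.0, sd, 5))
    ddm = tuple(
        DDMParams(
            drift_coef=p.drift_coef * f_k,
            boundary_sep=p.boundary_sep * f_a,
            nondecision_t=p.nondecision_t * f_t0,
            noise=p.noise,
            start_offset=p.start_offset,
            lapse_mix=p.lapse_mix,
            lapse_rate=p.lapse_rate,
        )
        for p in cfg.ddm_by_session
    )
    exg = {
        v: ExGaussParams(mu=p.mu * f_mu, sigma=p.sigma, tau=p.tau * f_tau)
        for v, p in cfg.single_offer_exgauss.items()
    }
    return RatParams(rat_id=f"rat{rat_index + 1:02d}", ddm_by_session=ddm,
                     single_offer_exgauss=exg)


def generate_session(
    rat_params: RatParams,
    session_index: int,
    cfg: CohortConfig,
    seed: int | np.random.SeedSequence,
) -> list[TrialRecord]:
    """One choice-learning session of ``cfg.trials_per_session`` trials.

    The within-session slowing term grows linearly with the trial's onset time
    and is added to every latency (it models drive satiation, not a property
    of either trial type).  Trial onsets accumulate latency plus an
    inter-trial draw of ``iti_fixed_s + Exp(iti_exp_mean_s)``.
    """
    if session_index > cfg.n_sessions:
        raise ValueError("session_index exceeds cfg.n_sessions")
    ddm = rat_params.ddm_by_session[session_index - 1]
    for val in (ddm.drift_coef, ddm.boundary_sep, ddm.nondecision_t):
        if not np.isfinite(val):
            raise ValueError("non-finite DDM parameter")
    rng = np.random.default_rng(seed)
    cond = cfg.condition
    slope_per_s = cfg.slowing_slope_s_per_min / 60.0

    n = cfg.trials_per_session
    is_dual = rng.random(n) < cfg.dual_fraction
    n_dual = int(is_dual.sum())
    if n_dual:
        dual_choices, dual_lats = simulate_ddm(
            ddm, cond, n_dual, dt=0.002, seed=rng
        )
    di = 0
    trials: list[TrialRecord] = []
    t_clock = 0.0
    for i in range(n):
        t_start = t_clock
        slow = slope_per_s * t_start
        high_side = "left" if rng.random() < 0.5 else "right"
        if is_dual[i]:
            chosen = str(dual_choices[di])
            latency = float(dual_lats[di]) + slow
            di += 1
            rec = TrialRecord(
                rat_id=rat_params.rat_id,
                phase="choice_learning",
                session_index=session_index,
                trial_index=i + 1,
                trial_type="dual",
                offered_high=True,
                offered_low=True,
                high_side=high_side,
                chosen=chosen,
                is_error=False,
                latency_s=latency,
                trial_start_s=t_start,
            )
        else:
            value = "high" if rng.random() < 0.5 else "low"
            exg = rat_params.single_offer_exgauss[value]
            latency = float(exgauss_sample(exg, 1, seed=rng)[0]) + slow
            latency = max(latency, 0.05)
            is_err = bool(rng.random() < cfg.single_error_rate)
            rec = TrialRecord(
                rat_id=rat_params.rat_id,
                phase="choice_learning",
                session_index=session_index,
                trial_index=i + 1,
                trial_type="single",
                offered_high=value == "high",
                offered_low=value == "low",
                high_side=high_side,
                chosen="none" if is_err else value,
                is_error=is_err,
                latency_s=latency,
                trial_start_s=t_start,
            )
        trials.append(rec)
        iti = cfg.iti_fixed_s + rng.exponential(cfg.iti_exp_mean_s)
        t_clock = t_start + rec.latency_s + iti
    return trials


def generate_cohort(cfg: CohortConfig) -> TrialDataset:
    """Full cohort: ``n_rats`` x ``n_sessions`` sessions, deterministically
    keyed from ``cfg.seed``; the result always passes dataset validation."""
    cfg.validate()
    trials: list[TrialRecord] = []
    for r in range(cfg.n_rats):
        rat = _jitter_rat(cfg, r)
        for s in range(1, cfg.n_sessions + 1):
            child = np.random.SeedSequence([cfg.seed, 2000 + r, s])
            trials.extend(generate_session(rat, s, cfg, child))
    meta = {
        "source": "synthetic",
        "config": {
            "n_rats": cfg.n_rats,
            "n_sessions": cfg.n_sessions,
            "trials_per_session": cfg.trials_per_session,
            "seed": cfg.seed,
        },
    }
    return TrialDataset(trials=trials, meta=meta)
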