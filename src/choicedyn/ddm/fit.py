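"""Maximum-likelihood fitting of the generalized DDM by differential evolution.

The likelihood of a dual-offer trial is the lapse-mixed first-passage density
evaluated at the observed (choice, latency).  All trials of a fit share one
luminance condition, so each objective evaluation needs a single solve of the
first-passage problem (analytic series) followed by interpolation at the
trial latencies.  The global search is differential evolution (rand/1/bin,
population >= 15 per free dimension, crossover 0.7, F in [0.5, 1)) with a
local polish, which is robust to the multimodality that the nondecision-time
parameter induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .fpt import fpt_solve, trial_likelihood
from .params import Condition, DDMParams

__all__ = ["DEConfig", "DDMFit", "fit_ddm", "trim_to_percentile", "DEFAULT_BOUNDS"]

#: search box for (drift_coef k, boundary_sep a, nondecision_t t0)
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((0.0, 6.0), (0.3, 6.0), (0.0, 1.0))


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings; ``seed`` makes the fit deterministic."""

    popsize: int = 15  # per free dimension -> population 45 for 3 parameters
    maxiter: int = 80
    tol: float = 0.01
    seed: int = 0
    polish: bool = True


@dataclass
class DDMFit:
    params: DDMParams
    loglik: float
    n_trials: int
    scope: str = "pooled"  # or "per_rat"
    rat_id: str | None = None
    session_index: int | None = None
    converged: bool = True
    boundary_warning: bool = False
    n_evals: int = 0
    seed: int = 0


def trim_to_percentile(latencies: np.ndarray, percentile: float = 95.0) -> tuple[np.ndarray, float]:
    """Keep latencies up to the pth empirical percentile (linear interpolation).

    Returns ``(kept, cut_point)``.  Used to drop the extreme tail before
    fitting, which the first-passage likelihood is sensitive to.
    """
    if not 50.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (50, 100], got {percentile}")
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        raise ValueError("empty latency sample")
    cut = float(np.percentile(lat, percentile))
    return lat[lat <= cut], cut


def fit_ddm(
    choices: np.ndarray,
    latencies: np.ndarray,
    cond: Condition,
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
    de_config: DEConfig | None = None,
    template: DDMParams | None = None,
    min_trials: int = 50,
    dt: float = 0.005,
) -> DDMFit:
    """Fit (k, a, t0) to dual-offer (choice, latency) data.

    ``template`` supplies the fixed constants (noise, start offset, lapse);
    defaults to the standard constants.  Latencies should already be screened
    and, if configured, percentile-trimmed.
    """
    de = de_config or DEConfig()
    choices = np.asarray(choices, dtype=object)
    lat = np.asarray(latencies, dtype=float)
    if len(choices) != len(lat):
        raise ValueError("choices and latencies must have equal length")
    if len(lat) < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {len(lat)}")
    base = template or DDMParams(drift_coef=1.0, boundary_sep=2.0, nondecision_t=0.3)

    hi = choices == "high"
    lo = ~hi
    T = float(max(3.0, np.max(lat) + 0.25))
    # a must stay comfortably above 2*|z0| for the start point to be interior
    a_floor = 2.0 * abs(base.start_offset) + 0.1
    bounds = tuple(
        (max(b[0], a_floor), b[1]) if i == 1 else b for i, b in enumerate(bounds)
    )
    n_evals = 0

    def nll(theta: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        k, a, t0 = theta
        p = base.with_free(k, a, t0)
        sol = fpt_solve(p, cond, dt=dt, T=T, method="series")
        ll = 0.0
        if hi.any():
            ll += np.sum(np.log(trial_likelihood(p, cond, "high", lat[hi], sol)))
        if lo.any():
            ll += np.sum(np.log(trial_likelihood(p, cond, "low", lat[lo], sol)))
        return -ll

    res = differential_evolution(
        nll,
        bounds=bounds,
        strategy="rand1bin",
        popsize=de.popsize,
        maxiter=de.maxiter,
        tol=de.tol,
        mutation=(0.5, 1.0),
        recombination=0.7,
        seed=de.seed,
        polish=de.polish,
        init="latinhypercube",
    )
    k, a, t0 = res.x
    at_edge = any(
        abs(xi - b[0]) < 1e-8 * max(1.0, abs(b[0])) or
        abs(xi - b[1]) < 1e-8 * max(1.0, abs(b[1]))
        for xi, b in zip(res.x, bounds)
    )
    return DDMFit(
        params=base.with_free(float(k), float(a), float(t0)),
        loglik=float(-res.fun),
        n_trials=len(lat),
        converged=bool(res.success),
        boundary_warning=at_edge,
        n_evals=n_evals,
        seed=de.seed,
    )
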