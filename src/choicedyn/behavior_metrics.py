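"""Descriptive behavioral measures for the choice-learning task.

Latency analyses operate on a screened view of the data: responses slower than
3 s (task disengagement) and error trials are removed first.  Choice and error
percentages are computed per rat and session; the "offer effect" — the
difference between dual- and single-offer median latencies at matched reward
value — is the task's behavioral signature of deliberation.  Within-session
slowing is quantified with a robust (Huber) linear regression of latency on
trial onset time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task_model import TrialDataset

__all__ = [
    "screen_latencies",
    "median_latency",
    "choice_percentage",
    "error_percentage",
    "offer_effect",
    "within_session_slowing",
    "HuberFitResult",
    "MIN_GROUP_SIZE",
    "MAX_LATENCY_DEFAULT",
]

MAX_LATENCY_DEFAULT = 3.0
#: medians on fewer trials than this are reported as missing
MIN_GROUP_SIZE = 5


def _frame(dataset: TrialDataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(dataset, TrialDataset):
        df = dataset.to_frame()
    else:
        df = dataset.copy()
    if len(df):
        # reward value addressed by the trial: the offer on single trials,
        # the chosen stimulus on dual trials; errors carry no value
        single = df.trial_type == "single"
        df["value"] = np.where(
            df.is_error,
            "none",
            np.where(single, np.where(df.offered_high, "high", "low"), df.chosen),
        )
    else:
        df["value"] = pd.Series(dtype=str)
    return df


def screen_latencies(
    dataset: TrialDataset, max_latency_s: float = MAX_LATENCY_DEFAULT
) -> TrialDataset:
    """Latency-analysis view: drop over-threshold latencies and error trials.

    Removal counts are recorded in ``meta`` so that screened + removed equals
    the original trial count.
    """
    if not max_latency_s > 0:
        raise ValueError(f"max_latency_s must be > 0, got {max_latency_s}")
    n0 = len(dataset)
    n_slow = sum(1 for t in dataset if t.latency_s > max_latency_s)
    n_err = sum(1 for t in dataset if t.is_error and t.latency_s <= max_latency_s)
    out = dataset.filtered(
        lambda t: t.latency_s <= max_latency_s and not t.is_error
    )
    out.meta.update(
        dict(dataset.meta),
        screened_max_latency_s=max_latency_s,
        n_original=n0,
        n_removed_slow=n_slow,
        n_removed_error=n_err,
    )
    return out


def median_latency(
    dataset: TrialDataset | pd.DataFrame,
    by: tuple[str, ...] = ("rat_id", "session_index", "trial_type", "value"),
    min_n: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Per-group median latencies (linear interpolation at even n).

    Groups smaller than ``min_n`` keep their trial count but report a missing
    median.  Cohort-level summaries should average these per-rat medians.
    """
    df = _frame(dataset)
    if df.empty:
        return pd.DataFrame(columns=[*by, "median_latency_s", "n_trials"])
    g = df.groupby(list(by), observed=True)["latency_s"]
    out = g.agg(median_latency_s="median", n_trials="size").reset_index()
    out.loc[out.n_trials < min_n, "median_latency_s"] = np.nan
    return out


def choice_percentage(dataset: TrialDataset | pd.DataFrame) -> pd.DataFrame:
    """Percent high-value choices of all dual-offer trials, per rat x session."""
    df = _frame(dataset)
    dual = df[df.trial_type == "dual"]
    if dual.empty:
        return pd.DataFrame(columns=["rat_id", "session_index", "choice_pct", "n_dual"])
    g = dual.groupby(["rat_id", "session_index"], observed=True)
    out = g.apply(
        lambda s: pd.Series(
            {"choice_pct": 100.0 * np.mean(s.chosen == "high"), "n_dual": len(s)}
        ),
        include_groups=False,
    ).reset_index()
    out["n_dual"] = out["n_dual"].astype(int)
    return out


def error_percentage(dataset: TrialDataset | pd.DataFrame) -> pd.DataFrame:
    """Percent error trials of all single-offer trials, per rat x session.

    Must be computed on the unscreened dataset, since screening removes the
    error trials themselves.
    """
    df = _frame(dataset)
    single = df[df.trial_type == "single"]
    if single.empty:
        return pd.DataFrame(columns=["rat_id", "session_index", "error_pct", "n_single"])
    g = single.groupby(["rat_id", "session_index"], observed=True)
    out = g.apply(
        lambda s: pd.Series(
            {"error_pct": 100.0 * np.mean(s.is_error), "n_single": len(s)}
        ),
        include_groups=False,
    ).reset_index()
    out["n_single"] = out["n_single"].astype(int)
    return out


def offer_effect(
    dataset: TrialDataset | pd.DataFrame, min_n: int = MIN_GROUP_SIZE
) -> pd.DataFrame:
    """Dual-offer minus single-offer median latency, per rat x session x value.

    A positive value is response slowing under choice (deliberation).  A
    missing median on either side propagates to a missing difference.
    """
    med = median_latency(dataset, min_n=min_n)
    med = med[med.value.isin(["high", "low"])]
    wide = med.pivot_table(
        index=["rat_id", "session_index", "value"],
        columns="trial_type",
        values="median_latency_s",
        observed=True,
    ).reset_index()
    for col in ("single", "dual"):
        if col not in wide:
            wide[col] = np.nan
    wide["offer_effect_s"] = wide["dual"] - wide["single"]
    return wide[["rat_id", "session_index", "value", "single", "dual", "offer_effect_s"]]


@dataclass
class HuberFitResult:
    slope: float  # seconds of latency per second of session time
    intercept: float
    weighted_r2: float
    converged: bool
    n: int
    scale: float

    @property
    def slope_s_per_min(self) -> float:
        return self.slope * 60.0


def within_session_slowing(
    trials: TrialDataset | pd.DataFrame,
    k: float = 1.345,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> HuberFitResult:
    """Robust (Huber M-estimator) regression of latency on trial onset time.

    IRLS with Huber weights at tuning constant ``k`` standardized-residual
    units and MAD scale; coincides with least squares when no residual exceeds
    the threshold.  Non-convergence is flagged, not raised.
    """
    df = _frame(trials)
    df = df[~df.is_error] if len(df) else df
    if len(df) < 10:
        raise ValueError(f"need at least 10 trials, got {len(df)}")
    x = df.trial_start_s.to_numpy(float)
    y = df.latency_s.to_numpy(float)
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=k))
    fit = model.fit(maxiter=max_iter, tol=tol, conv="coefs", scale_est="mad")
    w = fit.weights
    resid = y - fit.fittedvalues
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    return HuberFitResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        weighted_r2=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        converged=bool(getattr(fit, "converged", True)),
        n=len(df),
        scale=float(fit.scale),
    )
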