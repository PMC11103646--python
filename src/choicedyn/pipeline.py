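"""End-to-end analysis pipeline.

Stages, in order: load or simulate -> validate -> error rates (pre-screen) ->
latency screening -> descriptive metrics -> ex-Gaussian fits per rat x session
x trial type x value -> DDM fits (pooled per session and per rat, dual-offer
trials only, 95th-percentile trimmed) -> inference (paired permutation tests
of the offer effect per value x session with Bonferroni correction, rmANOVA of
per-rat medians, repeated-measures correlations among DDM parameters, choice
preference and ex-Gaussian components).

Everything is deterministic under the config seed; the report carries full
provenance (config hash, seeds, model constants).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior_metrics as bm
from .ddm import Condition, DEConfig, DDMParams, fit_ddm, trim_to_percentile
from .exgauss import MIN_FIT_SIZE, fit_exgauss, validate_exgauss_fit
from .resampling_stats import bonferroni, paired_permutation_test, rm_anova, rm_corr
from .synthetic_data import CohortConfig, default_config, generate_cohort
from .task_model import TrialDataset, read_trial_table, validate_dataset, write_trial_table

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "replicate_from_deposited"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    input_path: str | None = None
    simulate: CohortConfig | None = None
    max_latency_s: float = 3.0
    trim_percentile: float | None = 95.0
    exgauss_min_n: int = MIN_FIT_SIZE
    ddm_min_trials: int = 50
    ddm_per_rat: bool = True
    ddm_dual_only: bool = True
    de_config: DEConfig = field(default_factory=lambda: DEConfig(maxiter=80))
    bonferroni_m: int | None = None  # default: number of sessions per value
    n_perm: int = 5000
    n_boot: int = 5000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be set")


@dataclass
class AnalysisReport:
    metrics: dict  # name -> DataFrame
    exgauss_fits: pd.DataFrame
    ddm_fits: pd.DataFrame
    stats: dict
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "stats": self.stats,
            "provenance": self.provenance,
            "tables": {
                name: df.to_dict(orient="records")
                for name, df in {
                    **self.metrics,
                    "exgauss_fits": self.exgauss_fits,
                    "ddm_fits": self.ddm_fits,
                }.items()
            },
        }

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.metrics.items():
            df.to_csv(out / f"{name}.csv", index=False)
        self.exgauss_fits.to_csv(out / "exgauss_fits.csv", index=False)
        self.ddm_fits.to_csv(out / "ddm_fits.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _config_hash(cfg: PipelineConfig) -> str:
    # output_dir is excluded: it does not affect any computed number
    d = dataclasses.replace(cfg, output_dir=None)
    return hashlib.sha256(repr(d).encode()).hexdigest()[:16]


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit child seed from string/int parts."""
    h = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _fit_exgauss_cells(screened: pd.DataFrame, min_n: int, seed: int) -> pd.DataFrame:
    rows = []
    for (rat, sess, ttype, val), grp in screened.groupby(
        ["rat_id", "session_index", "trial_type", "value"], observed=True
    ):
        if val not in ("high", "low"):
            continue
        rec = {
            "rat_id": rat, "session_index": sess,
            "trial_type": ttype, "value": val, "n": len(grp),
        }
        if len(grp) < min_n:
            rec.update(mu=np.nan, sigma=np.nan, tau=np.nan, loglik=np.nan,
                       converged=False, accepted=False, skipped=True)
        else:
            fit = fit_exgauss(grp.latency_s.to_numpy(), min_n=min_n)
            validate_exgauss_fit(
                grp.latency_s.to_numpy(), fit,
                seed=_stable_seed(seed, "exg", rat, sess, ttype, val),
            )
            rec.update(
                mu=fit.params.mu, sigma=fit.params.sigma, tau=fit.params.tau,
                loglik=fit.loglik, converged=fit.converged,
                accepted=bool(fit.accepted), skipped=False,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def _fit_ddm_groups(
    screened: pd.DataFrame,
    cond: Condition,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    dual = screened[screened.trial_type == "dual"] if cfg.ddm_dual_only else screened
    rows = []

    def one_fit(grp: pd.DataFrame, scope: str, rat, sess) -> dict | None:
        lat = grp.latency_s.to_numpy(float)
        ch = grp.chosen.to_numpy(object)
        if cfg.trim_percentile is not None:
            lat_t, cut = trim_to_percentile(lat, cfg.trim_percentile)
            ch = ch[lat <= cut]
            lat = lat_t
        if len(lat) < cfg.ddm_min_trials:
            return {
                "scope": scope, "rat_id": rat, "session_index": sess,
                "n": len(lat), "k": np.nan, "a": np.nan, "t0": np.nan,
                "loglik": np.nan, "converged": False,
                "boundary_warning": False, "skipped": True,
            }
        de = DEConfig(
            popsize=cfg.de_config.popsize,
            maxiter=cfg.de_config.maxiter,
            tol=cfg.de_config.tol,
            seed=_stable_seed(cfg.seed, "ddm", scope, rat, sess),
            polish=cfg.de_config.polish,
        )
        fit = fit_ddm(ch, lat, cond, de_config=de, min_trials=cfg.ddm_min_trials)
        p = fit.params
        return {
            "scope": scope, "rat_id": rat, "session_index": sess, "n": fit.n_trials,
            "k": p.drift_coef, "a": p.boundary_sep, "t0": p.nondecision_t,
            "loglik": fit.loglik, "converged": fit.converged,
            "boundary_warning": fit.boundary_warning, "skipped": False,
        }

    for sess, grp in dual.groupby("session_index", observed=True):
        rows.append(one_fit(grp, "pooled", "all", sess))
    if cfg.ddm_per_rat:
        for (rat, sess), grp in dual.groupby(["rat_id", "session_index"], observed=True):
            rows.append(one_fit(grp, "per_rat", rat, sess))
    return pd.DataFrame([r for r in rows if r is not None])


def _offer_effect_tests(
    med: pd.DataFrame, cfg: PipelineConfig
) -> dict:
    """Paired permutation tests (dual vs single medians) per value x session."""
    out: dict = {}
    sessions = sorted(med.session_index.unique())
    m = cfg.bonferroni_m or len(sessions)
    for value in ("high", "low"):
        per_sess = []
        for sess in sessions:
            sub = med[(med.value == value) & (med.session_index == sess)]
            wide = sub.pivot_table(
                index="rat_id", columns="trial_type",
                values="median_latency_s", observed=True,
            ).dropna()
            if len(wide) < 3 or "single" not in wide or "dual" not in wide:
                per_sess.append({"session_index": int(sess), "insufficient": True})
                continue
            res = paired_permutation_test(
                wide["single"].to_numpy(), wide["dual"].to_numpy(),
                n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                seed=_stable_seed(cfg.seed, "perm", value, sess),
            )
            per_sess.append({"session_index": int(sess), "n_rats": len(wide),
                             **res.to_dict()})
        ps = [d["p_value"] for d in per_sess if "p_value" in d]
        adj = bonferroni(ps, m=max(m, len(ps))) if ps else []
        ai = iter(adj)
        for d in per_sess:
            if "p_value" in d:
                d["p_bonferroni"] = float(next(ai))
        out[value] = per_sess
    return out


def _rm_anova_block(med: pd.DataFrame) -> dict:
    """Session x trial-type rmANOVA of per-rat medians, one per value level.

    Restricted to rats with a complete design (every session x trial-type
    cell); rats missing cells are dropped and named.
    """
    out: dict = {}
    n_sess = med.session_index.nunique()
    for value in ("high", "low"):
        sub = med[(med.value == value)].dropna(subset=["median_latency_s"])
        counts = sub.groupby("rat_id", observed=True).size()
        complete = counts[counts == 2 * n_sess].index
        dropped = sorted(set(sub.rat_id.unique()) - set(complete))
        sub = sub[sub.rat_id.isin(complete)]
        if sub.rat_id.nunique() < 3:
            out[value] = {"insufficient": True, "dropped_rats": dropped}
            continue
        if n_sess > 1:
            res = rm_anova(sub, dv="median_latency_s",
                           within=["session_index", "trial_type"], subject="rat_id")
        else:
            res = rm_anova(sub, dv="median_latency_s",
                           within="trial_type", subject="rat_id")
        out[value] = {
            "effects": {k: {kk: vv for kk, vv in v.items()} for k, v in res.effects.items()},
            "n_rats": int(sub.rat_id.nunique()),
            "dropped_rats": dropped,
        }
    return out


def _rm_corr_block(
    ddm_fits: pd.DataFrame,
    choice: pd.DataFrame,
    exg: pd.DataFrame,
    med_offer: pd.DataFrame,
) -> dict:
    """Repeated-measures correlations of per-rat DDM parameters with choice
    preference, ex-Gaussian components and the latency-difference proxies."""
    per_rat = ddm_fits[(ddm_fits.scope == "per_rat") & (~ddm_fits.skipped)]
    if per_rat.empty:
        return {"insufficient": True}
    base = per_rat[["rat_id", "session_index", "k", "a", "t0"]].merge(
        choice[["rat_id", "session_index", "choice_pct"]],
        on=["rat_id", "session_index"], how="left",
    )
    # ex-Gaussian mu/tau per rat x session: average of the fitted cells
    exg_ok = exg[~exg.skipped] if len(exg) else exg
    if len(exg_ok):
        exg_rs = exg_ok.groupby(["rat_id", "session_index"], observed=True)[
            ["mu", "tau"]
        ].mean().reset_index()
        base = base.merge(exg_rs, on=["rat_id", "session_index"], how="left")
    else:
        base["mu"] = np.nan
        base["tau"] = np.nan
    # choice proxy: dual-single median difference on high value;
    # value proxy: low-high single-offer median difference
    base = base.merge(med_offer, on=["rat_id", "session_index"], how="left")

    out: dict = {}
    for param in ("k", "a", "t0"):
        out[param] = {}
        for meas in ("choice_pct", "mu", "tau", "offer_effect_high_s", "value_effect_s"):
            if meas not in base:
                continue
            sub = base[["rat_id", param, meas]].dropna()
            try:
                res = rm_corr(sub, x=param, y=meas, subject="rat_id")
                out[param][meas] = {
                    "r": res.r, "df": res.df, "p": res.p,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                }
            except ValueError as e:
                out[param][meas] = {"error": str(e)}
    return out


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and return the report.

    Raises on the first failing stage with the stage named; outputs written so
    far (when ``output_dir`` is set) are left in place.
    """
    if config.simulate is not None:
        dataset = generate_cohort(config.simulate)
        cond = config.simulate.condition
    else:
        dataset = read_trial_table(config.input_path)
        cond = Condition(8.0, 2.0)

    vrep = validate_dataset(dataset)
    if not vrep.ok:
        raise RuntimeError(
            f"stage=validate: {len(vrep)} violation(s); first: {vrep.issues[0].message}"
        )

    err = bm.error_percentage(dataset)  # needs unscreened data
    screened_ds = bm.screen_latencies(dataset, config.max_latency_s)
    screened = bm._frame(screened_ds)

    med = bm.median_latency(screened_ds)
    choice = bm.choice_percentage(screened_ds)
    offer = bm.offer_effect(screened_ds)

    exg = _fit_exgauss_cells(screened, config.exgauss_min_n, config.seed)
    ddm_fits = _fit_ddm_groups(screened, cond, config)

    # per rat x session proxies for the correlation block
    oe_high = offer[offer.value == "high"][
        ["rat_id", "session_index", "offer_effect_s"]
    ].rename(columns={"offer_effect_s": "offer_effect_high_s"})
    med_single = med[(med.trial_type == "single")].pivot_table(
        index=["rat_id", "session_index"], columns="value",
        values="median_latency_s", observed=True,
    ).reset_index()
    if {"high", "low"}.issubset(med_single.columns):
        med_single["value_effect_s"] = med_single["low"] - med_single["high"]
    else:
        med_single["value_effect_s"] = np.nan
    proxies = oe_high.merge(
        med_single[["rat_id", "session_index", "value_effect_s"]],
        on=["rat_id", "session_index"], how="outer",
    )

    stats = {
        "offer_effect_permutation": _offer_effect_tests(med, config),
        "rm_anova_median_latency": _rm_anova_block(med),
        "rm_corr": _rm_corr_block(ddm_fits, choice, exg, proxies),
        "screening": {
            "n_original": screened_ds.meta.get("n_original"),
            "n_removed_slow": screened_ds.meta.get("n_removed_slow"),
            "n_removed_error": screened_ds.meta.get("n_removed_error"),
        },
    }

    constants = {}
    if config.simulate is not None and config.simulate.ddm_by_session:
        p0 = config.simulate.ddm_by_session[0]
        constants = {
            "noise": p0.noise, "start_offset": p0.start_offset,
            "lapse_mix": p0.lapse_mix, "lapse_rate": p0.lapse_rate,
        }
    else:
        d0 = DDMParams(drift_coef=1.0, boundary_sep=2.0, nondecision_t=0.3)
        constants = {
            "noise": d0.noise, "start_offset": d0.start_offset,
            "lapse_mix": d0.lapse_mix, "lapse_rate": d0.lapse_rate,
        }
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "max_latency_s": config.max_latency_s,
        "trim_percentile": config.trim_percentile,
        "ddm_constants": constants,
        "schema_version": REPORT_SCHEMA_VERSION,
        "source": dataset.meta.get("source"),
    }

    report = AnalysisReport(
        metrics={
            "median_latency": med,
            "choice_percentage": choice,
            "error_percentage": err,
            "offer_effect": offer,
        },
        exgauss_fits=exg,
        ddm_fits=ddm_fits,
        stats=stats,
        provenance=provenance,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def replicate_from_deposited(path: str | Path, seed: int = 0,
                             output_dir: str | None = None) -> AnalysisReport:
    """Run the standard pipeline on user-converted deposited data.

    ``path`` must point to a canonical trial CSV (see the data-model module
    for the column set; converting the original MedPC session files is the
    user's step).  The report gains a small comparison block of the headline
    quantities; with fewer than 3 rats or fewer than 2 sessions it is marked
    insufficient rather than populated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: convert the deposited MedPC session files to "
            "the canonical trial CSV (one row per trial; see task_model) and "
            "point --data at that file"
        )
    cfg = PipelineConfig(input_path=str(path), seed=seed, output_dir=output_dir)
    report = run_pipeline(cfg)
    choice = report.metrics["choice_percentage"]
    med = report.metrics["median_latency"]
    n_rats = choice.rat_id.nunique() if len(choice) else 0
    n_sess = med.session_index.nunique() if len(med) else 0
    comparison: dict = {"n_rats": int(n_rats), "n_sessions": int(n_sess)}
    if n_rats < 3 or n_sess < 1:
        comparison["status"] = "insufficient n"
    else:
        comparison["status"] = "ok"
        by_type = med.groupby("trial_type", observed=True).median_latency_s.mean()
        comparison["mean_choice_pct"] = float(choice.choice_pct.mean())
        comparison["median_latency_by_type_s"] = {
            k: float(v) for k, v in by_type.items()
        }
        oe = report.metrics["offer_effect"]
        comparison["mean_offer_effect_s"] = {
            v: float(oe[oe.value == v].offer_effect_s.mean()) for v in ("high", "low")
        }
    report.stats["deposited_comparison"] = comparison
    if output_dir:
        report.write(output_dir)
    return report
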