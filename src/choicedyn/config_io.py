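"""YAML/JSON (de)serialization for cohort and pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .ddm import DDMParams, DEConfig
from .exgauss import ExGaussParams
from .synthetic_data import CohortConfig, default_config

__all__ = ["cohort_config_to_dict", "cohort_config_from_dict",
           "load_cohort_config", "dump_cohort_config"]


def cohort_config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["ddm_by_session"] = [asdict(p) for p in cfg.ddm_by_session]
    d["single_offer_exgauss"] = {
        k: asdict(v) for k, v in cfg.single_offer_exgauss.items()
    }
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["ddm_by_session"] = tuple(DDMParams(**p) for p in d.get("ddm_by_session", []))
    d["single_offer_exgauss"] = {
        k: ExGaussParams(**v) for k, v in d.get("single_offer_exgauss", {}).items()
    }
    cfg = CohortConfig(**d)
    cfg.validate()
    return cfg


def load_cohort_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        return cohort_config_from_dict(yaml.safe_load(fh))


def dump_cohort_config(cfg: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_config_to_dict(cfg), fh, sort_keys=True)
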