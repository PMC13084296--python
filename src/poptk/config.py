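"""YAML/JSON configuration round-trip for models and study designs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .nlme import PopulationModel
from .pkmodel import CovariateEffect, OmegaMatrix, ThetaVector
from .synthetic import StudyConfig

__all__ = ["model_to_dict", "model_from_dict", "load_model", "save_model", "load_study_config"]


def model_to_dict(model: PopulationModel) -> dict:
    return {
        "structure": model.structure,
        "theta": asdict(model.theta),
        "omega": {
            "names": list(model.omega.names),
            "matrix": [[float(v) for v in row] for row in model.omega.matrix],
        },
        "error_model": model.error_model,
        "sigma_prop": model.sigma_prop,
        "sigma_add": model.sigma_add,
        "covariate_effects": [asdict(e) for e in model.covariate_effects],
    }


def model_from_dict(cfg: dict) -> PopulationModel:
    om = cfg["omega"]
    if "matrix" in om:
        omega = OmegaMatrix(np.asarray(om["matrix"], dtype=float), tuple(om["names"]))
    else:
        # compact form: %CV per effect plus optional correlations
        offd = {
            tuple(k.split(",")): v for k, v in (om.get("correlations") or {}).items()
        }
        omega = OmegaMatrix.from_cv(om["cv_percents"], offd, om.get("offdiag", "correlation"))
    return PopulationModel(
        theta=ThetaVector(**cfg["theta"]),
        omega=omega,
        sigma_prop=cfg.get("sigma_prop", 0.02),
        sigma_add=cfg.get("sigma_add", 0.0),
        error_model=cfg.get("error_model", "proportional"),
        structure=cfg.get("structure", 3),
        covariate_effects=tuple(
            CovariateEffect(**e) for e in cfg.get("covariate_effects", [])
        ),
    )


def load_model(path: str | Path) -> PopulationModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_model(model: PopulationModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_study_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "sampling_times_h" in cfg:
        cfg["sampling_times_h"] = tuple(cfg["sampling_times_h"])
    for key in ("wt_range", "age_range", "crcl_range"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return StudyConfig(**cfg)
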