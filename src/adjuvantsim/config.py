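"""YAML/JSON (de)serialization of model and generator configuration.

The master config carries the full :class:`~adjuvantsim.microsim.ModelParams`
(effect sizes, disutilities, thresholds, baseline hazards) with the published
defaults embedded, so a round-tripped file documents every simulation input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .complications import ComplicationParams
from .microsim import ModelParams
from .synthetic import GeneratorConfig

__all__ = ["model_params_to_dict", "model_params_from_dict",
           "generator_config_to_dict", "generator_config_from_dict",
           "load_model_params", "save_model_params",
           "load_generator_config", "save_generator_config"]


def model_params_to_dict(params: ModelParams) -> dict:
    d = dataclasses.asdict(params)
    d["treatment_hr_nsclc_ci"] = list(params.treatment_hr_nsclc_ci)
    d["early_toxicity_hr_ci"] = list(params.early_toxicity_hr_ci)
    # explicit per-stratum rate tables are runtime objects, not config
    d.pop("monthly_rates_overrides", None)
    return d


def model_params_from_dict(d: dict) -> ModelParams:
    d = dict(d)
    comp = d.pop("complication_params", None)
    params = ModelParams(**{k: v for k, v in d.items()
                            if k in {f.name for f in
                                     dataclasses.fields(ModelParams)}})
    if comp is not None:
        params.complication_params = ComplicationParams(**comp)
    params.treatment_hr_nsclc_ci = tuple(params.treatment_hr_nsclc_ci)
    params.early_toxicity_hr_ci = tuple(params.early_toxicity_hr_ci)
    params.validate()
    params.complication_params.validate()
    return params


def generator_config_to_dict(cfg: GeneratorConfig) -> dict:
    return dataclasses.asdict(cfg)


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    cfg = GeneratorConfig(**d)
    cfg.age_probs = tuple(cfg.age_probs)
    cfg.validate()
    return cfg


def _load(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _save(d: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_model_params(path) -> ModelParams:
    return model_params_from_dict(_load(path))


def save_model_params(params: ModelParams, path) -> None:
    _save(model_params_to_dict(params), path)


def load_generator_config(path) -> GeneratorConfig:
    return generator_config_from_dict(_load(path))


def save_generator_config(cfg: GeneratorConfig, path) -> None:
    _save(generator_config_to_dict(cfg), path)
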