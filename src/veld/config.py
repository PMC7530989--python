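"""Structured text (YAML) configuration.

A single YAML file can override any scientific parameter of the
pipeline: climate-generator structure, experiment factorial, soil
bucket, fire constants and PFT traits.  The shipped
``data/default_config.yaml`` documents every default; absent keys keep
the library defaults, so an empty file is a valid configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

from .climate import ClimateConfig
from .experiments import ExperimentConfig
from .fire import FireParams, DEFAULT_FIRE
from .vegetation import DEFAULT_PFTS, DEFAULT_SOIL, PFTDef, SoilParams

__all__ = ["Config", "load_config", "default_config_text"]


@dataclass
class Config:
    climate: ClimateConfig
    experiment: ExperimentConfig
    soil: SoilParams
    fire: FireParams
    pfts: tuple[PFTDef, ...]


def _override(obj, section: dict | None, name: str):
    if not section:
        return obj
    valid = {f.name for f in dataclasses.fields(obj)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    if "fire" in section and name == "experiment":
        section = {**section, "fire": tuple(bool(x) for x in section["fire"])}
    for key in ("co2_levels", "variants"):
        if key in section:
            section = {**section, key: tuple(section[key])}
    return replace(obj, **section)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config file; ``None`` gives the library defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    pfts = []
    pft_over = raw.get("pfts") or {}
    for p in DEFAULT_PFTS:
        sec = pft_over.get(p.name)
        if sec and "pathway" in sec:
            raise ValueError("pathway parameters are set in the 'photosynthesis' "
                             "module, not per PFT in the config")
        pfts.append(_override(p, sec, f"pfts.{p.name}"))

    return Config(
        climate=_override(ClimateConfig(), raw.get("climate"), "climate"),
        experiment=_override(ExperimentConfig(), raw.get("experiment"), "experiment"),
        soil=_override(DEFAULT_SOIL, raw.get("soil"), "soil"),
        fire=_override(DEFAULT_FIRE, raw.get("fire"), "fire"),
        pfts=tuple(pfts),
    )


def default_config_text() -> str:
    """The shipped, fully commented default configuration."""
    return resources.files("veld").joinpath("data/default_config.yaml").read_text()
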