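"""YAML run configuration: schema, defaults and validation."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Configuration does not satisfy the documented schema."""


DEFAULTS: dict = {
    "input": {
        "phospho": None,  # path or list of fraction paths; or use simulate
        "design": None,
        "simulate": None,  # dict of SimulationConfig overrides
    },
    "database": {
        "load": None,  # bundle directory
        "sources": None,  # {PSP: path, ...}
        "synonyms": None,  # custom synonym TSV
        "networkin": None,  # NetworKIN output TSV
        "networkin_score_min": 2.0,
    },
    "preprocess": {
        "loc_prob_min": 0.75,
        "impute": True,  # False -> MNAR cells set to zero
        "minprob_q": 0.01,
        "minprob_sigma_scale": 0.3,
        "merge_multiplicity": False,
    },
    "comparison": {
        "mode": "two_group",  # or one_vs_rest
        "test": None,
        "reference": None,  # ignored for one_vs_rest
        "reference_style": "pooled",  # pooled | mean_of_means
    },
    "enrichment": {
        "min_set_size": 2,
        "set_p_cutoff": 0.01,
        "fdr_cutoff": 0.05,
        "b_null": 100,
    },
    "report": {
        "waterfall_plot": True,
        "min_confidence": 0.8,
        "cancermine": None,  # gene/role annotation TSV
    },
    "seed": 0,
    "output": "kea_run",
}

_REQUIRED = ("comparison.test", "output")


def _deep_merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise ConfigError(f"unknown configuration key: {path}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(base[key], value, prefix=f"{path}.")
        else:
            out[key] = value
    return out


def load_config(source: str | Path | dict) -> dict:
    """Load and validate a run configuration (YAML path or dict).

    Unknown keys and violated constraints raise :class:`ConfigError`
    naming every offending key.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = copy.deepcopy(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = _deep_merge(DEFAULTS, raw)
    _validate(cfg)
    return cfg


def _get(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        node = node[part]
    return node


def _validate(cfg: dict) -> None:
    problems: list[str] = []
    for key in _REQUIRED:
        if _get(cfg, key) in (None, ""):
            problems.append(f"missing required key: {key}")
    if cfg["input"]["simulate"] is None:
        if not cfg["input"]["phospho"]:
            problems.append("missing required key: input.phospho (or input.simulate)")
        if not cfg["input"]["design"]:
            problems.append("missing required key: input.design (or input.simulate)")
        if not cfg["database"]["load"] and not cfg["database"]["sources"]:
            problems.append(
                "missing required key: database.load or database.sources"
            )
    mode = cfg["comparison"]["mode"]
    if mode not in ("two_group", "one_vs_rest"):
        problems.append("comparison.mode must be two_group or one_vs_rest")
    if mode == "two_group" and not cfg["comparison"]["reference"]:
        problems.append("missing required key: comparison.reference")
    if not 0.0 <= cfg["preprocess"]["loc_prob_min"] <= 1.0:
        problems.append("preprocess.loc_prob_min must lie in [0, 1]")
    if cfg["enrichment"]["b_null"] < 1:
        problems.append("enrichment.b_null must be >= 1")
    if problems:
        raise ConfigError("; ".join(problems))


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
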