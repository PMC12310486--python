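"""Run configuration: one YAML file drives every pipeline stage.

Sections mirror the stage configs (synthetic, fragment, pretrain, grarep,
model, evaluation) plus paths and one global seed. Unknown keys are rejected
rather than ignored, so a typo cannot silently fall back to a default. Stage
seeds not set explicitly in the file are derived from the global seed, which
therefore fully determines every stochastic choice in a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .embeddings import FragmentConfig, SkipGramConfig
from .grarep import GraRepConfig
from .model import ModelConfig
from .synthetic import SyntheticSpec

# offsets keep stage streams distinct while derived from one global seed
_SEED_OFFSETS = {"synthetic": 11, "fragment": 23, "pretrain": 37, "model": 53}


@dataclass(frozen=True)
class EvalConfig:
    folds: int = 5
    threshold: float = 0.5
    full_graph: bool = False
    negatives_seed: int = 0


@dataclass(frozen=True)
class PathsConfig:
    outdir: str = "runs/default"
    mirna_fasta: str | None = None
    mrna_fasta: str | None = None
    pairs_tsv: str | None = None


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    paths: PathsConfig = field(default_factory=PathsConfig)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    fragment: FragmentConfig = field(default_factory=FragmentConfig)
    pretrain: SkipGramConfig = field(default_factory=SkipGramConfig)
    grarep: GraRepConfig = field(default_factory=GraRepConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "paths": PathsConfig,
    "synthetic": SyntheticSpec,
    "fragment": FragmentConfig,
    "pretrain": SkipGramConfig,
    "grarep": GraRepConfig,
    "model": ModelConfig,
    "evaluation": EvalConfig,
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load a YAML run config; omitted keys take documented defaults.

    Stage ``seed`` fields absent from the file are derived from the global
    seed. ``seed_override`` (the CLI ``--seed`` flag) replaces the global
    seed before derivation.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    seed = int(raw.get("seed", 0)) if seed_override is None else int(seed_override)
    parts = {}
    for name, cls in _SECTIONS.items():
        section = dict(raw.get(name) or {})
        if name in _SEED_OFFSETS and "seed" not in section:
            section["seed"] = seed + _SEED_OFFSETS[name]
        parts[name] = _build_section(cls, section, name)
    return RunConfig(seed=seed, **parts)


def default_config(seed: int = 0) -> RunConfig:
    parts = {}
    for name, cls in _SECTIONS.items():
        section = {"seed": seed + _SEED_OFFSETS[name]} if name in _SEED_OFFSETS else {}
        parts[name] = cls(**section)
    return RunConfig(seed=seed, **parts)


def to_dict(cfg: RunConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(cfg)))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=True))
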