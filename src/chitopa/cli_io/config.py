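"""Enzyme definition files, packaged presets, and pipeline run configs."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

from ..cda_kinetics import DeacetylaseSpec
from ..digestion import HydrolaseSpec

__all__ = [
    "load_packaged_deacetylases",
    "load_packaged_hydrolases",
    "load_deacetylase_file",
    "load_hydrolase_file",
    "resolve_deacetylase",
    "resolve_hydrolase",
    "RunConfig",
]


def _packaged_yaml(name: str) -> dict:
    text = resources.files("chitopa.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_packaged_deacetylases() -> dict[str, DeacetylaseSpec]:
    data = _packaged_yaml("deacetylases.yaml")
    return {name: DeacetylaseSpec.from_dict(name, entry) for name, entry in data.items()}


def load_packaged_hydrolases() -> dict[str, HydrolaseSpec]:
    data = _packaged_yaml("hydrolases.yaml")
    return {name: HydrolaseSpec.from_dict(name, entry) for name, entry in data.items()}


def _load_single(path: str | os.PathLike) -> tuple[str, Mapping]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise ValueError(f"enzyme file {os.fspath(path)!r} must hold one named mapping")
    if len(data) != 1:
        raise ValueError(f"enzyme file {os.fspath(path)!r} must define exactly one enzyme")
    return next(iter(data.items()))


def load_deacetylase_file(path: str | os.PathLike) -> DeacetylaseSpec:
    name, entry = _load_single(path)
    return DeacetylaseSpec.from_dict(name, entry)


def load_hydrolase_file(path: str | os.PathLike) -> HydrolaseSpec:
    name, entry = _load_single(path)
    return HydrolaseSpec.from_dict(name, entry)


def resolve_deacetylase(name_or_path: str) -> DeacetylaseSpec:
    """Resolve a preset name or a YAML config path to a spec."""
    presets = load_packaged_deacetylases()
    if name_or_path in presets:
        return presets[name_or_path]
    if os.path.exists(name_or_path):
        return load_deacetylase_file(name_or_path)
    raise ValueError(
        f"unknown deacetylase {name_or_path!r}; presets: {sorted(presets)} (or pass a YAML path)"
    )


def resolve_hydrolase(name_or_path: str) -> HydrolaseSpec:
    presets = load_packaged_hydrolases()
    if name_or_path in presets:
        return presets[name_or_path]
    if os.path.exists(name_or_path):
        return load_hydrolase_file(name_or_path)
    raise ValueError(
        f"unknown hydrolase {name_or_path!r}; presets: {sorted(presets)} (or pass a YAML path)"
    )


@dataclass
class RunConfig:
    """Stage parameters for the end-to-end pipeline.

    ``generator.family`` is one of ``bernoulli``/``markov``/``regular``;
    ``lengths`` follows :class:`~chitopa.pattern_synthesis.DPDistributionSpec`.
    ``acetylation`` (optional) names a deacetylase and a target F_A applied
    to an all-D starting ensemble instead of a pattern generator.
    """

    generator: dict = field(default_factory=lambda: {"family": "bernoulli", "fa": 0.34})
    lengths: dict = field(
        default_factory=lambda: {"family": "schulz_zimm", "dpn": 700, "dispersity": 1.8,
                                 "n_chains": 100}
    )
    acetylation: dict | None = None
    digestion: dict = field(default_factory=lambda: {"enzyme": "chitinosanase"})
    fingerprint: dict = field(default_factory=lambda: {"dp_min": 2, "dp_max": 10, "noise_cv": 0.0})
    nmr: dict = field(default_factory=lambda: {"noise_cv": 0.0})
    seed: int = 0
    outdir: str = "chitopa_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "generator": self.generator,
            "lengths": self.lengths,
            "acetylation": self.acetylation,
            "digestion": self.digestion,
            "fingerprint": self.fingerprint,
            "nmr": self.nmr,
            "seed": self.seed,
            "outdir": self.outdir,
            "log_level": self.log_level,
        }

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (outdir/log level excluded)."""
        payload = self.to_dict()
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
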