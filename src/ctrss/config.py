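"""Experiment configuration: one YAML file drives generate/grid/curve/screen.

Houses the fixed evaluation constants (33% test fraction, 30% per-step
training reduction, k in {20, 40} selected codes, 1,000 bootstrap resamples
at the 2.5/97.5 percentiles) alongside paths, grid axes and the master
seed, so a full experiment is reproducible from a single artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .code_hierarchy import AggregationLevel
from .attribute_selection import SelectionMethod
from .evaluation import GridConfig
from .model_suite import ModelFamily
from .synthetic_cohort import CohortConfig


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    # input paths (relative paths resolve against the config file location)
    eav: str = "eav.csv"
    demographics: str = "demographics.csv"
    labels: str = "labels.csv"
    block_map: str | None = "block_map.csv"
    output_dir: str = "results"
    # grid axes
    families: list[str] = field(default_factory=lambda: [f.value for f in ModelFamily])
    levels: list[str] = field(default_factory=lambda: [l.value for l in AggregationLevel])
    methods: list[str] = field(default_factory=lambda: [m.value for m in SelectionMethod])
    k_values: list[int] = field(default_factory=lambda: [20, 40])
    # evaluation constants
    test_fraction: float = 1 / 3
    reduction_fraction: float = 0.3
    min_train_size: int = 10
    n_boot: int = 1000
    master_seed: int = 0
    # toggles
    stratified: bool = True
    selection_scope: str = "train"  # or "all"
    strict_block: bool = False
    cohort_name: str = "cohort"
    # synthetic-cohort generation (field names of CohortConfig)
    generator: dict = field(default_factory=dict)

    def validate(self) -> "ExperimentConfig":
        for axis in ("families", "levels", "methods", "k_values"):
            if not getattr(self, axis):
                raise ConfigError(f"grid axis {axis!r} is empty")
        for f in self.families:
            ModelFamily(f)
        for l in self.levels:
            AggregationLevel(l)
        for m in self.methods:
            SelectionMethod(m)
        if self.selection_scope not in ("train", "all"):
            raise ConfigError("selection_scope must be 'train' or 'all'")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0,1)")
        if not 0 < self.reduction_fraction < 1:
            raise ConfigError("reduction_fraction must be in (0,1)")
        return self

    def grid_config(self) -> GridConfig:
        return GridConfig(
            families=[ModelFamily(f) for f in self.families],
            levels=[AggregationLevel(l) for l in self.levels],
            methods=[SelectionMethod(m) for m in self.methods],
            k_values=list(self.k_values),
            test_fraction=self.test_fraction,
            reduction_fraction=self.reduction_fraction,
            min_train_size=self.min_train_size,
            n_boot=self.n_boot,
            master_seed=self.master_seed,
            stratified=self.stratified,
            selection_scope=self.selection_scope,
            strict_block=self.strict_block,
            cohort_name=self.cohort_name,
        )

    def cohort_config(self) -> CohortConfig:
        params = dict(self.generator)
        params.setdefault("seed", self.master_seed)
        if "age_range" in params:
            params["age_range"] = tuple(params["age_range"])
        return CohortConfig(**params)

    def save(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["generator"] = dict(self.generator)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @staticmethod
    def load(path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return ExperimentConfig(**payload).validate()

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def write_provenance(config: ExperimentConfig, path: str | Path) -> None:
    """Record what produced a run: config hash, seed, package version."""
    from . import __version__

    record = {
        "config_sha256": config.digest(),
        "master_seed": config.master_seed,
        "ctrss_version": __version__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
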