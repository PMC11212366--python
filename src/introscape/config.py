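"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

#: branch-length keys of a rooted quartet: four tips plus the internal
#: branch above the sister pair
BRANCH_KEYS = ("O", "P", "D", "F", "internal")

DEFAULT_SPECIES_BRANCHES = {
    "O": 0.05, "P": 0.010, "D": 0.008, "F": 0.008, "internal": 0.025,
}
DEFAULT_INTROGRESSION_BRANCHES = {
    "O": 0.05, "P": 0.008, "D": 0.008, "F": 0.010, "internal": 0.025,
}
# depth model roughly on the scale of a mid-coverage resequencing study
DEFAULT_DEPTH_MODEL = {
    "O": (24.0, 6.0), "P": (12.0, 4.0), "D": (25.0, 6.0), "F": (32.0, 8.0),
}


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic quartet study.

    ``seed`` fully determines every output; all randomness is drawn from
    child streams spawned off a single root ``numpy`` SeedSequence.
    """

    seed: int = 0
    chromosome_lengths: list[int] = field(default_factory=lambda: [500_000, 500_000])
    snv_spacing_mean: float = 85.0
    invariant_spacing_mean: float = 25.0
    species_tree_branch_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_BRANCHES))
    introgression_tree_branch_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTROGRESSION_BRANCHES))
    tract_count: int = 8
    tract_length_distribution: dict[str, float] = field(
        default_factory=lambda: {"mu": 9.2, "sigma": 0.6})  # log-normal, bases
    min_tract_gap: int = 1000
    heterozygosity_rate: float = 0.05
    depth_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_MODEL))
    depth_window: int = 500
    gene_count: int = 60
    gene_length_distribution: dict[str, float] = field(
        default_factory=lambda: {"mu": 8.5, "sigma": 0.5})  # log-normal, bases
    family_gene_count: int = 4
    family_min_gap: int = 400_000
    psg_fraction: float = 0.1
    indel_spacing_mean: float = 2000.0
    gq_model: dict[str, float] = field(
        default_factory=lambda: {"gq_mean": 60.0, "gq_sd": 22.0,
                                 "rgq_mean": 55.0, "rgq_sd": 22.0})
    sample_names: list[str] = field(default_factory=lambda: ["O", "P", "D", "F"])

    def validate(self) -> "SimulationConfig":
        if not self.chromosome_lengths:
            raise ConfigError("chromosome_lengths must be non-empty")
        if any(c <= 0 for c in self.chromosome_lengths):
            raise ConfigError("all chromosome lengths must be positive")
        if self.snv_spacing_mean <= 0 or self.invariant_spacing_mean <= 0:
            raise ConfigError("site spacing means must be positive")
        for name, bl in (("species", self.species_tree_branch_lengths),
                         ("introgression", self.introgression_tree_branch_lengths)):
            missing = set(BRANCH_KEYS) - set(bl)
            if missing:
                raise ConfigError(f"{name} tree branch lengths missing {sorted(missing)}")
            if any(v < 0 for v in bl.values()):
                raise ConfigError(f"{name} tree branch lengths must be nonnegative")
        if self.tract_count < 0 or self.gene_count < 0 or self.family_gene_count < 0:
            raise ConfigError("counts must be nonnegative")
        if not 0.0 <= self.heterozygosity_rate <= 1.0:
            raise ConfigError("heterozygosity_rate must be in [0, 1]")
        if not 0.0 <= self.psg_fraction <= 1.0:
            raise ConfigError("psg_fraction must be in [0, 1]")
        if self.family_gene_count > self.gene_count:
            raise ConfigError("family_gene_count cannot exceed gene_count")
        if set(self.sample_names) != {"O", "P", "D", "F"} and len(self.sample_names) != 4:
            raise ConfigError("exactly four sample names required")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        if "depth_model" in d:
            d["depth_model"] = {k: tuple(v) for k, v in d["depth_model"].items()}
        return cls(**d).validate()


@dataclass
class RunConfig:
    """Pipeline constants: thresholds, filters, and replicate counts."""

    seed: int = 0
    posterior_threshold: float = 0.9
    background_threshold: float = 0.9
    min_depth: float = 5.0
    max_depth: float = 100.0
    max_genotype_gap: int = 25_000
    long_tract_min: int = 10_000
    n_restarts: int = 100
    n_bootstrap_mean: int = 100_000
    n_density_bootstrap: int = 1_000
    n_density_permutation: int = 1_000
    n_enrichment_draws: int = 1_000
    n_block_iterations: int = 10_000
    block_size: int = 10_000
    block_draws: int = 164
    gene_min_depth: float = 10.0
    gene_max_depth: float = 100.0
    gene_breadth1_min: float = 0.75
    gene_breadth10_min: float = 0.50

    def validate(self) -> "RunConfig":
        if not 0.0 < self.posterior_threshold <= 1.0:
            raise ConfigError("posterior_threshold must be in (0, 1]")
        if not 0.0 < self.background_threshold <= 1.0:
            raise ConfigError("background_threshold must be in (0, 1]")
        for name in ("n_restarts", "n_bootstrap_mean", "n_density_bootstrap",
                     "n_density_permutation", "n_enrichment_draws",
                     "n_block_iterations", "block_size", "block_draws"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.min_depth > self.max_depth:
            raise ConfigError("min_depth must not exceed max_depth")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**d).validate()


def config_hash(*configs) -> str:
    """Stable short hash of one or more config objects (for report headers)."""
    payload = json.dumps([c.to_dict() for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
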