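"""Configuration objects for every pipeline stage.

Defaults follow the analysis conventions used throughout the package: an
unsigned weighted co-expression network with the soft power searched over
integer exponents 1..40 against a scale-free fit threshold of R^2 = 0.6 and
a minimum module size of 30; an RBF support-vector classifier at cost
c = 5.278 and kernel width gamma = 0.574 over lag-30 auto-covariance
features; hypergeometric over-representation flagged at Bonferroni-corrected
P < 0.005 with kappa >= 0.3 term grouping; and composition vectors at
tuple length K = 6.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, get_args, get_origin

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or invalid values."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The expression section plants ``module_sizes`` co-expressed modules on
    top of ``n_background_genes`` pure-noise genes across ``n_samples``
    samples split evenly into a non-floral (trait 0) and a floral (trait 1)
    group; ``trait_assoc`` gives each module's latent correlation with that
    binary trait. The protein section plants ``n_families`` interaction
    families whose members share a segmental residue composition of
    strength ``signal_strength`` (0 erases the signal entirely).
    """

    # expression
    n_samples: int = 60
    module_sizes: tuple[int, ...] = (50, 40, 30)
    trait_assoc: tuple[float, ...] = (0.9, 0.1, 0.1)
    noise_sd: float = 0.3
    n_background_genes: int = 80
    # proteins / interactions
    n_proteins: int = 240
    n_families: int = 5
    family_fraction: float = 0.7
    protein_length_range: tuple[int, int] = (600, 1000)
    n_positive_pairs: int = 150
    signal_strength: float = 1.0
    n_compartments: int = 8
    # annotations
    n_go_terms: int = 60
    term_size_range: tuple[int, int] = (15, 40)
    enrichment_odds: float = 20.0
    # phylogeny
    n_taxa: int = 8
    root_seq_length: int = 3000
    subst_rate: float = 1.0
    true_tree: str | None = None
    # randomness
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_background_genes": self.n_background_genes,
            "n_proteins": self.n_proteins,
            "n_families": self.n_families,
            "n_positive_pairs": self.n_positive_pairs,
            "n_compartments": self.n_compartments,
            "n_go_terms": self.n_go_terms,
            "n_taxa": self.n_taxa,
            "root_seq_length": self.root_seq_length,
        }
        for key, value in counts.items():
            if value < 0:
                raise ConfigError(f"{key} must be >= 0, got {value}")
        if any(s < 0 for s in self.module_sizes):
            raise ConfigError("module_sizes entries must be >= 0")
        if len(self.trait_assoc) != len(self.module_sizes):
            raise ConfigError("trait_assoc must have one entry per module")
        if any(not 0.0 <= r <= 1.0 for r in self.trait_assoc):
            raise ConfigError("trait_assoc entries must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ConfigError("protein_length_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ConfigError("signal_strength must lie in [0, 1]")
        if self.subst_rate < 0:
            raise ConfigError("subst_rate must be non-negative")


@dataclass
class NetworkParams:
    """Co-expression network construction parameters."""

    power_search_interval: tuple[int, int] = (1, 40)
    r2_min: float = 0.6
    beta: int | None = None  # filled by pick_soft_threshold when None
    min_module_size: int = 30
    cut_height: float = 0.99
    pcc_filter_tau: float = 0.8
    # guards against powers so high the network is effectively empty; an
    # average degree below 2 (a tree's) means most nodes are isolated
    min_mean_connectivity: float = 2.0

    def validate(self) -> None:
        lo, hi = self.power_search_interval
        if lo < 1 or hi < lo:
            raise ConfigError("power_search_interval must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.r2_min < 1.0:
            raise ConfigError("r2_min must lie in [0, 1)")
        if self.min_mean_connectivity < 0:
            raise ConfigError("min_mean_connectivity must be >= 0")
        if self.beta is not None and not lo <= self.beta <= hi:
            raise ConfigError("beta must lie within power_search_interval")
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        if not 0.0 < self.cut_height <= 1.0:
            raise ConfigError("cut_height must lie in (0, 1]")
        if not 0.0 <= self.pcc_filter_tau <= 1.0:
            raise ConfigError("pcc_filter_tau must lie in [0, 1]")


@dataclass
class ACParams:
    """Auto-covariance encoding and SVM hyperparameters."""

    lag_max: int = 30
    svm_c: float = 5.278
    svm_gamma: float = 0.574

    def validate(self) -> None:
        if self.lag_max < 1:
            raise ConfigError("lag_max must be >= 1")
        if self.svm_c <= 0 or self.svm_gamma <= 0:
            raise ConfigError("svm_c and svm_gamma must be positive")


@dataclass
class EnrichmentParams:
    """Over-representation and term-grouping parameters."""

    kappa_threshold: float = 0.3
    alpha_raw: float = 0.05
    alpha_corrected: float = 0.005
    min_overlap: int = 3
    global_correction: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.kappa_threshold <= 1.0:
            raise ConfigError("kappa_threshold must lie in [0, 1]")
        for key in ("alpha_raw", "alpha_corrected"):
            v = getattr(self, key)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{key} must lie in (0, 1]")
        if self.min_overlap < 0:
            raise ConfigError("min_overlap must be >= 0")


@dataclass
class PhyloParams:
    """Composition-vector phylogenetics parameters."""

    k: int = 6
    method: str = "nj"

    def validate(self) -> None:
        if self.k < 3:
            raise ConfigError("k must be >= 3 (background subtraction needs k-2)")
        if self.method not in ("nj", "upgma"):
            raise ConfigError("method must be 'nj' or 'upgma'")


@dataclass
class PipelineConfig:
    """Top-level configuration composing every stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    ppi: ACParams = field(default_factory=ACParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    phylo: PhyloParams = field(default_factory=PhyloParams)
    seed: int = 0
    log_level: str = "INFO"
    # pipeline-level knobs
    n_seed_genes: int = 5
    partners_per_seed: int = 2
    alpha_override: float | None = None
    redundancy_filter: bool = False
    grid_search: bool = False

    def validate(self) -> None:
        self.simulation.validate()
        self.network.validate()
        self.ppi.validate()
        self.enrichment.validate()
        self.phylo.validate()
        if self.n_seed_genes < 1 or self.partners_per_seed < 1:
            raise ConfigError("n_seed_genes and partners_per_seed must be >= 1")


_SECTIONS = {
    "simulation": SimulationConfig,
    "network": NetworkParams,
    "ppi": ACParams,
    "enrichment": EnrichmentParams,
    "phylo": PhyloParams,
}


def _type_ok(value: Any, tp: Any) -> bool:
    origin = get_origin(tp)
    if origin is None:
        if tp is float:
            return isinstance(value, (int, float)) and not isinstance(value, bool)
        if tp is int:
            return isinstance(value, int) and not isinstance(value, bool)
        if tp is type(None):
            return value is None
        return isinstance(value, tp)
    if origin is tuple:
        if not isinstance(value, (list, tuple)):
            return False
        args = get_args(tp)
        if len(args) == 2 and args[1] is Ellipsis:
            return all(_type_ok(v, args[0]) for v in value)
        return len(value) == len(args) and all(
            _type_ok(v, a) for v, a in zip(value, args)
        )
    # unions (X | None)
    return any(_type_ok(value, a) for a in get_args(tp))


def _build(cls: type, data: dict[str, Any], prefix: str = "") -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    # resolve postponed annotations
    import typing

    hints = typing.get_type_hints(cls)
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key '{prefix}{key}'")
        tp = hints[key]
        if dataclasses.is_dataclass(tp):
            if not isinstance(value, dict):
                raise ConfigError(
                    f"key '{prefix}{key}' expects a mapping, got {type(value).__name__}"
                )
            kwargs[key] = _build(tp, value, prefix=f"{key}.")
            continue
        if not _type_ok(value, tp):
            raise ConfigError(
                f"key '{prefix}{key}' expects {tp}, got {type(value).__name__}"
            )
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any] | None) -> PipelineConfig:
    """Build and validate a :class:`PipelineConfig` from a plain mapping."""
    data = dict(data or {})
    cfg = _build(PipelineConfig, data)
    cfg.validate()
    return cfg


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML or TOML configuration file, fill defaults, and validate.

    An empty or missing ``path`` yields the all-defaults configuration.
    Unknown keys and type mismatches raise :class:`ConfigError` naming the
    offending key.
    """
    if path is None:
        return config_from_dict({})
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(data)
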