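"""Run configuration: YAML-backed, strict about unknown keys.

Every numeric default is the value the methods carry elsewhere in the
package (QC thresholds, d0 = 10 kb, cutoff 150 kb, scale 10,000, top
2000 variable genes, LSI 50, resolution 0.6, marker thresholds,
similarity 0.7, prediction-score cutoff 0.5).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .qc import ATAC_QC_DEFAULTS, RNA_QC_DEFAULTS, QCThresholds
from .rp_model import RPConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class PathsConfig:
    genes: str | None = None
    peaks: str | None = None
    rna_matrix: str | None = None
    atac_matrix: str | None = None
    fragments: str | None = None
    signatures: str | None = None
    pwms: str | None = None
    reference_sets: str | None = None
    outdir: str = "scregpot_out"


@dataclass
class ClusteringConfig:
    n_neighbors: int = 20
    resolution: float = 0.6
    seed: int = 2020
    lsi_dims: int = 50
    pca_dims: int = 15
    n_variable_genes: int = 2000


@dataclass
class MarkerConfig:
    gene_min_logfc: float = 0.25
    gene_min_pct: float = 0.25
    peak_min_logfc: float = 0.1
    peak_min_pct: float = 0.01
    max_p: float = 1e-5


@dataclass
class RegulatorConfig:
    similarity_threshold: float = 0.7
    min_overlap: int = 5
    min_mean_rp: float = 0.5
    top_n: int = 100


@dataclass
class IntegrationConfig:
    cca_dims: int = 20
    k_anchor: int = 5
    k_weight: int = 20
    prediction_score_cutoff: float = 0.5


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    rna_qc: QCThresholds = field(default_factory=lambda: dataclasses.replace(RNA_QC_DEFAULTS))
    atac_qc: QCThresholds = field(default_factory=lambda: dataclasses.replace(ATAC_QC_DEFAULTS))
    rp: RPConfig = field(default_factory=RPConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    regulators: RegulatorConfig = field(default_factory=RegulatorConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) under {context}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = _SECTION_TYPES.get((cls, name))
        kwargs[name] = _build(sub, value, f"{context}.{name}") if sub else value
    return cls(**kwargs)


_SECTION_TYPES = {
    (RunConfig, "paths"): PathsConfig,
    (RunConfig, "rna_qc"): QCThresholds,
    (RunConfig, "atac_qc"): QCThresholds,
    (RunConfig, "rp"): RPConfig,
    (RunConfig, "clustering"): ClusteringConfig,
    (RunConfig, "markers"): MarkerConfig,
    (RunConfig, "regulators"): RegulatorConfig,
    (RunConfig, "integration"): IntegrationConfig,
}


def load_config(path: str) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _build(RunConfig, data, "config")


def dump_config(config: RunConfig, path: str | None = None) -> str:
    """Serialize a RunConfig to canonical YAML."""
    text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
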