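"""Pipeline configuration: thresholds, stage seeds, input paths and the
optional synthetic-cohort section, loadable from YAML with validation
errors that name the offending field."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "SimulateSection", "demo_config"]


@dataclass
class SimulateSection:
    """Synthetic-cohort parameters for the two simulated datasets: the
    (non-genotyped) derivation cohort the clusters are learned on, and
    the genotyped cohort used for transfer + association."""

    n_subtypes: int = 5
    derivation_cases_per_subtype: int = 300
    cohort_cases_per_subtype: int = 200
    cohort_controls: int = 3000
    p_high: float = 0.8
    p_low: float = 0.05
    n_cluster_features: int = 17
    strata: list = field(default_factory=lambda: [["EUR", 0.7], ["AFR", 0.3]])
    n_lead_snps: int = 39
    n_tag_snps: int = 5
    tag_flip: float = 0.1
    global_or: float = 1.5      # odds ratio shared by all subtypes (lead 1)
    subtype_or: float = 1.8     # odds ratio confined to subtype 0 (lead 2)
    maf_range: list = field(default_factory=lambda: [0.1, 0.5])
    icd_sensitivity: float = 1.0


@dataclass
class PipelineConfig:
    # input paths (real-data mode; ignored when simulate is set)
    subjects_path: str | None = None
    icd_path: str | None = None
    genotypes_path: str | None = None       # VCF or dosage TSV
    cohort_subjects_path: str | None = None
    cohort_icd_path: str | None = None
    locus_list_path: str | None = None
    catalog_path: str | None = None         # YAML feature catalog

    simulate: SimulateSection | None = None

    # thresholds
    min_prevalence: float = 0.05
    r2_min: float = 0.1
    ld_window: int = 500_000
    bonferroni_n: int = 39
    gw_alpha: float = 5e-8

    # clustering
    methods: list = field(default_factory=lambda: ["spectral", "kmeans",
                                                   "hierarchical", "dbscan"])
    k_min: int = 2
    k_max: int = 20
    affinity_neighbors: int = 10
    dbscan_eps: float = 1.5
    dbscan_min_samples: int = 5
    linkage: str = "average"
    n_restarts: int = 10

    # transfer
    knn_k: int = 3

    # association
    n_pcs: int = 4
    beta_method: str = "onestep"
    n_negative_controls: int = 5

    # per-stage seeds
    seeds: dict = field(default_factory=lambda: {
        "simulate": 11, "cluster": 13, "negative_control": 17})

    def validate(self) -> None:
        for name in ("min_prevalence", "r2_min", "gw_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}: must be in (0, 1]")
        for name in ("ld_window", "bonferroni_n", "knn_k", "n_pcs", "k_min",
                     "k_max", "affinity_neighbors", "n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: must be a positive integer")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("k_min/k_max: need 2 <= k_min <= k_max")
        unknown = set(self.methods) - {"spectral", "kmeans", "hierarchical", "dbscan"}
        if unknown:
            raise ValueError(f"methods: unknown entries {sorted(unknown)}")
        if self.simulate is None:
            required = ["subjects_path", "icd_path", "genotypes_path",
                        "cohort_subjects_path", "cohort_icd_path",
                        "locus_list_path"]
            missing = [f for f in required if getattr(self, f) is None]
            if missing:
                raise ValueError(
                    f"config missing required input paths (no simulate "
                    f"section): {missing}")
        for key in ("simulate", "cluster", "negative_control"):
            if key not in self.seeds:
                raise ValueError(f"seeds: missing entry {key!r}")

    # -- YAML ---------------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        sim = payload.get("simulate")
        if sim is not None and not isinstance(sim, SimulateSection):
            sim_known = set(SimulateSection.__dataclass_fields__)
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulate fields: {sorted(sim_unknown)}")
            payload = dict(payload)
            payload["simulate"] = SimulateSection(**sim)
        return cls(**payload)


def demo_config(seed: int = 11) -> PipelineConfig:
    """Small self-contained demo: ~1,500-case derivation cohort, a
    genotyped cohort of 1,000 cases + 3,000 controls, 39 candidate lead
    SNPs (one global effect, one subtype-0-specific effect, the rest
    null) plus 5 LD tags."""
    cfg = PipelineConfig(simulate=SimulateSection())
    cfg.seeds = {"simulate": seed, "cluster": seed + 2, "negative_control": seed + 4}
    return cfg
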