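"""Configuration objects for cohort simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its valid range."""


#: Common class I alleles at 4-digit resolution; frequencies are not modelled,
#: draws are uniform with replacement within each locus.
DEFAULT_HLA_POOL: tuple[str, ...] = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-A*03:01",
    "HLA-A*11:01",
    "HLA-A*24:02",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-B*15:01",
    "HLA-B*35:01",
    "HLA-B*44:02",
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic tumor cohort.

    The defaults emulate a stage II microsatellite-stable colon-cancer study:
    42 patients split evenly between relapse ("poor" prognosis) and no relapse
    ("good"), roughly 90 functional somatic SNVs per tumor, HLA-A/B genotypes,
    paired tumor/normal expression with tumor under-expression of HLA class I
    and CD8A, and relapse hazards that decrease with antigen-presentation
    expression and predicted neoantigen load.

    Hazard-ratio parameters are log hazard ratios: ``presentation_effect`` per
    standard deviation of the antigen-presentation expression summary,
    ``neoantigen_effect`` per predicted neoantigen.
    """

    n_patients: int = 42
    relapse_fraction: float = 0.5
    n_genes: int = 300
    protein_length_range: tuple[int, int] = (100, 700)
    per_tumor_mutation_rate: float = 90.0
    hla_allele_pool: Sequence[str] = DEFAULT_HLA_POOL
    presentation_effect: float = -0.5
    neoantigen_effect: float = -0.10
    censoring_time: float = 60.0
    seed: int = 0
    # expression model (log2 scale)
    expression_sd: float = 0.5
    tumor_shift: float = -1.0  # planted tumor-vs-normal shift for HLA-A/B/C, CD8A
    # fraction of extra, non-functional SNVs added on top of the functional rate
    nonfunctional_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.relapse_fraction <= 1.0:
            raise ConfigurationError("relapse_fraction must lie in [0, 1]")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ConfigurationError("n_patients and n_genes must be positive")
        lo, hi = self.protein_length_range
        if lo < 25 or hi < lo:
            raise ConfigurationError(
                "protein_length_range must satisfy 25 <= lo <= hi"
            )
        if self.per_tumor_mutation_rate <= 0:
            raise ConfigurationError("per_tumor_mutation_rate must be positive")
        if self.censoring_time < 0:
            raise ConfigurationError("censoring_time must be non-negative")
        if not self.hla_allele_pool:
            raise ConfigurationError("hla_allele_pool must be non-empty")

    def config_hash(self) -> str:
        """Stable short hash of the configuration, used for provenance blocks."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    Thresholds default to the conventional values of the analysis: PPI
    confidence > 0.72, epitope calls at IC50 < 50 nM (mutant) and > 500 nM
    (wild type), peptide lengths 8-11, exclusivity threshold k = 3, nominal
    alpha 0.05 with Bonferroni-sized permutation counts.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    min_ppi_score: float = 0.72
    ic50_mut_max: float = 50.0
    ic50_wt_min: float = 500.0
    kmer_range: tuple[int, int] = (8, 11)
    exclusivity_k: int = 3
    alpha: float = 0.05
    min_recurrence: int = 2
    neoantigen_high_cut: int = 8
    cms_min_n: int = 10
    cd8a_rule: str = "upper-quartile"
    score_aggregator: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_ppi_score <= 1.0:
            raise ConfigurationError("min_ppi_score must lie in [0, 1]")
        if self.ic50_mut_max <= 0 or self.ic50_wt_min <= 0:
            raise ConfigurationError("IC50 thresholds must be positive")
        lo, hi = self.kmer_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("kmer_range must satisfy 1 <= lo <= hi")
        if self.exclusivity_k < 2:
            raise ConfigurationError("exclusivity_k must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
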