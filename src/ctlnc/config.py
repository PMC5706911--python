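"""Validated configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from pydantic import BaseModel, Field, ValidationError, model_validator

from .exceptions import ConfigurationError


class CohortSpec(BaseModel):
    """Parameters of the synthetic multi-cohort study.

    The defaults produce a small but fully featured study: a 24-tissue
    normal panel including testis, two tumor cohorts, planted
    testis-specific (TS) genes of which a subset is reactivated in tumors
    (CT) at an extreme level (EECT), co-expression modules tied to gene
    sets, regulatory elements placed in the documented windows, and
    methylation / mutation / clinical tables coupled to the activation
    ground truth.
    """

    model_config = {"frozen": True}

    n_tissues: int = Field(default=24, gt=0)
    tissue_labels: tuple[str, ...] | None = None
    n_normal_individuals: int = Field(default=4, gt=0)
    n_tumor_samples_per_type: int = Field(default=200, gt=0)
    cancer_types: tuple[str, ...] = ("CANCER_A", "CANCER_B")
    n_genes: int = Field(default=1100, gt=0)
    n_lncrna: int = Field(default=500, gt=0)
    frac_ts: float = Field(default=0.2, ge=0.0, le=1.0)
    frac_ct_of_ts: float = Field(default=0.5, ge=0.0, le=1.0)
    activation_frequency: float = Field(default=0.05, ge=0.0, le=1.0)
    activation_log2_effect: float = Field(default=6.0, gt=0.0)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = Field(default=1.0, gt=0.0)
    dropout_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    n_modules: int = Field(default=5, gt=0)
    module_size: int = Field(default=20, gt=0)
    rho_within: float = Field(default=0.8, ge=0.0, le=1.0)
    seed: int = 1

    # extensions beyond the core cohort geometry (documented defaults)
    frac_module_lnc: float = Field(default=0.25, ge=0.0, le=1.0)
    frac_promoter_targets: float = Field(default=0.6, ge=0.0, le=1.0)
    frac_methylation_targets: float = Field(default=0.6, ge=0.0, le=1.0)
    frac_enhancer_targets: float = Field(default=0.5, ge=0.0, le=1.0)
    n_background_elements: int = Field(default=50, ge=0)
    n_gene_sets: int = Field(default=50, gt=0)
    n_drivers: int = Field(default=4, ge=0)
    driver_mutation_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    methylation_beta_shift: float = Field(default=0.3, ge=0.0, le=0.6)
    stage_trend: float = 1.0
    smg_coupling: float = 0.25
    genes_per_chromosome: int = Field(default=500, gt=0)
    gene_spacing: int = Field(default=60_000, gt=0)
    gene_length: int = Field(default=2_000, gt=0)

    @model_validator(mode="after")
    def _check(self):
        labels = self.resolved_tissue_labels()
        if len(labels) != self.n_tissues:
            raise ValueError(
                f"tissue_labels: {len(labels)} labels given but n_tissues={self.n_tissues}"
            )
        if labels.count("testis") != 1:
            raise ValueError("tissue_labels: 'testis' must appear exactly once")
        if self.n_lncrna > self.n_genes:
            raise ValueError(f"n_lncrna: {self.n_lncrna} exceeds n_genes={self.n_genes}")
        n_coding = self.n_genes - self.n_lncrna
        if self.n_modules * self.n_coding_per_module > n_coding:
            raise ValueError(
                "n_modules: module coding demand "
                f"{self.n_modules * self.n_coding_per_module} exceeds coding genes {n_coding}"
            )
        return self

    def resolved_tissue_labels(self) -> list[str]:
        if self.tissue_labels is not None:
            return list(self.tissue_labels)
        labels = [f"tissue{i:02d}" for i in range(1, self.n_tissues)]
        return ["testis", *labels]

    @property
    def n_coding(self) -> int:
        return self.n_genes - self.n_lncrna

    @property
    def n_lnc_per_module(self) -> int:
        return int(round(self.module_size * self.frac_module_lnc))

    @property
    def n_coding_per_module(self) -> int:
        return self.module_size - self.n_lnc_per_module

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        try:
            return cls(**data)
        except ValidationError as exc:
            first = exc.errors()[0]
            field = ".".join(str(p) for p in first["loc"]) or "<spec>"
            raise ConfigurationError(f"invalid cohort spec field {field!r}: {first['msg']}") from None


def validated_spec(spec: CohortSpec | dict | None = None, **overrides) -> CohortSpec:
    if spec is None:
        return CohortSpec.from_dict(overrides)
    if isinstance(spec, dict):
        return CohortSpec.from_dict({**spec, **overrides})
    if overrides:
        return CohortSpec.from_dict({**spec.model_dump(), **overrides})
    return spec
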