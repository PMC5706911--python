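"""Testis-specificity classification of lncRNAs from a normal-tissue panel."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, CtlncError
from .io import ExpressionMatrix, GeneModel

TS_HIGH = "TS_high_confidence"
TS_MODERATE = "TS_moderate"
NON_TS = "non_TS"


@dataclass(frozen=True)
class SpmThresholds:
    high: float = 0.9
    moderate: float = 0.6

    def __post_init__(self):
        if not (0.0 < self.moderate <= self.high <= 1.0):
            raise ConfigurationError(
                f"need 0 < moderate <= high <= 1, got moderate={self.moderate} high={self.high}"
            )


@dataclass(frozen=True)
class SpecificityCall:
    gene_id: str
    spm_testis: float
    category: str
    passed_overlap_filter: bool = True


def compute_spm(expr_by_tissue, target_tissue: str = "testis") -> float:
    """Specificity measure: squared target expression over the squared norm.

    ``expr_by_tissue`` maps tissue label to that tissue's mean expression.
    Returns 1 iff expression is confined to the target tissue.
    """
    if target_tissue not in expr_by_tissue:
        raise ConfigurationError(f"target tissue {target_tissue!r} absent from panel")
    x = np.array([float(v) for v in expr_by_tissue.values()])
    if np.any(x < 0):
        raise CtlncError("expression must be non-negative")
    denom = float(np.sum(x**2))
    if denom == 0:
        raise CtlncError("specificity undefined for an all-zero expression vector")
    xt = float(expr_by_tissue[target_tissue])
    return xt**2 / denom


def filter_lncrna_models(
    genes: list[GeneModel], coding_genes: list[GeneModel]
) -> list[GeneModel]:
    """Keep lncRNA-biotype genes none of whose exons overlaps a coding span.

    Overlap is >= 1 bp against the coding gene's full span, strand-blind.
    """
    spans = defaultdict(list)
    for cg in coding_genes:
        spans[cg.chrom].append((cg.start, cg.end))
    for chrom in spans:
        spans[chrom].sort()

    def overlaps_coding(gene: GeneModel) -> bool:
        chrom_spans = spans.get(gene.chrom, ())
        for es, ee in gene.exons:
            for cs, ce in chrom_spans:
                if cs >= ee:
                    break
                if es < ce and cs < ee:
                    return True
        return False

    return [g for g in genes if g.is_lncrna and not overlaps_coding(g)]


def per_tissue_means(panel: ExpressionMatrix, tissue_labels: dict[str, str]) -> pd.DataFrame:
    """Mean expression per tissue; ``tissue_labels`` maps sample id -> tissue."""
    missing = [s for s in panel.sample_ids if s not in tissue_labels]
    if missing:
        raise ConfigurationError(f"samples without a tissue label: {missing[:3]}...")
    groups = pd.Series({s: tissue_labels[s] for s in panel.sample_ids})
    return panel.values.T.groupby(groups).mean().T


def classify_testis_specific(
    panel: ExpressionMatrix,
    tissue_labels: dict[str, str],
    thresholds: SpmThresholds | None = None,
    target_tissue: str = "testis",
) -> list[SpecificityCall]:
    """Per-gene SPM on per-tissue means, categorized by the configured cutoffs."""
    thresholds = thresholds or SpmThresholds()
    means = per_tissue_means(panel, tissue_labels)
    if target_tissue not in means.columns:
        raise ConfigurationError(f"no samples labeled {target_tissue!r} in the panel")
    arr = means.to_numpy()
    denom = (arr**2).sum(axis=1)
    target = means[target_tissue].to_numpy()
    calls = []
    for gid, xt2, d in zip(means.index, target**2, denom):
        if d == 0:
            spm = 0.0
            category = NON_TS
        else:
            spm = float(xt2 / d)
            if spm >= thresholds.high:
                category = TS_HIGH
            elif spm >= thresholds.moderate:
                category = TS_MODERATE
            else:
                category = NON_TS
        calls.append(SpecificityCall(gid, spm, category))
    return calls


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "spm_testis": [c.spm_testis for c in calls],
            "category": [c.category for c in calls],
            "passed_overlap_filter": [c.passed_overlap_filter for c in calls],
        }
    )
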