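"""Conservation scoring of exons and promoters, and group comparisons."""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, CtlncError
from .io import GeneModel, ScoreTrack
from .stats import wilcoxon_rank_sum

PROMOTER_UPSTREAM = 2_000
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class ConservationSummary:
    gene_id: str
    region: str  # "exons" | "promoter"
    mean_phastcons: float | None = None
    mean_phylop_rescaled: float | None = None


def promoter_region(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> tuple[int, int]:
    """Strand-aware promoter interval around the TSS, clipped at zero."""
    if gene.strand == "+":
        return max(0, gene.start - upstream), gene.start + downstream
    return max(0, gene.end - downstream), gene.end + upstream


def rescale_phylop(raw):
    """Map raw PhyloP onto (0, 1), strictly increasing.

    Positive scores map to 1 - 0.5*10**(-raw), negative to 0.5*10**raw;
    zero maps to 0.5, the common limit of both branches.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise CtlncError("PhyloP scores must be finite")
    out = np.where(arr > 0, 1.0 - 0.5 * np.power(10.0, -arr), 0.5 * np.power(10.0, arr))
    if np.isscalar(raw) or arr.ndim == 0:
        return float(out)
    return out


def _merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s >= e:
            raise CtlncError(f"bad interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mean_region_score(
    track: ScoreTrack, intervals_by_chrom: dict[str, list], missing: str = "skip"
) -> float:
    """Length-weighted mean per-base score over a union of intervals.

    ``missing`` controls bases without track coverage: "skip" drops them
    from the average, "zero" counts them as score 0.
    """
    if missing not in ("skip", "zero"):
        raise ConfigurationError(f"missing-policy must be 'skip' or 'zero', got {missing!r}")
    total_weight = 0.0
    total_score = 0.0
    any_interval = False
    for chrom, intervals in intervals_by_chrom.items():
        merged = _merge_intervals(intervals)
        if merged:
            any_interval = True
        segs = track.data.get(chrom, [])
        starts = [ts for ts, _, _ in segs]
        for s, e in merged:
            covered = 0
            # segments are sorted and non-overlapping: scan from the first
            # segment that can reach s
            i = max(0, bisect.bisect_right(starts, s) - 1)
            for ts, te, val in segs[i:]:
                if ts >= e:
                    break
                lo, hi = max(s, ts), min(e, te)
                if lo < hi:
                    total_score += val * (hi - lo)
                    total_weight += hi - lo
                    covered += hi - lo
            if missing == "zero":
                total_weight += (e - s) - covered
    if not any_interval:
        raise CtlncError("empty interval union")
    if total_weight == 0:
        raise CtlncError("no track coverage over the requested intervals (missing='skip')")
    return total_score / total_weight


def summarize_gene(
    gene: GeneModel,
    phastcons: ScoreTrack | None = None,
    phylop: ScoreTrack | None = None,
    region: str = "exons",
    missing: str = "skip",
) -> ConservationSummary:
    """Mean conservation of a gene's exon union or promoter."""
    if region == "exons":
        intervals = {gene.chrom: list(gene.exons)}
    elif region == "promoter":
        intervals = {gene.chrom: [promoter_region(gene)]}
    else:
        raise ConfigurationError(f"region must be 'exons' or 'promoter', got {region!r}")
    mean_pc = mean_region_score(phastcons, intervals, missing) if phastcons else None
    mean_pp = mean_rescaled_phylop(phylop, intervals, missing) if phylop else None
    return ConservationSummary(gene.gene_id, region, mean_pc, mean_pp)


def mean_rescaled_phylop(
    track: ScoreTrack, intervals_by_chrom: dict[str, list], missing: str = "skip"
) -> float:
    """Length-weighted mean of the rescaled PhyloP score (rescale per segment)."""
    rescaled = ScoreTrack(
        "phastcons",
        {
            chrom: [(s, e, float(rescale_phylop(v))) for s, e, v in segs]
            for chrom, segs in track.data.items()
        },
    )
    return mean_region_score(rescaled, intervals_by_chrom, missing)


def compare_groups(summaries_a, summaries_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two score collections."""
    a = np.asarray(list(summaries_a), dtype=float)
    b = np.asarray(list(summaries_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise CtlncError("both groups must be non-empty")
    return wilcoxon_rank_sum(a, b)
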