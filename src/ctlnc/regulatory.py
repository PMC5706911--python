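"""Strand-aware window enrichment of regulatory elements around genes."""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, CtlncError
from .io import GeneModel, Interval
from .stats import EnrichmentResult, fisher_two_sided, spearman_rho, wilcoxon_rank_sum

PROMOTER_WINDOW = "promoter_window"
METHYLATION_WINDOW = "methylation_window"
ENHANCER_FLANKS = "enhancer_flanks"


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the search window relative to a gene, in bp.

    ``upstream_far``/``upstream_near`` bound the 5' window (strand-aware;
    the near boundary is excluded); ``downstream`` extends past the 3' end
    and is only used by the enhancer-flank kind.
    """

    kind: str
    upstream_far: int
    upstream_near: int = 0
    downstream: int = 0

    def __post_init__(self):
        if self.kind not in (PROMOTER_WINDOW, METHYLATION_WINDOW, ENHANCER_FLANKS):
            raise ConfigurationError(f"unknown window kind {self.kind!r}")
        if not (self.upstream_far > self.upstream_near >= 0):
            raise ConfigurationError(
                f"need upstream_far > upstream_near >= 0, got "
                f"far={self.upstream_far} near={self.upstream_near}"
            )
        if self.downstream < 0:
            raise ConfigurationError("downstream must be >= 0")


PROMOTER_DEFAULT = WindowSpec(PROMOTER_WINDOW, 5_000, 100)
METHYLATION_DEFAULT = WindowSpec(METHYLATION_WINDOW, 1_000, 100)
ENHANCER_DEFAULT = WindowSpec(ENHANCER_FLANKS, 20_000, 0, 5_000)


def gene_windows(gene: GeneModel, spec: WindowSpec) -> list[tuple[int, int]]:
    """Search intervals on the gene's chromosome, clipped at 0, body excluded."""
    windows = []
    if gene.strand == "+":
        up = (max(0, gene.start - spec.upstream_far), max(0, gene.start - spec.upstream_near))
        down = (gene.end, gene.end + spec.downstream)
    else:
        up = (gene.end + spec.upstream_near, gene.end + spec.upstream_far)
        down = (max(0, gene.start - spec.downstream), gene.start)
    if up[0] < up[1]:
        windows.append(up)
    if spec.downstream > 0 and down[0] < down[1]:
        windows.append(down)
    return windows


def element_presence(
    genes: list[GeneModel], elements: list[Interval], spec: WindowSpec
) -> dict[str, bool]:
    """True per gene iff any (strandless) element overlaps a window by >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for el in elements:
        by_chrom[el.chrom].append((el.start, el.end))
    index: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, els in by_chrom.items():
        els.sort()
        starts = [s for s, _ in els]
        prefix_max_end: list[int] = []
        running = -1
        for _, e in els:
            running = max(running, e)
            prefix_max_end.append(running)
        index[chrom] = (starts, prefix_max_end)
    out = {}
    for gene in genes:
        hits = False
        idx = index.get(gene.chrom)
        if idx is not None:
            starts, prefix_max_end = idx
            for ws, we in gene_windows(gene, spec):
                # an overlap exists iff some element has start < we and end > ws
                j = bisect.bisect_left(starts, we)
                if j > 0 and prefix_max_end[j - 1] > ws:
                    hits = True
                    break
        out[gene.gene_id] = hits
    return out


def window_enrichment(
    target_genes: list[GeneModel],
    background_genes: list[GeneModel],
    elements: list[Interval],
    spec: WindowSpec,
) -> EnrichmentResult:
    """Two-sided Fisher test of element presence, targets vs background.

    Genes appearing in both lists are kept in the target group and removed
    from the background.
    """
    if not target_genes:
        raise CtlncError("empty target set")
    target_ids = {g.gene_id for g in target_genes}
    background = [g for g in background_genes if g.gene_id not in target_ids]
    if not background:
        raise CtlncError("empty background set after removing targets")
    presence_t = element_presence(target_genes, elements, spec)
    presence_b = element_presence(background, elements, spec)
    a = sum(presence_t.values())
    b = len(presence_t) - a
    c = sum(presence_b.values())
    d = len(presence_b) - c
    odds, p = fisher_two_sided([[a, b], [c, d]])
    total = a + b + c + d
    expected = (a + b) * (a + c) / total
    ratio = a / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        term=spec.kind,
        N=total,
        M=a + c,
        n=a + b,
        m=a,
        p_raw=p,
        p_adjusted=p,
        method="fisher",
        odds_ratio=odds,
        enrichment_ratio=ratio,
    )


def nearest_gene_pairs(
    lncrnas: list[GeneModel], candidates: list[GeneModel]
) -> list[tuple[str, str]]:
    """Pair each lncRNA with its nearest candidate gene on the same chromosome.

    Distance is the gap between gene spans (0 when they overlap); ties go to
    the lexicographically smaller candidate id. lncRNAs with no same-
    chromosome candidate are dropped.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in candidates:
        by_chrom[g.chrom].append(g)
    pairs = []
    for lnc in lncrnas:
        best = None
        for cand in by_chrom.get(lnc.chrom, ()):
            if cand.gene_id == lnc.gene_id:
                continue
            gap = max(cand.start - lnc.end, lnc.start - cand.end, 0)
            key = (gap, cand.gene_id)
            if best is None or key < best[0]:
                best = (key, cand.gene_id)
        if best is not None:
            pairs.append((lnc.gene_id, best[1]))
    return pairs


def enhancer_stratified_correlation(
    pairs: list[tuple[str, str]],
    expr_testis,
    enhancer_presence: dict[str, bool],
) -> dict:
    """Compare lncRNA-neighbor correlation between enhancer strata.

    ``expr_testis`` is an expression frame (genes x testis samples); per
    pair the Spearman rho is computed across samples, then the with- and
    without-enhancer rho distributions are compared by a two-sided Wilcoxon
    rank-sum test.
    """
    rho_with, rho_without = [], []
    for lnc, partner in pairs:
        try:
            rho = spearman_rho(expr_testis.loc[lnc], expr_testis.loc[partner])
        except CtlncError:
            continue
        (rho_with if enhancer_presence.get(lnc, False) else rho_without).append(rho)
    if not rho_with or not rho_without:
        raise CtlncError("one enhancer stratum is empty")
    stat, p = wilcoxon_rank_sum(rho_with, rho_without)
    return {
        "statistic": stat,
        "p_value": p,
        "n_with": len(rho_with),
        "n_without": len(rho_without),
        "median_rho_with": float(np.median(rho_with)),
        "median_rho_without": float(np.median(rho_without)),
    }
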