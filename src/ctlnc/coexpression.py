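"""Guilt-by-association annotation of lncRNAs and set-level enrichment.

For each lncRNA the protein-coding genes are ranked by Spearman correlation;
the leading decile at each end forms the query set, which is tested per
gene-set term with the upper-tail hypergeometric distribution and BH
adjustment. Successfully annotated genes are folded back into the database
(term membership and universe both grow) before the set-level enrichment of
the CT-lncRNA collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, CtlncError
from .io import ExpressionMatrix
from .stats import EnrichmentResult, bh_adjust, hypergeom_upper_tail, spearman_matrix

DEFAULT_PARTNER_FRACTION = 0.10
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class CoexpressionProfile:
    lncrna_id: str
    partners_pos: tuple[str, ...]
    partners_neg: tuple[str, ...]

    @property
    def query_set(self) -> set[str]:
        return set(self.partners_pos) | set(self.partners_neg)


@dataclass
class AnnotationDB:
    """Term -> member genes, with an explicit annotatable universe."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        for term, members in self.terms.items():
            if not members <= self.universe:
                raise ConsistencyError(f"term {term!r} has members outside the universe")

    @classmethod
    def from_gene_sets(cls, sets: dict) -> "AnnotationDB":
        terms = {t: set(m) for t, m in sets.items()}
        universe = set().union(*terms.values()) if terms else set()
        return cls(terms, universe)

    def copy(self) -> "AnnotationDB":
        return AnnotationDB({t: set(m) for t, m in self.terms.items()}, set(self.universe))


def expression_filter(
    expr: ExpressionMatrix, floor: float = 5.0, min_frac: float = 0.01
) -> list[str]:
    """Genes expressed strictly above ``floor`` in at least ``min_frac`` samples."""
    frac = (expr.values.to_numpy() > floor).mean(axis=1)
    return [g for g, f in zip(expr.gene_ids, frac) if f >= min_frac]


def top_decile_partners(
    rho_row: pd.Series, lncrna_id: str = "", fraction: float = DEFAULT_PARTNER_FRACTION
) -> CoexpressionProfile:
    """Leading positive and negative partner deciles, deterministically ordered.

    Ties at the decile boundary are broken by gene id (lexicographic).
    """
    n = len(rho_row)
    if n < 10:
        raise CtlncError(f"need >= 10 coding genes to take a decile, got {n}")
    k = math.floor(fraction * n)
    by_desc = sorted(rho_row.items(), key=lambda kv: (-kv[1], kv[0]))
    by_asc = sorted(rho_row.items(), key=lambda kv: (kv[1], kv[0]))
    pos = tuple(g for g, _ in by_desc[:k])
    neg = tuple(g for g, _ in by_asc[:k])
    return CoexpressionProfile(lncrna_id, pos, neg)


def coexpression_profiles(
    expr: ExpressionMatrix,
    lncrna_genes,
    coding_genes,
    fraction: float = DEFAULT_PARTNER_FRACTION,
) -> dict[str, CoexpressionProfile]:
    """Spearman profiles of every lncRNA against every coding gene.

    Constant rows (no rank variation) are excluded from the tested coding
    set; lncRNAs that are themselves constant get an empty profile.
    """
    lnc = [g for g in lncrna_genes if g in set(expr.gene_ids)]
    coding = [g for g in coding_genes if g in set(expr.gene_ids)]
    if len(coding) < 10:
        raise CtlncError("need >= 10 coding genes")
    a = expr.values.loc[lnc].to_numpy()
    b = expr.values.loc[coding].to_numpy()
    rho = spearman_matrix(a, b)
    coding_ok = ~np.all(np.isnan(rho), axis=0)
    profiles = {}
    for i, gid in enumerate(lnc):
        row = rho[i, coding_ok]
        names = [g for g, ok in zip(coding, coding_ok) if ok]
        if np.all(np.isnan(row)):
            profiles[gid] = CoexpressionProfile(gid, (), ())
            continue
        series = pd.Series(row, index=names).dropna()
        profiles[gid] = top_decile_partners(series, gid, fraction)
    return profiles


def enrich_query(
    query: set[str], db: AnnotationDB, universe: set[str] | None = None
) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric enrichment of a query gene set.

    The universe defaults to the database universe; when given (e.g. the
    filter-passing tested genes) both it and all counts are intersected
    with the database universe.
    """
    uni = db.universe if universe is None else (set(universe) & db.universe)
    if not uni:
        raise CtlncError("empty testing universe")
    q = set(query) & uni
    results = []
    for term in sorted(db.terms):
        members = db.terms[term] & uni
        N, M, n, m = len(uni), len(members), len(q), len(q & members)
        p = hypergeom_upper_tail(N, M, n, m)
        results.append(EnrichmentResult(term, N, M, n, m, p, np.nan, "hypergeometric"))
    adjusted = bh_adjust([r.p_raw for r in results])
    return [
        EnrichmentResult(r.term, r.N, r.M, r.n, r.m, r.p_raw, float(adj), r.method)
        for r, adj in zip(results, adjusted)
    ]


def annotate_lncrna(
    profile: CoexpressionProfile,
    db: AnnotationDB,
    alpha: float = DEFAULT_ALPHA,
    universe: set[str] | None = None,
    joint: bool = True,
) -> set[str]:
    """Terms assigned to one lncRNA at BH-adjusted p < alpha.

    With ``joint=True`` (default) the positive and negative partner sets are
    pooled into one query; otherwise each direction is tested separately and
    the assigned terms are unioned.
    """
    queries = (
        [profile.query_set]
        if joint
        else [set(profile.partners_pos), set(profile.partners_neg)]
    )
    assigned: set[str] = set()
    for query in queries:
        if not query:
            continue
        for res in enrich_query(query, db, universe):
            if res.p_adjusted < alpha:
                assigned.add(res.term)
    return assigned


def annotate_all(
    profiles: dict[str, CoexpressionProfile],
    db: AnnotationDB,
    alpha: float = DEFAULT_ALPHA,
    universe: set[str] | None = None,
    joint: bool = True,
) -> dict[str, set[str]]:
    """Annotation of every profiled gene; genes with no term are dropped."""
    out = {}
    for gid, profile in profiles.items():
        terms = annotate_lncrna(profile, db, alpha, universe, joint)
        if terms:
            out[gid] = terms
    return out


def expand_db(db: AnnotationDB, annotations: dict[str, set[str]]) -> AnnotationDB:
    """Fold annotated genes into the database; idempotent."""
    new = db.copy()
    for gid, terms in annotations.items():
        unknown = terms - set(new.terms)
        if unknown:
            raise ConsistencyError(f"annotation of {gid!r} references unknown terms {sorted(unknown)[:3]}")
        for term in terms:
            new.terms[term].add(gid)
        new.universe.add(gid)
    return new


def ct_set_enrichment(ct_lncrnas, expanded_db: AnnotationDB) -> list[EnrichmentResult]:
    """Set-level enrichment of the CT-lncRNA collection, sorted by adjusted p."""
    ct = set(ct_lncrnas)
    annotated_ct = ct & expanded_db.universe
    if not annotated_ct:
        raise CtlncError("no CT-lncRNA is annotated in the expanded database")
    N = len(expanded_db.universe)
    n = len(annotated_ct)
    results = []
    for term in sorted(expanded_db.terms):
        members = expanded_db.terms[term]
        M, m = len(members), len(annotated_ct & members)
        p = hypergeom_upper_tail(N, M, n, m)
        results.append(EnrichmentResult(term, N, M, n, m, p, np.nan, "hypergeometric"))
    adjusted = bh_adjust([r.p_raw for r in results])
    out = [
        EnrichmentResult(r.term, r.N, r.M, r.n, r.m, r.p_raw, float(adj), r.method)
        for r, adj in zip(results, adjusted)
    ]
    return sorted(out, key=lambda r: (r.p_adjusted, r.p_raw, r.term))


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "N": [r.N for r in results],
            "M": [r.M for r in results],
            "n": [r.n for r in results],
            "m": [r.m for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_BH": [r.p_adjusted for r in results],
        }
    )
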