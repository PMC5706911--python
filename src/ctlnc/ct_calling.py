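"""CT / EECT calling from tumor cohorts and composition enrichment.

Calling follows the published rule set: a testis-specific gene is CT in a
cancer type when it is expressed above the unit-specific floor (strictly) in
at least 1% of samples; a CT gene is EECT when its zero-ruled log2
expression strictly exceeds mean + k*SD (sample SD, n-1) in at least 1% of
samples. Zeros are set to one before the log2 transform, so they contribute
log2 value 0 to the mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, CtlncError
from .io import NORMALIZED_READ_COUNTS, RPKM, ExpressionMatrix
from .stats import EnrichmentResult, bh_adjust, fisher_two_sided

DEFAULT_FLOORS = {RPKM: 0.1, NORMALIZED_READ_COUNTS: 5.0}
DEFAULT_MIN_FRAC = 0.01
DEFAULT_K_SD = 3.0


def log2_with_zero_rule(values) -> np.ndarray:
    """log2 after mapping exact zeros to one (so a zero transforms to 0)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise CtlncError("negative expression value")
    v = np.where(v == 0, 1.0, v)
    return np.log2(v)


def floor_for_unit(unit: str, floor: float | None = None) -> float:
    if floor is not None:
        return float(floor)
    try:
        return DEFAULT_FLOORS[unit]
    except KeyError:
        raise CtlncError(f"no default expression floor for unit {unit!r}") from None


def call_ct(
    expr: ExpressionMatrix,
    ts_genes,
    floor: float | None = None,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> pd.Series:
    """Per-gene CT flag for one cancer type."""
    if expr.shape[1] == 0:
        raise CtlncError("empty cohort")
    floor = floor_for_unit(expr.unit, floor)
    ts = set(ts_genes)
    frac = (expr.values.to_numpy() > floor).mean(axis=1)
    is_ts = np.array([g in ts for g in expr.gene_ids])
    return pd.Series(is_ts & (frac >= min_frac), index=expr.gene_ids, name="is_ct")


def expressed_fraction(expr: ExpressionMatrix, floor: float | None = None) -> pd.Series:
    floor = floor_for_unit(expr.unit, floor)
    return pd.Series(
        (expr.values.to_numpy() > floor).mean(axis=1), index=expr.gene_ids, name="frac_expressed"
    )


def call_eect(
    expr: ExpressionMatrix,
    ct_genes,
    k_sd: float = DEFAULT_K_SD,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> pd.DataFrame:
    """EECT flag plus the per-gene EE threshold (log2 scale) and frac_ee.

    The mean/SD are computed over all samples of the cancer type after the
    zero rule; the SD uses the n-1 denominator. Returns a frame indexed by
    every gene of ``expr`` (non-CT genes carry is_eect=False and NaN
    threshold).
    """
    n = expr.shape[1]
    if n < 2:
        raise CtlncError("EE threshold undefined for cohorts with fewer than 2 samples")
    ct = set(ct_genes)
    log2 = log2_with_zero_rule(expr.values.to_numpy())
    mean = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    threshold = mean + k_sd * sd
    frac_ee = (log2 > threshold[:, None]).mean(axis=1)
    is_ct = np.array([g in ct for g in expr.gene_ids])
    out = pd.DataFrame(
        {
            "is_eect": is_ct & (frac_ee >= min_frac),
            "ee_threshold": np.where(is_ct, threshold, np.nan),
            "frac_ee": np.where(is_ct, frac_ee, np.nan),
        },
        index=expr.gene_ids,
    )
    return out


@dataclass
class CTCallTable:
    """Per (gene, cancer_type) call flags plus thresholds and fractions."""

    table: pd.DataFrame  # columns: gene, cancer_type, is_ct, is_eect, ee_threshold,
    #                               frac_expressed, frac_ee

    def ct_union(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_ct"], "gene"])

    def eect_union(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_eect"], "gene"])

    def eect_for(self, cancer_type: str) -> pd.DataFrame:
        t = self.table
        return t[(t["cancer_type"] == cancer_type) & t["is_eect"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_call_table(
    cohorts: dict[str, ExpressionMatrix],
    ts_genes,
    floor: float | None = None,
    min_frac: float = DEFAULT_MIN_FRAC,
    k_sd: float = DEFAULT_K_SD,
) -> CTCallTable:
    """Run CT then EECT calling on every cohort."""
    rows = []
    for ctype, expr in cohorts.items():
        ct = call_ct(expr, ts_genes, floor=floor, min_frac=min_frac)
        eect = call_eect(expr, set(ct.index[ct]), k_sd=k_sd, min_frac=min_frac)
        frac_expr = expressed_fraction(expr, floor=floor)
        for gid in expr.gene_ids:
            rows.append(
                {
                    "gene": gid,
                    "cancer_type": ctype,
                    "is_ct": bool(ct[gid]),
                    "is_eect": bool(eect.loc[gid, "is_eect"]),
                    "ee_threshold": eect.loc[gid, "ee_threshold"],
                    "frac_expressed": frac_expr[gid],
                    "frac_ee": eect.loc[gid, "frac_ee"],
                }
            )
    return CTCallTable(pd.DataFrame(rows))


def activation_counts(expr: ExpressionMatrix, eect_calls: pd.DataFrame) -> pd.Series:
    """Per-sample count of EECT genes exceeding their EE threshold.

    ``eect_calls`` is the frame produced by :func:`call_eect` on the same
    cohort.
    """
    eect = eect_calls[eect_calls["is_eect"]]
    missing = [g for g in eect.index if g not in set(expr.gene_ids)]
    if missing:
        raise ConsistencyError(f"EECT genes absent from the cohort: {missing[:3]}")
    counts = pd.Series(0, index=expr.sample_ids, name="n_activated_eect", dtype=int)
    if len(eect) == 0:
        return counts
    sub = expr.values.loc[eect.index]
    log2 = log2_with_zero_rule(sub.to_numpy())
    above = log2 > eect["ee_threshold"].to_numpy()[:, None]
    return pd.Series(above.sum(axis=0), index=expr.sample_ids, name="n_activated_eect")


def activation_matrix(expr: ExpressionMatrix, eect_calls: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-gene boolean activation indicators for the EECT genes."""
    eect = eect_calls[eect_calls["is_eect"]]
    sub = expr.values.loc[eect.index]
    log2 = log2_with_zero_rule(sub.to_numpy())
    above = log2 > eect["ee_threshold"].to_numpy()[:, None]
    return pd.DataFrame(above.T, index=expr.sample_ids, columns=eect.index)


def composition_enrichment(
    called, strata: dict[str, str], background
) -> list[EnrichmentResult]:
    """Per-stratum Fisher test of stratum membership against the call flag.

    ``strata`` maps each background gene to its stratum label (biotype or
    chromosome); ``called`` must be a subset of ``background``.
    """
    background = set(background)
    called = set(called)
    if not background:
        raise CtlncError("empty background")
    if not called <= background:
        raise ConsistencyError("called genes must be contained in the background")
    missing = [g for g in called if g not in strata]
    if missing:
        raise ConsistencyError(f"called genes without a stratum: {missing[:3]}")
    labels = sorted({strata[g] for g in background if g in strata})
    results = []
    n_called, n_bg = len(called), len(background)
    for label in labels:
        in_stratum = {g for g in background if strata.get(g) == label}
        a = len(called & in_stratum)
        b = len(called) - a
        c = len(in_stratum) - a
        d = n_bg - a - b - c
        odds, p = fisher_two_sided([[a, b], [c, d]])
        expected = n_called * len(in_stratum) / n_bg
        ratio = a / expected if expected > 0 else float("nan")
        results.append(
            EnrichmentResult(
                term=label,
                N=n_bg,
                M=len(in_stratum),
                n=n_called,
                m=a,
                p_raw=p,
                p_adjusted=np.nan,
                method="fisher",
                odds_ratio=odds,
                enrichment_ratio=ratio,
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    return [
        EnrichmentResult(
            r.term, r.N, r.M, r.n, r.m, r.p_raw, float(adj), r.method, r.odds_ratio,
            r.enrichment_ratio,
        )
        for r, adj in zip(results, adjusted)
    ]
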