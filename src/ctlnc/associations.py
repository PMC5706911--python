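"""Covariate-adjusted linear models, group tests and the exclusivity screen."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import CtlncError
from .stats import bh_adjust, fisher_two_sided, sample_odds_ratio, wilcoxon_rank_sum

STAGE_MAP = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass(frozen=True)
class TermFit:
    name: str
    beta: float
    se: float
    t: float
    p: float


@dataclass
class RegressionFit:
    response: str
    terms: list[TermFit]
    n_used: int
    adjustment: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.name for t in self.terms],
                "beta": [t.beta for t in self.terms],
                "SE": [t.se for t in self.terms],
                "t": [t.t for t in self.terms],
                "p": [t.p for t in self.terms],
            }
        )


@dataclass(frozen=True)
class ExclusivityResult:
    lncrna_id: str
    driver: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (mut, wt) x (active, inactive)
    odds_ratio: float
    p_raw: float
    p_adjusted: float
    direction: str  # exclusive | co_occurring | none


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # first sorted level is the reference
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{name}[{level}]")
    return np.column_stack(cols), names


def ols_fit(
    response: pd.Series, covariates: pd.DataFrame, response_name: str = "y"
) -> RegressionFit:
    """OLS with per-term t-tests; complete-case; errors on rank deficiency."""
    df = covariates.copy()
    df["__y__"] = np.asarray(response, dtype=float)
    df = df.dropna()
    y = df.pop("__y__").to_numpy()
    X, names = _design_matrix(df)
    n, k = X.shape
    if n <= k:
        raise CtlncError(f"n_used={n} too small for {k} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name columns that vanish under a QR factorization
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * max(1.0, diag.max()))[0]]
        raise CtlncError(f"rank-deficient design; collinear terms: {bad or names}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    if sigma2 == 0:
        sigma2 = np.finfo(float).tiny
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)
    terms = [
        TermFit(nm, float(b), float(s), float(t), float(max(p, np.finfo(float).tiny)))
        for nm, b, s, t, p in zip(names, beta, se, tvals, pvals)
    ]
    return RegressionFit(response_name, terms, n, list(covariates.columns))


def _encode_stage(stage: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        s = str(v).replace("Stage ", "").strip()
        if s in STAGE_MAP:
            return float(STAGE_MAP[s])
        try:
            f = float(s)
        except ValueError:
            return np.nan
        return f if 1 <= f <= 4 else np.nan

    return stage.map(conv)


def stage_association(counts: pd.Series, clinical: pd.DataFrame) -> RegressionFit:
    """count ~ stage + age + gender + cancer_type, stage numeric 1-4."""
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    common = [s for s in counts.index if s in clin.index]
    clin = clin.loc[common]
    stage = _encode_stage(clin["stage"])
    if stage.dropna().nunique() < 2:
        raise CtlncError("need at least 2 distinct stages")
    cov = pd.DataFrame(
        {"stage": stage, "age": clin["age"], "gender": clin["gender"].astype(str)},
        index=common,
    )
    if clin["cancer_type"].nunique() > 1:
        cov["cancer_type"] = clin["cancer_type"].astype(str)
    return ols_fit(counts.loc[common], cov, "n_activated_eect")


def smg_ratio_association(
    smg_ratio: pd.Series,
    counts: pd.Series,
    cancer_type: pd.Series | None = None,
    orientation: str = "count_on_ratio",
) -> RegressionFit:
    """Linear coupling of the SMG mutation ratio and the activated count.

    ``orientation`` selects which variable is the response; the planted
    association's sign is orientation-invariant.
    """
    if smg_ratio.dropna().lt(0).any() or smg_ratio.dropna().gt(1).any():
        raise CtlncError("smg_ratio must lie in [0, 1]")
    common = [s for s in counts.index if s in smg_ratio.index]
    data = pd.DataFrame(
        {"smg_ratio": smg_ratio.loc[common], "count": counts.loc[common]}, index=common
    )
    if orientation == "count_on_ratio":
        y, x, yname = data["count"], "smg_ratio", "n_activated_eect"
    elif orientation == "ratio_on_count":
        y, x, yname = data["smg_ratio"], "count", "smg_ratio"
    else:
        raise CtlncError(f"unknown orientation {orientation!r}")
    cov = pd.DataFrame({x: data[x]}, index=common)
    if cancer_type is not None and cancer_type.loc[common].nunique() > 1:
        cov["cancer_type"] = cancer_type.loc[common].astype(str)
    return ols_fit(y, cov, yname)


def methylation_association(
    mean_promoter_beta: pd.Series,
    counts: pd.Series,
    cancer_type: pd.Series | None = None,
    global_promoter_beta: pd.Series | None = None,
) -> RegressionFit:
    """count ~ mean EECT-promoter methylation (+ cancer type, + global level)."""
    beta = mean_promoter_beta.dropna()
    if beta.lt(0).any() or beta.gt(1).any():
        raise CtlncError("beta values must lie in [0, 1]")
    common = [s for s in counts.index if s in beta.index]
    cov = pd.DataFrame({"mean_promoter_beta": beta.loc[common]}, index=common)
    if cancer_type is not None and cancer_type.loc[common].nunique() > 1:
        cov["cancer_type"] = cancer_type.loc[common].astype(str)
    if global_promoter_beta is not None:
        cov["global_promoter_beta"] = global_promoter_beta.loc[common]
    return ols_fit(counts.loc[common], cov, "n_activated_eect")


def oncogene_group_test(counts: pd.Series, group_labels: pd.Series) -> tuple[float, float]:
    """Wilcoxon rank-sum of activated counts, oncogene-positive vs -negative."""
    labels = group_labels.loc[counts.index]
    pos = counts[labels == "positive"]
    neg = counts[labels == "negative"]
    if len(pos) == 0 or len(neg) == 0:
        raise CtlncError("both oncogene groups must be non-empty")
    return wilcoxon_rank_sum(pos.to_numpy(), neg.to_numpy())


def mutation_matrix(maf: pd.DataFrame, samples, drivers) -> pd.DataFrame:
    """Sample-by-driver boolean matrix from a MAF-lite table."""
    out = pd.DataFrame(False, index=list(samples), columns=list(drivers))
    for _, row in maf.iterrows():
        if row["sample_id"] in out.index and row["gene"] in out.columns:
            out.loc[row["sample_id"], row["gene"]] = True
    return out


def mutual_exclusivity_screen(
    activation: pd.DataFrame,
    mutations: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    include_any_driver: bool = True,
) -> list[ExclusivityResult]:
    """Per (lncRNA, driver) Fisher screen for exclusivity / co-occurrence.

    Both inputs are sample-by-gene boolean frames over the same samples.
    Pairs with a zero-variance margin are skipped. Returns every tested
    pair with BH-adjusted p; callers filter on ``direction`` and the chosen
    p at ``alpha``.
    """
    if list(activation.index) != list(mutations.index):
        shared = [s for s in activation.index if s in set(mutations.index)]
        if not shared:
            raise CtlncError("activation and mutation tables share no samples")
        activation = activation.loc[shared]
        mutations = mutations.loc[shared]
    drivers = list(mutations.columns)
    if include_any_driver and len(drivers) > 1:
        mutations = mutations.copy()
        mutations["ANY_DRIVER"] = mutations[drivers].any(axis=1)
    rows = []
    for lnc in activation.columns:
        act = activation[lnc].to_numpy(dtype=bool)
        if act.all() or not act.any():
            continue
        for drv in mutations.columns:
            mut = mutations[drv].to_numpy(dtype=bool)
            if mut.all() or not mut.any():
                continue
            a = int((mut & act).sum())
            b = int((mut & ~act).sum())
            c = int((~mut & act).sum())
            d = int((~mut & ~act).sum())
            _, p = fisher_two_sided([[a, b], [c, d]])
            rows.append((lnc, drv, ((a, b), (c, d)), p))
    if not rows:
        return []
    adjusted = bh_adjust([r[3] for r in rows])
    results = []
    for (lnc, drv, table, p), p_adj in zip(rows, adjusted):
        odds = sample_odds_ratio(table)
        if np.isnan(odds) or odds == 1.0:
            direction = "none"
        elif odds < 1.0:
            direction = "exclusive"
        else:
            direction = "co_occurring"
        results.append(ExclusivityResult(lnc, drv, table, odds, p, float(p_adj), direction))
    return results


def significant_exclusive(
    results: list[ExclusivityResult], alpha: float = 0.05, use_adjusted: bool = True
) -> list[ExclusivityResult]:
    key = (lambda r: r.p_adjusted) if use_adjusted else (lambda r: r.p_raw)
    return [r for r in results if r.direction == "exclusive" and key(r) < alpha]


def exclusivity_frame(results: list[ExclusivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna": [r.lncrna_id for r in results],
            "driver": [r.driver for r in results],
            "mut_active": [r.table[0][0] for r in results],
            "mut_inactive": [r.table[0][1] for r in results],
            "wt_active": [r.table[1][0] for r in results],
            "wt_inactive": [r.table[1][1] for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_BH": [r.p_adjusted for r in results],
            "direction": [r.direction for r in results],
        }
    )
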