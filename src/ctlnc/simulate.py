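"""Synthetic cohort generator with planted ground truth.

Every generator is a pure function of (spec, seed): child random streams are
derived from the spec's global seed by fixed offsets so the components stay
independent yet reproducible.

Expression model: log2-normal background with a point mass at zero
(dropout). Testis-specific (TS) genes are silent outside testis; reactivated
(CT) genes are silent in tumors except for a planted subset of samples whose
log2 expression is shifted up by ``activation_log2_effect``, which gives the
mean+k*SD outlier rule planted positives. Co-expression modules share a
per-sample latent factor; module CT genes are activated in the samples where
their module factor is highest, so their rank correlation with module coding
genes survives the sparse activation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortSpec, validated_spec
from .exceptions import ConfigurationError, ConsistencyError
from .io import (
    RPKM,
    ExpressionMatrix,
    GeneModel,
    Interval,
    ScoreTrack,
)
from .truth import SyntheticTruth

# fixed child-seed offsets
_OFF_PANEL = 1
_OFF_TUMOR = 2
_OFF_ANNOT = 3
_OFF_TABLES = 4

_LNC_BIOTYPE_CYCLE = (
    "lincRNA",
    "lincRNA",
    "lincRNA",
    "lincRNA",
    "lincRNA",
    "lincRNA",
    "antisense",
    "antisense",
    "processed_transcript",
    "sense_intronic",
)

_ACTIVATION_LOG2_SD = 0.5


def lncrna_ids(spec: CohortSpec) -> list[str]:
    return [f"LNC{i:04d}" for i in range(spec.n_lncrna)]

def coding_ids(spec: CohortSpec) -> list[str]:
    return [f"PC{i:04d}" for i in range(spec.n_coding)]

def gene_ids(spec: CohortSpec) -> list[str]:
    return lncrna_ids(spec) + coding_ids(spec)


def _rng(spec: CohortSpec, offset: int) -> np.random.Generator:
    return np.random.default_rng(spec.seed + offset)


def _choose(rng: np.random.Generator, pool: list[str], k: int) -> list[str]:
    k = min(k, len(pool))
    if k == 0:
        return []
    return sorted(rng.choice(pool, size=k, replace=False).tolist())


def build_truth(spec: CohortSpec | dict | None = None, **overrides) -> SyntheticTruth:
    """Plant the ground truth (gene roles, modules, elements, couplings)."""
    spec = validated_spec(spec, **overrides)
    rng = _rng(spec, 0)
    lnc = lncrna_ids(spec)
    coding = coding_ids(spec)

    ts = _choose(rng, lnc, int(round(spec.frac_ts * spec.n_lncrna)))
    ct = _choose(rng, ts, int(round(spec.frac_ct_of_ts * len(ts))))
    eect = list(ct)  # all planted reactivations are extreme by construction

    truth = SyntheticTruth(ts_genes=set(ts), ct_genes=set(ct), eect_genes=set(eect))

    # co-expression modules: coding members plus lncRNA members, the latter
    # drawn from CT genes first (their sparse activation tracks the module
    # factor) and topped up from non-TS lncRNAs if needed.
    module_coding = _choose(rng, coding, spec.n_modules * spec.n_coding_per_module)
    non_ts_lnc = [g for g in lnc if g not in truth.ts_genes]
    want_lnc = spec.n_modules * spec.n_lnc_per_module
    module_lnc = _choose(rng, ct, want_lnc)
    if len(module_lnc) < want_lnc:
        module_lnc += _choose(rng, non_ts_lnc, want_lnc - len(module_lnc))
    for i, g in enumerate(module_coding):
        truth.module_assignment[g] = f"M{i // spec.n_coding_per_module + 1:02d}"
    for i, g in enumerate(module_lnc):
        truth.module_assignment[g] = f"M{i // max(1, spec.n_lnc_per_module) + 1:02d}"

    # regulatory elements target subsets of the TS genes
    for prefix, frac in (
        ("PROM", spec.frac_promoter_targets),
        ("METH", spec.frac_methylation_targets),
        ("ENH", spec.frac_enhancer_targets),
    ):
        targets = _choose(rng, ts, int(round(frac * len(ts))))
        for j, g in enumerate(targets):
            truth.element_placements[f"{prefix}{j:04d}"] = g
    for j in range(spec.n_background_elements):
        truth.element_placements[f"BG{j:04d}"] = "background"

    truth.methylation_effect = {
        g: (-1 if g in truth.eect_genes and spec.methylation_beta_shift > 0 else 0) for g in ts
    }

    # mutual exclusivity: drivers are coding genes outside the modules
    driver_pool = [g for g in coding if g not in truth.module_assignment]
    drivers = _choose(rng, driver_pool, spec.n_drivers)
    partners = _choose(rng, eect, len(drivers))
    truth.exclusive_pairs = list(zip(drivers, partners))

    truth.validate()
    return truth


# ---------------------------------------------------------------------------


def generate_normal_panel(
    spec: CohortSpec | dict | None = None, truth: SyntheticTruth | None = None, **overrides
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multi-tissue normal panel; TS genes expressed only in testis."""
    spec = validated_spec(spec, **overrides)
    if truth is None:
        truth = build_truth(spec)
    rng = _rng(spec, _OFF_PANEL)
    tissues = spec.resolved_tissue_labels()
    samples = [f"{t}_{i + 1:02d}" for t in tissues for i in range(spec.n_normal_individuals)]
    testis_mask = np.array([s.startswith("testis_") for s in samples])
    ids = gene_ids(spec)
    n_g, n_s = len(ids), len(samples)

    log2 = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=(n_g, n_s))
    values = np.exp2(log2)
    values[rng.random((n_g, n_s)) < spec.dropout_rate] = 0.0

    ts_idx = np.array([gid in truth.ts_genes for gid in ids])
    if ts_idx.any():
        values[np.ix_(ts_idx, ~testis_mask)] = 0.0
        n_ts = int(ts_idx.sum())
        testis_log2 = rng.normal(
            spec.baseline_log2_mean + spec.activation_log2_effect,
            spec.baseline_log2_sd,
            size=(n_ts, int(testis_mask.sum())),
        )
        testis_vals = np.exp2(testis_log2)
        testis_vals[rng.random(testis_vals.shape) < spec.dropout_rate] = 0.0
        values[np.ix_(ts_idx, testis_mask)] = testis_vals

    matrix = ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples), RPKM)
    return matrix, truth


def tissue_of_sample(sample_id: str) -> str:
    return sample_id.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------


def generate_tumor_cohorts(
    spec: CohortSpec, truth: SyntheticTruth, unit: str = RPKM
) -> dict[str, ExpressionMatrix]:
    """Per-cancer-type tumor matrices with planted sparse reactivation.

    Fills ``truth.activated_samples`` with the planted activation sets.
    """
    spec = validated_spec(spec)
    known = set(gene_ids(spec))
    if not truth.ts_genes <= known:
        raise ConsistencyError("truth refers to genes absent from this spec's cohort")
    truth.validate(known)

    rng = _rng(spec, _OFF_TUMOR)
    ids = gene_ids(spec)
    n_g = len(ids)
    module_names = sorted({m for m in truth.module_assignment.values()})
    module_index = {m: i for i, m in enumerate(module_names)}
    r = spec.rho_within

    cohorts: dict[str, ExpressionMatrix] = {}
    truth.activated_samples = {g: set() for g in truth.ct_genes}
    n = spec.n_tumor_samples_per_type
    k_active = 0 if spec.activation_frequency == 0 else max(1, int(round(spec.activation_frequency * n)))

    for ctype in spec.cancer_types:
        samples = [f"{ctype}_T{i:04d}" for i in range(n)]
        factors = rng.normal(size=(max(1, len(module_names)), n))
        eps = rng.normal(size=(n_g, n))
        log2 = np.full((n_g, n), spec.baseline_log2_mean)
        values = np.zeros((n_g, n))
        dropout = rng.random((n_g, n)) < spec.dropout_rate
        act_noise = rng.normal(0.0, _ACTIVATION_LOG2_SD, size=(n_g, n))

        for gi, gid in enumerate(ids):
            is_ts = gid in truth.ts_genes
            is_ct = gid in truth.ct_genes
            module = truth.module_assignment.get(gid)
            if is_ct:
                if k_active > 0:
                    if module is not None:
                        f = factors[module_index[module]]
                        active = np.argsort(f)[-k_active:]
                    else:
                        active = rng.choice(n, size=k_active, replace=False)
                    vals = np.exp2(spec.activation_log2_effect + act_noise[gi, active])
                    values[gi, active] = vals
                    truth.activated_samples[gid].update(samples[j] for j in active)
            elif is_ts:
                pass  # silent in tumors
            elif module is not None:
                f = factors[module_index[module]]
                row = log2[gi] + spec.baseline_log2_sd * (
                    np.sqrt(r) * f + np.sqrt(1.0 - r) * eps[gi]
                )
                values[gi] = np.exp2(row)
            else:
                row = log2[gi] + spec.baseline_log2_sd * eps[gi]
                values[gi] = np.exp2(row)
                values[gi, dropout[gi]] = 0.0

        cohorts[ctype] = ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples), unit)
    return cohorts


# ---------------------------------------------------------------------------


def generate_gene_models(spec: CohortSpec) -> list[GeneModel]:
    """Deterministic genome layout: fixed spacing, alternating strands."""
    spec = validated_spec(spec)
    margin = 25_000  # farthest window reach (20 kb) plus slack
    if spec.gene_spacing <= spec.gene_length:
        raise ConfigurationError(
            f"gene_spacing={spec.gene_spacing} too small for gene_length={spec.gene_length}: "
            "genes would overlap"
        )
    ids = gene_ids(spec)
    genes = []
    for i, gid in enumerate(ids):
        chrom = f"chr{i // spec.genes_per_chromosome + 1}"
        start = 50_000 + (i % spec.genes_per_chromosome) * spec.gene_spacing
        end = start + spec.gene_length
        strand = "+" if i % 2 == 0 else "-"
        third = spec.gene_length // 3
        exons = ((start, start + third), (start + 2 * third, end))
        if gid.startswith("LNC"):
            biotype = _LNC_BIOTYPE_CYCLE[i % len(_LNC_BIOTYPE_CYCLE)]
        else:
            biotype = "protein_coding"
        genes.append(GeneModel(gid, chrom, start, end, strand, exons, biotype))
    _ = margin
    return genes


def _upstream_window(gene: GeneModel, far: int, near: int) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.start - far), max(0, gene.start - near)
    return gene.end + near, gene.end + far


def _place_in(rng, lo: int, hi: int, length: int) -> tuple[int, int]:
    start = int(rng.integers(lo, max(lo + 1, hi - length)))
    return start, start + length


def generate_annotation(
    spec: CohortSpec, truth: SyntheticTruth
) -> tuple[list[GeneModel], list[Interval], ScoreTrack, ScoreTrack, dict[str, set[str]]]:
    """Gene models, element catalog, conservation tracks and gene sets.

    Planted promoters fall 100 bp-5 kb upstream, methylation sites
    100 bp-1 kb upstream, enhancers within 20 kb upstream or 5 kb
    downstream of their target gene, all strand-aware. Background elements
    sit in inter-gene safe zones at least 25 kb from any gene span.
    Conservation is lower over CT-gene exons/promoters than elsewhere.
    """
    spec = validated_spec(spec)
    rng = _rng(spec, _OFF_ANNOT)
    genes = generate_gene_models(spec)
    by_id = {g.gene_id: g for g in genes}
    truth.validate(set(by_id))

    elements: list[Interval] = []
    for elem_id in sorted(truth.element_placements):
        target = truth.element_placements[elem_id]
        if target == "background":
            continue
        g = by_id[target]
        if elem_id.startswith("PROM"):
            lo, hi = _upstream_window(g, 5_000, 100)
            s, e = _place_in(rng, lo, hi, 200)
        elif elem_id.startswith("METH"):
            lo, hi = _upstream_window(g, 1_000, 100)
            s, e = _place_in(rng, lo, hi, 2)
        elif elem_id.startswith("ENH"):
            if rng.random() < 0.5:  # upstream flank, up to 20 kb 5' of the TSS
                lo, hi = _upstream_window(g, 20_000, 0)
            else:  # downstream flank, up to 5 kb past the 3' end
                if g.strand == "+":
                    lo, hi = g.end, g.end + 5_000
                else:
                    lo, hi = max(0, g.start - 5_000), g.start
            s, e = _place_in(rng, lo, hi, 500)
        else:
            raise ConsistencyError(f"unknown planted element class for {elem_id!r}")
        elements.append(Interval(g.chrom, s, e, elem_id, 0.0, "."))

    # background elements: mid-gap zones >= 25 kb clear of every gene span
    margin = 25_000
    safe_zones = []
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start))
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.chrom != nxt.chrom:
            continue
        lo, hi = prev.end + margin, nxt.start - margin
        if hi - lo >= 1_000:
            safe_zones.append((prev.chrom, lo, hi))
    n_bg = sum(1 for t in truth.element_placements.values() if t == "background")
    if n_bg > 0 and not safe_zones:
        raise ConfigurationError(
            "gene_spacing leaves no element-free zone for background elements"
        )
    bg_ids = sorted(e for e, t in truth.element_placements.items() if t == "background")
    for j, elem_id in enumerate(bg_ids):
        chrom, lo, hi = safe_zones[j % len(safe_zones)]
        s, e = _place_in(rng, lo, hi, 200)
        elements.append(Interval(chrom, s, e, elem_id, 0.0, "."))
    elements.sort(key=lambda iv: (iv.chrom, iv.start, iv.name))

    # conservation tracks in 500 bp chunks over each gene's span +/- 2.5 kb
    phast = ScoreTrack("phastcons")
    phylo = ScoreTrack("phylop")
    chunk = 500
    for g in genes:
        low_cons = g.gene_id in truth.ct_genes
        lo = max(0, g.start - 2_500)
        hi = g.end + 2_500
        for s in range(lo, hi, chunk):
            e = min(s + chunk, hi)
            if low_cons:
                phast.add(g.chrom, s, e, rng.beta(2.0, 8.0))
                phylo.add(g.chrom, s, e, rng.normal(-1.0, 0.7))
            else:
                phast.add(g.chrom, s, e, rng.beta(8.0, 2.0))
                phylo.add(g.chrom, s, e, rng.normal(1.5, 0.7))

    # gene sets: one per module (its coding members) plus random decoys
    gene_sets: dict[str, set[str]] = {}
    modules: dict[str, set[str]] = {}
    for gid, mod in truth.module_assignment.items():
        if gid.startswith("PC"):
            modules.setdefault(mod, set()).add(gid)
    for mod, members in sorted(modules.items()):
        gene_sets[f"SET_{mod}"] = set(members)
    non_module_coding = [g for g in coding_ids(spec) if g not in truth.module_assignment]
    n_decoys = max(0, spec.n_gene_sets - len(gene_sets))
    for j in range(n_decoys):
        size = min(spec.n_coding_per_module, len(non_module_coding))
        gene_sets[f"SET_DECOY{j:03d}"] = set(_choose(rng, non_module_coding, size))

    return genes, elements, phast.finalize(), phylo.finalize(), gene_sets


# ---------------------------------------------------------------------------


def generate_methylation_mutations_clinical(
    spec: CohortSpec, truth: SyntheticTruth, cohorts: dict[str, ExpressionMatrix]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Promoter methylation, MAF-lite mutations and a clinical table.

    Activated samples of planted EECT genes get promoter beta values shifted
    down by ``methylation_beta_shift``; driver mutations of each planted
    exclusive pair avoid that lncRNA's activated samples; AJCC stage trends
    with the per-sample activated count by ``stage_trend``; ``smg_ratio``
    is coupled negatively to the activated count by ``smg_coupling``.
    """
    spec = validated_spec(spec)
    if not truth.activated_samples and truth.ct_genes:
        raise ConsistencyError("generate_tumor_cohorts must run first (activated_samples empty)")
    rng = _rng(spec, _OFF_TABLES)

    samples: list[str] = []
    sample_ctype: dict[str, str] = {}
    for ctype in spec.cancer_types:
        if ctype not in cohorts:
            raise ConsistencyError(f"cohort for cancer type {ctype!r} missing")
        for s in cohorts[ctype].sample_ids:
            samples.append(s)
            sample_ctype[s] = ctype
    n = len(samples)
    sample_pos = {s: i for i, s in enumerate(samples)}

    # methylation: beta values for TS-gene promoters
    ts_sorted = sorted(truth.ts_genes)
    conc = 10.0
    meth = np.empty((len(ts_sorted), n))
    for gi, gid in enumerate(ts_sorted):
        mu = np.full(n, 0.7)
        if truth.methylation_effect.get(gid, 0) < 0:
            for s in truth.activated_samples.get(gid, ()):
                mu[sample_pos[s]] = 0.7 - spec.methylation_beta_shift
        meth[gi] = rng.beta(conc * mu, conc * (1.0 - mu))
    meth_df = pd.DataFrame(meth, index=ts_sorted, columns=samples)

    # mutations
    rows: list[tuple[str, str, str]] = []
    for driver, lnc in truth.exclusive_pairs:
        active = truth.activated_samples.get(lnc, set())
        eligible = [s for s in samples if s not in active]
        k = min(int(round(spec.driver_mutation_rate * n)), len(eligible))
        for s in _choose(rng, eligible, k):
            rows.append((s, driver, "Missense_Mutation"))
    passenger_pool = [
        g
        for g in coding_ids(spec)
        if g not in truth.module_assignment and g not in {d for d, _ in truth.exclusive_pairs}
    ][:5]
    for gene in passenger_pool:
        for s in _choose(rng, samples, int(round(0.05 * n))):
            rows.append((s, gene, "Missense_Mutation"))
    rows.sort()
    maf_df = pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class"])

    # clinical: stage and smg_ratio coupled to the activated EECT count
    counts = np.zeros(n)
    for gid in truth.eect_genes:
        for s in truth.activated_samples.get(gid, ()):
            counts[sample_pos[s]] += 1
    c_sd = counts.std() if counts.std() > 0 else 1.0
    z = spec.stage_trend * (counts - counts.mean()) / c_sd + rng.normal(size=n)
    order = np.argsort(np.argsort(z, kind="stable"), kind="stable")
    stage_num = np.ceil(4 * (order + 1) / n).astype(int)
    stage = np.array(["I", "II", "III", "IV"])[stage_num - 1]
    max_c = max(1.0, counts.max())
    smg = np.clip(
        0.5 - spec.smg_coupling * counts / max_c + rng.normal(0.0, 0.12, size=n), 0.0, 1.0
    )
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "age": np.clip(np.round(rng.normal(65, 10, size=n)), 30, 90).astype(int),
            "gender": rng.choice(["female", "male"], size=n),
            "stage": stage,
            "cancer_type": [sample_ctype[s] for s in samples],
            "smg_ratio": np.round(smg, 6),
        }
    )
    return meth_df, maf_df, clinical
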