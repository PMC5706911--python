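"""End-to-end orchestration on a validated config, with an output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import associations as am
from . import coexpression as cx
from . import conservation as cons
from . import ct_calling as ctc
from . import io as gio
from . import regulatory as reg
from . import simulate as sim
from . import specificity as spc
from .config import CohortSpec
from .exceptions import ConfigurationError, PipelineError

log = logging.getLogger("ctlnc")

STAGES = (
    "simulate",
    "specificity",
    "ct_calling",
    "conservation",
    "coexpression",
    "regulatory",
    "associations",
)


class Thresholds(BaseModel):
    model_config = {"frozen": True}

    floor: float | None = None  # None -> unit default (0.1 RPKM / 5 counts)
    min_frac: float = Field(default=0.01, ge=0.0, le=1.0)
    k_sd: float = Field(default=3.0, gt=0.0)
    spm_high: float = Field(default=0.9, gt=0.0, le=1.0)
    spm_moderate: float = Field(default=0.6, gt=0.0, le=1.0)
    alpha_annotation: float = Field(default=0.01, gt=0.0, le=1.0)
    alpha_exclusivity: float = Field(default=0.05, gt=0.0, le=1.0)
    coexpr_floor: float = 5.0


class PipelineConfig(BaseModel):
    model_config = {"frozen": True}

    seed: int = 1
    simulate: CohortSpec = CohortSpec()
    stages: dict[str, bool] = Field(default_factory=dict)
    thresholds: Thresholds = Thresholds()

    def stage_enabled(self, name: str) -> bool:
        if name not in STAGES:
            raise ConfigurationError(f"unknown stage {name!r}")
        return self.stages.get(name, True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        try:
            cfg = cls(**data)
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"]) or "<config>"
            raise ConfigurationError(f"invalid config field {loc!r}: {first['msg']}") from None
        unknown = set(cfg.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages in config: {sorted(unknown)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(**{**config.simulate.model_dump(), "seed": config.seed})
    thr = config.thresholds
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    written: list[Path] = []

    def emit(name: str):
        path = outdir / name
        written.append(path)
        return path

    state: dict = {}

    def stage_simulate():
        truth = sim.build_truth(spec)
        panel, _ = sim.generate_normal_panel(spec, truth)
        cohorts = sim.generate_tumor_cohorts(spec, truth)
        genes, elements, phast, phylo, gene_sets = sim.generate_annotation(spec, truth)
        meth, maf, clinical = sim.generate_methylation_mutations_clinical(spec, truth, cohorts)
        gio.write_expression(panel, emit("normal_panel.tsv"))
        for ctype, expr in cohorts.items():
            gio.write_expression(expr, emit(f"tumor_{ctype}.tsv"))
        gio.write_bed12(genes, emit("genes.bed12"))
        gio.write_bed6(elements, emit("elements.bed"))
        gio.write_bedgraph(phast, emit("phastcons.bedgraph"))
        gio.write_bedgraph(phylo, emit("phylop.bedgraph"))
        gio.write_gmt(gene_sets, emit("gene_sets.gmt"))
        meth.to_csv(emit("methylation.tsv"), sep="\t", index_label="gene_id", float_format="%.10g")
        gio.write_maf_lite(maf, emit("mutations.maf.tsv"))
        gio.write_clinical(clinical, emit("clinical.tsv"))
        gio.write_json(truth.to_dict(), emit("truth.json"))
        state.update(
            truth=truth, panel=panel, cohorts=cohorts, genes=genes, elements=elements,
            phastcons=phast, phylop=phylo, gene_sets=gene_sets, methylation=meth,
            maf=maf, clinical=clinical,
        )

    def stage_specificity():
        panel = state["panel"]
        labels = {s: sim.tissue_of_sample(s) for s in panel.sample_ids}
        genes = state["genes"]
        coding_models = [g for g in genes if g.biotype == "protein_coding"]
        kept = spc.filter_lncrna_models(genes, coding_models)
        kept_ids = {g.gene_id for g in kept}
        thresholds = spc.SpmThresholds(thr.spm_high, thr.spm_moderate)
        lnc_panel = panel.subset_genes([g for g in panel.gene_ids if g in kept_ids])
        calls = spc.classify_testis_specific(lnc_panel, labels, thresholds)
        frame = spc.calls_to_frame(calls)
        frame.to_csv(emit("specificity.tsv"), sep="\t", index=False, float_format="%.10g")
        state["ts_genes"] = {c.gene_id for c in calls if c.category == spc.TS_HIGH}

    def stage_ct_calling():
        table = ctc.build_call_table(
            state["cohorts"], state["ts_genes"], floor=thr.floor,
            min_frac=thr.min_frac, k_sd=thr.k_sd,
        )
        table.to_tsv(emit("ct_calls.tsv"))
        state["call_table"] = table
        counts = {}
        activations = {}
        for ctype, expr in state["cohorts"].items():
            ct = ctc.call_ct(expr, state["ts_genes"], floor=thr.floor, min_frac=thr.min_frac)
            eect = ctc.call_eect(expr, set(ct.index[ct]), k_sd=thr.k_sd, min_frac=thr.min_frac)
            counts[ctype] = ctc.activation_counts(expr, eect)
            activations[ctype] = ctc.activation_matrix(expr, eect)
        all_counts = pd.concat(counts.values())
        all_counts.rename("n_activated_eect").to_frame().to_csv(
            emit("activation_counts.tsv"), sep="\t", index_label="sample_id"
        )
        state["activation_counts"] = all_counts
        state["activation_matrices"] = activations
        biotypes = {g.gene_id: g.biotype for g in state["genes"]}
        chroms = {g.gene_id: g.chrom for g in state["genes"]}
        lnc_bg = [g.gene_id for g in state["genes"] if g.is_lncrna]
        eect_union = table.eect_union()
        for strat_name, strata in (("biotype", biotypes), ("chromosome", chroms)):
            if eect_union:
                res = ctc.composition_enrichment(eect_union, strata, lnc_bg)
                frame = pd.DataFrame(
                    [
                        {
                            "stratum": r.term, "N": r.N, "M": r.M, "n": r.n, "m": r.m,
                            "enrichment_ratio": r.enrichment_ratio, "odds_ratio": r.odds_ratio,
                            "p_raw": r.p_raw, "p_BH": r.p_adjusted,
                        }
                        for r in res
                    ]
                )
                frame.to_csv(
                    emit(f"composition_{strat_name}.tsv"), sep="\t", index=False,
                    float_format="%.10g",
                )

    def stage_conservation():
        genes = [g for g in state["genes"] if g.is_lncrna]
        eect = state["call_table"].eect_union() if "call_table" in state else set()
        rows = []
        groups: dict[str, dict[str, list[float]]] = {
            "exons": {"eect": [], "other": []},
            "promoter": {"eect": [], "other": []},
        }
        for g in genes:
            for region in ("exons", "promoter"):
                s = cons.summarize_gene(g, state["phastcons"], state["phylop"], region)
                rows.append(
                    {
                        "gene_id": g.gene_id, "region": region,
                        "mean_phastcons": s.mean_phastcons,
                        "mean_phylop_rescaled": s.mean_phylop_rescaled,
                    }
                )
                bucket = "eect" if g.gene_id in eect else "other"
                groups[region][bucket].append(s.mean_phastcons)
        pd.DataFrame(rows).to_csv(
            emit("conservation.tsv"), sep="\t", index=False, float_format="%.10g"
        )
        tests = {}
        for region, d in groups.items():
            if d["eect"] and d["other"]:
                stat, p = cons.compare_groups(d["eect"], d["other"])
                tests[region] = {"statistic": stat, "p_value": p,
                                 "n_eect": len(d["eect"]), "n_other": len(d["other"])}
        gio.write_json(tests, emit("conservation_tests.json"))

    def stage_coexpression():
        ctype = spec.cancer_types[0]
        expr = state["cohorts"][ctype]
        coding = [g for g in expr.gene_ids if g.startswith("PC")]
        lnc = [g for g in expr.gene_ids if g.startswith("LNC")]
        tested_coding = set(cx.expression_filter(expr.subset_genes(coding), thr.coexpr_floor, thr.min_frac))
        tested_lnc = cx.expression_filter(expr.subset_genes(lnc), thr.coexpr_floor, thr.min_frac)
        db = cx.AnnotationDB.from_gene_sets(state["gene_sets"])
        profiles = cx.coexpression_profiles(expr, tested_lnc, sorted(tested_coding & db.universe))
        annotations = cx.annotate_all(profiles, db, thr.alpha_annotation, tested_coding)
        gio.write_json({g: sorted(t) for g, t in annotations.items()}, emit("annotations.json"))
        expanded = cx.expand_db(db, annotations)
        ct_union = state["call_table"].ct_union() if "call_table" in state else set()
        if ct_union & expanded.universe:
            res = cx.ct_set_enrichment(ct_union, expanded)
            cx.enrichment_frame(res).to_csv(
                emit("ct_set_enrichment.tsv"), sep="\t", index=False, float_format="%.10g"
            )

    def stage_regulatory():
        genes = state["genes"]
        elements = state["elements"]
        lnc_models = [g for g in genes if g.is_lncrna]
        ts = state.get("ts_genes", set())
        targets = [g for g in lnc_models if g.gene_id in ts]
        background = [g for g in lnc_models if g.gene_id not in ts]
        rows = []
        for wspec in (reg.PROMOTER_DEFAULT, reg.METHYLATION_DEFAULT, reg.ENHANCER_DEFAULT):
            kind_prefix = {"promoter_window": "PROM", "methylation_window": "METH",
                           "enhancer_flanks": "ENH"}[wspec.kind]
            els = [e for e in elements if e.name.startswith((kind_prefix, "BG"))]
            if targets and background:
                r = reg.window_enrichment(targets, background, els, wspec)
                rows.append(
                    {
                        "window": wspec.kind, "N": r.N, "M": r.M, "n": r.n, "m": r.m,
                        "odds_ratio": r.odds_ratio, "enrichment_ratio": r.enrichment_ratio,
                        "p": r.p_raw,
                    }
                )
        if rows:
            pd.DataFrame(rows).to_csv(
                emit("regulatory_enrichment.tsv"), sep="\t", index=False, float_format="%.10g"
            )

    def stage_associations():
        counts = state["activation_counts"]
        clinical = state["clinical"]
        fits = {}
        fits["stage"] = am.stage_association(counts, clinical)
        clin = clinical.set_index("sample_id")
        fits["smg_ratio"] = am.smg_ratio_association(
            clin["smg_ratio"], counts, clin["cancer_type"]
        )
        truth = state["truth"]
        eect = sorted(truth.eect_genes & set(state["methylation"].index))
        if eect:
            mean_beta = state["methylation"].loc[eect].mean(axis=0)
            fits["methylation"] = am.methylation_association(
                mean_beta, counts, clin["cancer_type"]
            )
        for name, fit in fits.items():
            fit.to_frame().to_csv(
                emit(f"fit_{name}.tsv"), sep="\t", index=False, float_format="%.10g"
            )
        drivers = sorted({d for d, _ in truth.exclusive_pairs})
        if drivers:
            activation = pd.concat(state["activation_matrices"].values())
            activation = activation.fillna(False).astype(bool)
            mut = am.mutation_matrix(state["maf"], activation.index, drivers)
            group = pd.Series(
                ["positive" if any_ else "negative" for any_ in mut.any(axis=1)],
                index=mut.index,
            )
            if group.nunique() > 1:
                stat, p = am.oncogene_group_test(counts, group)
                gio.write_json(
                    {"statistic": stat, "p_value": p}, emit("oncogene_group_test.json")
                )
            results = am.mutual_exclusivity_screen(activation, mut, thr.alpha_exclusivity)
            if results:
                am.exclusivity_frame(results).to_csv(
                    emit("exclusivity.tsv"), sep="\t", index=False, float_format="%.10g"
                )

    runners = {
        "simulate": stage_simulate,
        "specificity": stage_specificity,
        "ct_calling": stage_ct_calling,
        "conservation": stage_conservation,
        "coexpression": stage_coexpression,
        "regulatory": stage_regulatory,
        "associations": stage_associations,
    }
    for name in STAGES:
        if not config.stage_enabled(name):
            manifest["stages"][name] = "skipped"
            continue
        t0 = time.monotonic()
        try:
            runners[name]()
        except Exception as exc:  # noqa: BLE001 - stage failures must name the stage
            manifest["stages"][name] = f"failed: {exc}"
            _write_manifest(manifest, written, outdir, partial=True)
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = "ok"
        log.info("stage %s finished in %.2fs", name, time.monotonic() - t0)

    _write_manifest(manifest, written, outdir, partial=False)
    return manifest


def _write_manifest(manifest: dict, written: list[Path], outdir: Path, partial: bool) -> None:
    manifest["partial"] = partial
    manifest["files"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in written if p.exists()
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
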