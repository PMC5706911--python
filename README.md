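# ctlnc

Identification of cancer-testis long non-coding RNAs (CT-lncRNAs) and their
extremely highly expressed subset (EECT-lncRNAs) from expression cohorts,
with the downstream analyses that typically accompany such a screen:

- **specificity** — testis-specificity classification of lncRNAs from a
  multi-tissue normal panel (SPM statistic on per-tissue means, configurable
  cutoffs) plus coding-overlap filtering of lncRNA gene models.
- **ct_calling** — CT calls (expressed above a unit-specific floor — 0.1 for
  RPKM, 5 for normalized read counts — in ≥ 1% of samples) and EECT calls
  (zero-ruled log2 expression strictly above mean + 3×SD in ≥ 1% of
  samples), per-sample activation counts, and biotype/chromosome
  composition enrichment.
- **conservation** — PhastCons/PhyloP averaging over exon unions and
  promoters (2 kb upstream / 0.5 kb downstream of the TSS), PhyloP
  rescaling onto (0, 1), Wilcoxon group comparisons.
- **coexpression** — guilt-by-association annotation: Spearman profiles of
  each lncRNA against protein-coding genes, leading-decile partner sets,
  per-term upper-tail hypergeometric enrichment with BH adjustment,
  database expansion with the newly annotated genes, and set-level
  enrichment of the CT-lncRNA collection.
- **regulatory** — strand-aware window enrichment of regulatory elements
  (promoters 100 bp–5 kb upstream, methylation sites 100 bp–1 kb upstream,
  enhancers 20 kb upstream / 5 kb downstream) via Fisher's exact test, and
  the enhancer-stratified correlation comparison with nearest neighbours.
- **associations** — covariate-adjusted OLS (activation count vs AJCC
  stage / SMG mutation ratio / promoter methylation), oncogene-group
  Wilcoxon test, and the per-(lncRNA, driver) mutual-exclusivity Fisher
  screen.
- **simulate** — a synthetic-cohort generator (normal panel, tumor
  cohorts, gene models, element catalogs, conservation tracks, gene sets,
  methylation, mutations, clinical tables) with a planted ground truth so
  the whole pipeline is testable offline.

## CLI

```bash
# full synthetic study + all analysis stages, deterministic under --seed
ctlnc run --config config.yaml --seed 1 --outdir out/

# individual stages on files
ctlnc simulate --seed 1 --outdir out/
ctlnc classify --panel panel.tsv --labels labels.tsv --out spm.tsv
ctlnc call-ct --expr tumor.tsv --unit rpkm --ts-genes ts.txt --out calls.tsv
ctlnc conserve --track phastcons.bedgraph --genes genes.bed12 --region promoter --out cons.tsv
ctlnc annotate --expr tumor.tsv --lncrnas lnc.txt --gmt sets.gmt --out annotations.json
ctlnc enrich-reg --genes genes.bed12 --elements elements.bed --window enhancer \
    --targets ts.txt --background bg.txt --out enr.tsv
ctlnc associate --counts counts.tsv --clinical clinical.tsv --model stage --out fit.tsv
```

A config file is YAML with `seed`, a `simulate` block (cohort geometry and
planted effect sizes), optional `stages` toggles and a `thresholds` block;
defaults are 0.1 RPKM / counts > 5, 1% of samples, 3×SD, P_BH < 0.01 and
the window geometries above. `ctlnc run`
writes a `manifest.json` with SHA-256 hashes of every output; reruns with
the same config and seed are byte-identical.

## File formats

Expression matrices are TSV (genes × samples, header row); gene models are
BED12 (the name field carries `gene_id|biotype`) or a GTF-lite subset;
elements are BED6 (strandless); conservation tracks are bedGraph; gene sets
are GMT; mutations are a MAF-lite TSV (`sample_id`, `gene`,
`variant_class`); clinical tables are TSV with `sample_id`, `age`,
`gender`, `stage` (I–IV), `cancer_type` and optional `smg_ratio`. All
coordinates are 0-based half-open internally.

## Acceptance

Acceptance is property-based and implemented in
`tests/test_acceptance.py`: exhaustive oracle equivalence for the
hypergeometric / Fisher / Wilcoxon implementations, planted-truth recovery
for EECT calling, guilt-by-association and the association models,
power/calibration of the window enrichment, formula exactness of the
PhyloP rescaling, and end-to-end determinism. The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke of the pipeline and writes the numeric target
report (empty: no desk-scale numeric targets are defined, since realistic
headline counts would require large external cohorts).
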