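"""Simulator contracts: determinism, planted structure, coordinate placement."""

import io

import numpy as np
import pytest

from ctlnc import simulate as sim
from ctlnc.config import CohortSpec
from ctlnc.exceptions import ConfigurationError, ConsistencyError
from ctlnc.io import write_expression
from ctlnc.stats import spearman_rho


def matrix_bytes(matrix) -> bytes:
    buf = io.StringIO()
    write_expression(matrix, buf)
    return buf.getvalue().encode()


def test_invalid_spec_names_field():
    with pytest.raises(ConfigurationError, match="frac_ts"):
        CohortSpec.from_dict({"frac_ts": 1.5})
    with pytest.raises(ConfigurationError, match="activation_log2_effect"):
        CohortSpec.from_dict({"activation_log2_effect": -1})
    with pytest.raises(ConfigurationError, match="testis"):
        CohortSpec.from_dict({"n_tissues": 2, "tissue_labels": ("liver", "lung")})
    with pytest.raises(ConfigurationError, match="testis"):
        CohortSpec.from_dict({"n_tissues": 3, "tissue_labels": ("testis", "testis", "lung")})


def test_truth_nesting(small_truth):
    assert small_truth.eect_genes <= small_truth.ct_genes <= small_truth.ts_genes


class TestNormalPanel:
    def test_zero_frac_ts_empty_truth(self):
        spec = CohortSpec(n_genes=50, n_lncrna=20, frac_ts=0.0, n_modules=1, module_size=4)
        _, truth = sim.generate_normal_panel(spec)
        assert truth.ts_genes == set()

    def test_all_ts_testis_dominates(self):
        spec = CohortSpec(
            n_genes=60, n_lncrna=30, frac_ts=1.0, dropout_rate=0.0,
            n_normal_individuals=3, n_modules=1, module_size=4,
        )
        panel, truth = sim.generate_normal_panel(spec)
        testis = [s for s in panel.sample_ids if s.startswith("testis_")]
        other = [s for s in panel.sample_ids if not s.startswith("testis_")]
        for gid in sim.lncrna_ids(spec):
            assert panel.values.loc[gid, testis].mean() > panel.values.loc[gid, other].mean()

    def test_determinism(self, small_spec):
        a, _ = sim.generate_normal_panel(small_spec)
        b, _ = sim.generate_normal_panel(small_spec)
        assert matrix_bytes(a) == matrix_bytes(b)

    def test_non_negative(self, small_panel):
        assert (small_panel.values.to_numpy() >= 0).all()


class TestTumorCohorts:
    def test_determinism(self, small_spec):
        t1 = sim.build_truth(small_spec)
        t2 = sim.build_truth(small_spec)
        a = sim.generate_tumor_cohorts(small_spec, t1)
        b = sim.generate_tumor_cohorts(small_spec, t2)
        for ctype in small_spec.cancer_types:
            assert matrix_bytes(a[ctype]) == matrix_bytes(b[ctype])

    def test_activation_frequency_honoured(self, small_spec, small_truth, small_cohorts):
        n = small_spec.n_tumor_samples_per_type
        for gid in small_truth.ct_genes:
            active_frac = max(
                (small_cohorts[ct].values.loc[gid] > 0).mean() for ct in small_spec.cancer_types
            )
            assert active_frac >= small_spec.activation_frequency

    def test_non_ct_ts_silent(self, small_truth, small_cohorts):
        silent = small_truth.ts_genes - small_truth.ct_genes
        for ct, expr in small_cohorts.items():
            assert (expr.values.loc[sorted(silent)].to_numpy() == 0).all()

    def test_zero_activation_frequency(self):
        spec = CohortSpec(
            n_genes=60, n_lncrna=30, activation_frequency=0.0,
            n_tumor_samples_per_type=30, n_modules=1, module_size=4,
        )
        truth = sim.build_truth(spec)
        cohorts = sim.generate_tumor_cohorts(spec, truth)
        for expr in cohorts.values():
            assert (expr.values.loc[sorted(truth.ct_genes)].to_numpy() == 0).all()

    def test_truth_spec_mismatch_rejected(self, small_spec):
        truth = sim.build_truth(small_spec)
        truth.ts_genes.add("LNC9999")
        with pytest.raises(ConsistencyError):
            sim.generate_tumor_cohorts(small_spec, truth)

    def test_module_correlation_structure(self):
        spec = CohortSpec(
            n_genes=200, n_lncrna=60, rho_within=0.9, module_size=20, n_modules=3,
            frac_module_lnc=0.0, n_tumor_samples_per_type=120, cancer_types=("CA",),
            frac_ts=0.0, dropout_rate=0.0, seed=11,
        )
        truth = sim.build_truth(spec)
        expr = sim.generate_tumor_cohorts(spec, truth)["CA"].values
        modules = {}
        for g, m in truth.module_assignment.items():
            modules.setdefault(m, []).append(g)
        rng = np.random.default_rng(0)
        within, between = [], []
        mods = sorted(modules)
        for m in mods:
            genes = modules[m]
            for _ in range(30):
                g1, g2 = rng.choice(genes, size=2, replace=False)
                within.append(spearman_rho(expr.loc[g1], expr.loc[g2]))
        for _ in range(60):
            m1, m2 = rng.choice(mods, size=2, replace=False)
            g1 = rng.choice(modules[m1])
            g2 = rng.choice(modules[m2])
            between.append(spearman_rho(expr.loc[g1], expr.loc[g2]))
        assert np.median(within) > np.median(between) + 0.3


class TestAnnotation:
    def test_planted_enhancer_geometry(self, small_spec, small_truth, small_annotation):
        genes, elements, _, _, _ = small_annotation
        by_id = {g.gene_id: g for g in genes}
        enh = [e for e in elements if e.name.startswith("ENH")]
        assert enh
        for el in enh:
            target = by_id[small_truth.element_placements[el.name]]
            assert el.chrom == target.chrom
            if target.strand == "+":
                upstream_ok = target.start - 20_000 <= el.start and el.end <= target.start
                downstream_ok = target.end <= el.start and el.end <= target.end + 5_000
            else:
                upstream_ok = target.end <= el.start and el.end <= target.end + 20_000
                downstream_ok = target.start - 5_000 <= el.start and el.end <= target.start
            assert upstream_ok or downstream_ok

    def test_planted_promoter_and_methylation_windows(self, small_truth, small_annotation):
        genes, elements, _, _, _ = small_annotation
        by_id = {g.gene_id: g for g in genes}
        for el in elements:
            if el.name.startswith("BG"):
                continue
            target = by_id[small_truth.element_placements[el.name]]
            if target.strand == "+":
                dist_start = target.start - el.end
                dist_end = target.start - el.start
            else:
                dist_start = el.start - target.end
                dist_end = el.end - target.end
            if el.name.startswith("PROM"):
                assert 100 <= dist_start and dist_end <= 5_000
            elif el.name.startswith("METH"):
                assert 100 <= dist_start and dist_end <= 1_000

    def test_background_far_from_genes(self, small_annotation):
        genes, elements, _, _, _ = small_annotation
        bg = [e for e in elements if e.name.startswith("BG")]
        assert bg
        for el in bg:
            for g in genes:
                if g.chrom != el.chrom:
                    continue
                gap = max(g.start - el.end, el.start - g.end, 0)
                if el.start < g.end and g.start < el.end:
                    gap = 0
                assert gap >= 20_000

    def test_zero_background_all_targeted(self):
        spec = CohortSpec(
            n_genes=60, n_lncrna=30, n_background_elements=0, n_modules=1, module_size=4
        )
        truth = sim.build_truth(spec)
        _, elements, _, _, _ = sim.generate_annotation(spec, truth)
        for el in elements:
            assert truth.element_placements[el.name] != "background"

    def test_determinism(self, small_spec, small_truth):
        a = sim.generate_annotation(small_spec, small_truth)
        b = sim.generate_annotation(small_spec, small_truth)
        assert [(e.chrom, e.start, e.end, e.name) for e in a[1]] == [
            (e.chrom, e.start, e.end, e.name) for e in b[1]
        ]
        assert a[2].data == b[2].data

    def test_overlapping_layout_rejected(self):
        spec = CohortSpec(
            n_genes=30, n_lncrna=10, gene_spacing=1_000, gene_length=2_000,
            n_modules=1, module_size=4,
        )
        with pytest.raises(ConfigurationError, match="spacing"):
            sim.generate_gene_models(spec)

    def test_phastcons_in_unit_interval(self, small_annotation):
        _, _, phast, _, _ = small_annotation
        for segs in phast.data.values():
            assert all(0.0 <= v <= 1.0 for _, _, v in segs)


class TestTables:
    def test_zero_methylation_effect_no_group_shift(self):
        spec = CohortSpec(
            n_genes=120, n_lncrna=60, methylation_beta_shift=0.0,
            n_tumor_samples_per_type=250, cancer_types=("CA", "CB"),
            n_modules=1, module_size=4, seed=5,
        )
        truth = sim.build_truth(spec)
        cohorts = sim.generate_tumor_cohorts(spec, truth)
        meth, _, _ = sim.generate_methylation_mutations_clinical(spec, truth, cohorts)
        for gid in sorted(truth.eect_genes):
            active = sorted(truth.activated_samples.get(gid, set()))
            inactive = [s for s in meth.columns if s not in set(active)]
            if len(active) < 5:
                continue
            a = meth.loc[gid, active]
            b = meth.loc[gid, inactive]
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert abs(a.mean() - b.mean()) < 3 * se + 1e-9

    def test_exclusive_pairs_avoid_activated_samples(self, small_spec, small_truth, small_cohorts):
        meth, maf, _ = sim.generate_methylation_mutations_clinical(
            small_spec, small_truth, small_cohorts
        )
        for driver, lnc in small_truth.exclusive_pairs:
            mutated = set(maf.loc[maf["gene"] == driver, "sample_id"])
            active = small_truth.activated_samples.get(lnc, set())
            assert not (mutated & active)

    def test_requires_tumor_generation_first(self, small_spec):
        truth = sim.build_truth(small_spec)
        with pytest.raises(ConsistencyError, match="activated_samples"):
            sim.generate_methylation_mutations_clinical(small_spec, truth, {})

    def test_determinism(self, small_spec, small_truth, small_cohorts):
        a = sim.generate_methylation_mutations_clinical(small_spec, small_truth, small_cohorts)
        b = sim.generate_methylation_mutations_clinical(small_spec, small_truth, small_cohorts)
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[2].equals(b[2])

    def test_clinical_schema(self, small_spec, small_truth, small_cohorts):
        _, _, clinical = sim.generate_methylation_mutations_clinical(
            small_spec, small_truth, small_cohorts
        )
        assert set(clinical["stage"]) <= {"I", "II", "III", "IV"}
        assert clinical["smg_ratio"].between(0, 1).all()
        assert len(clinical) == 2 * small_spec.n_tumor_samples_per_type
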