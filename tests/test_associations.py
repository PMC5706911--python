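import math

import numpy as np
import pandas as pd
import pytest

from ctlnc import associations as am
from ctlnc import simulate as sim
from ctlnc.config import CohortSpec
from ctlnc.exceptions import CtlncError


class TestOlsFit:
    def test_exact_proportional_fit(self):
        x = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        y = pd.Series([2.0, 4.0, 6.0, 8.0, 10.0])
        fit = am.ols_fit(y, x)
        assert fit.term("x").beta == pytest.approx(2.0, abs=1e-12)
        assert fit.term("intercept").beta == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_line(self):
        fit = am.ols_fit(pd.Series([1.0, 2.0, 3.0, 4.0]), pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]}))
        assert fit.term("intercept").beta == pytest.approx(1.0, abs=1e-12)
        assert fit.term("x").beta == pytest.approx(1.0, abs=1e-12)

    def test_seeded_slope_recovery(self):
        rng = np.random.default_rng(1)
        stage = rng.integers(1, 5, size=400).astype(float)
        y = stage * 1.0 + rng.normal(0, 2, size=400)
        fit = am.ols_fit(pd.Series(y), pd.DataFrame({"stage": stage}))
        t = fit.term("stage")
        assert abs(t.beta - 1.0) <= 0.3
        assert t.beta > 0 and t.p < 0.01

    def test_categorical_dummy_coding_reference_level(self):
        df = pd.DataFrame({"grp": ["b", "a", "b", "a", "c", "c"]})
        y = pd.Series([2.0, 1.0, 2.2, 0.8, 3.0, 3.1])
        fit = am.ols_fit(y, df)
        names = [t.name for t in fit.terms]
        assert "grp[b]" in names and "grp[c]" in names and "grp[a]" not in names

    def test_rank_deficiency_names_terms(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "x2": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(CtlncError, match="collinear"):
            am.ols_fit(pd.Series([1.0, 2.0, 3.0, 4.0]), df)

    def test_complete_case_dropping(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0, 5.0]})
        fit = am.ols_fit(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]), df)
        assert fit.n_used == 4


class TestStageAssociation:
    def _clinical(self, stages, n=None, cancer_types=None):
        n = n or len(stages)
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age": rng.integers(40, 80, size=n),
                "gender": rng.choice(["female", "male"], size=n),
                "stage": stages,
                "cancer_type": cancer_types or ["CA"] * n,
            }
        )

    def test_planted_positive_slope_recovered(self):
        hits = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 300
            stage_num = rng.integers(1, 5, size=n)
            counts = pd.Series(
                stage_num + rng.normal(0, 1.5, size=n), index=[f"s{i}" for i in range(n)]
            )
            clin = self._clinical([["I", "II", "III", "IV"][s - 1] for s in stage_num], n)
            fit = am.stage_association(counts, clin)
            t = fit.term("stage")
            if t.beta > 0 and t.p < 0.05:
                hits += 1
        assert hits / reps >= 0.9

    def test_shuffled_stage_null(self):
        rng = np.random.default_rng(42)
        n = 300
        pvals = []
        for _ in range(30):
            counts = pd.Series(rng.normal(5, 2, size=n), index=[f"s{i}" for i in range(n)])
            clin = self._clinical(rng.choice(["I", "II", "III", "IV"], size=n).tolist(), n)
            pvals.append(am.stage_association(counts, clin).term("stage").p)
        assert np.mean(np.array(pvals) < 0.05) <= 0.2
        assert np.median(pvals) > 0.15

    def test_single_stage_errors(self):
        counts = pd.Series([1.0, 2.0, 3.0], index=["s0", "s1", "s2"])
        clin = self._clinical(["II", "II", "II"])
        with pytest.raises(CtlncError, match="stage"):
            am.stage_association(counts, clin)

    def test_stage_string_forms(self):
        enc = am._encode_stage(pd.Series(["I", "Stage IV", "3", "weird", None]))
        assert list(enc[:3]) == [1.0, 4.0, 3.0]
        assert np.isnan(enc[3]) and np.isnan(enc[4])


class TestSmgRatio:
    def test_planted_negative_coupling(self):
        hits = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 250
            counts = pd.Series(
                rng.poisson(4, size=n).astype(float), index=[f"s{i}" for i in range(n)]
            )
            ratio = np.clip(0.6 - 0.05 * counts + rng.normal(0, 0.1, size=n), 0, 1)
            fit = am.smg_ratio_association(pd.Series(ratio.values, index=counts.index), counts)
            t = fit.term("smg_ratio")
            if t.beta < 0 and t.p < 0.05:
                hits += 1
        assert hits / reps >= 0.9

    def test_null_sign_symmetric(self):
        rng = np.random.default_rng(7)
        signs = []
        for _ in range(60):
            n = 100
            counts = pd.Series(rng.normal(5, 1, size=n), index=[f"s{i}" for i in range(n)])
            ratio = pd.Series(rng.uniform(0, 1, size=n), index=counts.index)
            signs.append(am.smg_ratio_association(ratio, counts).term("smg_ratio").beta > 0)
        assert 0.3 <= np.mean(signs) <= 0.7

    def test_constant_ratio_errors(self):
        counts = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        ratio = pd.Series([0.5] * 4, index=list("abcd"))
        with pytest.raises(CtlncError):
            am.smg_ratio_association(ratio, counts)

    def test_out_of_range_ratio_errors(self):
        counts = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(CtlncError, match="smg_ratio"):
            am.smg_ratio_association(pd.Series([0.5, 1.2], index=["a", "b"]), counts)

    def test_both_orientations_share_sign(self):
        rng = np.random.default_rng(3)
        n = 200
        counts = pd.Series(rng.poisson(4, size=n).astype(float), index=[f"s{i}" for i in range(n)])
        ratio = pd.Series(
            np.clip(0.6 - 0.05 * counts + rng.normal(0, 0.1, size=n), 0, 1).values,
            index=counts.index,
        )
        f1 = am.smg_ratio_association(ratio, counts, orientation="count_on_ratio")
        f2 = am.smg_ratio_association(ratio, counts, orientation="ratio_on_count")
        assert f1.term("smg_ratio").beta < 0
        assert f2.term("count").beta < 0


class TestMethylation:
    def test_planted_negative_coupling_robust_to_global(self):
        rng = np.random.default_rng(11)
        n = 300
        idx = [f"s{i}" for i in range(n)]
        beta = pd.Series(rng.uniform(0.2, 0.9, size=n), index=idx)
        counts = pd.Series(20 - 15 * beta + rng.normal(0, 1, size=n), index=idx)
        global_beta = pd.Series(rng.uniform(0.4, 0.6, size=n), index=idx)
        f1 = am.methylation_association(beta, counts)
        f2 = am.methylation_association(beta, counts, global_promoter_beta=global_beta)
        assert f1.term("mean_promoter_beta").beta < 0 and f1.term("mean_promoter_beta").p < 0.01
        assert f2.term("mean_promoter_beta").beta < 0 and f2.term("mean_promoter_beta").p < 0.01

    def test_constant_beta_errors(self):
        idx = list("abcd")
        beta = pd.Series([0.5] * 4, index=idx)
        counts = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        with pytest.raises(CtlncError):
            am.methylation_association(beta, counts)

    def test_out_of_range_beta_errors(self):
        idx = ["a", "b"]
        with pytest.raises(CtlncError, match="beta"):
            am.methylation_association(
                pd.Series([0.5, 1.5], index=idx), pd.Series([1.0, 2.0], index=idx)
            )


class TestOncogeneGroups:
    def test_small_exact_example(self):
        counts = pd.Series([0.0, 0.0, 0.0, 5.0, 6.0, 7.0], index=list("abcdef"))
        groups = pd.Series(
            ["positive"] * 3 + ["negative"] * 3, index=list("abcdef")
        )
        _, p = am.oncogene_group_test(counts, groups)
        assert p == pytest.approx(0.1)

    def test_identical_distributions(self):
        counts = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        groups = pd.Series(["positive"] * 3 + ["negative"] * 3, index=list("abcdef"))
        _, p = am.oncogene_group_test(counts, groups)
        assert p > 0.9

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 30
        for _ in range(reps):
            pos = rng.poisson(3, size=100)
            neg = rng.poisson(6, size=100)
            counts = pd.Series(
                np.concatenate([pos, neg]).astype(float),
                index=[f"s{i}" for i in range(200)],
            )
            groups = pd.Series(
                ["positive"] * 100 + ["negative"] * 100, index=counts.index
            )
            _, p = am.oncogene_group_test(counts, groups)
            if p < 0.01:
                hits += 1
        assert hits / reps >= 0.95

    def test_empty_group_errors(self):
        counts = pd.Series([1.0, 2.0], index=["a", "b"])
        groups = pd.Series(["positive", "positive"], index=["a", "b"])
        with pytest.raises(CtlncError):
            am.oncogene_group_test(counts, groups)


class TestExclusivityScreen:
    def test_cross_table_direction(self):
        samples = [f"s{i}" for i in range(20)]
        act = pd.DataFrame({"lnc": [True] * 10 + [False] * 10}, index=samples)
        mut = pd.DataFrame({"drv": [False] * 10 + [True] * 10}, index=samples)
        (res,) = am.mutual_exclusivity_screen(act, mut)
        assert res.direction == "exclusive"
        assert res.p_raw == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_zero_margin_pairs_skipped(self):
        samples = [f"s{i}" for i in range(10)]
        act = pd.DataFrame({"lnc": [False] * 10}, index=samples)
        mut = pd.DataFrame({"drv": [True] * 5 + [False] * 5}, index=samples)
        assert am.mutual_exclusivity_screen(act, mut) == []

    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        n = 200
        reps = 300
        rejected = 0
        for _ in range(reps):
            act = pd.DataFrame(
                {"lnc": rng.random(n) < 0.3}, index=[f"s{i}" for i in range(n)]
            )
            mut = pd.DataFrame(
                {"drv": rng.random(n) < 0.3}, index=act.index
            )
            res = am.mutual_exclusivity_screen(act, mut)
            if res and res[0].p_raw < 0.05:
                rejected += 1
        assert 0.02 <= rejected / reps <= 0.08

    def test_planted_pairs_recovered_from_simulator(self):
        spec = CohortSpec(
            n_genes=120, n_lncrna=40, n_tumor_samples_per_type=150,
            cancer_types=("CA", "CB"), activation_frequency=0.3,
            n_modules=1, module_size=6, n_drivers=3, seed=13,
        )
        truth = sim.build_truth(spec)
        cohorts = sim.generate_tumor_cohorts(spec, truth)
        _, maf, _ = sim.generate_methylation_mutations_clinical(spec, truth, cohorts)
        samples = [s for ct in spec.cancer_types for s in cohorts[ct].sample_ids]
        lncs = sorted({lnc for _, lnc in truth.exclusive_pairs})
        act = pd.DataFrame(
            {lnc: [s in truth.activated_samples[lnc] for s in samples] for lnc in lncs},
            index=samples,
        )
        drivers = sorted({d for d, _ in truth.exclusive_pairs})
        mut = am.mutation_matrix(maf, samples, drivers)
        results = am.mutual_exclusivity_screen(act, mut, include_any_driver=False)
        sig = {(r.driver, r.lncrna_id) for r in am.significant_exclusive(results)}
        recovered = sum(1 for pair in truth.exclusive_pairs if pair in sig)
        assert recovered / len(truth.exclusive_pairs) >= 0.9
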