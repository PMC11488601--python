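"""Family contributions, subgroup reruns and FDR-corrected clinical correlations."""

import numpy as np
import pandas as pd
import pytest

from gutbrainmap import (
    FoldAssignment,
    MicrobiomeBrainModel,
    PermutationScheme,
    clinical_correlations,
    family_contributions,
    subgroup_rerun,
)
from gutbrainmap.association import GcvRidge
from gutbrainmap.posthoc import SubgroupTooSmallError, significance_class
from gutbrainmap.preprocess import MaskError

from _oracles import bh_stepup


class TestFamilyContributions:
    def test_planted_families_dominate_with_correct_sign(self, planted_results, planted_cohort):
        rep = planted_results.clusters()
        fc = planted_results.family_contributions(rep)
        peak1 = fc[fc.peak_id == 1].set_index("family")
        top3 = peak1["coefficient"].abs().sort_values(ascending=False).index[:3]
        planted = {"Family002", "Family003"}
        assert planted <= set(top3)
        for fam in planted:
            assert peak1.loc[fam, "coefficient"] > 0
            assert peak1.loc[fam, "p"] <= 0.05

    def test_single_family_design_coefficient_matches_full_model(self, planted_cohort):
        model = MicrobiomeBrainModel.from_cohort(planted_cohort)
        design = model.design
        peak = tuple(np.array(planted_cohort.truth.clusters[0]["center"]))
        scheme = PermutationScheme.create(len(design.subjects) - 4, 10, seed=1)
        fc = family_contributions([peak], design, model.images, scheme, mask=model.mask.mask)
        y = model.images.data[(slice(None),) + peak]
        sol = GcvRidge(design.X).fit(y)
        got = fc.set_index("family")["coefficient"]
        for j, fam in enumerate(design.families):
            assert got[fam] == pytest.approx(sol.coef[j] / design.record.sds[j], rel=1e-10)

    def test_peak_outside_mask_rejected(self, planted_cohort):
        model = MicrobiomeBrainModel.from_cohort(planted_cohort)
        scheme = PermutationScheme.create(len(model.design.subjects) - 4, 10, seed=1)
        with pytest.raises(MaskError):
            family_contributions(
                [(0, 0, 0)], model.design, model.images, scheme, mask=model.mask.mask
            )

    def test_null_family_contribution_p_is_uniform(self):
        # at a voxel driven by family 0 only, family 3's |coefficient| should be
        # unremarkable within its permutation null: p ~ Uniform over replicates
        from gutbrainmap.preprocess import DesignMatrix, ImageStack, StandardizationRecord

        r = np.random.default_rng(42)
        n, B = 40, 60
        X = r.normal(size=(n, 8))
        X = (X - X.mean(0)) / X.std(0)
        subjects = [f"s{i}" for i in range(n)]
        families = [f"fam{j}" for j in range(5)]
        design = DesignMatrix(
            subjects,
            families,
            X,
            StandardizationRecord(families + ["sex", "age", "bmi"], np.zeros(8), np.ones(8)),
        )
        ps = []
        for rep in range(50):
            rr = np.random.default_rng(1000 + rep)
            y = X[:, 0] + rr.normal(size=n)
            stack = ImageStack(subjects, y[:, None, None, None], np.eye(4))
            scheme = PermutationScheme.create(n, B, seed=rep)
            fc = family_contributions([(0, 0, 0)], design, stack, scheme)
            ps.append(float(fc.set_index("family").loc["fam3", "p"]))
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_significance_tiers(self):
        assert significance_class(0.5) == ""
        assert significance_class(0.005) == "<0.01"
        assert significance_class(5e-4) == "<0.001"
        assert significance_class(1e-7) == "<1e-06"


class TestSubgroups:
    def test_full_cohort_subgroup_gives_exact_zero_deltas(self, planted_results):
        rep = planted_results.clusters()
        n = len(planted_results.design.subjects)
        res = planted_results.subgroup_rerun(np.ones(n, dtype=bool), label="all", report=rep)
        assert np.all(res.table["delta"] == 0.0)
        assert res.mean_delta == 0.0

    def test_small_subgroup_refused(self, planted_results):
        n = len(planted_results.design.subjects)
        flags = np.zeros(n, dtype=bool)
        flags[:5] = True
        with pytest.raises(SubgroupTooSmallError, match="5 subjects"):
            planted_results.subgroup_rerun(flags, label="tiny")

    def test_random_half_deltas_are_moderate(self):
        # in a homogeneous cohort, subgroup RSS ratios track the full-sample
        # ratios: the mean delta over random-half subgroups stays small
        from gutbrainmap import SyntheticScenario, generate_cohort

        cohort = generate_cohort(
            SyntheticScenario.global_null(
                n_subjects=80, n_families=10, image_shape=(10, 10, 10), seed=7
            )
        )
        model = MicrobiomeBrainModel.from_cohort(cohort)
        folds = FoldAssignment.create(len(model.design.subjects), K=10, seed=2)
        peaks = [tuple(ijk) for ijk in np.argwhere(model.mask.mask)[[0, 50, 100]]]
        n = len(model.design.subjects)
        r = np.random.default_rng(9)
        deltas = []
        for rep in range(30):
            flags = np.zeros(n, dtype=bool)
            flags[r.choice(n, n // 2, replace=False)] = True
            res = subgroup_rerun(
                flags, peaks, model.design, model.images, folds, label=f"half{rep}"
            )
            deltas.append(res.mean_delta)
        assert abs(np.mean(deltas)) < 0.15


class TestClinicalCorrelations:
    def test_perfect_correlations(self):
        x = np.linspace(0, 1, 20)
        pv = pd.DataFrame({"peak_1": x})
        clin = pd.DataFrame({"up": x, "down": -x})
        out = clinical_correlations(pv, clin)
        out = out.set_index("variable")
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "r"] == pytest.approx(-1.0)

    def test_pairwise_complete_and_q_dominates_p(self, rng):
        n = 40
        pv = pd.DataFrame({"peak_1": rng.normal(size=n), "peak_2": rng.normal(size=n)})
        clin = pd.DataFrame(
            {
                "phq9": rng.normal(size=n),
                "tmt_a": rng.normal(size=n),
            }
        )
        clin.iloc[:5, 0] = np.nan
        out = clinical_correlations(pv, clin)
        assert set(out.loc[out.variable == "phq9", "n_used"]) == {n - 5}
        assert np.all(out["q"] >= out["p"] - 1e-12)

    def test_bh_family_matches_stepup_by_hand(self, rng):
        n = 60
        pv = pd.DataFrame({f"peak_{i}": rng.normal(size=n) for i in range(2)})
        signal = pv["peak_0"] * 0.8 + rng.normal(size=n) * 0.4
        clin = pd.DataFrame(
            {
                "phq9": signal,
                "tmt_a": rng.normal(size=n),
                "stroop": rng.normal(size=n),
            }
        )
        out = clinical_correlations(pv, clin)
        expected = bh_stepup(out["p"].to_numpy(), alpha=0.05)
        assert set(np.flatnonzero(out["fdr_significant"].to_numpy())) == expected

    def test_constant_vector_excluded_with_warning(self, rng):
        pv = pd.DataFrame({"peak_1": rng.normal(size=10)})
        clin = pd.DataFrame({"flat": np.ones(10), "ok": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="constant"):
            out = clinical_correlations(pv, clin)
        assert list(out["variable"]) == ["ok"]

    def test_bh_stepup_hand_derived_example(self):
        # p = (0.005, 0.03, 0.04, 0.8), m=4: the largest k with p(k) <= 0.05k/4
        # is k=1, so only the 0.005 test is declared FDR-significant
        assert bh_stepup([0.005, 0.03, 0.04, 0.8]) == {0}

    def test_bh_monotone_in_pvalues(self):
        # lowering any p never removes a previously significant test
        base = bh_stepup([0.005, 0.03, 0.04, 0.8])
        lowered = bh_stepup([0.005, 0.001, 0.04, 0.8])
        assert base <= lowered
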