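"""TFCE, permutation p-values, FWE correction and cluster reporting."""

import numpy as np
import pytest

from gutbrainmap import (
    MicrobiomeBrainModel,
    PermutationScheme,
    TfceParams,
    freedman_lane_surrogate,
    fwe_correct,
    permutation_pvalues,
    report_clusters,
    tfce,
)
from gutbrainmap.inference import (
    ClusterThresholds,
    InferenceResult,
    SurrogateFactory,
    ratio_excess,
)

from _oracles import brute_force_tfce


class TestTfce:
    def test_all_zero_map(self):
        assert np.all(tfce(np.zeros((4, 4, 4))) == 0)

    def test_single_voxel_discrete_sum(self):
        # one isolated voxel at s=1, E=0.5, H=2, dh=0.01:
        # sum_{i=1..100} 1^0.5 * (0.01 i)^2 * 0.01 = 0.338350
        s = np.zeros((5, 5, 5))
        s[2, 2, 2] = 1.0
        out = tfce(s, params=TfceParams(E=0.5, H=2.0, dh=0.01))
        assert out[2, 2, 2] == pytest.approx(0.338350, abs=1e-6)

    def test_two_adjacent_voxels_scale_by_sqrt_extent(self):
        s = np.zeros((5, 5, 5))
        s[2, 2, 2] = s[2, 2, 3] = 1.0
        out = tfce(s, params=TfceParams(E=0.5, H=2.0, dh=0.01))
        assert out[2, 2, 2] == pytest.approx(np.sqrt(2) * 0.338350, abs=1e-5)
        assert out[2, 2, 3] == out[2, 2, 2]

    @pytest.mark.parametrize("E", [0.5, 1.0])
    @pytest.mark.parametrize("H", [1.0, 2.0])
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_on_random_maps(self, E, H, connectivity):
        r = np.random.default_rng(int(E * 10 + H + connectivity))
        s = np.maximum(r.normal(size=(4, 4, 4)), 0)
        params = TfceParams(E=E, H=H, connectivity=connectivity)
        assert np.array_equal(tfce(s, params=params), brute_force_tfce(s, E, H, connectivity=connectivity))

    def test_monotone_in_the_statistic(self):
        r = np.random.default_rng(3)
        s = np.maximum(r.normal(size=(5, 5, 5)), 0)
        base = tfce(s, params=TfceParams(dh=0.05))
        s2 = s.copy()
        s2[2, 2, 2] += 0.5
        higher = tfce(s2, params=TfceParams(dh=0.05))
        assert np.all(higher >= base - 1e-12)

    def test_ratio_excess_anchors_at_zero(self):
        ratio = np.array([[[0.5, 1.0, 1.5, np.nan]]])
        assert np.array_equal(ratio_excess(ratio), np.array([[[0.0, 0.0, 0.5, 0.0]]]))


class TestPermutationPvalues:
    def test_direct_count(self):
        # null (incl. identity) {5,4,3,2,1}, observed 3 -> 3 of 5 are >= 3
        p = permutation_pvalues(np.array([3.0]), np.array([[5.0], [4.0], [3.0], [2.0], [1.0]]))
        assert p[0] == pytest.approx(3 / 5)

    def test_minimum_attainable_p_at_250(self):
        null = np.concatenate([[10.0], np.linspace(0, 1, 249)])[:, None]
        p = permutation_pvalues(np.array([10.0]), null)
        assert p[0] == pytest.approx(1 / 250) == pytest.approx(0.004)

    def test_worst_case_is_one(self):
        p = permutation_pvalues(np.array([0.0]), np.abs(np.random.default_rng(0).normal(size=(50, 1))))
        assert p[0] == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalues(np.array([1.0]), np.empty((0, 1)))


class TestFwe:
    def test_toy_max_null(self):
        obs = np.array([[[2.5]]])
        p = fwe_correct(obs, np.array([10.0, 3.0, 2.0, 1.0]))
        assert p[0, 0, 0] == pytest.approx(0.5)  # 2 of 4 maxes reach 2.5

    def test_zero_statistic_has_p_one(self):
        p = fwe_correct(np.zeros((2, 2, 2)), np.array([5.0, 1.0, 0.5]))
        assert np.all(p == 1.0)


class TestSurrogates:
    def _zy(self, rng, n=30):
        Z = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = Z @ np.array([1.0, 0.5, -0.2]) + rng.normal(size=n)
        return Z, y

    def test_identity_permutation_returns_y_exactly(self, rng):
        Z, y = self._zy(rng)
        out = freedman_lane_surrogate(y, Z, np.arange(30))
        assert np.array_equal(out, y)

    def test_intercept_only_reduces_to_plain_permutation(self, rng):
        y = rng.normal(size=20)
        perm = rng.permutation(20)
        out = freedman_lane_surrogate(y, np.ones((20, 1)), perm)
        assert np.allclose(out, y[perm], atol=1e-12)

    def test_mean_preserved_under_any_permutation(self, rng):
        Z, y = self._zy(rng)
        for _ in range(100):
            perm = rng.permutation(30)
            out = freedman_lane_surrogate(y, Z, perm)
            assert out.mean() == pytest.approx(y.mean(), abs=1e-10)

    def test_orthogonal_scheme_preserves_energy_and_covariate_fit(self, rng):
        Z, y = self._zy(rng)
        fac = SurrogateFactory(Z, y, method="orthogonal")
        scheme = PermutationScheme.create(fac.n_units, 20, seed=9)
        h = Z @ np.linalg.pinv(Z)
        for b in [0, 1, 5, 19]:
            yb = fac.surrogate(b, scheme)
            # covariate-aligned component identical for every permutation
            assert np.allclose(h @ yb, h @ y, atol=1e-10)
            # residual energy identical for every permutation
            assert np.sum((yb - h @ yb) ** 2) == pytest.approx(
                np.sum((y - h @ y) ** 2), rel=1e-10
            )
        assert np.array_equal(fac.surrogate(0, scheme), y)

    def test_exhaustive_enumeration_for_tiny_n(self):
        scheme = PermutationScheme.create(5, 250, seed=0)
        assert scheme.exhaustive
        assert scheme.B == 120  # 5!
        assert np.array_equal(scheme.permutation(0), np.arange(5))

    def test_permutations_pure_function_of_seed_and_index(self):
        a = PermutationScheme.create(50, 10, seed=4)
        b = PermutationScheme.create(50, 200, seed=4)
        for i in range(10):
            assert np.array_equal(a.permutation(i), b.permutation(i))


class TestEndToEnd:
    def test_fwe_p_dominates_uncorrected_p(self, planted_results):
        inf = planted_results.inference
        m = inf.mask
        assert np.all(inf.p_fwe[m] >= inf.p_uncorrected[m] - 1e-12)
        assert np.all((inf.p_uncorrected[m] >= inf.min_p()) & (inf.p_uncorrected[m] <= 1))

    def test_staged_extension_equals_single_run(self, small_null_cohort):
        model = MicrobiomeBrainModel.from_cohort(small_null_cohort)
        r_single = model.fit(n_perms=25, seed=77)
        r_staged = model.fit(n_perms=10, seed=77).extend_permutations(15)
        a, b = r_single.inference, r_staged.inference
        assert np.array_equal(a.null_ratios, b.null_ratios)
        assert np.array_equal(a.null_max_tfce, b.null_max_tfce)
        assert np.array_equal(a.p_uncorrected[a.mask], b.p_uncorrected[b.mask])
        assert np.array_equal(a.p_fwe[a.mask], b.p_fwe[b.mask])

    def test_planted_cluster_recovered(self, planted_results, planted_cohort):
        rep = planted_results.clusters()
        assert len(rep) >= 1
        truth = planted_cohort.truth.signal_mask()
        found = False
        for ijk in rep.peak_voxels():
            if truth[ijk]:
                found = True
        assert found


class TestClusterReport:
    def _result_with_pmaps(self, surviving, ratio, connectivity=26):
        shape = surviving.shape
        mask = np.ones(shape, dtype=bool)
        from gutbrainmap.association import StatMap

        p = np.where(surviving, 0.01, 1.0)
        smap = StatMap(
            ratio=ratio, rss_covariates=ratio, rss_full=np.ones(shape), mask=mask,
            affine=np.eye(4),
        )
        return InferenceResult(
            stat_map=smap,
            tfce_map=np.zeros(shape),
            p_uncorrected=np.ones(shape),
            p_fwe=p,
            null_max_tfce=np.ones(10),
            null_ratios=np.ones((10, mask.sum())),
            n_perms=10,
            tfce_params=TfceParams(connectivity=connectivity),
            seed=0,
        )

    def test_connectivity_splits_diagonal_clusters(self):
        surviving = np.zeros((4, 4, 4), dtype=bool)
        surviving[1, 1, 1] = surviving[2, 2, 2] = True  # diagonal neighbors
        ratio = np.where(surviving, 2.0, 0.5)
        res26 = self._result_with_pmaps(surviving, ratio, connectivity=26)
        rep26 = report_clusters(res26)
        fwe26 = rep26.table[rep26.table.p_type == "fwe"]
        assert len(fwe26) == 1 and fwe26.iloc[0]["cs"] == 2

        res6 = self._result_with_pmaps(surviving, ratio, connectivity=6)
        rep6 = report_clusters(res6)
        fwe6 = rep6.table[rep6.table.p_type == "fwe"]
        assert len(fwe6) == 2 and set(fwe6["cs"]) == {1}

    def test_empty_report_when_nothing_survives(self):
        surviving = np.zeros((3, 3, 3), dtype=bool)
        res = self._result_with_pmaps(surviving, np.full((3, 3, 3), 0.5))
        rep = report_clusters(res)
        assert len(rep) == 0

    def test_uncorrected_regime_requires_ratio_floor(self):
        surviving = np.zeros((3, 3, 3), dtype=bool)
        res = self._result_with_pmaps(surviving, np.full((3, 3, 3), 2.0))
        # uncorrected p small everywhere but ratio below the floor at one voxel
        res.p_uncorrected[:] = 1.0
        res.p_fwe[:] = 1.0
        res.p_uncorrected[1, 1, 1] = 0.001
        res.stat_map.ratio[1, 1, 1] = 1.2  # below 1.33 -> not reported
        rep = report_clusters(res)
        assert len(rep) == 0
        res.stat_map.ratio[1, 1, 1] = 1.5  # above the floor -> reported
        rep = report_clusters(res)
        assert len(rep) == 1
        assert rep.table.iloc[0]["p_type"] == "uncorrected"

    def test_world_coordinates_use_affine(self):
        surviving = np.zeros((3, 3, 3), dtype=bool)
        surviving[1, 2, 0] = True
        ratio = np.where(surviving, 2.0, 0.5)
        res = self._result_with_pmaps(surviving, ratio)
        res.stat_map.affine = np.array(
            [[2.0, 0, 0, -2.0], [0, 2.0, 0, -2.0], [0, 0, 2.0, -2.0], [0, 0, 0, 1.0]]
        )
        rep = report_clusters(res)
        row = rep.table[rep.table.p_type == "fwe"].iloc[0]
        assert (row["x"], row["y"], row["z"]) == (0.0, 2.0, -2.0)
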