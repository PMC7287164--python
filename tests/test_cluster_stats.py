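"""Cluster-based permutation inference: t-maps, cluster formation, the
sign-flip null, and oracle equivalences."""

import numpy as np
import pytest
from scipy import stats

from assrpac.cluster_stats import (
    ClusterTestParams,
    cluster_permutation_test,
    form_clusters,
    paired_t_map,
)


class TestPairedTMap:
    def test_identical_conditions_give_zero(self, rng):
        grids = [rng.standard_normal((4, 5)) for _ in range(5)]
        assert np.allclose(paired_t_map(grids, grids), 0.0)

    def test_matches_textbook_hand_computation(self):
        diffs = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
        stim = [np.full((2, 2), d) for d in diffs]
        base = [np.zeros((2, 2)) for _ in diffs]
        t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        t_map = paired_t_map(stim, base)
        assert np.allclose(t_map, t_expected)
        # cross-check against scipy's paired t
        t_scipy = stats.ttest_rel(diffs, np.zeros(5)).statistic
        assert t_map[0, 0] == pytest.approx(t_scipy)

    def test_constant_nonzero_difference_errors(self):
        stim = [np.full((2, 2), 1.0) for _ in range(4)]
        base = [np.zeros((2, 2)) for _ in range(4)]
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_map(stim, base)

    def test_mismatched_grids_error(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            paired_t_map(
                [rng.standard_normal((3, 3))] * 4, [rng.standard_normal((3, 4))] * 4
            )

    def test_too_few_subjects_error(self, rng):
        g = [rng.standard_normal((2, 2)) for _ in range(2)]
        with pytest.raises(ValueError, match="3 subjects"):
            paired_t_map(g, [np.zeros((2, 2))] * 2)


class TestFormClusters:
    def test_all_zero_grid_has_no_clusters(self):
        assert form_clusters(np.zeros((5, 5)), df=9) == []

    def test_plus_shape_single_cluster(self):
        t_crit = stats.t.ppf(0.99, 9)
        grid = np.zeros((3, 3))
        plus = [(0, 1), (1, 0), (1, 1), (1, 2), (2, 1)]
        for ij in plus:
            grid[ij] = t_crit + 1.0
        clusters = form_clusters(grid, df=9)
        assert len(clusters) == 1
        assert sorted(clusters[0].cells) == sorted(plus)
        assert clusters[0].mass == pytest.approx(5 * (t_crit + 1.0))

    def test_diagonal_cells_are_separate_under_4_adjacency(self):
        t_crit = stats.t.ppf(0.99, 9)
        grid = np.zeros((3, 3))
        grid[0, 0] = grid[1, 1] = t_crit + 0.5
        assert len(form_clusters(grid, df=9)) == 2
        # but joined under 8-adjacency
        p8 = ClusterTestParams(adjacency=8)
        assert len(form_clusters(grid, df=9, params=p8)) == 1

    def test_partition_property(self, rng):
        grid = rng.standard_normal((6, 10)) * 3
        df = 11
        clusters = form_clusters(grid, df=df)
        t_crit = stats.t.ppf(0.99, df)
        supra = {tuple(ij) for ij in np.argwhere(grid >= t_crit)}
        members = [ij for c in clusters for ij in c.cells]
        assert len(members) == len(set(members))
        assert set(members) == supra


class TestPermutationNull:
    def _cohort(self, rng, n=10, effect=0.0):
        stim = [rng.standard_normal((4, 6)) for _ in range(n)]
        base = [rng.standard_normal((4, 6)) for _ in range(n)]
        for s in stim:
            s[1:3, 2:4] += effect
        return stim, base

    def test_strong_effect_p_formula_and_floor(self, rng):
        stim, base = self._cohort(rng, n=15, effect=8.0)
        params = ClusterTestParams(n_permutations=500, seed=0)
        res = cluster_permutation_test(stim, base, params)
        top = res.clusters[0]
        # +1 convention: p never below 1/(n_perm + 1), exact when the
        # observed mass beats every permuted maximum
        expected = (1 + np.sum(res.null_max_mass >= top.mass)) / 501.0
        assert top.p_corrected == pytest.approx(expected)
        assert top.p_corrected >= 1.0 / 501.0
        assert top.p_corrected <= 5.0 / 501.0
        assert top.significant
        if np.all(res.null_max_mass < top.mass):
            assert top.p_corrected == pytest.approx(1.0 / 501.0)

    def test_deterministic_null_from_seed(self, rng):
        stim, base = self._cohort(rng, effect=1.0)
        params = ClusterTestParams(n_permutations=300, seed=7)
        r1 = cluster_permutation_test(stim, base, params)
        r2 = cluster_permutation_test(stim, base, params)
        assert np.array_equal(r1.null_max_mass, r2.null_max_mass)

    def test_p_monotone_in_mass(self, rng):
        stim, base = self._cohort(rng, effect=1.5)
        res = cluster_permutation_test(
            stim, base, ClusterTestParams(n_permutations=500, seed=1)
        )
        if len(res.clusters) >= 2:
            masses = [c.mass for c in res.clusters]
            ps = [c.p_corrected for c in res.clusters]
            assert all(
                p1 <= p2 for (m1, p1), (m2, p2) in zip(
                    sorted(zip(masses, ps), reverse=True),
                    sorted(zip(masses, ps), reverse=True)[1:],
                )
            )

    def test_exact_enumeration_matches_monte_carlo(self, rng):
        """With <= 8 subjects, Monte-Carlo p agrees with the exhaustive 2^n
        sign-flip enumeration within Monte-Carlo error."""
        for k in range(10):
            local = np.random.default_rng(100 + k)
            stim = [local.standard_normal((3, 5)) for _ in range(7)]
            base = [local.standard_normal((3, 5)) for _ in range(7)]
            for s in stim:
                s[0:2, 1:3] += 1.5
            mc = cluster_permutation_test(
                stim, base, ClusterTestParams(n_permutations=2000, seed=k)
            )
            ex = cluster_permutation_test(
                stim, base, ClusterTestParams(n_permutations=2000), exact=True
            )
            if not mc.clusters:
                assert not ex.clusters
                continue
            p_mc, p_ex = mc.clusters[0].p_corrected, ex.clusters[0].p_corrected
            se = np.sqrt(p_ex * (1 - p_ex) / 2000) + 1e-3
            assert abs(p_mc - p_ex) < 4 * se + 2e-3

    def test_matches_mne_cluster_masses(self, rng):
        """Independent oracle: identical t-map and cluster masses from MNE's
        one-sample cluster permutation test on the paired differences."""
        mne_stats = pytest.importorskip("mne.stats")
        d = rng.standard_normal((10, 6, 8))
        d[:, 2:4, 3:6] += 1.2
        res = cluster_permutation_test(
            list(d), [np.zeros((6, 8))] * 10, ClusterTestParams(n_permutations=500, seed=0)
        )
        t_crit = stats.t.ppf(0.99, 9)
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            d, threshold=t_crit, tail=1, n_permutations=250, out_type="mask", verbose=False
        )
        assert np.allclose(t_obs, res.t_map)
        mne_masses = sorted(float(t_obs[m].sum()) for m in clusters)
        ours = sorted(c.mass for c in res.clusters)
        assert np.allclose(mne_masses, ours)

    def test_few_subjects_warns(self, rng):
        stim = [rng.standard_normal((2, 2)) for _ in range(4)]
        base = [rng.standard_normal((2, 2)) for _ in range(4)]
        with pytest.warns(RuntimeWarning, match="sign patterns"):
            cluster_permutation_test(
                stim, base, ClusterTestParams(n_permutations=200, seed=0)
            )


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClusterTestParams(cluster_forming_p=1.5)
        with pytest.raises(ValueError):
            ClusterTestParams(n_permutations=10)
        with pytest.raises(ValueError):
            ClusterTestParams(adjacency=6)
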