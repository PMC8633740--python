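"""Dual regression, TFCE, and sign-flip permutation inference tests."""

import numpy as np
import pytest
from scipy import ndimage, stats

from conftest import consensus_from_truth
from pharmconn import dualreg, synthdata
from pharmconn.core import BoldSession, zscore_masked
from pharmconn.dualreg import (CollinearMapsError, TfceParams,
                               bonferroni_gate, build_adjacency,
                               dual_regression, paired_differences,
                               permutation_inference, tfce)
from pharmconn.metagica import ConsensusNetwork, ConsensusNetworkSet


def tfce_oracle(stat, E=0.5, H=2.0, dh=None, n_steps=100, connectivity=26):
    """Brute-force reference: rebuild clusters independently per threshold."""
    stat = np.asarray(stat, float)
    out = np.zeros_like(stat)
    mx = stat.max()
    if mx <= 0:
        return out
    if dh is None:
        dh = mx / n_steps
    if stat.ndim == 3:
        structure = ndimage.generate_binary_structure(
            3, {6: 1, 18: 2, 26: 3}[connectivity])
    else:
        structure = np.ones([3] * stat.ndim, dtype=bool)
    for k in range(1, int(np.floor(mx / dh + 1e-12)) + 1):
        h = k * dh
        sup = stat >= h
        lab, n = ndimage.label(sup, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(lab.ravel())
        out[sup] += sizes[lab[sup]] ** E * h ** H * dh
    return out


class TestTfce:
    def test_two_step_example(self):
        # 1D map [0, 2, 0] with dh=1: centre = 1^0.5*1^2 + 1^0.5*2^2 = 5
        out = tfce(np.array([0.0, 2.0, 0.0]),
                   TfceParams(E=0.5, H=2.0, dh=1.0))
        np.testing.assert_allclose(out, [0.0, 5.0, 0.0])

    def test_all_zero_map(self):
        out = tfce(np.zeros((5, 5, 5)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_bruteforce_oracle_on_random_maps(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            stat = np.maximum(rng.normal(size=(9, 8, 7)), 0)
            got = tfce(stat, TfceParams())
            want = tfce_oracle(stat)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_respects_connectivity(self):
        stat = np.zeros((3, 3, 3))
        stat[0, 0, 0] = stat[1, 1, 1] = 1.0    # diagonal neighbours
        p26 = tfce(stat, TfceParams(dh=1.0, connectivity=26))
        p6 = tfce(stat, TfceParams(dh=1.0, connectivity=6))
        assert p26[0, 0, 0] == pytest.approx(np.sqrt(2.0))
        assert p6[0, 0, 0] == pytest.approx(1.0)

    def test_negative_values_ignored(self):
        out = tfce(np.array([-3.0, 2.0, -1.0]), TfceParams(dh=1.0))
        assert out[0] == 0 and out[2] == 0 and out[1] > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TfceParams(E=0)
        with pytest.raises(ValueError):
            TfceParams(connectivity=10)


class TestDualRegression:
    def test_noiseless_round_trip(self, small_truth, noiseless_session):
        cons = consensus_from_truth(small_truth)
        dr = dual_regression(noiseless_session, cons)
        mask = small_truth.mask
        for k in range(4):
            r_tc = np.corrcoef(dr.timecourses[k],
                               noiseless_session._true_timecourses[k])[0, 1]
            r_map = np.corrcoef(dr.maps[k][mask],
                                small_truth.maps[k][mask])[0, 1]
            assert abs(r_tc) == pytest.approx(1.0, abs=1e-6)
            assert abs(r_map) == pytest.approx(1.0, abs=1e-6)

    def test_single_allones_map_gives_global_mean_course(self, small_truth):
        mask = small_truth.mask
        rng = np.random.default_rng(3)
        data = np.zeros(mask.shape + (50,))
        data[mask] = rng.normal(size=(int(mask.sum()), 50))
        sess = BoldSession(data=data, mask=mask, tr_seconds=3.0)
        ones = np.zeros(mask.shape)
        ones[mask] = 1.0
        net = ConsensusNetwork(map=ones, support=10, members=[], label="g")
        cons = ConsensusNetworkSet(networks=[net], mask=mask, threshold=0.7)
        # a constant map is collinear with the intercept...
        with pytest.raises(CollinearMapsError):
            dual_regression(sess, cons)
        # ...without the intercept its course is the global mean signal
        dr = dual_regression(sess, cons, intercept=False)
        gm = sess.masked_timeseries().mean(axis=1)
        r = np.corrcoef(dr.timecourses[0], gm)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_absent_network_has_null_stage2_map(self, small_truth):
        # session built from 3 networks; regressing a 4th (absent) map
        spec = synthdata.StudySpec(n_subjects=1, n_networks=3,
                                   grid_shape=(12, 12, 10), noise_sd=0.05,
                                   spike_prob=0.0, subject_sd=0.0)
        sub_truth = synthdata.GroundTruthNetworks(
            maps=small_truth.maps[:3], mask=small_truth.mask,
            grid_shape=small_truth.grid_shape,
            network_labels=small_truth.network_labels[:3],
            tissue_masks=small_truth.tissue_masks)
        sess = synthdata.simulate_session(sub_truth, spec,
                                          spec.edge_corr_placebo, None, 21)
        cons = consensus_from_truth(small_truth)   # includes absent net 3
        dr = dual_regression(sess, cons)
        present_scale = np.abs(dr.maps[:3][:, small_truth.mask]).max()
        absent_scale = np.abs(dr.maps[3][small_truth.mask]).max()
        assert absent_scale < 0.15 * present_scale

    def test_collinear_maps_rejected(self, small_truth):
        mask = small_truth.mask
        m = zscore_masked(small_truth.maps[0], mask)
        nets = [ConsensusNetwork(map=m, support=10, members=[], label="a"),
                ConsensusNetwork(map=m * 1.0, support=10, members=[],
                                 label="b")]
        cons = ConsensusNetworkSet(networks=nets, mask=mask, threshold=0.7)
        rng = np.random.default_rng(1)
        data = np.zeros(mask.shape + (30,))
        data[mask] = rng.normal(size=(int(mask.sum()), 30))
        sess = BoldSession(data=data, mask=mask, tr_seconds=3.0)
        with pytest.raises(CollinearMapsError):
            dual_regression(sess, cons)

    def test_stage1_courses_unit_variance(self, small_study):
        cons = consensus_from_truth(small_study.truth)
        dr = dual_regression(small_study.sessions[("s00", "drug")], cons)
        np.testing.assert_allclose(dr.timecourses.var(axis=1, ddof=1), 1.0,
                                   atol=1e-6)


class TestPairedDifferences:
    def _maps(self, vals, sid):
        m = np.zeros((1, 4, 4, 2))
        m[0] = vals
        return dualreg.SubjectNetworkMaps(
            timecourses=np.zeros((1, 10)), maps=m, subject_id=sid,
            condition="x")

    def test_identical_conditions_give_zero_t(self):
        rng = np.random.default_rng(0)
        mask = np.ones((4, 4, 2), bool)
        drug, pl = [], []
        for i in range(5):
            v = rng.normal(size=(4, 4, 2))
            drug.append(self._maps(v, f"s{i}"))
            pl.append(self._maps(v, f"s{i}"))
        diffs, t = paired_differences(drug, pl, 0, mask)
        np.testing.assert_array_equal(t, 0.0)

    def test_constant_effect_t_converges_to_analytic(self):
        # constant difference c with noise sd s at one voxel: the module's
        # t statistic concentrates around c*sqrt(N)/s over repetitions
        rng = np.random.default_rng(1)
        N, c, s = 12, 0.8, 1.0
        mask = np.ones((1, 1, 1), bool)
        ts = []
        for rep in range(300):
            diffs = c + s * rng.standard_normal((N, 1, 1, 1))
            maps_d = [dualreg.SubjectNetworkMaps(
                np.zeros((1, 5)), diffs[i][None], f"s{i}", "drug")
                for i in range(N)]
            maps_p = [dualreg.SubjectNetworkMaps(
                np.zeros((1, 5)), np.zeros((1, 1, 1, 1)), f"s{i}", "placebo")
                for i in range(N)]
            _, t = paired_differences(maps_d, maps_p, 0, mask)
            ts.append(t[0, 0, 0])
        assert np.mean(ts) == pytest.approx(c * np.sqrt(N) / s, rel=0.15)

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(2)
        mask = np.ones((4, 4, 2), bool)
        drug = [self._maps(rng.normal(size=(4, 4, 2)), f"s{i}")
                for i in range(22)]
        pl = [self._maps(rng.normal(size=(4, 4, 2)), f"s{i}")
              for i in range(22)]
        diffs, _ = paired_differences(drug, pl, 0, mask)
        assert diffs.shape[0] == 22       # df = 21 in downstream t tests

    def test_mismatched_subjects_rejected(self):
        rng = np.random.default_rng(3)
        mask = np.ones((4, 4, 2), bool)
        drug = [self._maps(rng.normal(size=(4, 4, 2)), "a")] * 3
        pl = [self._maps(rng.normal(size=(4, 4, 2)), "b")] * 3
        with pytest.raises(ValueError):
            paired_differences(drug, pl, 0, mask)


class TestPermutationInference:
    def test_extreme_observation_gets_minimal_p(self):
        rng = np.random.default_rng(4)
        mask = np.ones((5, 5, 4), bool)
        # overwhelming effect: the observed TFCE is the all-time maximum
        # (N=20 so no random sign pattern can duplicate the identity)
        diffs = 5.0 + 0.1 * rng.standard_normal((20, 5, 5, 4))
        res = permutation_inference(diffs, mask, n_perm=200, seed=0)
        assert res.p_fwe_pos.min() == pytest.approx(1 / 201)

    def test_full_enumeration_close_to_monte_carlo(self):
        rng = np.random.default_rng(5)
        mask = np.ones((4, 4, 3), bool)
        diffs = rng.standard_normal((7, 4, 4, 3)) + 0.6
        exact = permutation_inference(diffs, mask, n_perm=200, seed=1)
        approx = permutation_inference(diffs, mask, n_perm=5000, seed=1)
        # 2^7=128 <= 200 -> exact enumeration; MC agrees within 2/sqrt(n)
        v = np.unravel_index(exact.tfce_pos.argmax(), mask.shape)
        assert abs(exact.p_fwe_pos[v] - approx.p_fwe_pos[v]) < 2 / np.sqrt(5000) + 0.01

    def test_null_pvalues_uniform(self):
        # the familywise p at the maximum voxel is Uniform{k/(n+1)} under
        # the null; Kolmogorov-Smirnov across independent simulations
        rng = np.random.default_rng(6)
        mask = np.ones((4, 4, 3), bool)
        pvals = []
        for rep in range(80):
            diffs = rng.standard_normal((8, 4, 4, 3))
            res = permutation_inference(diffs, mask, n_perm=200,
                                        seed=1000 + rep)
            pvals.append(res.p_fwe_pos.min())
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        mask = np.ones((4, 4, 3), bool)
        diffs = rng.standard_normal((10, 4, 4, 3))
        a = permutation_inference(diffs, mask, n_perm=300, seed=9)
        b = permutation_inference(diffs, mask, n_perm=300, seed=9)
        np.testing.assert_array_equal(a.p_fwe_pos, b.p_fwe_pos)

    def test_minimum_permutations_enforced(self):
        mask = np.ones((3, 3, 2), bool)
        with pytest.raises(ValueError):
            permutation_inference(np.zeros((5, 3, 3, 2)), mask, n_perm=50)


class TestBonferroniGate:
    def _result(self, p_pos, p_neg):
        shape = p_pos.shape
        return dualreg.VoxelContrastResult(
            network_id=0, diff_maps=np.zeros((3,) + shape),
            t_map=np.zeros(shape), tfce_pos=np.zeros(shape),
            tfce_neg=np.zeros(shape), p_fwe_pos=p_pos, p_fwe_neg=p_neg)

    def test_reference_arithmetic_23_networks(self):
        # 23 networks x 2 directions: per-test alpha 0.05/46 ~ 0.00109
        shape = (3, 3, 2)
        results = [self._result(np.ones(shape), np.ones(shape))
                   for _ in range(23)]
        results[0].p_fwe_pos[0, 0, 0] = 0.001
        bonferroni_gate(results, 0.05)
        assert len(results[0].significant_clusters) == 1
        results[0].p_fwe_pos[0, 0, 0] = 0.0012   # above 0.05/46
        bonferroni_gate(results, 0.05)
        assert len(results[0].significant_clusters) == 0

    def test_single_test_uses_familywise_alpha(self):
        shape = (3, 3, 2)
        res = self._result(np.ones(shape), np.ones(shape))
        res.p_fwe_pos[1, 1, 1] = 0.04
        bonferroni_gate([res], 0.05, n_tests=1)
        assert len(res.significant_clusters) == 1

    def test_all_ones_pmap_has_no_clusters(self):
        shape = (3, 3, 2)
        res = self._result(np.ones(shape), np.ones(shape))
        bonferroni_gate([res], 0.05)
        assert res.significant_clusters == []

    def test_passing_voxels_grouped_into_connected_clusters(self):
        shape = (7, 3, 2)
        res = self._result(np.ones(shape), np.ones(shape))
        res.p_fwe_pos[0:2, 0, 0] = 1e-5
        res.p_fwe_pos[5:7, 0, 0] = 1e-5   # separated group
        bonferroni_gate([res], 0.05, n_tests=1)
        assert len(res.significant_clusters) == 2
        assert sorted(c["size"] for c in res.significant_clusters) == [2, 2]
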