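"""Consensus group-ICA tests: model order, runs, matching, averaging."""

import numpy as np
import pytest

from pharmconn import denoise, metagica, synthdata
from pharmconn.core import zscore_masked
from pharmconn.metagica import (ComponentMatchGraph, IcaRun,
                                cross_correlate_runs, estimate_model_order,
                                extract_consensus, fit_group_ica,
                                flag_artifact_components, relaxed_consensus,
                                run_meta_gica)


class TestModelOrder:
    def test_planted_rank_five_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5)) @ rng.normal(size=(5, 200))
        X += 0.01 * rng.normal(size=(60, 200))
        assert estimate_model_order(X, 15) == 5

    def test_planted_rank_eight_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8)) @ rng.normal(size=(8, 500))
        X += 0.05 * rng.normal(size=(60, 500))
        assert estimate_model_order(X, 20) == 8

    def test_pure_noise_gives_low_order(self):
        low = 0
        for s in range(100):
            X = np.random.default_rng(1000 + s).normal(size=(30, 300))
            if estimate_model_order(X, 10) <= 1:
                low += 1
        assert low >= 95

    def test_degenerate_spectrum_returns_zero_with_warning(self):
        X = np.zeros((10, 50))
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_model_order(X, 5) == 0

    def test_matches_reference_evidence_formula(self):
        # independent oracle: sklearn's internal Minka assessment
        from sklearn.decomposition._pca import _assess_dimension
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8)) @ rng.normal(size=(8, 300))
        X += 0.1 * rng.normal(size=(40, 300))
        Xc = X - X.mean(axis=1, keepdims=True)
        spectrum = np.linalg.eigvalsh(Xc @ Xc.T / 300)[::-1]
        for k in range(1, 12):
            mine = metagica._laplace_log_evidence(spectrum, 300, k)
            ref = _assess_dimension(spectrum, k, 300)
            assert mine == pytest.approx(ref, abs=1e-8)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            estimate_model_order(np.zeros((5, 50)), 10)


@pytest.fixture(scope="module")
def hisnr_study():
    spec = synthdata.StudySpec(
        n_subjects=8, n_networks=4, grid_shape=(12, 12, 10),
        noise_sd=0.12, subject_sd=0.05, spike_prob=0.0, seed=77)
    bundle = synthdata.simulate_paired_study(spec)
    den = [denoise.denoise_session(s, fwhm_mm=0)[0]
           for s in bundle.condition_sessions("placebo")]
    return bundle, den


class TestFitGroupIca:
    def test_planted_networks_recovered(self, hisnr_study):
        bundle, den = hisnr_study
        run = fit_group_ica(den, order=4, subject_order_seed=1, ica_seed=2)
        mask = bundle.truth.mask
        comp = run.components[:, mask]
        for t in bundle.truth.masked_maps():
            rs = np.abs([np.corrcoef(t, c)[0, 1] for c in comp])
            assert rs.max() > 0.9

    def test_seeded_determinism(self, hisnr_study):
        _, den = hisnr_study
        a = fit_group_ica(den, 4, subject_order_seed=1, ica_seed=2)
        b = fit_group_ica(den, 4, subject_order_seed=1, ica_seed=2)
        np.testing.assert_array_equal(a.components, b.components)

    def test_subject_order_invariance_at_high_snr(self, hisnr_study):
        bundle, den = hisnr_study
        a = fit_group_ica(den, 4, subject_order_seed=1, ica_seed=2)
        b = fit_group_ica(den, 4, subject_order_seed=99, ica_seed=2)
        mask = bundle.truth.mask
        # greedy matching: every component of a matches one of b at |r|>0.9
        used = set()
        for ca in a.components[:, mask]:
            rs = [abs(np.corrcoef(ca, cb)[0, 1]) if j not in used else -1
                  for j, cb in enumerate(b.components[:, mask])]
            j = int(np.argmax(rs))
            assert rs[j] > 0.9
            used.add(j)

    def test_component_maps_are_zscored_with_nonneg_skew(self, hisnr_study):
        bundle, den = hisnr_study
        from scipy.stats import skew
        run = fit_group_ica(den, 4, subject_order_seed=1, ica_seed=2)
        mask = bundle.truth.mask
        for c in run.components:
            vals = c[mask]
            assert vals.std() == pytest.approx(1.0, abs=1e-9)
            assert skew(vals) >= 0

    def test_needs_two_sessions(self, hisnr_study):
        _, den = hisnr_study
        with pytest.raises(ValueError):
            fit_group_ica(den[:1], 4, 0, 0)


class TestRunMetaGica:
    def test_orders_near_planted_k(self, hisnr_study):
        bundle, den = hisnr_study
        runs = run_meta_gica(den, n_runs=4, master_seed=5, max_order=10)
        assert len(runs) == 4
        for run in runs:
            assert abs(run.model_order - 4) <= 2

    def test_minimum_two_runs(self, hisnr_study):
        _, den = hisnr_study
        with pytest.raises(ValueError):
            run_meta_gica(den, n_runs=1, master_seed=0)
        runs = run_meta_gica(den, n_runs=2, master_seed=0, order=4)
        assert len(runs) == 2

    def test_master_seed_determinism(self, hisnr_study):
        _, den = hisnr_study
        a = run_meta_gica(den, n_runs=2, master_seed=3, order=4)
        b = run_meta_gica(den, n_runs=2, master_seed=3, order=4)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.components, rb.components)


def _runs_from_maps(truth, present, noise=0.2, seed=0):
    """Build IcaRun objects holding noisy copies of selected truth maps.

    ``present[r]`` lists the truth indices included in run r.
    """
    rng = np.random.default_rng(seed)
    mask = truth.mask
    runs = []
    for r, idxs in enumerate(present):
        comps = np.zeros((len(idxs),) + mask.shape)
        for i, k in enumerate(idxs):
            m = truth.maps[k][mask]
            noisy = m + noise * m.std() * rng.standard_normal(m.shape)
            vol = np.zeros(mask.shape)
            vol[mask] = noisy
            comps[i] = zscore_masked(vol, mask)
        runs.append(IcaRun(run_id=r, components=comps,
                           subject_order=[], model_order=len(idxs), seed=r))
    return runs


class TestCrossCorrelateRuns:
    def test_copied_component_matches_at_one(self, small_truth):
        runs = _runs_from_maps(small_truth, [[0], [0]], noise=0.0)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        assert graph.weight((0, 0), (1, 0)) == pytest.approx(1.0)

    def test_distinct_blobs_do_not_match(self, small_truth):
        runs = _runs_from_maps(small_truth, [[0], [1]], noise=0.0)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        assert graph.edges == {}

    def test_no_edges_within_a_run(self, small_truth):
        runs = _runs_from_maps(small_truth, [[0, 1, 2], [0, 1]], noise=0.1)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        for e in graph.edges:
            a, b = tuple(e)
            assert a[0] != b[0]

    def test_default_threshold_is_point_seven(self, small_truth):
        runs = _runs_from_maps(small_truth, [[0], [0]])
        graph = cross_correlate_runs(runs, small_truth.mask)
        assert graph.threshold == 0.7


class TestConsensus:
    def test_full_support_network_recovered(self, small_truth):
        present = [[0, 1, 2, 3]] * 10
        runs = _runs_from_maps(small_truth, present, noise=0.15, seed=4)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        cons = extract_consensus(graph, n_runs=10, runs=runs,
                                 mask=small_truth.mask)
        assert cons.n_networks == 4
        assert all(n.support == 10 for n in cons.networks)

    def test_partial_support_excluded_at_full_requirement(self, small_truth):
        present = [[0, 1]] * 6 + [[0]] * 4      # truth 1 in only 6 runs
        runs = _runs_from_maps(small_truth, present, noise=0.1, seed=5)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        cons = extract_consensus(graph, n_runs=10, runs=runs,
                                 mask=small_truth.mask)
        assert cons.n_networks == 1

    def test_members_come_from_distinct_runs(self, small_truth):
        present = [[0, 1]] * 10
        runs = _runs_from_maps(small_truth, present, noise=0.15, seed=6)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        cons = extract_consensus(graph, n_runs=10, runs=runs,
                                 mask=small_truth.mask)
        for net in cons.networks:
            run_ids = [m[0] for m in net.members]
            assert len(run_ids) == len(set(run_ids))

    def test_average_recorrelates_with_members(self, small_truth):
        present = [[0, 1, 2, 3]] * 10
        runs = _runs_from_maps(small_truth, present, noise=0.2, seed=7)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        cons = extract_consensus(graph, n_runs=10, runs=runs,
                                 mask=small_truth.mask)
        for net in cons.networks:
            assert min(net.member_correlations) > 0.7

    def test_support_monotone_in_nested_run_sets(self, small_truth):
        present5 = [[0, 1]] * 5
        runs10 = _runs_from_maps(small_truth, present5 * 2, noise=0.1, seed=8)
        runs5 = runs10[:5]
        g5 = cross_correlate_runs(runs5, small_truth.mask, 0.7)
        g10 = cross_correlate_runs(runs10, small_truth.mask, 0.7)
        c5 = extract_consensus(g5, n_runs=5, min_support=5, runs=runs5,
                               mask=small_truth.mask)
        c10 = extract_consensus(g10, n_runs=10, min_support=5, runs=runs10,
                                mask=small_truth.mask)
        for n5 in c5.networks:
            best = max(abs(np.corrcoef(n5.map[small_truth.mask],
                                       n10.map[small_truth.mask])[0, 1])
                       for n10 in c10.networks)
            matching = [n10 for n10 in c10.networks
                        if abs(np.corrcoef(n5.map[small_truth.mask],
                                           n10.map[small_truth.mask])[0, 1])
                        > 0.9]
            assert matching and max(m.support for m in matching) >= n5.support


class TestRelaxedConsensus:
    def test_weak_network_needs_relaxed_pass(self, small_truth):
        present = [[0, 1, 2, 3]] * 4 + [[0, 1, 2]] * 6   # truth 3 in 4 runs
        runs = _runs_from_maps(small_truth, present, noise=0.15, seed=9)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        full = extract_consensus(graph, n_runs=10, runs=runs,
                                 mask=small_truth.mask)
        assert full.n_networks == 3
        used = {m for n in full.networks for m in n.members}
        extra = relaxed_consensus(graph, min_support=4, exclude=used,
                                  runs=runs, mask=small_truth.mask)
        assert extra.n_networks == 1
        assert extra.networks[0].support == 4
        r = abs(np.corrcoef(extra.networks[0].map[small_truth.mask],
                            small_truth.maps[3][small_truth.mask])[0, 1])
        assert r > 0.9

    def test_excluded_components_never_reused(self, small_truth):
        present = [[0]] * 10
        runs = _runs_from_maps(small_truth, present, noise=0.1, seed=10)
        graph = cross_correlate_runs(runs, small_truth.mask, 0.7)
        full = extract_consensus(graph, n_runs=10, runs=runs,
                                 mask=small_truth.mask)
        used = {m for n in full.networks for m in n.members}
        extra = relaxed_consensus(graph, min_support=4, exclude=used,
                                  runs=runs, mask=small_truth.mask)
        assert extra.n_networks == 0


class TestArtifactFlagging:
    def _consensus_with(self, mask, vol, label="net00"):
        net = metagica.ConsensusNetwork(map=vol, support=10, members=[],
                                        label=label)
        return metagica.ConsensusNetworkSet(networks=[net], mask=mask,
                                            threshold=0.7)

    def test_boundary_shell_blob_flagged(self, small_truth):
        from scipy import ndimage
        mask = small_truth.mask
        shell = mask & ~ndimage.binary_erosion(mask)
        vol = np.zeros(mask.shape)
        vol[shell] = 5.0
        vol[mask & ~shell] = np.random.default_rng(0).normal(
            0, 0.1, (mask & ~shell).sum())
        vol = zscore_masked(vol, mask)
        cons = self._consensus_with(mask, vol)
        flag_artifact_components(cons, mask)
        assert cons.networks[0].artifact_flag

    def test_interior_blob_not_flagged(self, small_truth):
        vol = zscore_masked(small_truth.maps[0], small_truth.mask)
        cons = self._consensus_with(small_truth.mask, vol)
        flag_artifact_components(cons, small_truth.mask)
        assert not cons.networks[0].artifact_flag

    def test_override_takes_precedence(self, small_truth):
        vol = zscore_masked(small_truth.maps[0], small_truth.mask)
        cons = self._consensus_with(small_truth.mask, vol)
        flag_artifact_components(cons, small_truth.mask,
                                 override={"net00": True})
        assert cons.networks[0].artifact_flag

    def test_high_frequency_course_flagged(self, small_truth):
        vol = zscore_masked(small_truth.maps[0], small_truth.mask)
        cons = self._consensus_with(small_truth.mask, vol)
        t = np.arange(124) * 3.0
        tc = np.sin(2 * np.pi * 0.15 * t)       # power above 0.1 Hz
        flag_artifact_components(cons, small_truth.mask,
                                 member_timecourses={"net00": tc},
                                 tr_seconds=3.0)
        assert cons.networks[0].artifact_flag
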