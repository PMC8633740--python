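import numpy as np
import pytest

from pharmconn import metagica, synthdata
from pharmconn.core import zscore_masked


def consensus_from_truth(truth) -> metagica.ConsensusNetworkSet:
    """Wrap ground-truth maps as a consensus set (for round-trip tests)."""
    nets = [
        metagica.ConsensusNetwork(
            map=zscore_masked(m, truth.mask), support=10, members=[],
            label=f"net{i:02d}")
        for i, m in enumerate(truth.maps)
    ]
    return metagica.ConsensusNetworkSet(networks=nets, mask=truth.mask,
                                        threshold=0.7)


@pytest.fixture(scope="session")
def small_truth():
    return synthdata.generate_network_maps(4, (12, 12, 10), seed=3)


@pytest.fixture(scope="session")
def small_study(small_truth):
    spec = synthdata.StudySpec(
        n_subjects=6, n_networks=4, grid_shape=(12, 12, 10),
        noise_sd=0.2, subject_sd=0.05, spike_prob=0.05, seed=11)
    return synthdata.simulate_paired_study(spec, small_truth)


@pytest.fixture(scope="session")
def noiseless_session(small_truth):
    spec = synthdata.StudySpec(
        n_subjects=1, n_networks=4, grid_shape=(12, 12, 10),
        noise_sd=0.0, subject_sd=0.0, spike_prob=0.0, seed=5)
    return synthdata.simulate_session(
        small_truth, spec, spec.edge_corr_placebo, None, seed=17)


def best_truth_matches(consensus, truth):
    """|r| of each consensus network against its best-matching truth map."""
    mask = truth.mask
    out = []
    for net in consensus.networks:
        rs = [abs(np.corrcoef(net.map[mask], t)[0, 1])
              for t in truth.masked_maps()]
        out.append((int(np.argmax(rs)), float(max(rs))))
    return out
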