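"""Consensus resting-state network identification by repeated group ICA.

Group ICA is sensitive to the order in which subjects' scans are
concatenated, so the procedure repeats it ``n_runs`` times with randomized
scan input order, matches components across runs by absolute spatial
correlation, and averages any set of mutually correlated components (one per
run, all pairwise |r| above the threshold) into a consensus network.  A
relaxed pass with a lower support requirement recovers networks that only a
minority of runs express (e.g. a weak subcortical network present in 4 of 10
runs).  Model order per run comes from the Laplace approximation to the
Bayesian evidence of probabilistic PCA over the eigenvalue spectrum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import BoldSession, spawn_seeds, zscore_masked

logger = logging.getLogger(__name__)

__all__ = [
    "IcaRun",
    "ComponentMatchGraph",
    "ConsensusNetwork",
    "ConsensusNetworkSet",
    "estimate_model_order",
    "fit_group_ica",
    "run_meta_gica",
    "cross_correlate_runs",
    "extract_consensus",
    "relaxed_consensus",
    "flag_artifact_components",
]

MATCH_THRESHOLD = 0.7
N_RUNS = 10
RELAXED_SUPPORT = 4
SESSION_RANK_FACTOR = 1.5


class IcaConvergenceError(RuntimeError):
    def __init__(self, run_id: int, msg: str = ""):
        super().__init__(f"group ICA run {run_id} failed to converge {msg}")
        self.run_id = run_id


@dataclass
class IcaRun:
    """One group-ICA decomposition: M z-scaled spatial component maps."""

    run_id: int
    components: np.ndarray            # (M, X, Y, Z), z-scaled within mask
    subject_order: list[int]          # permutation of session indices
    model_order: int
    seed: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class ComponentMatchGraph:
    """Cross-run component matches: |spatial r| > threshold, between runs only."""

    nodes: list[tuple[int, int]]                       # (run_id, component_id)
    edges: dict[frozenset, float]                      # pair -> |r|
    threshold: float

    def neighbors(self, node: tuple[int, int]) -> set[tuple[int, int]]:
        out = set()
        for e in self.edges:
            if node in e:
                (other,) = set(e) - {node}
                out.add(other)
        return out

    def weight(self, a, b) -> float:
        return self.edges.get(frozenset((a, b)), 0.0)

    def adjacency(self) -> dict[tuple[int, int], set[tuple[int, int]]]:
        adj: dict[tuple[int, int], set[tuple[int, int]]] = {n: set() for n in self.nodes}
        for e in self.edges:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        return adj


@dataclass
class ConsensusNetwork:
    map: np.ndarray                   # (X, Y, Z) z-scaled
    support: int
    members: list[tuple[int, int]]
    label: str
    artifact_flag: bool = False
    member_correlations: list[float] = field(default_factory=list)


@dataclass
class ConsensusNetworkSet:
    networks: list[ConsensusNetwork]
    mask: np.ndarray
    threshold: float

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def maps(self, include_artifacts: bool = True) -> np.ndarray:
        nets = [n for n in self.networks if include_artifacts or not n.artifact_flag]
        return np.stack([n.map for n in nets]) if nets else np.empty((0,) + self.mask.shape)

    def labels(self, include_artifacts: bool = True) -> list[str]:
        return [n.label for n in self.networks
                if include_artifacts or not n.artifact_flag]


# ---------------------------------------------------------------------------
# model-order estimation (Laplace evidence for probabilistic PCA)

def _laplace_log_evidence(spectrum: np.ndarray, n_samples: int, k: int) -> float:
    """Minka's Laplace approximation to log p(D | k) from the eigenspectrum.

    ``spectrum`` holds the descending eigenvalues of the d x d covariance of
    ``n_samples`` observations.
    """
    d = len(spectrum)
    n = n_samples
    if k >= d:
        return -np.inf
    if k > 0 and spectrum[k - 1] <= 0:
        return -np.inf
    v = spectrum[k:].sum() / (d - k)
    if v <= 0:
        return -np.inf
    pu = -k * np.log(2.0)
    for i in range(1, k + 1):
        pu += gammaln((d - i + 1) / 2.0) - np.log(np.pi) * (d - i + 1) / 2.0
    pl = -np.log(spectrum[:k]).sum() * n / 2.0
    pv = -np.log(v) * n * (d - k) / 2.0
    m = d * k - k * (k + 1) / 2.0
    pp = np.log(2.0 * np.pi) * (m + k) / 2.0
    spectrum_ = spectrum.copy()
    spectrum_[k:] = v
    pa = 0.0
    for i in range(k):
        for j in range(i + 1, d):
            pa += np.log((spectrum[i] - spectrum[j])
                         * (1.0 / spectrum_[j] - 1.0 / spectrum_[i])) + np.log(n)
    return pu + pl + pv + pp - pa / 2.0 - k * np.log(n) / 2.0


def estimate_model_order(stacked_data: np.ndarray, max_order: int) -> int:
    """Number of latent components maximizing the Laplace PPCA evidence.

    Rows of ``stacked_data`` are the observed variables and columns the
    samples (for a time x voxel matrix, voxels are samples of the
    time-dimensional vector).  Deterministic; a degenerate (flat) spectrum
    returns 0 with a warning.
    """
    X = np.asarray(stacked_data, float)
    d, n = X.shape
    if d < max_order + 2:
        raise ValueError("need at least max_order + 2 rows")
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = (Xc @ Xc.T) / n
    spectrum = np.linalg.eigvalsh(cov)[::-1]
    spectrum = np.clip(spectrum, 0.0, None)
    if spectrum[0] <= 0 or np.allclose(spectrum, spectrum[0], rtol=1e-10):
        warnings.warn("degenerate eigenvalue spectrum; returning order 0")
        return 0
    ks = range(0, min(max_order, d - 1) + 1)
    lls = [_laplace_log_evidence(spectrum, n, k) for k in ks]
    return int(np.argmax(lls))


# ---------------------------------------------------------------------------
# group ICA

def _masked(sessions: list[BoldSession]) -> tuple[np.ndarray, list[np.ndarray]]:
    mask = sessions[0].mask
    for s in sessions[1:]:
        if s.mask.shape != mask.shape or not np.array_equal(s.mask, mask):
            raise ValueError("all sessions must share grid and mask")
    mats = []
    for s in sessions:
        Y = s.masked_timeseries()
        mats.append(Y - Y.mean(axis=0, keepdims=True))
    return mask, mats


def _reduced_concat(mats: list[np.ndarray], order: list[int],
                    session_rank: int) -> np.ndarray:
    """Per-session temporal PCA to ``session_rank`` dims, then row-concat."""
    rows = []
    for idx in order:
        Y = mats[idx]                          # (T, V)
        r = min(session_rank, Y.shape[0] - 1)
        U, s, Vt = np.linalg.svd(Y, full_matrices=False)
        rows.append((s[:r, None] * Vt[:r]))    # principal time-modes x voxels
    return np.vstack(rows)


def _sources_agree(a: np.ndarray, b: np.ndarray, r_min: float = 0.95) -> bool:
    """Greedy one-to-one matching of (V, M) source sets by |correlation|."""
    M = a.shape[1]
    R = np.abs(np.corrcoef(a.T, b.T)[:M, M:])
    used: set[int] = set()
    for i in range(M):
        order_j = np.argsort(-R[i])
        j = next((j for j in order_j if j not in used), None)
        if j is None or R[i, j] < r_min:
            return False
        used.add(int(j))
    return True


def fit_group_ica(sessions: list[BoldSession], order: int,
                  subject_order_seed: int, ica_seed: int,
                  session_rank: int | None = None,
                  nonlinearity: str = "logcosh", max_restarts: int = 5,
                  max_iter: int = 300, tol: float = 1e-4,
                  run_id: int = 0) -> IcaRun:
    """One group ICA: session-wise PCA, seeded concatenation order, group
    PCA to ``order`` dimensions, fixed-point spatial ICA.

    Component maps are z-scaled within the mask and sign-oriented so the
    within-mask skewness is nonnegative.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    if order < 2:
        raise ValueError("model order must be >= 2")
    mask, mats = _masked(sessions)
    if session_rank is None:
        session_rank = int(np.ceil(SESSION_RANK_FACTOR * order))
    perm = list(np.random.default_rng(subject_order_seed)
                .permutation(len(sessions)))
    concat = _reduced_concat(mats, perm, session_rank)     # (n*r, V)
    if order > concat.shape[0]:
        raise ValueError("model order exceeds total reduced dimension")

    # a fit is accepted when the fixed-point iteration converges, or when
    # two independent restarts agree component-wise (|r| >= 0.95 after
    # greedy matching) -- FastICA's tolerance test often keeps churning on
    # pure-noise components even when the signal components are stable
    sources = None
    prev = None
    for attempt in range(max_restarts):
        ica = FastICA(n_components=order, fun=nonlinearity,
                      whiten="unit-variance", max_iter=max_iter, tol=tol,
                      random_state=ica_seed + attempt)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always", ConvergenceWarning)
            cand = ica.fit_transform(concat.T)             # (V, M) spatial maps
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in wlist)
        if converged:
            sources = cand
            break
        if prev is not None and _sources_agree(prev, cand):
            logger.info("run %d: accepting stable non-converged ICA fit",
                        run_id)
            sources = cand
            break
        prev = cand
    else:
        # tolerance-based convergence routinely fails on the noise
        # components even when the signal subspace is stable; run-to-run
        # component variability is exactly what the cross-run consensus
        # absorbs, so only a degenerate decomposition is fatal
        if (prev is None or not np.all(np.isfinite(prev))
                or np.any(prev.std(axis=0) == 0)):
            raise IcaConvergenceError(run_id, f"after {max_restarts} restarts")
        warnings.warn(f"group ICA run {run_id}: no converged or stable fit "
                      f"in {max_restarts} restarts; using the final fit")
        sources = prev

    comps = np.zeros((order,) + mask.shape)
    for m in range(order):
        vol = np.zeros(mask.shape)
        vol[mask] = sources[:, m]
        vol = zscore_masked(vol, mask)
        if skew(vol[mask]) < 0:
            vol = -vol
        comps[m] = vol
    return IcaRun(run_id=run_id, components=comps, subject_order=perm,
                  model_order=order, seed=ica_seed)


def run_meta_gica(sessions: list[BoldSession], n_runs: int = N_RUNS,
                  master_seed: int = 0, max_order: int = 20,
                  order: int | None = None) -> list[IcaRun]:
    """Repeat group ICA ``n_runs`` times with randomized scan input order.

    Per run, the model order is estimated on that run's reduced concatenated
    group matrix by Laplace evidence (unless ``order`` pins it).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    _, mats = _masked(sessions)
    seeds = spawn_seeds(master_seed, 2 * n_runs)
    runs = []
    for r in range(n_runs):
        order_seed, ica_seed = seeds[2 * r], seeds[2 * r + 1]
        if order is None:
            perm = list(np.random.default_rng(order_seed)
                        .permutation(len(sessions)))
            rank0 = int(np.ceil(SESSION_RANK_FACTOR * max_order))
            concat = _reduced_concat(mats, perm, rank0)
            M = max(estimate_model_order(concat, max_order), 2)
        else:
            M = order
        runs.append(fit_group_ica(sessions, M, order_seed, ica_seed,
                                  run_id=r))
    return runs


# ---------------------------------------------------------------------------
# cross-run matching and consensus

def cross_correlate_runs(runs: list[IcaRun], mask: np.ndarray,
                         threshold: float = MATCH_THRESHOLD) -> ComponentMatchGraph:
    """Match components across runs by absolute spatial correlation.

    An edge joins components of *different* runs whose within-mask Pearson
    correlation exceeds ``threshold`` in absolute value (ICA sign is
    arbitrary, so |r| is used).
    """
    for run in runs:
        if run.components.shape[1:] != mask.shape:
            raise ValueError(f"run {run.run_id}: grid mismatch with mask")
    nodes = [(run.run_id, c) for run in runs for c in range(run.n_components)]
    stack = np.vstack([run.components[:, mask] for run in runs])
    owner = [(run.run_id, c) for run in runs for c in range(run.n_components)]
    R = np.corrcoef(stack)
    edges: dict[frozenset, float] = {}
    for i in range(len(owner)):
        for j in range(i + 1, len(owner)):
            if owner[i][0] == owner[j][0]:
                continue
            r = abs(R[i, j])
            if r > threshold:
                edges[frozenset((owner[i], owner[j]))] = float(r)
    return ComponentMatchGraph(nodes=nodes, edges=edges, threshold=threshold)


def _grow_clique(seed_node, adj, graph, used):
    members = [seed_node]
    runs_used = {seed_node[0]}
    while True:
        cands = set.intersection(*(adj[m] for m in members)) if members else set()
        cands = {c for c in cands if c not in used and c[0] not in runs_used}
        if not cands:
            break
        best = max(cands, key=lambda c: (np.mean([graph.weight(c, m)
                                                  for m in members]), c))
        members.append(best)
        runs_used.add(best[0])
    return members


def _average_members(graph: ComponentMatchGraph, members, comp_lookup, mask):
    scores = [np.mean([graph.weight(m, o) for o in members if o != m])
              for m in members]
    ref = members[int(np.argmax(scores))]
    ref_map = comp_lookup[ref][mask]
    acc = np.zeros(mask.shape)
    for m in members:
        vol = comp_lookup[m]
        r = np.corrcoef(ref_map, vol[mask])[0, 1]
        acc += vol if r >= 0 else -vol
    avg = zscore_masked(acc / len(members), mask)
    member_rs = [float(abs(np.corrcoef(avg[mask], comp_lookup[m][mask])[0, 1]))
                 for m in members]
    return avg, member_rs


def extract_consensus(graph: ComponentMatchGraph, n_runs: int,
                      min_support: int | None = None,
                      runs: list[IcaRun] | None = None,
                      mask: np.ndarray | None = None,
                      exclude: set | None = None,
                      label_prefix: str = "net") -> ConsensusNetworkSet:
    """Average mutually matched component sets into consensus networks.

    Candidate sets are cliques with one component per run, grown greedily by
    mean internal |r|; each component is usable once.  Sets reaching
    ``min_support`` (default: every run) are sign-aligned to the member with
    the greatest mean match strength, averaged, and re-z-scaled.
    """
    if runs is None or mask is None:
        raise ValueError("runs and mask are required to average maps")
    if min_support is None:
        min_support = n_runs
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    comp_lookup = {(run.run_id, c): run.components[c]
                   for run in runs for c in range(run.n_components)}
    adj = graph.adjacency()
    used: set = set(exclude) if exclude else set()
    # seed candidates ordered by total incident match strength (deterministic)
    strength = {n: sum(graph.weight(n, o) for o in adj[n]) for n in graph.nodes}
    order = sorted(graph.nodes, key=lambda n: (-strength[n], n))
    networks: list[ConsensusNetwork] = []
    for seed_node in order:
        if seed_node in used or len(adj[seed_node]) + 1 < min_support:
            continue
        members = _grow_clique(seed_node, adj, graph, used)
        if len(members) < min_support:
            continue
        avg, member_rs = _average_members(graph, members, comp_lookup, mask)
        networks.append(ConsensusNetwork(
            map=avg, support=len(members), members=sorted(members),
            label=f"{label_prefix}{len(networks):02d}",
            member_correlations=member_rs))
        used.update(members)
    return ConsensusNetworkSet(networks=networks, mask=mask,
                               threshold=graph.threshold)


def relaxed_consensus(graph: ComponentMatchGraph, min_support: int = RELAXED_SUPPORT,
                      exclude: set | None = None,
                      runs: list[IcaRun] | None = None,
                      mask: np.ndarray | None = None,
                      label_prefix: str = "relaxed") -> ConsensusNetworkSet:
    """Second consensus pass at reduced support on the remaining components.

    Mirrors the first pass but accepts cliques of ``min_support`` runs
    (default 4); recovered networks carry their true support count.
    Components already consumed by the full-support pass are excluded.
    """
    return extract_consensus(graph, n_runs=min_support, min_support=min_support,
                             runs=runs, mask=mask, exclude=exclude,
                             label_prefix=label_prefix)


def _spatial_smoothness(vol: np.ndarray, mask: np.ndarray) -> float:
    """Mean lag-1 neighbour correlation of a map over in-mask voxel pairs.

    Plausible networks are spatially smooth; motion/spike components are
    close to white (smoothness near zero).
    """
    rs = []
    for axis in range(vol.ndim):
        a = [slice(None)] * vol.ndim
        b = [slice(None)] * vol.ndim
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        pair_mask = mask[tuple(a)] & mask[tuple(b)]
        if pair_mask.sum() < 10:
            continue
        x = vol[tuple(a)][pair_mask]
        y = vol[tuple(b)][pair_mask]
        if x.std() > 0 and y.std() > 0:
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


def flag_artifact_components(consensus: ConsensusNetworkSet,
                             mask: np.ndarray,
                             member_timecourses: dict[str, np.ndarray] | None = None,
                             tr_seconds: float | None = None,
                             boundary_fraction: float = 0.5,
                             min_smoothness: float = 0.2,
                             hf_cutoff_hz: float = 0.1,
                             override: dict[str, bool] | None = None) -> ConsensusNetworkSet:
    """Heuristic artifact flagging (a surrogate for visual inspection).

    A network is flagged when more than ``boundary_fraction`` of its
    top-decile weight voxels sit on the mask boundary shell, when its map
    is spatially near-white (mean neighbour correlation below
    ``min_smoothness``, the signature of a motion/spike component), or when
    the supplied member time course carries most of its power above
    ``hf_cutoff_hz``.  Entries in ``override`` (label -> bool) always win.
    """
    from scipy import ndimage
    shell = mask & ~ndimage.binary_erosion(mask)
    for net in consensus.networks:
        vals = np.abs(net.map[mask])
        thresh = np.quantile(vals, 0.9)
        top = np.abs(net.map) >= thresh
        top &= mask
        n_top = top.sum()
        flag = False
        if n_top > 0 and (top & shell).sum() / n_top > boundary_fraction:
            flag = True
        if _spatial_smoothness(net.map, mask) < min_smoothness:
            flag = True
        if member_timecourses is not None and tr_seconds is not None:
            tc = member_timecourses.get(net.label)
            if tc is not None:
                freqs = np.fft.rfftfreq(len(tc), d=tr_seconds)
                power = np.abs(np.fft.rfft(tc - np.mean(tc))) ** 2
                tot = power.sum()
                if tot > 0 and power[freqs > hf_cutoff_hz].sum() / tot > 0.5:
                    flag = True
        if override and net.label in override:
            flag = bool(override[net.label])
        net.artifact_flag = flag
    return consensus
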