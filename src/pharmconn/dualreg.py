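"""Within-network contrasts: dual regression, TFCE, sign-flip permutations.

Dual regression maps the consensus networks into each session: a spatial
multiple regression of all network maps on every volume yields per-network
time courses (stage 1, variance-normalised), and a temporal multiple
regression of those courses on every voxel series yields per-network spatial
fit maps (stage 2).  The drug-placebo contrast per network is a one-sample
test on the N subject difference maps, enhanced with threshold-free cluster
enhancement (TFCE) and assessed by sign-flip permutation of the differences
-- the exact exchangeability of a within-subject two-condition design --
with a Bonferroni gate across networks and both contrast directions.

TFCE(v) = sum over thresholds h = dh, 2dh, ... of e_h(v)^E * h^H * dh where
e_h(v) is the size of v's connected suprathreshold cluster at height h.
Defaults E = 0.5, H = 2, dh = max(stat)/100, 26-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import BoldSession
from .metagica import ConsensusNetworkSet

logger = logging.getLogger(__name__)

__all__ = [
    "TfceParams",
    "SubjectNetworkMaps",
    "VoxelContrastResult",
    "dual_regression",
    "paired_differences",
    "tfce",
    "permutation_inference",
    "bonferroni_gate",
    "build_adjacency",
]

N_PERM = 5000
FAMILYWISE_ALPHA = 0.05
TFCE_N_STEPS = 100


class CollinearMapsError(ValueError):
    pass


@dataclass
class TfceParams:
    """TFCE integration parameters (extent exponent, height exponent, step)."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None          # None: max(stat)/n_steps per map
    n_steps: int = TFCE_N_STEPS
    connectivity: int = 26

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class SubjectNetworkMaps:
    """Per-session dual-regression outputs."""

    timecourses: np.ndarray           # (K, T), unit variance each
    maps: np.ndarray                  # (K, X, Y, Z) stage-2 fit coefficients
    subject_id: str
    condition: str


@dataclass
class VoxelContrastResult:
    """Voxelwise paired contrast for one network, both directions."""

    network_id: int
    diff_maps: np.ndarray             # (N, X, Y, Z) drug - placebo
    t_map: np.ndarray
    tfce_pos: np.ndarray
    tfce_neg: np.ndarray
    p_fwe_pos: np.ndarray
    p_fwe_neg: np.ndarray
    significant_clusters: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dual regression

def dual_regression(session: BoldSession, consensus: ConsensusNetworkSet,
                    include_artifacts: bool = False,
                    cond_tol: float = 1e8,
                    normalize_stage1: bool = True,
                    intercept: bool = True) -> SubjectNetworkMaps:
    """Two-stage least squares against the consensus maps.

    Stage 1 regresses all K maps (plus intercept) on each volume to get K
    time courses; courses are normalised to unit variance.  Stage 2 regresses
    the K courses (plus intercept) on each voxel series to get K fit maps.
    ``intercept=False`` drops the constant column (needed when a map is
    itself spatially constant).
    """
    maps = consensus.maps(include_artifacts=include_artifacts)
    K = maps.shape[0]
    if K < 1:
        raise ValueError("consensus set is empty")
    mask = consensus.mask
    if mask.shape != session.mask.shape or not np.array_equal(mask, session.mask):
        raise ValueError("session and consensus must share grid and mask")
    M = maps[:, mask]                                    # (K, V)
    if intercept:
        X1 = np.column_stack([np.ones(M.shape[1]), M.T])  # (V, K+1)
    else:
        X1 = M.T
    cond = np.linalg.cond(X1)
    if cond > cond_tol:
        R = np.corrcoef(M) if K > 1 else np.ones((1, 1))
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.abs(R).argmax(), R.shape)
        raise CollinearMapsError(
            f"consensus maps nearly collinear (condition number {cond:.3g}; "
            f"worst pair {i}, {j} with |r|={abs(R[i, j]):.3f})")
    Y = session.masked_timeseries()                      # (T, V)
    beta1, *_ = np.linalg.lstsq(X1, Y.T, rcond=None)     # (K+1, T)
    tc = beta1[1:] if intercept else beta1               # (K, T)
    if normalize_stage1:
        sd = tc.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd.ravel() == 0)[0])
            raise ValueError(f"stage-1 time course {bad} is constant")
        tc = tc / sd
    X2 = np.column_stack([np.ones(session.n_volumes), tc.T])   # (T, K+1)
    beta2, *_ = np.linalg.lstsq(X2, Y, rcond=None)       # (K+1, V)
    out_maps = np.zeros((K,) + mask.shape)
    out_maps[:, mask] = beta2[1:]
    return SubjectNetworkMaps(timecourses=tc, maps=out_maps,
                              subject_id=session.subject_id,
                              condition=session.condition)


def paired_differences(maps_drug: list[SubjectNetworkMaps],
                       maps_placebo: list[SubjectNetworkMaps],
                       network: int,
                       mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subject difference fields (drug - placebo) and the one-sample t map.

    Subjects are matched by id; df = N - 1.  Zero-variance voxels get t = 0.
    """
    by_id = {m.subject_id: m for m in maps_placebo}
    pairs = [(d, by_id[d.subject_id]) for d in maps_drug
             if d.subject_id in by_id]
    if len(pairs) != len(maps_drug) or len(pairs) != len(maps_placebo):
        raise ValueError("drug and placebo lists must contain the same subjects")
    N = len(pairs)
    if N < 3:
        raise ValueError("need at least 3 subjects")
    diffs = np.stack([d.maps[network] - p.maps[network] for d, p in pairs])
    t_map = one_sample_t(diffs[:, mask])
    out = np.zeros(mask.shape)
    out[mask] = t_map
    return diffs, out


def one_sample_t(D: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t over axis 0; zero-variance entries get t=0."""
    N = D.shape[0]
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    if not nz.all():
        logger.info("one_sample_t: %d zero-variance entries set to t=0",
                    int((~nz).sum()))
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(N))
    return t


# ---------------------------------------------------------------------------
# TFCE

@njit(cache=False)
def _tfce_kernel(vals, indptr, indices, order, E, H, dh, n_steps):
    V = vals.shape[0]
    parent = np.full(V, -1, np.int64)
    size = np.zeros(V, np.int64)
    out = np.zeros(V, np.float64)
    active = np.zeros(V, np.uint8)
    act_list = np.empty(V, np.int64)
    n_act = 0
    ptr = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        while ptr < V and vals[order[ptr]] >= h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            active[v] = 1
            act_list[n_act] = v
            n_act += 1
            for jj in range(indptr[v], indptr[v + 1]):
                u = indices[jj]
                if active[u]:
                    rv = v
                    while parent[rv] != rv:
                        rv = parent[rv]
                    ru = u
                    while parent[ru] != ru:
                        ru = parent[ru]
                    if rv != ru:
                        if size[rv] < size[ru]:
                            rv, ru = ru, rv
                        parent[ru] = rv
                        size[rv] += size[ru]
        hH = h ** H
        for i in range(n_act):
            v = act_list[i]
            r = v
            while parent[r] != r:
                r = parent[r]
            w = v
            while parent[w] != r:
                nxt = parent[w]
                parent[w] = r
                w = nxt
            out[v] += size[r] ** E * hH * dh
    return out


def build_adjacency(mask: np.ndarray,
                    connectivity: int = 26) -> tuple[np.ndarray, np.ndarray]:
    """CSR neighbour lists over in-mask voxels for the TFCE kernel.

    Works for any dimensionality; for 3D, ``connectivity`` selects the 6-,
    18- or 26-neighbourhood.
    """
    mask = np.asarray(mask, bool)
    nd = mask.ndim
    idx = -np.ones(mask.shape, np.int64)
    coords = np.argwhere(mask)
    idx[mask] = np.arange(len(coords))
    offs = []
    for off in np.ndindex(*([3] * nd)):
        d = tuple(o - 1 for o in off)
        if all(o == 0 for o in d):
            continue
        manhattan = sum(abs(o) for o in d)
        if nd == 3 and connectivity == 6 and manhattan > 1:
            continue
        if nd == 3 and connectivity == 18 and manhattan > 2:
            continue
        offs.append(d)
    indptr = [0]
    indices: list[int] = []
    shape = mask.shape
    for c in coords:
        for d in offs:
            p = tuple(int(ci + di) for ci, di in zip(c, d))
            if all(0 <= pi < si for pi, si in zip(p, shape)) and idx[p] >= 0:
                indices.append(int(idx[p]))
        indptr.append(len(indices))
    return (np.asarray(indptr, np.int64), np.asarray(indices, np.int64))


def tfce(stat_map: np.ndarray, params: TfceParams | None = None,
         mask: np.ndarray | None = None,
         adjacency: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    Only strictly positive values contribute; apply to the negated map for
    the negative tail.  ``adjacency`` (from :func:`build_adjacency`) may be
    passed to amortise neighbour construction across many calls.
    """
    if params is None:
        params = TfceParams()
    stat_map = np.asarray(stat_map, float)
    if mask is None:
        mask = np.ones(stat_map.shape, bool)
    if adjacency is None:
        adjacency = build_adjacency(mask, params.connectivity)
    vals = stat_map[mask]
    out = np.zeros(stat_map.shape)
    mx = vals.max(initial=0.0)
    if mx <= 0:
        return out
    dh = params.dh if params.dh is not None else mx / params.n_steps
    n_steps = int(np.floor(mx / dh + 1e-12))
    if n_steps < 1:
        return out
    order = np.argsort(-vals, kind="stable")
    indptr, indices = adjacency
    out[mask] = _tfce_kernel(vals.astype(np.float64), indptr, indices,
                             order.astype(np.int64), params.E, params.H,
                             float(dh), n_steps)
    return out


# ---------------------------------------------------------------------------
# permutation inference

def _sign_matrix(N: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Sign-flip schedule: full enumeration when 2^N <= n_perm, else seeded
    random flips with the identity always included as permutation 0."""
    if N <= 30 and 2**N <= n_perm:
        bits = np.arange(2**N)[:, None] >> np.arange(N)[None, :]
        signs = 1.0 - 2.0 * (bits & 1)
        return signs, True
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm + 1, N))
    signs[0] = 1.0
    return signs, False


def permutation_inference(diff_maps: np.ndarray, mask: np.ndarray,
                          params: TfceParams | None = None,
                          n_perm: int = N_PERM, seed: int = 0,
                          network_id: int = 0) -> VoxelContrastResult:
    """Sign-flip TFCE inference on N subject difference maps.

    For every permutation the t map is recomputed, TFCE applied to both
    tails, and the image-wide maximum recorded; familywise-corrected
    p(v) = (1 + #{permutation max >= observed TFCE(v)}) / (1 + n_perm).
    With 2^N <= n_perm the full enumeration is used instead.
    """
    if params is None:
        params = TfceParams()
    diff_maps = np.asarray(diff_maps, float)
    N = diff_maps.shape[0]
    if N < 3:
        raise ValueError("need at least 3 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    D = diff_maps[:, mask] if diff_maps.ndim > 2 else diff_maps
    adjacency = build_adjacency(mask, params.connectivity)

    t_obs = one_sample_t(D)
    tmap3 = np.zeros(mask.shape)
    tmap3[mask] = t_obs
    tfce_pos = tfce(tmap3, params, mask, adjacency)
    tfce_neg = tfce(-tmap3, params, mask, adjacency)

    signs, exhaustive = _sign_matrix(N, n_perm, seed)
    n_total = signs.shape[0]
    ss = (D**2).sum(axis=0)
    max_pos = np.empty(n_total)
    max_neg = np.empty(n_total)
    buf = np.zeros(mask.shape)
    for p in range(n_total):
        mean = signs[p] @ D / N
        var = (ss - N * mean**2) / (N - 1)
        t = np.zeros_like(mean)
        nz = var > 0
        t[nz] = mean[nz] / np.sqrt(var[nz] / N)
        buf[mask] = t
        max_pos[p] = tfce(buf, params, mask, adjacency).max()
        buf[mask] = -t
        max_neg[p] = tfce(buf, params, mask, adjacency).max()

    def pvals(obs, null):
        out = np.ones(mask.shape)
        if exhaustive:
            cnt = (null[:, None] >= obs[mask][None, :] - 1e-12).sum(axis=0)
            out[mask] = cnt / n_total
        else:
            cnt = (null[1:, None] >= obs[mask][None, :] - 1e-12).sum(axis=0)
            out[mask] = (1 + cnt) / (1 + n_perm)
        return out

    p_pos = pvals(tfce_pos, max_pos)
    p_neg = pvals(tfce_neg, max_neg)
    return VoxelContrastResult(
        network_id=network_id,
        diff_maps=diff_maps if diff_maps.ndim > 2 else diff_maps,
        t_map=tmap3, tfce_pos=tfce_pos, tfce_neg=tfce_neg,
        p_fwe_pos=p_pos, p_fwe_neg=p_neg)


def _clusters_from_mask(passing: np.ndarray, connectivity: int) -> list[np.ndarray]:
    from scipy import ndimage
    if passing.ndim == 3:
        structure = ndimage.generate_binary_structure(
            3, {6: 1, 18: 2, 26: 3}[connectivity])
    else:
        structure = np.ones([3] * passing.ndim, dtype=bool)
    lab, n = ndimage.label(passing, structure=structure)
    return [np.argwhere(lab == i + 1) for i in range(n)]


def bonferroni_gate(results: list[VoxelContrastResult],
                    familywise_alpha: float = FAMILYWISE_ALPHA,
                    n_tests: int | None = None,
                    connectivity: int = 26) -> list[VoxelContrastResult]:
    """Bonferroni gate across networks and both contrast directions.

    Per-test alpha = familywise_alpha / n_tests with n_tests = (#networks
    tested) x 2 directions; voxels pass iff p_fwe < per-test alpha, and
    passing voxels are grouped into connected clusters per direction.
    """
    if not results:
        return results
    if n_tests is None:
        n_tests = len(results) * 2
    alpha = familywise_alpha / n_tests
    for res in results:
        res.significant_clusters = []
        for direction, pmap in (("drug>placebo", res.p_fwe_pos),
                                ("placebo>drug", res.p_fwe_neg)):
            passing = pmap < alpha
            for voxels in _clusters_from_mask(passing, connectivity):
                peak_p = float(pmap[tuple(voxels.T)].min())
                res.significant_clusters.append({
                    "network": res.network_id, "direction": direction,
                    "voxels": voxels, "size": len(voxels),
                    "peak_p": peak_p})
    return results
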