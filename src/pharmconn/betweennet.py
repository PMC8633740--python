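"""Between-network connectivity: Fisher-z edges and network-level inference.

Each session's K network time courses (stage-1 dual regression against the
consensus maps) yield a K x K matrix of Fisher-transformed bivariate
correlations.  The drug-placebo contrast is a paired t test per edge; the
family of K(K-1)/2 edges is assessed with the network-based-statistic (NBS)
procedure: gate edges at an uncorrected threshold (P < 0.01), find connected
components of the suprathreshold graph per direction, score each component
by the sum of |t| over its edges (mass), and compare against a sign-flip
permutation null of the maximum component mass (components kept at
familywise P < 0.05).  One joint null -- the per-permutation maximum over
both directions -- controls the familywise rate across increases and
decreases together without splitting alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import BoldSession
from .dualreg import dual_regression, _sign_matrix
from .metagica import ConsensusNetworkSet

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeMatrix",
    "EdgeContrastResult",
    "network_timeseries",
    "edge_matrix",
    "paired_edge_test",
    "network_level_inference",
    "report_pairs",
]

EDGE_P = 0.01
COMPONENT_ALPHA = 0.05
N_PERM = 5000


@dataclass
class EdgeMatrix:
    """K x K Fisher-z connectivity matrix for one session."""

    z: np.ndarray
    subject_id: str = ""
    condition: str = ""
    labels: list[str] = field(default_factory=list)

    @property
    def n_networks(self) -> int:
        return self.z.shape[0]

    def correlations(self) -> np.ndarray:
        r = np.tanh(self.z)
        np.fill_diagonal(r, 1.0)
        return r


@dataclass
class EdgeContrastResult:
    t_edges: np.ndarray               # K x K paired t
    p_edges: np.ndarray               # K x K uncorrected two-sided p
    components: list[dict]            # edges, networks, mass, p_fwe, direction
    thresholds: dict
    labels: list[str] = field(default_factory=list)


def network_timeseries(session: BoldSession, consensus: ConsensusNetworkSet,
                       method: str = "dualreg",
                       include_artifacts: bool = False) -> np.ndarray:
    """K x T network time courses for one session, unit variance each.

    ``method='dualreg'`` (default) returns the stage-1 dual-regression
    courses -- the weighted extraction consistent with the within-network
    stage.  ``method='weighted_mean'`` uses map-weighted voxel means instead.
    """
    if method == "dualreg":
        return dual_regression(session, consensus,
                               include_artifacts=include_artifacts).timecourses
    if method == "weighted_mean":
        maps = consensus.maps(include_artifacts=include_artifacts)
        M = maps[:, consensus.mask]
        w = M / np.abs(M).sum(axis=1, keepdims=True)
        tc = w @ session.masked_timeseries().T          # (K, T)
        sd = tc.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant weighted-mean time course")
        return tc / sd
    raise ValueError(f"unknown method {method!r}")


def edge_matrix(timeseries: np.ndarray, subject_id: str = "",
                condition: str = "",
                labels: list[str] | None = None) -> EdgeMatrix:
    """Fisher-z matrix: z(i,j) = atanh(r(i,j)) of the Pearson correlations.

    |r| is clipped at 1 - 1e-12 before atanh; the diagonal is masked (NaN).
    """
    ts = np.asarray(timeseries, float)
    K, T = ts.shape
    if K < 2:
        raise ValueError("need at least 2 networks")
    if T < 3:
        raise ValueError("need at least 3 timepoints")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = labels[bad] if labels else str(bad)
        raise ValueError(f"network {name} has a constant time course")
    r = np.corrcoef(ts)
    r = np.clip(r, -(1 - 1e-12), 1 - 1e-12)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return EdgeMatrix(z=z, subject_id=subject_id, condition=condition,
                      labels=labels or [f"net{i:02d}" for i in range(K)])


def _paired_z_diffs(drug: list[EdgeMatrix],
                    placebo: list[EdgeMatrix]) -> np.ndarray:
    by_id = {m.subject_id: m for m in placebo}
    diffs = []
    for d in drug:
        if d.subject_id not in by_id:
            raise ValueError(f"no placebo matrix for subject {d.subject_id}")
        diffs.append(d.z - by_id[d.subject_id].z)
    return np.stack(diffs)


def paired_edge_test(drug: list[EdgeMatrix],
                     placebo: list[EdgeMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge paired t on Fisher-z differences; df = N-1, two-sided p.

    The parametric p feeds only the NBS edge gate; inference is by
    permutation.  Zero-variance edges get t = 0, p = 1.
    """
    z_diffs = _paired_z_diffs(drug, placebo)
    if z_diffs.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return edge_t_from_diffs(z_diffs)


def edge_t_from_diffs(z_diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    N, K, _ = z_diffs.shape
    mean = z_diffs.mean(axis=0)
    sd = z_diffs.std(axis=0, ddof=1)
    t = np.zeros((K, K))
    off = ~np.eye(K, dtype=bool)
    nz = (sd > 0) & off
    if (off & ~nz).any():
        logger.info("paired_edge_test: %d zero-variance edges set to t=0",
                    int((off & ~nz).sum()) // 2)
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(N))
    p = np.ones((K, K))
    p[off] = 2 * stats.t.sf(np.abs(t[off]), df=N - 1)
    np.fill_diagonal(t, np.nan)
    np.fill_diagonal(p, np.nan)
    return t, p


def _components_and_masses(t: np.ndarray, suprathreshold: np.ndarray,
                           K: int) -> list[tuple[list[tuple[int, int]], float]]:
    """Connected components (with >= 1 edge) of a thresholded edge graph."""
    iu = np.triu_indices(K, 1)
    sel = suprathreshold[iu]
    if not sel.any():
        return []
    rows = iu[0][sel]
    cols = iu[1][sel]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(K, K))
    n_comp, labels = connected_components(adj, directed=False)
    out = []
    for c in range(n_comp):
        edges = [(int(i), int(j)) for i, j in zip(rows, cols)
                 if labels[i] == c]
        if edges:
            mass = float(sum(abs(t[i, j]) for i, j in edges))
            out.append((edges, mass))
    return out


def network_level_inference(z_diffs: np.ndarray, edge_p: float = EDGE_P,
                            component_alpha: float = COMPONENT_ALPHA,
                            n_perm: int = N_PERM, seed: int = 0,
                            labels: list[str] | None = None) -> EdgeContrastResult:
    """NBS permutation inference on N paired Fisher-z difference matrices.

    Edges are gated per direction (t > 0 for increases, t < 0 for decreases)
    at uncorrected p < ``edge_p``; component mass = sum of |t|.  The null is
    the per-permutation maximum component mass over both directions, built
    from whole-matrix sign flips (one sign per subject per permutation).
    """
    z_diffs = np.asarray(z_diffs, float)
    N, K, _ = z_diffs.shape
    if N < 3:
        raise ValueError("need at least 3 subjects")
    if not (0 < edge_p < 1 and 0 < component_alpha < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    iu = np.triu_indices(K, 1)
    D = z_diffs[:, iu[0], iu[1]]                     # (N, E)
    t_crit = stats.t.isf(edge_p / 2.0, df=N - 1)

    def edge_t(vec_mean, vec_var):
        t = np.zeros_like(vec_mean)
        nz = vec_var > 0
        t[nz] = vec_mean[nz] / np.sqrt(vec_var[nz] / N)
        return t

    def max_mass(tvec):
        tmat = np.zeros((K, K))
        tmat[iu] = tvec
        tmat = tmat + tmat.T
        best = 0.0
        for sign in (1, -1):
            sup = (sign * tmat > t_crit)
            for _, mass in _components_and_masses(tmat, sup, K):
                best = max(best, mass)
        return best

    # observed statistics
    t_edges, p_edges = edge_t_from_diffs(z_diffs)
    t_off = np.nan_to_num(t_edges)
    observed = []
    for direction, sign in (("increase", 1), ("decrease", -1)):
        sup = sign * t_off > t_crit
        for edges, mass in _components_and_masses(t_off, sup, K):
            nets = sorted({n for e in edges for n in e})
            observed.append({"direction": direction, "edges": edges,
                             "networks": nets, "mass": mass})

    # permutation null: max component mass over both directions
    signs, exhaustive = _sign_matrix(N, n_perm, seed)
    means = signs @ D / N                            # (P, E)
    ss = (D**2).sum(axis=0)
    null_max = np.empty(signs.shape[0])
    for p in range(signs.shape[0]):
        var = (ss - N * means[p]**2) / (N - 1)
        null_max[p] = max_mass(edge_t(means[p], var))

    for comp in observed:
        if exhaustive:
            cnt = int((null_max >= comp["mass"] - 1e-12).sum())
            comp["p_fwe"] = cnt / len(null_max)
        else:
            cnt = int((null_max[1:] >= comp["mass"] - 1e-12).sum())
            comp["p_fwe"] = (1 + cnt) / (1 + n_perm)
    significant = [c for c in observed if c["p_fwe"] < component_alpha]
    return EdgeContrastResult(
        t_edges=t_edges, p_edges=p_edges, components=significant,
        thresholds={"edge_p": edge_p, "component_p": component_alpha},
        labels=labels or [f"net{i:02d}" for i in range(K)])


def report_pairs(result: EdgeContrastResult) -> pd.DataFrame:
    """Significant network pairs: decrease block then increase block,
    each sorted by |t| descending, i < j canonical edge order."""
    rows = []
    for comp in result.components:
        for i, j in comp["edges"]:
            i, j = (i, j) if i < j else (j, i)
            li = result.labels[i] if i < len(result.labels) else str(i)
            lj = result.labels[j] if j < len(result.labels) else str(j)
            rows.append({
                "pair": f"{li} and {lj}",
                "direction": ("placebo>drug" if comp["direction"] == "decrease"
                              else "drug>placebo"),
                "t": float(result.t_edges[i, j]),
                "p": float(comp["p_fwe"]),
                "_dir_order": 0 if comp["direction"] == "decrease" else 1,
            })
    df = pd.DataFrame(rows, columns=["pair", "direction", "t", "p", "_dir_order"])
    if len(df):
        df = df.drop_duplicates(subset=["pair", "direction"])
        df["_abs_t"] = df["t"].abs()
        df = (df.sort_values(["_dir_order", "_abs_t"],
                             ascending=[True, False])
                .drop(columns=["_dir_order", "_abs_t"])
                .reset_index(drop=True))
    else:
        df = df.drop(columns=["_dir_order"])
    return df
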