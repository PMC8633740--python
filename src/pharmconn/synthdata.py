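"""Synthetic paired drug/placebo resting-state studies with known ground truth.

The generator is the test bed for the whole pipeline: it plants K compact
spatial networks on a small voxel grid, draws network time courses from a
condition-dependent between-network correlation matrix, mixes them linearly
into voxel space (the generative converse of dual regression), adds white
Gaussian noise, motion-spike volumes, and drug-responsive subjective-rating
time courses.  Every quantity the analysis stages estimate therefore has a
known target.

Defaults emulate the study conditions the pipeline is built for: 22 subjects,
two sessions each (drug / placebo, within subject), TR = 3 s, 124 volumes per
scan, ratings collected pre-dose and at 15, 30, 75, 115 and 200 min
post-dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BoldSession, ellipsoid_mask, nearest_correlation, spawn_seeds

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthNetworks",
    "StudySpec",
    "RatingsSchedule",
    "StudyBundle",
    "generate_network_maps",
    "simulate_session",
    "simulate_paired_study",
    "simulate_ratings",
    "default_edge_corr",
    "hub_scenario_deltas",
]

DEFAULT_GRID = (16, 16, 12)
DEFAULT_TIMEPOINTS = (-10.0, 15.0, 30.0, 75.0, 115.0, 200.0)

# signal-level surrogates for head-motion events: a recorded displacement
# excursion plus a global-signal excursion, so both outlier detectors
# (composite-motion > 0.5 mm, global-signal z > 3 SD) have true positives
SPIKE_TRANSLATION_MM = 1.0
SPIKE_GLOBAL_Z = 8.0
# spatially structured part of a motion artifact (map-weight units); the
# global offset alone would be absorbed by the intercept of any spatial
# regression and leave network time courses untouched
SPIKE_VOXEL_SD = 5.0
MOTION_JITTER_TRANS_MM = 0.02
MOTION_JITTER_ROT_RAD = 2e-4


class PlacementError(RuntimeError):
    """Raised when K separated blobs cannot be placed in the mask."""


@dataclass
class GroundTruthNetworks:
    """K planted spatial networks (nonnegative compact blobs) on a grid."""

    maps: np.ndarray                 # (K, X, Y, Z), zero outside mask
    mask: np.ndarray                 # (X, Y, Z) bool
    grid_shape: tuple[int, int, int]
    network_labels: list[str]
    # anatomical stand-ins: outer shell ("csf") and central core ("wm");
    # networks live in the band between, as gray matter does
    tissue_masks: dict[str, np.ndarray] | None = None

    @property
    def n_networks(self) -> int:
        return self.maps.shape[0]

    def masked_maps(self) -> np.ndarray:
        """(K, V) view of the maps restricted to the mask."""
        return self.maps[:, self.mask]

    def pairwise_spatial_correlation(self) -> np.ndarray:
        return np.corrcoef(self.masked_maps())


@dataclass
class StudySpec:
    """Parameters of a paired drug/placebo synthetic study."""

    n_subjects: int = 22
    tr_seconds: float = 3.0
    n_volumes: int = 124
    n_networks: int = 8
    edge_corr_placebo: np.ndarray | None = None
    edge_delta_drug: np.ndarray | None = None
    noise_sd: float = 0.5
    subject_sd: float = 0.05
    spike_prob: float = 0.05
    seed: int = 0
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    ar1_rho: float = 0.0     # optional temporal autocorrelation, off by default
    # shared physiological fluctuation, strongest in the wm/csf stand-ins
    # with a weak global echo in gray matter; expressed as multiples of
    # noise_sd so a noiseless session (noise_sd=0) is exactly noiseless
    physio_ratio: float = 2.0
    physio_gray_frac: float = 0.3

    def __post_init__(self) -> None:
        K = self.n_networks
        if self.edge_corr_placebo is None:
            self.edge_corr_placebo = default_edge_corr(K)
        if self.edge_delta_drug is None:
            self.edge_delta_drug = np.zeros((K, K))
        self.edge_corr_placebo = np.asarray(self.edge_corr_placebo, float)
        self.edge_delta_drug = np.asarray(self.edge_delta_drug, float)
        self.validate()

    def validate(self) -> None:
        K = self.n_networks
        C = self.edge_corr_placebo
        if C.shape != (K, K):
            raise ValueError("edge_corr_placebo must be K x K")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("edge_corr_placebo must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("edge_corr_placebo must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("edge_corr_placebo must be positive semidefinite")
        D = C + self.edge_delta_drug
        if np.abs(D[~np.eye(K, dtype=bool)]).max(initial=0.0) > 1.0:
            raise ValueError("drug-condition correlations exceed |1|")
        if np.linalg.eigvalsh((D + D.T) / 2).min() < -1e-6:
            raise ValueError("edge_corr_placebo + edge_delta_drug is not PSD")
        if not (0 <= self.spike_prob < 0.5):
            raise ValueError("spike_prob must lie in [0, 0.5)")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be nonnegative")


@dataclass
class RatingsSchedule:
    """Session timepoints and drug-response parameters for rating measures."""

    timepoints_min: tuple[float, ...] = DEFAULT_TIMEPOINTS
    measures: tuple[str, ...] = ("arci_a", "heart_rate")
    drug_effect_size: dict[str, float] = field(
        default_factory=lambda: {"arci_a": 3.0, "heart_rate": 12.0})
    within_subject_sd: float = 1.0
    baseline_level: dict[str, float] = field(
        default_factory=lambda: {"arci_a": 2.0, "heart_rate": 65.0})
    sensitivity_log_sd: float = 0.25

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, float)
        if t[0] >= 0:
            raise ValueError("first timepoint must be pre-dose (negative)")
        if np.sum(t > 0) < 2:
            raise ValueError("need at least 2 post-dose timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.within_subject_sd < 0:
            raise ValueError("within_subject_sd must be nonnegative")

    @property
    def post_dose(self) -> np.ndarray:
        t = np.asarray(self.timepoints_min, float)
        return t[t > 0]


@dataclass
class StudyBundle:
    """A complete simulated paired study with its ground truth."""

    sessions: dict[tuple[str, str], BoldSession]   # (subject_id, condition)
    truth: GroundTruthNetworks
    edge_truth: dict[tuple[str, str], np.ndarray]  # realized correlation per session
    timecourse_truth: dict[tuple[str, str], np.ndarray]
    spec: StudySpec

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.sessions})

    def condition_sessions(self, condition: str) -> list[BoldSession]:
        return [self.sessions[(s, condition)] for s in self.subjects]


def default_edge_corr(K: int, base: float = 0.2) -> np.ndarray:
    """A mild block-free default: neighbouring networks correlate at ``base``."""
    C = np.eye(K)
    for i in range(K - 1):
        C[i, i + 1] = C[i + 1, i] = base
    C, _ = nearest_correlation(C)
    return C


def hub_scenario_deltas(K: int, hub: int = 0, cortical: tuple[int, int] = (1, 2),
                        effect: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Build the thalamus-like hub scenario.

    Under placebo the two "cortical" networks correlate with each other but
    not with the "hub"; drug raises both hub-cortical correlations by
    ``effect`` and lowers the cortical-cortical correlation by ``effect``.
    Returns ``(edge_corr_placebo, edge_delta_drug)``.
    """
    c1, c2 = cortical
    C = np.eye(K)
    C[c1, c2] = C[c2, c1] = 0.45
    C[hub, c1] = C[c1, hub] = 0.10
    C[hub, c2] = C[c2, hub] = 0.10
    C, _ = nearest_correlation(C)
    D = np.zeros((K, K))
    D[hub, c1] = D[c1, hub] = effect
    D[hub, c2] = D[c2, hub] = effect
    D[c1, c2] = D[c2, c1] = -effect
    return C, D


# ---------------------------------------------------------------------------
# network map generation

def tissue_regions(mask: np.ndarray) -> dict[str, np.ndarray]:
    """Anatomical stand-in regions: boundary shell -> "csf", a central core
    (the mask shrunk toward its centroid) -> "wm"; the band between is the
    "gray" territory where networks are planted."""
    from scipy import ndimage
    shell = mask & ~ndimage.binary_erosion(mask)
    grids = np.indices(mask.shape).astype(float)
    center = [(s - 1) / 2.0 for s in mask.shape]
    semi = [max((s - 1) / 2.0, 1e-9) * 0.45 for s in mask.shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    core = (r2 <= 1.0) & mask & ~shell
    gray = mask & ~shell & ~core
    return {"csf": shell, "wm": core, "gray": gray}


def _blob(grid_shape, center, sigmas, cutoff_frac=0.05):
    grids = np.indices(grid_shape).astype(float)
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigmas))
    w = np.exp(-0.5 * d2)
    w[w < cutoff_frac] = 0.0
    return w


def generate_network_maps(K: int, grid_shape: tuple[int, int, int] | None = None,
                          mask: np.ndarray | None = None, seed: int = 0,
                          max_pair_corr: float = 0.15,
                          max_retries: int = 500) -> GroundTruthNetworks:
    """Place K compact anisotropic Gaussian blobs with low mutual overlap.

    Blobs are truncated at 5% of peak, zeroed outside the mask, and accepted
    only if every pairwise spatial correlation (over the mask) stays below
    ``max_pair_corr``.  Deterministic for a fixed seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if grid_shape is None:
        grid_shape = DEFAULT_GRID
    if mask is None:
        mask = ellipsoid_mask(grid_shape)
    mask = np.asarray(mask, bool)
    if mask.sum() < 20 * K:
        raise PlacementError(f"mask has {int(mask.sum())} voxels; "
                             f"need at least {20 * K} for K={K}")
    rng = np.random.default_rng(seed)
    tissues = tissue_regions(mask)
    gray = tissues["gray"] if tissues["gray"].sum() >= 20 * K else mask
    wm = tissues["wm"]
    candidates = np.argwhere(gray)
    maps: list[np.ndarray] = []
    flat: list[np.ndarray] = []
    tries = 0
    while len(maps) < K:
        if tries > max_retries:
            raise PlacementError(
                f"could not place {K} blobs with pairwise correlation "
                f"< {max_pair_corr} after {max_retries} retries")
        tries += 1
        center = candidates[rng.integers(len(candidates))]
        # blob scale tracks the mask size so small desk-scale grids still
        # hold K separated networks; the narrow range keeps the planted
        # networks' signal energies comparable, so none sits at a
        # qualitatively different SNR
        scale = (mask.sum() / 1072.0) ** (1.0 / 3.0)
        sigmas = rng.uniform(1.3, 2.0, size=3) * min(1.0, scale)
        w = _blob(grid_shape, center, sigmas)
        w[~mask] = 0.0
        # gray-matter networks carry no signal inside the white-matter or
        # CSF stand-ins, so the nuisance tissue means stay free of planted
        # network fluctuations
        if gray is not mask:
            w[wm | tissues["csf"]] = 0.0
        v = w[mask]
        if v.max() <= 0 or v.std() == 0:
            continue
        ok = all(abs(np.corrcoef(v, f)[0, 1]) < max_pair_corr for f in flat)
        if ok:
            maps.append(w)
            flat.append(v)
    return GroundTruthNetworks(
        maps=np.stack(maps), mask=mask, grid_shape=tuple(grid_shape),
        network_labels=[f"net{i:02d}" for i in range(K)],
        tissue_masks={"wm": tissues["wm"], "csf": tissues["csf"]})


# ---------------------------------------------------------------------------
# session simulation

def _sample_timecourses(corr: np.ndarray, T: int, rng: np.random.Generator,
                        ar1_rho: float = 0.0) -> np.ndarray:
    K = corr.shape[0]
    w, v = np.linalg.eigh(corr)
    L = v * np.sqrt(np.clip(w, 0, None))
    z = rng.standard_normal((K, T))
    if ar1_rho:
        # optional AR(1) innovation filtering, stationary unit variance
        for t in range(1, T):
            z[:, t] = ar1_rho * z[:, t - 1] + np.sqrt(1 - ar1_rho**2) * z[:, t]
    return L @ z


def simulate_session(truth: GroundTruthNetworks, spec: StudySpec,
                     edge_corr: np.ndarray, subject_offsets: np.ndarray | None,
                     seed: int, subject_id: str = "s00",
                     condition: str = "placebo") -> BoldSession:
    """Simulate one BOLD session: time courses x maps + noise + motion spikes.

    ``edge_corr + subject_offsets`` is projected to the nearest correlation
    matrix when needed (the projection is logged).  Spike volumes receive a
    global-signal offset and a recorded >0.5 mm displacement excursion, and
    their indices are stored on the returned session as ground truth.
    """
    K = truth.n_networks
    T = spec.n_volumes
    target = np.asarray(edge_corr, float).copy()
    if subject_offsets is not None:
        target = target + subject_offsets
    np.fill_diagonal(target, 1.0)
    target = np.clip(target, -0.99, 0.99)
    np.fill_diagonal(target, 1.0)
    corr, projected = nearest_correlation(target)
    if projected:
        logger.info("subject %s/%s: edge matrix projected to nearest "
                    "correlation matrix", subject_id, condition)
    rng = np.random.default_rng(seed)
    tc = _sample_timecourses(corr, T, rng, spec.ar1_rho)          # (K, T)
    M = truth.masked_maps()                                       # (K, V)
    ts = tc.T @ M                                                 # (T, V)
    if spec.noise_sd > 0:
        ts = ts + rng.normal(0, spec.noise_sd, size=ts.shape)
        if spec.physio_ratio > 0 and truth.tissue_masks:
            physio = rng.standard_normal(T)
            amp = spec.physio_ratio * spec.noise_sd
            in_mask_idx = np.zeros(truth.mask.shape, dtype=int)
            in_mask_idx[truth.mask] = np.arange(int(truth.mask.sum()))
            tissue = np.zeros(truth.mask.shape, bool)
            for name in ("wm", "csf"):
                m = truth.tissue_masks.get(name)
                if m is not None:
                    tissue |= m
            tissue &= truth.mask
            ts[:, in_mask_idx[tissue]] += amp * physio[:, None]
            gray = truth.mask & ~tissue
            ts[:, in_mask_idx[gray]] += (spec.physio_gray_frac * amp
                                         * physio[:, None])

    motion = np.zeros((T, 6))
    motion[:, :3] = rng.normal(0, MOTION_JITTER_TRANS_MM, size=(T, 3))
    motion[:, 3:] = rng.normal(0, MOTION_JITTER_ROT_RAD, size=(T, 3))
    spikes = np.array([], dtype=int)
    if spec.spike_prob > 0:
        spikes = np.flatnonzero(rng.random(T) < spec.spike_prob)
        if len(spikes):
            gs_sd = ts.mean(axis=1).std()
            if gs_sd == 0:
                gs_sd = max(spec.noise_sd, 1e-3)
            ts[spikes] += SPIKE_GLOBAL_Z * gs_sd
            ts[spikes] += rng.normal(0, SPIKE_VOXEL_SD,
                                     size=(len(spikes), ts.shape[1]))
            motion[spikes, 0] += SPIKE_TRANSLATION_MM

    session = BoldSession(
        data=np.zeros(truth.grid_shape + (T,)), mask=truth.mask,
        tr_seconds=spec.tr_seconds, subject_id=subject_id,
        condition=condition, motion_params=motion,
        true_spike_volumes=spikes, tissue_masks=truth.tissue_masks)
    session = session.with_masked_timeseries(ts)
    session.motion_params = motion
    session.true_spike_volumes = spikes
    session._true_timecourses = tc          # stashed for round-trip tests
    session._true_edge_corr = corr
    return session


def simulate_paired_study(spec: StudySpec,
                          truth: GroundTruthNetworks | None = None) -> StudyBundle:
    """Simulate the full within-subject study: every subject scanned twice.

    One subject-level random edge perturbation (sd ``subject_sd``) is shared
    across the subject's drug and placebo sessions, creating the
    within-subject correlation the paired contrasts exploit.  All randomness
    descends deterministically from ``spec.seed``.
    """
    seeds = spawn_seeds(spec.seed, 1 + 2 * spec.n_subjects + spec.n_subjects)
    if truth is None:
        truth = generate_network_maps(spec.n_networks, spec.grid_shape,
                                      seed=seeds[0])
    K = truth.n_networks
    sessions: dict[tuple[str, str], BoldSession] = {}
    edge_truth: dict[tuple[str, str], np.ndarray] = {}
    tc_truth: dict[tuple[str, str], np.ndarray] = {}
    drug_corr = spec.edge_corr_placebo + spec.edge_delta_drug
    for i in range(spec.n_subjects):
        sid = f"s{i:02d}"
        off_rng = np.random.default_rng(seeds[1 + i])
        off = np.zeros((K, K))
        if spec.subject_sd > 0:
            iu = np.triu_indices(K, 1)
            vals = off_rng.normal(0, spec.subject_sd, size=len(iu[0]))
            off[iu] = vals
            off = off + off.T
        for j, (condition, base) in enumerate(
                [("placebo", spec.edge_corr_placebo), ("drug", drug_corr)]):
            s_seed = seeds[1 + spec.n_subjects + 2 * i + j]
            sess = simulate_session(truth, spec, base, off, s_seed,
                                    subject_id=sid, condition=condition)
            sessions[(sid, condition)] = sess
            edge_truth[(sid, condition)] = sess._true_edge_corr
            tc_truth[(sid, condition)] = sess._true_timecourses
    return StudyBundle(sessions=sessions, truth=truth, edge_truth=edge_truth,
                       timecourse_truth=tc_truth, spec=spec)


# ---------------------------------------------------------------------------
# ratings

def _bump_profile(schedule: RatingsSchedule) -> np.ndarray:
    """Smooth rise-and-fall weight at each timepoint, peaking between the
    2nd and 3rd post-dose samples, normalised to max 1 over post-dose times."""
    t = np.asarray(schedule.timepoints_min, float)
    post = schedule.post_dose
    t_peak = (post[1] + post[2]) / 2.0 if len(post) >= 3 else post[-1]
    width = max((post[2] - post[0]) if len(post) >= 3 else post[-1] / 2, 1e-6)
    prof = np.exp(-0.5 * ((t - t_peak) / width) ** 2)
    prof[t < 0] = 0.0
    m = prof[t > 0].max()
    return prof / m if m > 0 else prof


def simulate_ratings(schedule: RatingsSchedule, n_subjects: int,
                     seed: int = 0) -> pd.DataFrame:
    """Long-format ratings table for both sessions of every subject.

    Placebo sessions fluctuate around the measure baseline; drug sessions add
    a rise-and-fall bump of amplitude ``drug_effect_size[measure]`` scaled by
    a per-subject lognormal sensitivity factor (stored in the
    ``sensitivity`` column for ground-truth checks).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(schedule.timepoints_min, float)
    prof = _bump_profile(schedule)
    rows = []
    for i in range(n_subjects):
        sid = f"s{i:02d}"
        sens = float(np.exp(rng.normal(0.0, schedule.sensitivity_log_sd)))
        for cond in ("placebo", "drug"):
            session = 1 if (i % 2 == 0) == (cond == "placebo") else 2
            for m in schedule.measures:
                base = schedule.baseline_level.get(m, 0.0)
                amp = schedule.drug_effect_size.get(m, 0.0)
                for k, tp in enumerate(t):
                    val = base
                    if cond == "drug":
                        val += amp * sens * prof[k]
                    if schedule.within_subject_sd > 0:
                        val += rng.normal(0, schedule.within_subject_sd)
                    rows.append((sid, session, cond, float(tp), m, val, sens))
    return pd.DataFrame(rows, columns=["subject", "session", "condition",
                                       "time_min", "measure", "value",
                                       "sensitivity"])
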