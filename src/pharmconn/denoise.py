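"""Confound removal for resting-state BOLD sessions.

The stage mirrors a CompCor-style stream: framewise-displacement and
global-signal outlier flagging ("scrubbing" via spike regressors), subject
exclusion on composite-motion summaries, nuisance regression (drift
polynomials, motion parameters and their first derivatives, white-matter and
CSF signals, one indicator per flagged volume), zero-phase bandpass
filtering, and mask-restricted Gaussian smoothing.

Conservative defaults: motion threshold 0.5 mm, global-signal threshold
3 SD, drift order 2, passband 0.008-0.09 Hz, smoothing FWHM 6 mm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BoldSession

logger = logging.getLogger(__name__)

__all__ = [
    "ConfoundSet",
    "framewise_displacement",
    "detect_outliers",
    "subject_exclusion",
    "build_confound_matrix",
    "regress_confounds",
    "bandpass",
    "smooth",
    "denoise_session",
]

FD_THRESH_MM = 0.5
GS_THRESH_SD = 3.0
DRIFT_ORDER = 2
BAND_HZ = (0.008, 0.09)
FWHM_MM = 6.0
HEAD_RADIUS_MM = 50.0


@dataclass
class ConfoundSet:
    """Per-session confound quantities and the assembled nuisance design."""

    outlier_flags: np.ndarray                  # (T,) bool
    fd_series: np.ndarray                      # (T-1,) mm
    global_z: np.ndarray                       # (T,) SD units
    nuisance_matrix: np.ndarray | None = None  # (T, P)
    column_names: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)
    excluded_subject: bool = False
    exclusion_reason: str = ""


def framewise_displacement(motion_params: np.ndarray,
                           head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Power-style composite framewise displacement.

    Sum of absolute backward differences of the three translations (mm) plus
    the three rotations converted to arc length at ``head_radius_mm``.
    Returns T-1 values; FD[i] is the displacement between volumes i and i+1.
    """
    mp = np.asarray(motion_params, float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion_params must be (T, 6)")
    if mp.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(mp, axis=0))
    return d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)


def detect_outliers(session: BoldSession, fd_series: np.ndarray | None = None,
                    fd_thresh: float = FD_THRESH_MM,
                    gs_thresh: float = GS_THRESH_SD) -> ConfoundSet:
    """Flag volumes by composite motion or global-signal excursion.

    Volume t is flagged iff FD between t-1 and t exceeds ``fd_thresh`` or the
    z-scored global (within-mask mean) signal change at t exceeds
    ``gs_thresh`` in absolute value.
    """
    T = session.n_volumes
    if fd_series is None:
        if session.motion_params is None:
            fd_series = np.zeros(T - 1)
        else:
            fd_series = framewise_displacement(session.motion_params)
    fd_series = np.asarray(fd_series, float)
    if fd_series.shape != (T - 1,):
        raise ValueError("fd_series must have length T-1")

    gs = session.masked_timeseries().mean(axis=1)
    change = np.zeros(T)
    change[1:] = np.diff(gs)
    sd = change[1:].std()
    global_z = np.zeros(T)
    if sd > 0:
        global_z[1:] = (change[1:] - change[1:].mean()) / sd
    flags = np.zeros(T, dtype=bool)
    flags[1:] = fd_series > fd_thresh
    flags |= np.abs(global_z) > gs_thresh
    return ConfoundSet(outlier_flags=flags, fd_series=fd_series,
                       global_z=global_z)


def subject_exclusion(fd_by_session: dict[str, np.ndarray],
                      fd_thresh: float = FD_THRESH_MM) -> tuple[bool, str]:
    """Exclude a subject when either scan shows excessive composite motion.

    True iff, in either session, mean FD exceeds ``fd_thresh`` or more than
    half the volumes exceed ``fd_thresh`` (strict inequalities).
    """
    for name, fd in fd_by_session.items():
        fd = np.asarray(fd, float)
        if fd.mean() > fd_thresh:
            return True, f"session {name}: mean FD {fd.mean():.3f} > {fd_thresh}"
        frac = (fd > fd_thresh).mean()
        if frac > 0.5:
            return True, (f"session {name}: {frac:.0%} of volumes exceed "
                          f"{fd_thresh} mm")
    return False, ""


def default_tissue_signals(session: BoldSession) -> dict[str, np.ndarray]:
    """White-matter / CSF signals from the session's tissue masks.

    Sessions carrying segmentation-derived (or generator-designated) tissue
    masks use those; otherwise two mask subregions stand in -- a central
    core ("wm") and the boundary shell ("csf").
    """
    if session.tissue_masks:
        return {name: session.data[m].mean(axis=0)
                for name, m in session.tissue_masks.items()
                if name in ("wm", "csf") and m.any()}
    core = ndimage.binary_erosion(session.mask, iterations=3)
    if not core.any():
        core = session.mask
    shell = session.mask & ~ndimage.binary_erosion(session.mask)
    if not shell.any():
        shell = session.mask
    return {"wm": session.data[core].mean(axis=0),
            "csf": session.data[shell].mean(axis=0)}


def build_confound_matrix(session: BoldSession, confounds: ConfoundSet,
                          tissue_signals: dict[str, np.ndarray] | None = None,
                          drift_order: int = DRIFT_ORDER,
                          collinearity_tol: float = 1e-8) -> np.ndarray:
    """Assemble the nuisance design: drift, motion (+derivatives), tissue
    signals, one indicator per flagged volume; near-collinear columns dropped.
    """
    T = session.n_volumes
    flags = confounds.outlier_flags
    if flags.all():
        raise ValueError("all volumes flagged as outliers; nothing to analyze")
    if tissue_signals is None:
        tissue_signals = default_tissue_signals(session)

    t = np.linspace(-1.0, 1.0, T)
    cols: list[np.ndarray] = [np.ones(T)]
    names: list[str] = ["intercept"]
    for d in range(1, drift_order + 1):
        cols.append(t**d)
        names.append(f"drift{d}")
    if session.motion_params is not None:
        mp = session.motion_params
        for j in range(6):
            cols.append(mp[:, j])
            names.append(f"motion{j}")
        deriv = np.vstack([np.zeros((1, 6)), np.diff(mp, axis=0)])
        for j in range(6):
            cols.append(deriv[:, j])
            names.append(f"dmotion{j}")
    for key in ("wm", "csf"):
        if key in tissue_signals:
            sig = np.asarray(tissue_signals[key], float)
            if sig.shape != (T,):
                raise ValueError(f"{key} signal must have length T")
            cols.append(sig)
            names.append(key)
    for v in np.flatnonzero(flags):
        spike = np.zeros(T)
        spike[v] = 1.0
        cols.append(spike)
        names.append(f"spike{v}")

    X = np.column_stack(cols)
    keep, dropped = _drop_collinear(X, names, collinearity_tol)
    confounds.nuisance_matrix = X[:, keep]
    confounds.column_names = [names[i] for i in keep]
    confounds.dropped_columns = dropped
    if dropped:
        logger.info("dropped near-collinear confound columns: %s", dropped)
    return confounds.nuisance_matrix


def _drop_collinear(X: np.ndarray, names: list[str],
                    tol: float) -> tuple[list[int], list[str]]:
    """Greedy rank repair: drop any column nearly spanned by earlier ones."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        norm = np.linalg.norm(col)
        if norm == 0:
            dropped.append(names[j])
            continue
        if keep:
            B = X[:, keep]
            resid = col - B @ np.linalg.lstsq(B, col, rcond=None)[0]
            if np.linalg.norm(resid) < tol * max(norm, 1.0):
                dropped.append(names[j])
                continue
        keep.append(j)
    return keep, dropped


def regress_confounds(session: BoldSession,
                      nuisance_matrix: np.ndarray) -> BoldSession:
    """Per-voxel OLS removal of the nuisance design; residuals replace data."""
    X = np.asarray(nuisance_matrix, float)
    T = session.n_volumes
    if X.shape[0] != T:
        raise ValueError("nuisance matrix rows must equal number of volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [str(i) for i in np.flatnonzero(np.abs(np.diag(R)) < 1e-10)]
        raise ValueError(f"rank-deficient nuisance matrix (columns {bad})")
    Y = session.masked_timeseries()           # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return session.with_masked_timeseries(resid)


def bandpass(session: BoldSession, low_hz: float = BAND_HZ[0],
             high_hz: float = BAND_HZ[1]) -> BoldSession:
    """Zero-phase ideal (hard frequency-mask) bandpass of every voxel series.

    ``high_hz`` is clamped to 0.99x Nyquist with a warning when it exceeds
    Nyquist; ``low_hz`` at or above Nyquist is an error.
    """
    nyq = 1.0 / (2.0 * session.tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if low_hz >= nyq:
        raise ValueError(f"low cutoff {low_hz} Hz is at or above Nyquist "
                         f"({nyq:.4f} Hz)")
    if high_hz > nyq:
        warnings.warn(f"high cutoff {high_hz} Hz exceeds Nyquist "
                      f"({nyq:.4f} Hz); clamping to 0.99 x Nyquist")
        high_hz = 0.99 * nyq
    Y = session.masked_timeseries()
    T = session.n_volumes
    freqs = np.fft.rfftfreq(T, d=session.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    F = np.fft.rfft(Y, axis=0)
    F[~keep] = 0.0
    out = np.fft.irfft(F, n=T, axis=0)
    return session.with_masked_timeseries(out)


def smooth(session: BoldSession, fwhm_mm: float = FWHM_MM,
           voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)) -> BoldSession:
    """Mask-restricted Gaussian smoothing of each volume.

    Values outside the mask are neither read nor written: each volume is
    convolved as data*mask and renormalised by the smoothed mask, so a
    constant field inside a full mask is preserved.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return session
    sigma_vox = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
                 for v in voxel_size_mm]
    mask = session.mask.astype(float)
    wm = ndimage.gaussian_filter(mask, sigma_vox)
    data = np.zeros_like(session.data)
    for tt in range(session.n_volumes):
        vol = session.data[..., tt] * mask
        sm = ndimage.gaussian_filter(vol, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(wm > 1e-12, sm / wm, 0.0)
        data[..., tt] = out * session.mask
    new = session.with_masked_timeseries(data[session.mask].T)
    return new


def denoise_session(session: BoldSession,
                    tissue_signals: dict[str, np.ndarray] | None = None,
                    fd_thresh: float = FD_THRESH_MM,
                    gs_thresh: float = GS_THRESH_SD,
                    drift_order: int = DRIFT_ORDER,
                    band_hz: tuple[float, float] = BAND_HZ,
                    fwhm_mm: float = 0.0,
                    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
                    ) -> tuple[BoldSession, ConfoundSet]:
    """Full denoising pass in fixed order: outlier detection, confound
    regression (with spike regressors), bandpass, optional smoothing.

    Smoothing defaults off here because group ICA and dual regression are
    typically run on the same smoothed data only once; the pipeline sets
    ``fwhm_mm`` explicitly.
    """
    confounds = detect_outliers(session, fd_thresh=fd_thresh,
                                gs_thresh=gs_thresh)
    X = build_confound_matrix(session, confounds, tissue_signals,
                              drift_order=drift_order)
    out = regress_confounds(session, X)
    out = bandpass(out, *band_hz)
    if fwhm_mm > 0:
        out = smooth(out, fwhm_mm, voxel_size_mm)
    return out, confounds
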