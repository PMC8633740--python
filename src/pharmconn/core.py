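"""Shared containers and small numerical utilities.

The central in-memory object is :class:`BoldSession`, one subject-session 4D
BOLD time series on a common voxel grid with its brain mask and repetition
time.  Everything downstream (denoising, group ICA, dual regression,
ROI-to-ROI connectivity) consumes and produces these.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BoldSession",
    "ellipsoid_mask",
    "nearest_correlation",
    "spawn_seeds",
    "zscore_masked",
    "save_session_nifti",
    "load_session_nifti",
    "save_maps_nifti",
    "load_maps_nifti",
    "config_hash",
]


@dataclass
class BoldSession:
    """One subject-session 4D BOLD scan.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        BOLD signal in arbitrary units.
    mask : ndarray of bool, shape (X, Y, Z)
        Brain mask; analysis is restricted to in-mask voxels.
    tr_seconds : float
        Repetition time in seconds.
    subject_id, condition : str
        Provenance labels ("drug" / "placebo" for the two sessions).
    motion_params : ndarray, shape (T, 6), optional
        Rigid-body realignment parameters: 3 translations (mm) and
        3 rotations (radians) per volume.
    true_spike_volumes : ndarray of int, optional
        Ground-truth indices of simulated motion-spike volumes (synthetic
        sessions only; never used by the analysis path).
    tissue_masks : dict of ndarray, optional
        Segmentation-derived (or generator-designated) "wm" / "csf" voxel
        masks used for nuisance tissue signals.
    """

    data: np.ndarray
    mask: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    condition: str = ""
    motion_params: np.ndarray | None = None
    true_spike_volumes: np.ndarray | None = None
    tissue_masks: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (X, Y, Z, T)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial dims of data")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=np.float64)
            if self.motion_params.shape != (self.n_volumes, 6):
                raise ValueError("motion_params must be (T, 6)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds

    def masked_timeseries(self) -> np.ndarray:
        """Return the in-mask data as a (T, V) matrix."""
        return self.data[self.mask].T

    def with_masked_timeseries(self, ts: np.ndarray) -> "BoldSession":
        """Return a copy whose in-mask data is replaced by ``ts`` (T, V)."""
        data = np.zeros_like(self.data)
        data[self.mask] = np.asarray(ts, dtype=np.float64).T
        return replace(self, data=data)


def ellipsoid_mask(shape: tuple[int, int, int], margin: float = 0.5) -> np.ndarray:
    """Binary ellipsoidal mask inscribed in ``shape`` (a convex brain stand-in)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    semi = [(s - 1) / 2.0 - margin for s in shape]
    r2 = sum(((g - c) / max(a, 1e-9)) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def nearest_correlation(mat: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalue clipping followed by diagonal renormalisation, iterated until
    the result is PSD with unit diagonal.  Returns ``(matrix, projected)``
    where ``projected`` records whether any repair was needed.
    """
    m = np.asarray(mat, dtype=np.float64)
    m = (m + m.T) / 2.0
    projected = False
    out = m.copy()
    np.fill_diagonal(out, 1.0)
    if not np.allclose(out, m, atol=1e-12):
        projected = True
    for _ in range(100):
        w, v = np.linalg.eigh(out)
        if w.min() >= -1e-12:
            break
        projected = True
        w = np.clip(w, eps, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    else:
        raise ValueError("matrix could not be repaired to a correlation matrix")
    return out, projected


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def zscore_masked(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score a 3D map within the mask; zero outside."""
    out = np.zeros_like(vol, dtype=np.float64)
    vals = vol[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant map")
    out[mask] = (vals - vals.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_session_nifti(session: BoldSession, path: str | Path,
                       voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)) -> None:
    img = nib.Nifti1Image(session.data.astype(np.float32), _affine(voxel_size_mm))
    img.header.set_zooms(tuple(voxel_size_mm) + (session.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_session_nifti(path: str | Path, mask: np.ndarray,
                       subject_id: str = "", condition: str = "",
                       motion_params: np.ndarray | None = None) -> BoldSession:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    tr = float(img.header.get_zooms()[3])
    return BoldSession(data=data, mask=mask, tr_seconds=tr,
                       subject_id=subject_id, condition=condition,
                       motion_params=motion_params)


def save_maps_nifti(maps: np.ndarray, path: str | Path,
                    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)) -> None:
    """Save a (K, X, Y, Z) stack of spatial maps with the map index as dim 4."""
    img = nib.Nifti1Image(np.moveaxis(maps, 0, -1).astype(np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_maps_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.moveaxis(np.asanyarray(img.dataobj, dtype=np.float64), -1, 0)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
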