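"""SBRT-frame coordinate reconstruction from MR-visible rods.

The stereotactic body frame carries three silicone rods at its bottom
that appear bright on T2-weighted MRI. Localizing the rods and fitting
the rigid transform onto their known frame-coordinate reference points
lets any MRI position (e.g. a detected fiducial) be expressed in frame
coordinates. The rod geometry is institution-specific hardware, so the
frame model is user-supplied configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import GridMeta

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FrameModel:
    """Rod reference points in frame coordinates (mm), >= 3 non-collinear."""

    rod_reference_points: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.rod_reference_points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "rod_reference_points", pts)
        if len(pts) < 3:
            raise ValueError("need at least 3 rod reference points")
        if _collinear(pts):
            raise ValueError("rod reference points are collinear")


@dataclass
class RigidTransform:
    """Proper rigid map x -> R x + t with its fit residual."""

    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # mm
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-6):
            raise ValueError("rotation must have determinant +1")
        self.rotation = r
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.rms_residual)


def _collinear(pts: np.ndarray, tol: float = 1e-6) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


# --------------------------------------------------------------------------
# rod detection
# --------------------------------------------------------------------------

def detect_rods(
    t2w_volume: np.ndarray,
    grid: GridMeta,
    intensity_percentile: float = 99.5,
    expected_count: int = 3,
    inferior_axis: int = 2,
    elongation_ratio: float = 3.0,
) -> np.ndarray:
    """Localize bright frame rods in the inferior quarter of a volume.

    Voxels above the intensity percentile within the inferior quarter are
    26-connected-labeled; the `expected_count` largest components whose
    principal axis is at least `elongation_ratio` times the second axis
    are kept; each rod's reference point is the component centroid in
    world mm, returned sorted left-to-right (ascending first axis).
    """
    if expected_count < 3:
        raise ValueError("expected_count must be >= 3")
    vol = np.asarray(t2w_volume, dtype=float)
    n_inf = vol.shape[inferior_axis]
    sl = [slice(None)] * 3
    sl[inferior_axis] = slice(0, max(1, n_inf // 4))
    region = vol[tuple(sl)]
    thr = np.percentile(region, intensity_percentile)
    binary = np.zeros(vol.shape, dtype=bool)
    binary[tuple(sl)] = region > thr
    labels, n = ndimage.label(binary, structure=_CONN26)
    rods = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < 3:
            continue
        pts = idx * np.asarray(grid.voxel_size)
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 0 or s[0] / max(s[1], 1e-12) >= elongation_ratio:
            rods.append((len(idx), idx.mean(axis=0)))
    if len(rods) < expected_count:
        raise ValueError(
            f"found {len(rods)} rod-like components, expected {expected_count}"
        )
    if len(rods) > expected_count:
        logger.warning(
            "found %d rod-like components, keeping the %d largest",
            len(rods), expected_count,
        )
    rods.sort(key=lambda r: -r[0])
    centroids = np.array([grid.voxel_to_world(c) for _, c in rods[:expected_count]])
    return centroids[np.argsort(centroids[:, 0])]


# --------------------------------------------------------------------------
# rigid registration (Kabsch)
# --------------------------------------------------------------------------

def fit_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rotation + translation mapping source onto target.

    SVD of the cross-covariance of the centered point sets, with a sign
    flip of the smallest singular direction to exclude reflections.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape or len(src) < 3:
        raise ValueError("need equal point counts >= 3")
    if _collinear(src) or _collinear(tgt):
        raise ValueError("points are collinear; rotation is not determined")
    sc = src.mean(axis=0)
    tc = tgt.mean(axis=0)
    h = (src - sc).T @ (tgt - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = tc - rot @ sc
    resid = (rot @ src.T).T + t - tgt
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return RigidTransform(rotation=rot, translation=t, rms_residual=rms)


def map_point(transform: RigidTransform, point: np.ndarray) -> np.ndarray:
    """Apply the rigid transform to one point or an (n, 3) array."""
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = p.reshape(-1, 3)
    out = (transform.rotation @ p.T).T + transform.translation
    return out[0] if single else out
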