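"""Shared containers and dipole numerics for the QSM fiducial pipeline.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based; world coordinates (mm) are
  ``origin + index * voxel_size`` per axis, i.e. a diagonal NIfTI-style
  affine with the origin at the center of voxel (0, 0, 0).
* Susceptibility (chi) and field maps are expressed in ppm of B0,
  Lorentz-sphere convention, relative to background tissue (tissue = 0).
* The main field B0 lies along ``GridMeta.b0_axis`` (default: the slice
  axis of an axial pelvis acquisition).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.fft as sfft

GAMMA_BAR_MHZ_PER_T = 42.577  # proton gyromagnetic ratio / 2pi


# --------------------------------------------------------------------------
# grid metadata
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridMeta:
    """Geometry and field context of a reconstructed volume.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis.
    voxel_size : tuple of float
        Voxel edge length per axis in mm; all > 0.
    origin : tuple of float
        World-mm position of the center of voxel (0, 0, 0).
    b0_axis : int
        Axis index parallel to the main field.
    b0 : float
        Field strength in tesla.
    gamma_bar : float
        Gyromagnetic ratio in MHz/T.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    b0_axis: int = 2
    b0: float = 1.5
    gamma_bar: float = GAMMA_BAR_MHZ_PER_T

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.b0_axis not in (0, 1, 2):
            raise ValueError(f"b0_axis must be 0, 1 or 2, got {self.b0_axis}")
        if self.b0 <= 0:
            raise ValueError("b0 must be > 0")

    @property
    def hz_per_ppm(self) -> float:
        """Larmor shift in Hz corresponding to 1 ppm of B0."""
        return self.gamma_bar * 1e6 * self.b0 * 1e-6

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) 0-based voxel indices to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    @staticmethod
    def centered(shape, voxel_size=(1.0, 1.0, 2.0), **kw) -> "GridMeta":
        """Grid whose world origin sits at the volume center."""
        shape = tuple(int(n) for n in shape)
        voxel_size = tuple(float(v) for v in voxel_size)
        origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size))
        return GridMeta(shape=shape, voxel_size=voxel_size, origin=origin, **kw)


# --------------------------------------------------------------------------
# multi-echo data container
# --------------------------------------------------------------------------

@dataclass
class MultiEchoGRE:
    """Complex multi-echo gradient-echo volumes with acquisition metadata."""

    data: np.ndarray          # complex, shape (n_echoes, *grid.shape)
    tes: np.ndarray           # echo times in seconds, strictly increasing
    grid: GridMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.tes = np.asarray(self.tes, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != self.tes.size:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{self.tes.size} echo times"
            )
        if tuple(self.data.shape[1:]) != tuple(self.grid.shape):
            raise ValueError("data grid does not match GridMeta.shape")
        if self.tes.size < 2 or np.any(np.diff(self.tes) <= 0):
            raise ValueError("tes must be strictly increasing with >= 2 echoes")

    @property
    def n_echoes(self) -> int:
        return int(self.tes.size)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in (-pi, pi]."""
        return wrap_phase(np.angle(self.data))


@dataclass
class FieldMap:
    """Per-voxel off-resonance field with complex-fit diagnostics."""

    field_ppm: np.ndarray
    r2star: np.ndarray        # 1/s
    phi0: np.ndarray          # rad
    amplitude: np.ndarray
    residual: np.ndarray      # per-voxel RMS complex misfit
    reliability: np.ndarray   # amplitude-based weight in [0, 1]
    grid: GridMeta

    def field_hz(self) -> np.ndarray:
        return self.field_ppm * self.grid.hz_per_ppm


@dataclass
class SusceptibilityMap:
    """Zero-referenced susceptibility map in ppm."""

    chi: np.ndarray
    reference_mask: np.ndarray
    method: str               # {"tkd", "medi0"}
    grid: GridMeta
    params: dict = dc_field(default_factory=dict)
    converged: bool = True


# --------------------------------------------------------------------------
# phase helpers
# --------------------------------------------------------------------------

def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2.0 * np.pi)


# --------------------------------------------------------------------------
# dipole kernel and convolution
# --------------------------------------------------------------------------

def dipole_kernel_ft(padded_shape, voxel_size, b0_axis, dtype=np.float64) -> np.ndarray:
    """Fourier-domain unit dipole D(k) = 1/3 - k_b0^2/|k|^2 on an rfft grid.

    D(0) is defined as 0: the mean field of a periodic uniform
    susceptibility distribution vanishes in the Lorentz convention.
    """
    freqs = []
    for ax, (n, v) in enumerate(zip(padded_shape, voxel_size)):
        if ax == len(padded_shape) - 1:
            f = sfft.rfftfreq(n, d=v)
        else:
            f = sfft.fftfreq(n, d=v)
        freqs.append(f.astype(dtype))
    kx = freqs[0][:, None, None]
    ky = freqs[1][None, :, None]
    kz = freqs[2][None, None, :]
    k2 = kx * kx + ky * ky + kz * kz
    kb = (kx, ky, kz)[b0_axis]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (kb * kb) / k2
    d[k2 == 0] = 0.0
    return d


def _pad_shape(shape, pad_factor):
    return tuple(int(np.ceil(n * pad_factor)) for n in shape)


def dipole_convolve(
    chi: np.ndarray,
    grid: GridMeta,
    pad_factor: float = 2.0,
    kernel_ft: np.ndarray | None = None,
    dtype=np.float64,
) -> np.ndarray:
    """Field (same units as chi) induced by a susceptibility distribution.

    Zero-padding by ``pad_factor`` suppresses FFT wrap-around; sources are
    assumed compactly supported (zero background).
    """
    chi = np.asarray(chi, dtype=dtype)
    pshape = _pad_shape(chi.shape, pad_factor)
    if kernel_ft is None:
        kernel_ft = dipole_kernel_ft(pshape, grid.voxel_size, grid.b0_axis,
                                     dtype=dtype)
    spec = sfft.rfftn(chi, s=pshape)
    spec *= kernel_ft
    out = sfft.irfftn(spec, s=pshape)
    sl = tuple(slice(0, n) for n in chi.shape)
    return np.ascontiguousarray(out[sl])


def make_dipole_op(grid: GridMeta, shape=None, pad_factor: float = 2.0,
                   dtype=np.float64, inverse: bool = False,
                   delta: float = 0.1):
    """Return a closure applying the dipole convolution with a cached kernel.

    The dipole operator is real, even and therefore self-adjoint; iterative
    solvers (PDF, regularized inversion, field completion) reuse the cached
    kernel spectrum. With ``inverse=True`` the closure applies the
    truncated-inverse kernel (|D| clipped at `delta`) instead.
    """
    shape = tuple(shape if shape is not None else grid.shape)
    pshape = _pad_shape(shape, pad_factor)
    kernel = dipole_kernel_ft(pshape, grid.voxel_size, grid.b0_axis, dtype=dtype)
    if inverse:
        sgn = np.where(kernel >= 0, 1.0, -1.0).astype(dtype)
        kernel = 1.0 / np.where(np.abs(kernel) < delta, sgn * delta, kernel)
    sl = tuple(slice(0, n) for n in shape)

    def apply(vol: np.ndarray) -> np.ndarray:
        spec = sfft.rfftn(np.asarray(vol, dtype=dtype), s=pshape)
        spec *= kernel
        out = sfft.irfftn(spec, s=pshape)
        return np.ascontiguousarray(out[sl])

    return apply
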