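"""Cross-hair (orthogonal-plane) approximation of 3-D convolution.

A full 3-D convolution correlates a volume with a dense ``(k_x, k_y, k_z)``
kernel. The cross-hair operator replaces the dense kernel with three 2-D
kernels living on the orthogonal planes through each voxel::

    out[i,j,k] =  beta_c * (slice i  ** M_i)      # (k_y x k_z) plane
                + beta_s * (slice j  ** M_j)      # (k_x x k_z) plane
                + beta_a * (slice k  ** M_k)      # (k_x x k_y) plane

which drops the per-voxel multiplication count from ``k_x*k_y*k_z`` to
``k_y*k_z + k_x*k_z + k_x*k_y``.

Index convention: correlation (no kernel flip), kernel centered at
``floor(k/2)`` along each axis, zero padding so output shape equals input
shape. Accumulation is double precision regardless of input dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "Kernel3D",
    "CrossHairKernel",
    "OpCountReport",
    "CountInequalityReport",
    "convolve_full",
    "convolve_crosshair_pointwise",
    "convolve_crosshair",
    "count_ops_full",
    "count_ops_crosshair",
    "verify_count_inequality",
]


@dataclass
class Kernel3D:
    """Dense 3-D correlation kernel of shape ``(k_x, k_y, k_z)``."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError(f"expected 3-D kernel, got ndim={self.weights.ndim}")
        if min(self.weights.shape) < 1:
            raise ValueError(f"kernel sides must be >= 1, got {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.weights.shape


@dataclass
class CrossHairKernel:
    """Triplet of 2-D plane kernels with plane weights.

    ``M_i`` acts on the (j,k) plane, ``M_j`` on the (i,k) plane and ``M_k``
    on the (i,j) plane; their shapes must be consistent with a single
    underlying ``(k_x, k_y, k_z)``. Plane weights default to 1 and exist to
    de-weight planes with coarser spatial resolution.
    """

    M_i: np.ndarray  # (k_y, k_z)
    M_j: np.ndarray  # (k_x, k_z)
    M_k: np.ndarray  # (k_x, k_y)
    beta_c: float = 1.0
    beta_s: float = 1.0
    beta_a: float = 1.0

    def __post_init__(self) -> None:
        self.M_i = np.asarray(self.M_i, dtype=np.float64)
        self.M_j = np.asarray(self.M_j, dtype=np.float64)
        self.M_k = np.asarray(self.M_k, dtype=np.float64)
        for name, m in (("M_i", self.M_i), ("M_j", self.M_j), ("M_k", self.M_k)):
            if m.ndim != 2:
                raise ValueError(f"{name} must be 2-D, got ndim={m.ndim}")
        kx, ky, kz = self.kernel_shape  # raises on inconsistency
        for b in (self.beta_c, self.beta_s, self.beta_a):
            if not np.isfinite(b):
                raise ValueError("plane weights must be finite")

    @property
    def kernel_shape(self) -> tuple[int, int, int]:
        """The implied dense kernel shape ``(k_x, k_y, k_z)``."""
        ky, kz = self.M_i.shape
        kx, kz2 = self.M_j.shape
        kx2, ky2 = self.M_k.shape
        if kz2 != kz or kx2 != kx or ky2 != ky:
            raise ValueError(
                "inconsistent plane shapes: "
                f"M_i={self.M_i.shape}, M_j={self.M_j.shape}, M_k={self.M_k.shape}"
            )
        return (kx, ky, kz)


@dataclass
class OpCountReport:
    """Multiplication/addition counts of a convolution variant."""

    multiplications: int
    additions: int
    per_voxel: bool

    def __post_init__(self) -> None:
        if self.multiplications < 0 or self.additions < 0:
            raise ValueError("operation counts must be non-negative")
        if self.per_voxel and self.multiplications >= 1:
            assert self.additions == self.multiplications - 1

    def as_dict(self) -> dict:
        return {
            "multiplications": self.multiplications,
            "additions": self.additions,
            "per_voxel": self.per_voxel,
        }


def _unwrap(I) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    if isinstance(I, Volume3D):
        return np.asarray(I.data, dtype=np.float64), I.spacing
    arr = np.asarray(I, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={arr.ndim}")
    return arr, None


def _rewrap(out: np.ndarray, spacing) -> Volume3D | np.ndarray:
    if spacing is None:
        return out
    return Volume3D(out, spacing)


def _check_kernel_fits(kshape, vshape) -> None:
    if any(k > n for k, n in zip(kshape, vshape)):
        raise ValueError(f"kernel {kshape} larger than volume {vshape}")


def convolve_full(I, M) -> Volume3D | np.ndarray:
    """Full 3-D correlation of a volume with a dense kernel.

    Zero padding, same-size output, kernel centered at ``floor(k/2)`` per
    axis. Serves as the exact reference the cross-hair operator
    approximates.
    """
    arr, spacing = _unwrap(I)
    kernel = M if isinstance(M, Kernel3D) else Kernel3D(M)
    _check_kernel_fits(kernel.shape, arr.shape)
    out = ndimage.correlate(arr, kernel.weights, mode="constant", cval=0.0)
    return _rewrap(out, spacing)


def convolve_crosshair_pointwise(I, K: CrossHairKernel) -> Volume3D | np.ndarray:
    """Per-voxel evaluation of the cross-hair sum.

    Literal triple loop over voxels with explicit plane sums. Quadratic-in-
    kernel, cubic-in-volume Python loops: intended as a readable reference
    and oracle for :func:`convolve_crosshair`, not for production use.
    """
    arr, spacing = _unwrap(I)
    kx, ky, kz = K.kernel_shape
    _check_kernel_fits((kx, ky, kz), arr.shape)
    ni, nj, nk = arr.shape
    cx, cy, cz = kx // 2, ky // 2, kz // 2
    out = np.zeros((ni, nj, nk), dtype=np.float64)

    def at(i, j, k):
        if 0 <= i < ni and 0 <= j < nj and 0 <= k < nk:
            return arr[i, j, k]
        return 0.0

    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                acc = 0.0
                for s in range(ky):
                    for t in range(kz):
                        acc += K.beta_c * at(i, j + s - cy, k + t - cz) * K.M_i[s, t]
                for r in range(kx):
                    for t in range(kz):
                        acc += K.beta_s * at(i + r - cx, j, k + t - cz) * K.M_j[r, t]
                for r in range(kx):
                    for s in range(ky):
                        acc += K.beta_a * at(i + r - cx, j + s - cy, k) * K.M_k[r, s]
                out[i, j, k] = acc
    return _rewrap(out, spacing)


def convolve_crosshair(I, K: CrossHairKernel) -> Volume3D | np.ndarray:
    """Efficient cross-hair correlation via three slice-stack 2-D passes.

    Each plane kernel is applied as a degenerate 3-D kernel (one singleton
    axis), so every pass is a single strided correlation over the whole
    stack of slices; only one volume copy is held at a time.
    """
    arr, spacing = _unwrap(I)
    kx, ky, kz = K.kernel_shape
    _check_kernel_fits((kx, ky, kz), arr.shape)

    out = K.beta_c * ndimage.correlate(
        arr, K.M_i[np.newaxis, :, :], mode="constant", cval=0.0
    )
    out += K.beta_s * ndimage.correlate(
        arr, K.M_j[:, np.newaxis, :], mode="constant", cval=0.0
    )
    out += K.beta_a * ndimage.correlate(
        arr, K.M_k[:, :, np.newaxis], mode="constant", cval=0.0
    )
    return _rewrap(out, spacing)


def _validate_kernel_shape(kernel_shape) -> tuple[int, int, int]:
    ks = tuple(int(k) for k in kernel_shape)
    if len(ks) != 3 or any(k < 1 for k in ks):
        raise ValueError(f"kernel shape must be three positive sides, got {kernel_shape}")
    return ks


def _voxel_count(volume_shape) -> int:
    vs = tuple(int(n) for n in volume_shape)
    if len(vs) != 3 or any(n < 1 for n in vs):
        raise ValueError(f"volume shape must be three positive sides, got {volume_shape}")
    return vs[0] * vs[1] * vs[2]


def count_ops_full(kernel_shape, volume_shape=None) -> OpCountReport:
    """Closed-form cost of full 3-D convolution.

    Per voxel: ``k_x*k_y*k_z`` multiplications and one fewer additions.
    With ``volume_shape`` given, totals scale by the voxel count.
    """
    kx, ky, kz = _validate_kernel_shape(kernel_shape)
    mult = kx * ky * kz
    add = mult - 1
    if volume_shape is None:
        return OpCountReport(mult, add, per_voxel=True)
    n = _voxel_count(volume_shape)
    return OpCountReport(mult * n, add * n, per_voxel=False)


def count_ops_crosshair(kernel_shape, volume_shape=None) -> OpCountReport:
    """Closed-form cost of the cross-hair approximation.

    Per voxel: ``k_y*k_z + k_x*k_z + k_x*k_y`` multiplications and one fewer
    additions.
    """
    kx, ky, kz = _validate_kernel_shape(kernel_shape)
    mult = ky * kz + kx * kz + kx * ky
    add = mult - 1
    if volume_shape is None:
        return OpCountReport(mult, add, per_voxel=True)
    n = _voxel_count(volume_shape)
    return OpCountReport(mult * n, add * n, per_voxel=False)


@dataclass
class CountInequalityReport:
    """Result of checking the cost-ordering chain for one kernel shape.

    The chain ``k_y*k_z + k_x*k_z + k_x*k_y <= 3*k_m1*k_m2 <= k_x*k_y*k_z``
    (sides sorted so ``k_m1 >= k_m2 >= k_m3``) requires ``k_m3 >= 3`` for
    its second link; ``applicable`` is False below that domain.
    """

    kernel_shape: tuple[int, int, int]
    crosshair_mult: int
    middle_bound: int
    full_mult: int
    holds: bool
    strict: bool
    applicable: bool
    margin: int = field(init=False)

    def __post_init__(self) -> None:
        self.margin = self.full_mult - self.crosshair_mult


def verify_count_inequality(kernel_shape) -> CountInequalityReport:
    """Check the operation-count ordering for a kernel shape.

    Returns whether the two-link chain holds and whether the second link is
    strict. Strictness is guaranteed whenever the smallest side exceeds 3;
    at a smallest side of exactly 3 the chain collapses to equalities.
    """
    kx, ky, kz = _validate_kernel_shape(kernel_shape)
    km1, km2, km3 = sorted((kx, ky, kz), reverse=True)
    crosshair = ky * kz + kx * kz + kx * ky
    middle = 3 * km1 * km2
    full = kx * ky * kz
    holds = crosshair <= middle <= full
    strict = middle < full
    return CountInequalityReport(
        kernel_shape=(kx, ky, kz),
        crosshair_mult=crosshair,
        middle_bound=middle,
        full_mult=full,
        holds=holds,
        strict=strict,
        applicable=km3 >= 3,
    )
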