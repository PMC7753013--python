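"""Basic 3-D scalar volume container.

Axis convention: axis 0 = sagittal index i, axis 1 = coronal index j,
axis 2 = axial index k. Indexing is 0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume3D"]


@dataclass
class Volume3D:
    """A 3-D scalar grid with voxel spacing.

    Carrier of images, probability maps, and binary masks.

    Parameters
    ----------
    data : ndarray, shape (n_i, n_j, n_k)
        Scalar value per voxel. Stored as a contiguous float or integer array.
    spacing : tuple of float, optional
        Physical edge length of a voxel along each axis. Defaults to
        isotropic unit spacing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume data must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype(self, dtype) -> "Volume3D":
        return Volume3D(self.data.astype(dtype), self.spacing)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, Volume3D):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
            and self.spacing == other.spacing
        )
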