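"""Core in-memory containers for 3D OCT volumes and vascular masks.

Axis convention throughout the package: arrays are indexed ``(z, x, y)``
where ``z`` is depth (index 0 = glass/tissue interface, increasing
downward), ``x`` is the fast lateral axis within a B-scan, and ``y`` is the
slow lateral axis (one index per B-scan position).  Physical coordinates
are voxel centers: voxel ``i`` along an axis with spacing ``s`` sits at
``(i + 0.5) * s`` micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Volume", "BinaryVascularMask", "VOIMask", "BScanSeries"]

Spacing = tuple[float, float, float]


def _validate_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)  # type: ignore[assignment]
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing!r}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar volume with per-axis voxel spacing in micrometres.

    Parameters
    ----------
    data
        Array of shape ``(nz, nx, ny)``.
    spacing
        Voxel spacing ``(dz, dx, dy)`` in micrometres.
    meta
        Free-form metadata (provenance, processing parameters, ...).
    """

    data: np.ndarray
    spacing: Spacing
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        dz, dx, dy = self.spacing
        return np.isclose(dz, dx) and np.isclose(dx, dy)

    def depth_coords(self) -> np.ndarray:
        """Physical depth (μm) of each z slice, measured at voxel centers."""
        nz = self.data.shape[0]
        return (np.arange(nz) + 0.5) * self.spacing[0]

    def copy_with(self, data: np.ndarray, **meta: Any) -> "Volume":
        merged = {**self.meta, **meta}
        return type(self)(data=data, spacing=self.spacing, meta=merged)


class BinaryVascularMask(Volume):
    """A boolean 3D vessel map.  ``True`` marks vessel voxels."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)

    def vessel_fraction(self) -> float:
        return float(self.data.mean())


class VOIMask(Volume):
    """A boolean volume of interest (tumour region) on the same grid as
    the volume it masks.  Must be non-empty."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        if not self.data.any():
            raise ValueError("VOI mask is empty")


@dataclass
class BScanSeries:
    """Repeated same-position B-scans: intensities of shape
    ``(depth, width, frames)`` plus spacings.

    The frame axis holds the M sequentially acquired B-scans whose
    inter-frame speckle decorrelation carries the angiographic contrast.
    """

    intensities: np.ndarray
    axial_spacing: float
    lateral_spacing: float
    frame_interval_ms: float = 25.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected (depth, width, frames), got shape {self.intensities.shape}"
            )
        if self.intensities.shape[2] < 2:
            raise ValueError("at least 2 frames are required")
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[2]
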