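"""Shared volumetric containers.

Arrays are indexed (slice, row, col) = (z, y, x); voxels are isotropic and
sized in millimetres. ``ScalarVolume`` is the universal image container for
MR echoes, microCT intensities and ground-truth partial-volume maps;
``DualEchoVolume`` bundles the two co-registered UTE echoes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ScalarVolume", "DualEchoVolume", "MicrostructureGrid", "block_ratio"]


def block_ratio(coarse_voxel: float, fine_voxel: float) -> int:
    """Integer coarse/fine voxel-size ratio, or raise if not integral."""
    ratio = coarse_voxel / fine_voxel
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"coarse voxel {coarse_voxel} mm is not an integer multiple of "
            f"fine voxel {fine_voxel} mm"
        )
    return k


@dataclass
class ScalarVolume:
    """A 3-D grid of nonnegative intensities with isotropic voxel size.

    Parameters
    ----------
    intensities:
        ``(nz, ny, nx)`` array of finite, nonnegative values.
    voxel_size:
        Isotropic voxel edge length in mm.
    modality:
        One of ``"MR_echo"``, ``"uCT"``, ``"truth_fraction"``.
    meta:
        Free-form acquisition annotations (echo time, noise level, ...).
    """

    intensities: np.ndarray
    voxel_size: float
    modality: str = "MR_echo"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.size and self.intensities.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class DualEchoVolume:
    """Two co-registered UTE echoes with their echo times in ms."""

    echo1: ScalarVolume
    echo2: ScalarVolume
    te_pair: tuple[float, float]

    def __post_init__(self) -> None:
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echoes must share a shape")
        if self.echo1.voxel_size != self.echo2.voxel_size:
            raise ValueError("echoes must share a voxel size")
        te1, te2 = self.te_pair
        if not (0 < te1 < te2):
            raise ValueError("te_pair must be strictly increasing and positive")

    @property
    def voxel_size(self) -> float:
        return self.echo1.voxel_size

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.echo1.shape


@dataclass
class MicrostructureGrid:
    """Fine-resolution binary bone/marrow grid: the ground-truth specimen.

    ``bone_mask`` holds 1 for bone and 0 for marrow; ``bvtv_true`` is the
    exact bone-voxel fraction and is computed at construction from integer
    counts, never stored independently.
    """

    bone_mask: np.ndarray
    voxel_size: float
    specimen_id: str = "phantom"
    bvtv_true: float = field(init=False)

    MIN_AXIS = 32

    def __post_init__(self) -> None:
        mask = np.asarray(self.bone_mask)
        if mask.ndim != 3:
            raise ValueError("bone_mask must be 3-D")
        if min(mask.shape) < self.MIN_AXIS:
            raise ValueError(
                f"grid must have at least {self.MIN_AXIS} voxels per axis, "
                f"got {mask.shape}"
            )
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("bone_mask must contain only 0 and 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.bone_mask = mask.astype(np.uint8)
        self.bvtv_true = float(int(self.bone_mask.sum()) / self.bone_mask.size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bone_mask.shape  # type: ignore[return-value]
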