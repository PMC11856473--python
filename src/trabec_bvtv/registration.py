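"""Corner-landmark 2D registration and MR-to-microCT slice pairing.

MR analysis regions are mapped onto the microCT frame with a similarity
transform (rotation + isotropic scale + translation) fitted by least squares
to matched corner landmarks picked on both modalities. A similarity is the
right family for a rigid cube imaged by two calibrated scanners: rotation
and translation, plus a scale term as a safety factor; a full affine would
be under-constrained by 2-4 corners.

Through-plane correspondence is a fixed thickness ratio: each 0.5 mm MR
slice covers k = 10 consecutive 0.05 mm microCT slices, and the microCT
BVTV paired with an MR slice is the mean over its k slices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bvtv import ROISpec

__all__ = [
    "LandmarkSet",
    "Transform2D",
    "SliceCorrespondence",
    "PairedMeasurement",
    "fit_similarity",
    "map_roi",
    "pair_measurements",
]

#: Default gate on landmark fit RMSE before an ROI may be mapped: half an MR voxel.
DEFAULT_RMSE_GATE_MM = 0.25


@dataclass(frozen=True)
class LandmarkSet:
    """Matched corner points, in mm, on the MR and microCT image planes."""

    mr_points: np.ndarray
    uct_points: np.ndarray
    slice_link: tuple[int, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        mr = np.atleast_2d(np.asarray(self.mr_points, dtype=float))
        uct = np.atleast_2d(np.asarray(self.uct_points, dtype=float))
        if mr.shape != uct.shape or mr.shape[1] != 2:
            raise ValueError("mr_points and uct_points must be matching (n, 2) arrays")
        if mr.shape[0] < 2:
            raise ValueError("at least 2 landmark pairs are required")
        for pts, name in ((mr, "MR"), (uct, "microCT")):
            d = pts[:, None, :] - pts[None, :, :]
            dist = np.sqrt((d**2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            if dist.min() < 1e-12:
                raise ValueError(f"coincident {name} landmarks")
        if mr.shape[0] >= 3 and _collinear(mr):
            warnings.warn(
                "landmarks are (near-)collinear; similarity fit is ill-conditioned",
                stacklevel=2,
            )
        object.__setattr__(self, "mr_points", mr)
        object.__setattr__(self, "uct_points", uct)

    @property
    def n(self) -> int:
        return self.mr_points.shape[0]


def _collinear(pts: np.ndarray, tol: float = 1e-8) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[-1] <= tol * max(s[0], 1.0))


@dataclass(frozen=True)
class Transform2D:
    """Similarity transform x' = s R(theta) x + t, with fit residual."""

    rotation: float
    scale: float
    translation: tuple[float, float]
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not math.isfinite(self.rmse):
            raise ValueError("rmse must be finite")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "Transform2D":
        inv_t = -np.linalg.solve(self.matrix, np.asarray(self.translation))
        return Transform2D(
            rotation=-self.rotation,
            scale=1.0 / self.scale,
            translation=(float(inv_t[0]), float(inv_t[1])),
            rmse=self.rmse,
        )


def fit_similarity(landmarks: LandmarkSet) -> Transform2D:
    """Least-squares similarity transform mapping MR landmarks onto microCT.

    Solved via the linear parametrisation (a, b, tx, ty) with
    x' = a x - b y + tx, y' = b x + a y + ty, which is the exact
    least-squares similarity fit (equivalent to the closed-form Procrustes
    solution). Exact (zero residual) with two distinct pairs.
    """
    src = landmarks.mr_points
    dst = landmarks.uct_points
    n = landmarks.n
    design = np.zeros((2 * n, 4))
    design[0::2, 0] = src[:, 0]
    design[0::2, 1] = -src[:, 1]
    design[0::2, 2] = 1.0
    design[1::2, 0] = src[:, 1]
    design[1::2, 1] = src[:, 0]
    design[1::2, 3] = 1.0
    target = dst.reshape(-1)
    sol, *_ = np.linalg.lstsq(design, target, rcond=None)
    a, b, tx, ty = sol
    scale = math.hypot(a, b)
    if scale <= 0:
        raise ValueError("degenerate landmark configuration: zero scale")
    transform = Transform2D(
        rotation=math.atan2(b, a),
        scale=scale,
        translation=(float(tx), float(ty)),
    )
    resid = transform.apply(src) - dst
    rmse = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return Transform2D(
        rotation=transform.rotation,
        scale=transform.scale,
        translation=transform.translation,
        rmse=rmse,
    )


@dataclass(frozen=True)
class SliceCorrespondence:
    """MR slice i covers microCT slices [k*i, k*i + k - 1].

    k is the MR slice thickness over the microCT voxel size; the default
    0.5 mm / 0.05 mm gives k = 10.
    """

    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")

    @classmethod
    def from_voxel_sizes(cls, mr_voxel: float, uct_voxel: float) -> "SliceCorrespondence":
        return cls(k=int(round(mr_voxel / uct_voxel)))

    def uct_slices(self, mr_slice: int) -> range:
        return range(self.k * mr_slice, self.k * mr_slice + self.k)


def map_roi(
    roi: ROISpec,
    transform: Transform2D,
    corr: SliceCorrespondence,
    uct_voxel: float,
    uct_shape: tuple[int, int, int] | None = None,
    rmse_gate_mm: float = DEFAULT_RMSE_GATE_MM,
) -> list[ROISpec]:
    """Map an MR ROI into the microCT frame, one ROI per linked microCT slice.

    The four ROI corners (in mm, via the MR voxel size) are mapped through
    the transform; the axis-aligned bounding box of the mapped corners is
    taken (keeps ROIs rectangular) and converted to microCT voxel bounds.
    The transform's landmark RMSE must be below ``rmse_gate_mm``.
    """
    if transform.rmse > rmse_gate_mm:
        raise ValueError(
            f"transform RMSE {transform.rmse:.3g} mm exceeds gate {rmse_gate_mm} mm"
        )
    (r0, r1), (c0, c1) = roi.bounds
    v = roi.voxel_size
    corners_xy = np.array(
        [[c0 * v, r0 * v], [c1 * v, r0 * v], [c0 * v, r1 * v], [c1 * v, r1 * v]]
    )
    mapped = transform.apply(corners_xy)
    x0, y0 = mapped.min(axis=0)
    x1, y1 = mapped.max(axis=0)
    # floor(x + 0.5): round-half-up for deterministic voxel snapping
    br0 = int(math.floor(y0 / uct_voxel + 0.5))
    br1 = int(math.floor(y1 / uct_voxel + 0.5))
    bc0 = int(math.floor(x0 / uct_voxel + 0.5))
    bc1 = int(math.floor(x1 / uct_voxel + 0.5))
    uct_slices = corr.uct_slices(roi.slice_index)
    if uct_shape is not None:
        nz, ny, nx = uct_shape
        if br0 < 0 or bc0 < 0 or br1 > ny or bc1 > nx or uct_slices[-1] >= nz:
            raise ValueError(
                f"mapped ROI rows [{br0},{br1}) cols [{bc0},{bc1}) slices "
                f"{uct_slices} exceed microCT shape {uct_shape}"
            )
    return [
        ROISpec(
            specimen_id=roi.specimen_id,
            slice_index=z,
            bounds=((br0, br1), (bc0, bc1)),
            voxel_size=uct_voxel,
            margin_policy=roi.margin_policy,
        )
        for z in uct_slices
    ]


@dataclass(frozen=True)
class PairedMeasurement:
    """One (specimen, MR slice) row of the paired MR/microCT comparison."""

    specimen_id: str
    mr_slice: int
    bvtv_mr: float
    bvtv_uct: float

    def __post_init__(self) -> None:
        for name in ("bvtv_mr", "bvtv_uct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def pair_measurements(
    mr_means: Mapping[tuple[str, int], float],
    uct_means: Mapping[tuple[str, int], float],
    corr: SliceCorrespondence,
) -> list[PairedMeasurement]:
    """Pair each MR slice mean with the mean of its k microCT slice means.

    ``mr_means`` is keyed by (specimen_id, MR slice index); ``uct_means`` by
    (specimen_id, microCT slice index). A missing microCT slice raises an
    error naming the gap.
    """
    pairs: list[PairedMeasurement] = []
    for (specimen, mr_slice) in sorted(mr_means):
        uct_vals = []
        for z in corr.uct_slices(mr_slice):
            key = (specimen, z)
            if key not in uct_means:
                raise KeyError(
                    f"missing microCT slice {z} for specimen {specimen!r}, "
                    f"MR slice {mr_slice}"
                )
            uct_vals.append(uct_means[key])
        pairs.append(
            PairedMeasurement(
                specimen_id=specimen,
                mr_slice=mr_slice,
                bvtv_mr=float(mr_means[(specimen, mr_slice)]),
                bvtv_uct=float(np.mean(uct_vals)),
            )
        )
    return pairs
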