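"""Reading and writing volumes, tables and sidecars.

Volumes go to NIfTI (via nibabel, isotropic affine) or multi-page TIFF
(via tifffile, one page per slice); every NIfTI/TIFF written by this
package gets a YAML sidecar carrying the voxel size, modality and metadata
that the image header cannot hold. Tables (landmarks, per-slice BVTV,
paired measurements) are CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .registration import LandmarkSet, PairedMeasurement, Transform2D
from .volumes import MicrostructureGrid, ScalarVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "save_landmarks_csv",
    "load_landmarks_csv",
    "save_transform_yaml",
    "load_transform_yaml",
    "pairs_to_frame",
    "save_pairs_csv",
    "load_pairs_csv",
]


def _sidecar_path(path: Path) -> Path:
    stem = path.name.split(".")[0]
    return path.parent / f"{stem}.yaml"


def _write_sidecar(path: Path, voxel_size: float, modality: str, meta: Mapping[str, Any]) -> None:
    doc = {"voxel_size_mm": float(voxel_size), "modality": modality, "meta": dict(meta)}
    _sidecar_path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def save_volume(vol: ScalarVolume, path: str | Path, dtype=np.float32) -> Path:
    """Write a ScalarVolume as NIfTI (.nii/.nii.gz) or multi-page TIFF (.tif)."""
    path = Path(path)
    data = np.asarray(vol.intensities, dtype=dtype)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        affine = np.diag([vol.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(data, affine), path)
    _write_sidecar(path, vol.voxel_size, vol.modality, vol.meta)
    return path


def save_mask(grid: MicrostructureGrid, path: str | Path) -> Path:
    """Write a binary microstructure as uint8 NIfTI or TIFF, with sidecar."""
    vol = ScalarVolume(
        intensities=grid.bone_mask,
        voxel_size=grid.voxel_size,
        modality="truth_fraction",
        meta={"specimen_id": grid.specimen_id, "bvtv_true": grid.bvtv_true},
    )
    return save_volume(vol, path, dtype=np.uint8)


def load_volume(path: str | Path, voxel_size: float | None = None, modality: str | None = None) -> ScalarVolume:
    """Read a NIfTI or TIFF volume, preferring the YAML sidecar for metadata."""
    path = Path(path)
    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        doc = yaml.safe_load(sidecar.read_text())
        voxel_size = voxel_size or doc.get("voxel_size_mm")
        modality = modality or doc.get("modality")
        meta = doc.get("meta", {})
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path))
        if voxel_size is None:
            raise ValueError("TIFF carries no voxel size; pass voxel_size or provide a sidecar")
    else:
        img = nib.load(path)
        data = np.asarray(img.get_fdata())
        if voxel_size is None:
            zooms = img.header.get_zooms()[:3]
            voxel_size = float(zooms[0])
    return ScalarVolume(
        intensities=data,
        voxel_size=float(voxel_size),
        modality=modality or "MR_echo",
        meta=meta,
    )


def save_landmarks_csv(landmarks: LandmarkSet, path: str | Path, mr_slice: int = 0) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "x_mr": landmarks.mr_points[:, 0],
            "y_mr": landmarks.mr_points[:, 1],
            "x_uct": landmarks.uct_points[:, 0],
            "y_uct": landmarks.uct_points[:, 1],
            "mr_slice": mr_slice,
        }
    )
    df.to_csv(path, index=False)
    return path


def load_landmarks_csv(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(
        mr_points=df[["x_mr", "y_mr"]].to_numpy(),
        uct_points=df[["x_uct", "y_uct"]].to_numpy(),
    )


def save_transform_yaml(transform: Transform2D, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            {
                "rotation_rad": transform.rotation,
                "scale": transform.scale,
                "translation_mm": list(transform.translation),
                "rmse_mm": transform.rmse,
            }
        )
    )
    return path


def load_transform_yaml(path: str | Path) -> Transform2D:
    doc = yaml.safe_load(Path(path).read_text())
    return Transform2D(
        rotation=float(doc["rotation_rad"]),
        scale=float(doc["scale"]),
        translation=tuple(float(t) for t in doc["translation_mm"]),
        rmse=float(doc["rmse_mm"]),
    )


def pairs_to_frame(pairs: Sequence[PairedMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": [p.specimen_id for p in pairs],
            "mr_slice": [p.mr_slice for p in pairs],
            "bvtv_mr": [p.bvtv_mr for p in pairs],
            "bvtv_uct": [p.bvtv_uct for p in pairs],
        }
    )


def save_pairs_csv(pairs: Sequence[PairedMeasurement], path: str | Path) -> Path:
    path = Path(path)
    pairs_to_frame(pairs).to_csv(path, index=False, float_format="%.10g")
    return path


def load_pairs_csv(path: str | Path) -> list[PairedMeasurement]:
    df = pd.read_csv(path)
    return [
        PairedMeasurement(
            specimen_id=str(row.specimen_id),
            mr_slice=int(row.mr_slice),
            bvtv_mr=float(row.bvtv_mr),
            bvtv_uct=float(row.bvtv_uct),
        )
        for row in df.itertuples()
    ]
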