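"""File exchange: NIfTI volumes, YAML phantom specs, CSV cohort manifests."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import PhantomSpec, VoxelVolume, true_defect_area
from .segmentation import BoneMask

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_mask_nifti",
    "spec_to_yaml",
    "spec_from_yaml",
    "write_cohort_manifest",
    "read_cohort_manifest",
]


def write_nifti(volume: VoxelVolume, path: str | Path) -> None:
    """Write an HU volume as float32 NIfTI; spacing goes into the affine diagonal."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> VoxelVolume:
    """Read a NIfTI volume back; float32 HU grid and spacing are preserved bit-exactly."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(values=values, spacing=spacing)


def write_mask_nifti(mask: BoneMask, path: str | Path) -> None:
    """Write a bone mask as uint8 NIfTI."""
    affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def spec_to_yaml(spec: PhantomSpec, path: str | Path | None = None) -> str:
    """Serialize a phantom spec to YAML; optionally write it to ``path``."""
    d = asdict(spec)
    d["voxel_spacing_mm"] = list(d["voxel_spacing_mm"])
    d["volume_extent_mm"] = list(d["volume_extent_mm"])
    text = yaml.safe_dump(d, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def spec_from_yaml(source: str | Path) -> PhantomSpec:
    """Load a phantom spec from a YAML string or file path."""
    text = str(source)
    if "\n" not in text:
        p = Path(text)
        if p.is_file():
            text = p.read_text()
    d = yaml.safe_load(text)
    d["voxel_spacing_mm"] = tuple(d["voxel_spacing_mm"])
    d["volume_extent_mm"] = tuple(d["volume_extent_mm"])
    return PhantomSpec(**d)


def write_cohort_manifest(specs: list[PhantomSpec], path: str | Path) -> pd.DataFrame:
    """One row per case: id, spec parameters and the analytic true area."""
    rows = []
    for i, spec in enumerate(specs):
        d = asdict(spec)
        d["voxel_spacing_mm"] = "x".join(str(v) for v in d["voxel_spacing_mm"])
        d["volume_extent_mm"] = "x".join(str(v) for v in d["volume_extent_mm"])
        rows.append({"case_id": f"case{i:04d}", **d, "true_area_3d": true_defect_area(spec)})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_cohort_manifest(path: str | Path) -> list[PhantomSpec]:
    """Rebuild phantom specs from a cohort manifest CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    specs = []
    for _, row in df.iterrows():
        kwargs = {
            k: row[k]
            for k in PhantomSpec.__dataclass_fields__
            if k not in ("voxel_spacing_mm", "volume_extent_mm")
        }
        kwargs["seed"] = int(row["seed"])
        kwargs["voxel_spacing_mm"] = tuple(float(v) for v in str(row["voxel_spacing_mm"]).split("x"))
        kwargs["volume_extent_mm"] = tuple(float(v) for v in str(row["volume_extent_mm"]).split("x"))
        specs.append(PhantomSpec(**kwargs))
    return specs
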