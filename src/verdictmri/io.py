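"""NIfTI volume I/O, matched-b0 normalisation and ROI summaries."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datasets import DEFAULT_AFFINE, ParameterMaps, VoxelDataset, volume_layout
from .scheme import AcquisitionScheme

__all__ = [
    "read_dwi",
    "write_dwi",
    "write_maps",
    "read_maps",
    "dataset_to_volume",
    "roi_summary",
]


def dataset_to_volume(dataset: VoxelDataset) -> np.ndarray:
    """Scatter a voxel dataset back onto its 4-D grid (NaN outside the mask)."""
    vol = np.full(dataset.shape + (dataset.n_volumes,), np.nan)
    vol[tuple(dataset.coords.T)] = dataset.signals
    return vol


def write_dwi(
    dataset: VoxelDataset, path: str | Path, affine: np.ndarray | None = None
) -> None:
    """Write the (normalised) 4-D signal volume of a dataset as NIfTI-1."""
    vol = dataset_to_volume(dataset)
    nib.save(nib.Nifti1Image(vol.astype(np.float32),
                             DEFAULT_AFFINE if affine is None else affine), str(path))


def read_dwi(
    path: str | Path,
    scheme: AcquisitionScheme,
    mask: np.ndarray | str | Path | None = None,
) -> VoxelDataset:
    """Load a 4-D DWI volume and apply matched-b0 normalisation.

    The 4th dimension must equal the scheme's volume count, in combo-major
    order (b0 then spherically-averaged DW per combo).  Each DW volume is
    divided by its matched b0; voxels whose b0 is zero (or non-finite) are
    dropped with a warning stating how many.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got {data.ndim}-D")
    if data.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"4th dimension is {data.shape[3]} but the scheme expects "
            f"{scheme.n_volumes} volumes"
        )
    if mask is None:
        mask_arr = np.all(np.isfinite(data), axis=3)
    else:
        if isinstance(mask, (str, Path)):
            mask_arr = np.asarray(nib.load(str(mask)).dataobj) > 0
        else:
            mask_arr = np.asarray(mask, bool)
        if mask_arr.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask_arr.shape} does not match volume "
                f"{data.shape[:3]}"
            )
        mask_arr = mask_arr & np.all(np.isfinite(data), axis=3)

    coords = np.argwhere(mask_arr)
    sig = data[mask_arr]  # (n, n_volumes)
    b0_idx, dw_idx = volume_layout(scheme)
    b0 = sig[:, b0_idx]
    good = np.all(b0 > 0, axis=1)
    n_dropped = int((~good).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} voxels with zero or invalid b0")
    sig, coords = sig[good], coords[good]
    norm = np.ones_like(sig)
    norm[:, dw_idx] = sig[:, dw_idx] / sig[:, b0_idx]
    # clip away non-positive normalised values (rectified noise floor)
    norm[:, dw_idx] = np.clip(norm[:, dw_idx], 1e-6, None)
    return VoxelDataset(
        signals=norm, coords=coords, shape=data.shape[:3], mask_id=None
    )


def write_maps(maps: ParameterMaps, out_dir: str | Path) -> list[Path]:
    """Write one NIfTI per parameter map; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in maps.names():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(maps[name].astype(np.float32), maps.affine), str(p))
        paths.append(p)
    return paths


def read_maps(out_dir: str | Path, names: list[str]) -> ParameterMaps:
    out_dir = Path(out_dir)
    vols = {}
    affine = None
    for name in names:
        img = nib.load(str(out_dir / f"{name}.nii.gz"))
        vols[name] = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    mask = np.all([np.isfinite(v) for v in vols.values()], axis=0)
    return ParameterMaps(maps=vols, mask=mask, affine=affine)


def roi_summary(maps: ParameterMaps, mask: np.ndarray) -> pd.DataFrame:
    """Per-parameter mean, SD and voxel count over a region of interest."""
    mask = np.asarray(mask, bool)
    if mask.shape != maps.mask.shape:
        raise ValueError("ROI mask shape does not match maps")
    roi = mask & maps.mask
    n = int(roi.sum())
    if n == 0:
        raise ValueError("empty ROI: no voxels inside both mask and maps")
    rows = []
    for name in maps.names():
        vals = maps[name][roi]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n_voxels": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
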