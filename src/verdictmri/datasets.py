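"""In-memory containers shared across the fitting and simulation modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import AcquisitionScheme

__all__ = ["VoxelDataset", "ParameterMaps", "volume_layout"]


def volume_layout(scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """Volume ordering convention for a matched-b0 scheme.

    Volumes are combo-major: index 2i is the b0 of combo i, index 2i+1 the
    spherically-averaged DW volume of combo i.  Returns (b0_idx, dw_idx).
    """
    n = scheme.n_combos
    idx = np.arange(n)
    return 2 * idx, 2 * idx + 1


@dataclass
class VoxelDataset:
    """Masked, matched-b0-normalised voxel signals for one subject.

    signals : (n_voxels, n_volumes) array; b0 columns are exactly 1 after
        dividing each volume by its matched b0.
    coords : (n_voxels, 3) integer voxel coordinates into ``shape``.
    shape : 3-D grid shape the coordinates index.
    mask_id : per-voxel integer label (ROI / tissue class id), or None.
    dw_directions : optional (n_voxels, n_dw) direction-resolved normalised DW
        measurements (3 per combo, combo-major), used by protocol selection.
    """

    signals: np.ndarray
    coords: np.ndarray
    shape: tuple[int, int, int]
    mask_id: np.ndarray | None = None
    dw_directions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (n_voxels, n_volumes)")
        if self.coords.shape != (self.signals.shape[0], 3):
            raise ValueError("coords must be (n_voxels, 3)")
        if not np.all(np.isfinite(self.signals)) or np.any(self.signals <= 0):
            raise ValueError("signals must be finite and positive")

    @property
    def n_voxels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[1]

    def validate_against(self, scheme: AcquisitionScheme) -> None:
        if self.n_volumes != scheme.n_volumes:
            raise ValueError(
                f"dataset has {self.n_volumes} volumes, scheme expects "
                f"{scheme.n_volumes}"
            )
        b0_idx, _ = volume_layout(scheme)
        if not np.allclose(self.signals[:, b0_idx], 1.0):
            raise ValueError("b0 columns must be exactly 1 after normalisation")


# NIfTI affine for the study's voxel grid: 1.25 x 1.25 x 5 mm
DEFAULT_AFFINE = np.diag([1.25, 1.25, 5.0, 1.0])


@dataclass
class ParameterMaps:
    """Named voxelwise parameter volumes sharing one geometry.

    maps : name -> 3-D float array; out-of-mask voxels carry NaN.
    mask : boolean 3-D array of fitted voxels.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: DEFAULT_AFFINE.copy())
    loss_trace: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for name, vol in self.maps.items():
            if vol.shape != self.mask.shape:
                raise ValueError(
                    f"map {name!r} shape {vol.shape} != mask shape {self.mask.shape}"
                )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def names(self) -> list[str]:
        return list(self.maps)

    def masked_values(self, name: str) -> np.ndarray:
        return self.maps[name][self.mask]

    @staticmethod
    def from_voxels(
        values: dict[str, np.ndarray],
        coords: np.ndarray,
        shape: tuple[int, int, int],
        affine: np.ndarray | None = None,
        **kwargs,
    ) -> "ParameterMaps":
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(coords.T)] = True
        maps = {}
        for name, vec in values.items():
            vol = np.full(shape, np.nan)
            vol[tuple(coords.T)] = vec
            maps[name] = vol
        affine = DEFAULT_AFFINE.copy() if affine is None else affine
        return ParameterMaps(maps=maps, mask=mask, affine=affine, **kwargs)
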