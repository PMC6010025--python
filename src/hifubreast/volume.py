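"""Voxel-lattice containers shared by the phantom, segmentation and acoustics stages.

Index order is (x, y, z) with z the anterior beam axis; world coordinates are
millimetres measured at voxel centers (NIfTI convention), ``world = origin_mm +
index * voxel_mm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum

import nibabel as nib
import numpy as np
from scipy import ndimage


class Tissue(IntEnum):
    """Voxel labels of the segmented breast phantom.

    Air is treated as water for the acoustic stage, hence the single WATER
    label for both.
    """

    WATER = 0
    SKIN = 1
    FAT = 2
    GLAND = 3


#: Sentinel brightness marking skin in the intermediate working volume.
SKIN_SENTINEL = -1.0


@dataclass
class BrightnessVolume:
    """A 3-D (or 2-D cross-section) scalar brightness lattice.

    values are arbitrary MRI-like brightness units, non-negative for raw
    data; the segmentation stage reserves ``-1`` as the skin sentinel.
    """

    values: np.ndarray
    voxel_mm: np.ndarray
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=np.float64).reshape(-1)
        if self.voxel_mm.size == 1:
            self.voxel_mm = np.repeat(self.voxel_mm, self.values.ndim)
        if self.origin_mm is None:
            self.origin_mm = np.zeros(self.values.ndim)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(-1)
        if np.any(self.voxel_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("brightness values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def copy(self) -> "BrightnessVolume":
        return replace(self, values=self.values.copy())

    def world_coords(self, index: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(index) * self.voxel_mm


@dataclass
class TissueLabelVolume:
    """Voxelwise tissue labels on the same lattice as the source brightness."""

    labels: np.ndarray
    voxel_mm: np.ndarray
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=np.float64).reshape(-1)
        if self.voxel_mm.size == 1:
            self.voxel_mm = np.repeat(self.voxel_mm, self.labels.ndim)
        if self.origin_mm is None:
            self.origin_mm = np.zeros(self.labels.ndim)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(-1)
        valid = set(int(t) for t in Tissue)
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown labels {present - valid}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


def _affine(voxel_mm: np.ndarray, origin_mm: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_mm[:3])
    aff[:3, 3] = origin_mm[:3]
    return aff


def save_nifti(vol: BrightnessVolume | TissueLabelVolume, path: str) -> None:
    data = vol.values if isinstance(vol, BrightnessVolume) else vol.labels
    img = nib.Nifti1Image(np.asarray(data), _affine(vol.voxel_mm, vol.origin_mm))
    img.header.set_zooms(tuple(vol.voxel_mm[: data.ndim]))
    nib.save(img, path)


def load_brightness(path: str) -> BrightnessVolume:
    img = nib.load(path)
    vox = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return BrightnessVolume(np.asarray(img.dataobj, dtype=np.float64), vox, origin)


def load_labels(path: str) -> TissueLabelVolume:
    img = nib.load(path)
    vox = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return TissueLabelVolume(np.rint(np.asarray(img.dataobj)).astype(np.int16), vox, origin)


def resample_to_grid(
    vol: BrightnessVolume | TissueLabelVolume,
    target_spacing_mm,
    fill=None,
):
    """Resample a volume onto a lattice with the given spacing.

    Brightness volumes are interpolated tri-linearly, label volumes by
    nearest neighbour, so oversampling a coarse MRI lattice to the acoustic
    grid never invents labels.  World coordinates are preserved: target voxel
    0 is centered on the source voxel 0 center.  Queries outside the source
    domain receive ``fill`` (default 0 for brightness, WATER for labels).
    """

    target = np.asarray(target_spacing_mm, dtype=np.float64).reshape(-1)
    data = vol.values if isinstance(vol, BrightnessVolume) else vol.labels
    if target.size == 1:
        target = np.repeat(target, data.ndim)
    if np.any(target <= 0):
        raise ValueError("target spacing must be strictly positive")

    extent = (np.asarray(data.shape) - 1) * vol.voxel_mm[: data.ndim]
    new_shape = np.floor(extent / target + 1e-9).astype(int) + 1
    axes = [np.arange(n) * target[i] / vol.voxel_mm[i] for i, n in enumerate(new_shape)]
    coords = np.meshgrid(*axes, indexing="ij")

    if isinstance(vol, BrightnessVolume):
        out = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
        fill_value = 0.0 if fill is None else fill
    else:
        out = ndimage.map_coordinates(data, coords, order=0, mode="nearest")
        fill_value = int(Tissue.WATER) if fill is None else fill

    outside = np.zeros(tuple(new_shape), dtype=bool)
    for i, ax in enumerate(axes):
        bad = (ax < -1e-9) | (ax > data.shape[i] - 1 + 1e-9)
        if bad.any():
            sl = [np.newaxis] * len(new_shape)
            sl[i] = slice(None)
            outside |= bad[tuple(sl)]
    if outside.any():
        logging.getLogger(__name__).info(
            "resample_to_grid: %d voxels outside the source domain filled with %s",
            int(outside.sum()), fill_value,
        )
    out[outside] = fill_value

    if isinstance(vol, BrightnessVolume):
        return BrightnessVolume(out, target, vol.origin_mm.copy())
    return TissueLabelVolume(out.astype(np.int16), target, vol.origin_mm.copy())
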