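"""Hounsfield-unit extraction from a CT voxel volume.

Recipe for the mean cancellous HU of each vertebral hemisphere:

1. ``threshold_fill`` -- bone mask by HU thresholding, holes filled per
   slice and in 3-D (captures the marrow space inside the cortex);
2. ``erode`` -- morphological erosion by a physical radius larger than
   the cortical thickness, leaving only cancellous interior;
3. ``hemisphere_means`` -- split at the sagittal plane through the mask
   centroid along the left-right axis and average the HU per side.

Volumes carry voxel spacing (mm) and axis orientation codes; the
left-right axis is taken from the metadata, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .parametrize import HemisphereHU

__all__ = [
    "VoxelVolume",
    "Mask",
    "threshold_fill",
    "erode",
    "hemisphere_means",
    "load_volume",
    "save_volume",
    "DEFAULT_BONE_THRESHOLD_HU",
    "DEFAULT_ERODE_RADIUS_MM",
]

#: default lower HU bound of the bone mask
DEFAULT_BONE_THRESHOLD_HU = 150.0
#: default erosion radius (mm); must exceed the cortical thickness
DEFAULT_ERODE_RADIUS_MM = 3.0

# orientation codes: each array axis is labelled by the anatomical
# direction of increasing index, one of R/L (right/left), A/P
# (anterior/posterior), S/I (superior/inferior) -- the nibabel axis-code
# convention.
_LR = {"R", "L"}


@dataclass
class VoxelVolume:
    """3-D grid of HU values with spacing (mm) and orientation metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation: tuple[str, str, str] = ("R", "A", "S")
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        codes = tuple(str(c).upper() for c in self.orientation)
        groups = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}
        if any(c not in groups for c in codes) or len({groups[c] for c in codes}) != 3:
            raise ValueError(f"invalid orientation codes {self.orientation}")
        self.orientation = codes

    @property
    def lr_axis(self) -> int:
        """Index of the array axis running left-right."""
        for k, c in enumerate(self.orientation):
            if c in _LR:
                return k
        raise ValueError("no left-right axis in orientation metadata")

    @property
    def left_is_low_index(self) -> bool:
        """True when decreasing index along ``lr_axis`` moves toward Left."""
        return self.orientation[self.lr_axis] == "R"


@dataclass
class Mask:
    """Binary grid congruent with a parent :class:`VoxelVolume`."""

    data: np.ndarray
    volume: Optional[VoxelVolume] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.volume is not None and self.data.shape != self.volume.data.shape:
            raise ValueError("mask shape must match its volume")

    @property
    def count(self) -> int:
        return int(self.data.sum())


def threshold_fill(
    vol: VoxelVolume,
    lo: float = DEFAULT_BONE_THRESHOLD_HU,
    hi: float = np.inf,
    slice_axis: Optional[int] = None,
) -> Mask:
    """Threshold mask (lo <= HU <= hi) with hole filling.

    Holes are filled slice-wise along ``slice_axis`` (default: the axis
    with the coarsest spacing, i.e. the scanner slice direction) and
    then in 3-D, so a closed cortical shell yields a filled solid mask.
    """
    if lo >= hi:
        raise ValueError("need lo < hi")
    raw = (vol.data >= lo) & (vol.data <= hi)
    if not raw.any():
        raise ValueError("threshold produced an empty mask")
    if slice_axis is None:
        slice_axis = int(np.argmax(vol.spacing))
    filled = np.empty_like(raw)
    for idx in range(raw.shape[slice_axis]):
        sl = [slice(None)] * 3
        sl[slice_axis] = idx
        filled[tuple(sl)] = ndimage.binary_fill_holes(raw[tuple(sl)])
    filled = ndimage.binary_fill_holes(filled)
    return Mask(filled, volume=vol)


def erode(mask: Mask, radius_mm: float = DEFAULT_ERODE_RADIUS_MM) -> Mask:
    """Erode by a ball of physical radius, honouring anisotropic spacing.

    Implemented via the Euclidean distance transform: a voxel survives
    when its distance to the nearest background voxel exceeds the
    radius.  This is exact up to voxel discretisation and makes
    ``erode(m, r1 + r2) == erode(erode(m, r1), r2)``.
    """
    if radius_mm <= 0:
        raise ValueError("erosion radius must be positive")
    if mask.volume is None:
        raise ValueError("mask needs its parent volume (for the spacing)")
    spacing = mask.volume.spacing
    dist = ndimage.distance_transform_edt(mask.data, sampling=spacing)
    out = dist > radius_mm
    if not out.any():
        raise ValueError(f"erosion by {radius_mm} mm emptied the mask")
    return Mask(out, volume=mask.volume)


def hemisphere_means(vol: VoxelVolume, mask: Mask) -> HemisphereHU:
    """Mean HU of the masked voxels on each side of the sagittal midplane.

    The split plane passes through the mask centroid along the
    left-right axis (taken from the orientation metadata); voxels on the
    plane itself go to the side their center falls on.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    axis = vol.lr_axis
    idx = np.nonzero(m)
    centroid = idx[axis].mean()
    coords = idx[axis]
    low = coords < centroid
    high = ~low
    if not low.any() or not high.any():
        raise ValueError("mask lies entirely on one side of the split plane")
    values = vol.data[idx].astype(float)
    mean_low = float(values[low].mean())
    mean_high = float(values[high].mean())
    if vol.left_is_low_index:
        hu_left, hu_right = mean_low, mean_high
    else:
        hu_left, hu_right = mean_high, mean_low
    return HemisphereHU(hu_left=hu_left, hu_right=hu_right)


# ---------------------------------------------------------------------------
# NIfTI I/O

_WORLD_AXIS = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}
_SIGN = {"R": 1.0, "L": -1.0, "A": 1.0, "P": -1.0, "S": 1.0, "I": -1.0}


def _affine(vol: VoxelVolume) -> np.ndarray:
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for array_axis, code in enumerate(vol.orientation):
        w = _WORLD_AXIS[code]
        aff[w, array_axis] = _SIGN[code] * vol.spacing[array_axis]
        aff[w, 3] = vol.origin[array_axis]
    return aff


def save_volume(path, vol: VoxelVolume) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol))
    nib.save(img, str(path))


def load_volume(path) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    codes = nib.orientations.aff2axcodes(img.affine)  # direction of increase
    # aff2axcodes returns the *destination* of increasing index (RAS+ codes)
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelVolume(
        data=np.asanyarray(img.dataobj).astype(np.float32),
        spacing=spacing,
        orientation=tuple(codes),
        origin=origin,
    )
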