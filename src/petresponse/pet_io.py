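"""SUV volume and tumor-mask handling.

Quantitative PET volumes carry body-weight-normalized standardized uptake
values (SUV) on an axis-aligned grid with millimetre voxel spacing.  This
module reads and writes such volumes as NIfTI, delineates a volume of
interest (VOI) by SUV thresholding, and resamples image/mask pairs onto an
isotropic 2 mm grid with trilinear interpolation — the geometry every
downstream feature computation assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "SUVImage",
    "VOIMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "delineate_suv_threshold",
    "resample_to_isotropic",
]

_FULL_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SUVImage:
    """A 3-D SUV volume with voxel spacing and world origin in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"SUVImage requires a 3-D grid, got {self.values.ndim}-D "
                f"shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive mm values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class VOIMask:
    """Binary tumor mask sharing grid, spacing and origin with its image."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"VOIMask requires a 3-D grid, got shape {arr.shape}")
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError("mask values must be binary (0/1)")
        self.values = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def check_paired(self, image: SUVImage) -> None:
        """Raise unless this mask shares the image's grid exactly."""
        if self.shape != image.shape:
            raise ValueError(f"mask shape {self.shape} != image shape {image.shape}")
        if not np.allclose(self.spacing, image.spacing):
            raise ValueError(f"mask spacing {self.spacing} != image spacing {image.spacing}")
        if not np.allclose(self.origin, image.origin):
            raise ValueError(f"mask origin {self.origin} != image origin {image.origin}")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(image: SUVImage | VOIMask, path) -> None:
    """Write an SUV volume or mask to NIfTI (.nii / .nii.gz)."""
    data = image.values.astype(np.uint8) if isinstance(image, VOIMask) else image.values
    nib.save(nib.Nifti1Image(data, _affine(image.spacing, image.origin)), str(path))


def _load(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D data")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: NIfTI header carries no valid voxel spacing ({zooms})")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path) -> SUVImage:
    """Read a 3-D SUV volume from NIfTI, taking spacing from the affine."""
    data, spacing, origin = _load(path)
    return SUVImage(np.asarray(data, dtype=np.float64), spacing, origin)


def read_mask(path) -> VOIMask:
    """Read a binary VOI mask from NIfTI."""
    data, spacing, origin = _load(path)
    return VOIMask(np.asarray(data) > 0.5, spacing, origin)


def delineate_suv_threshold(
    image: SUVImage,
    mode: str = "percent_of_max",
    value: float = 40.0,
    seed_region: tuple[slice, slice, slice] | None = None,
) -> VOIMask:
    """Delineate the tumor as the largest 26-connected super-threshold component.

    Parameters
    ----------
    mode
        ``"absolute_suv"`` thresholds at ``value`` SUV; ``"percent_of_max"``
        at ``value`` percent of the maximum SUV inside ``seed_region``.
    value
        Threshold, in SUV or percent depending on ``mode``.
    seed_region
        Optional index slices bounding the search; defaults to the full grid.

    Voxels strictly above the threshold are candidates; the largest
    26-connected candidate component inside the seed region becomes the VOI.
    """
    if mode not in ("absolute_suv", "percent_of_max"):
        raise ValueError(f"mode must be 'absolute_suv' or 'percent_of_max', got {mode!r}")
    region = seed_region if seed_region is not None else tuple(slice(None) for _ in range(3))
    sub = image.values[region]
    if sub.size == 0:
        raise ValueError("seed_region selects no voxels")
    threshold = float(value) if mode == "absolute_suv" else float(value) / 100.0 * float(sub.max())
    above = sub > threshold
    if not above.any():
        raise ValueError(
            f"no voxel exceeds the threshold ({threshold:.3g} SUV); "
            "lower the threshold or widen the seed region"
        )
    labels, n = ndimage.label(above, structure=_FULL_26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    full = np.zeros(image.shape, dtype=bool)
    full[region] = labels == keep
    return VOIMask(full, image.spacing, image.origin)


def resample_to_isotropic(
    image: SUVImage,
    mask: VOIMask,
    target_spacing: float = 2.0,
) -> tuple[SUVImage, VOIMask]:
    """Resample a paired image and mask onto an isotropic grid.

    Both are trilinearly interpolated onto a ``target_spacing`` mm grid that
    shares the input origin and stays inside the input physical extent.  The
    interpolated mask is then rounded to binary with 0.5 rounding *up*, so a
    voxel exactly half-covered remains foreground.
    """
    mask.check_paired(image)
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    shape = image.shape
    if any(n < 2 for n in shape):
        raise ValueError(
            f"cannot resample a degenerate volume (shape {shape}); "
            "each axis needs at least 2 voxels"
        )
    new_shape = tuple(
        int(np.floor((n - 1) * s / target_spacing)) + 1 for n, s in zip(shape, image.spacing)
    )
    # index coordinates of the new grid expressed on the old grid
    axes = [
        np.arange(m) * target_spacing / s for m, s in zip(new_shape, image.spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])

    vals = ndimage.map_coordinates(image.values, coords, order=1, mode="nearest")
    new_vals = vals.reshape(new_shape)
    mvals = ndimage.map_coordinates(mask.values.astype(np.float64), coords, order=1, mode="nearest")
    new_mask = (mvals.reshape(new_shape) >= 0.5)  # round half up

    sp = (target_spacing,) * 3
    out_img = SUVImage(np.clip(new_vals, 0.0, None), sp, image.origin)
    out_mask = VOIMask(new_mask, sp, image.origin)
    if out_mask.voxel_count == 0:
        raise ValueError("mask is empty after resampling; input VOI thinner than the target grid")
    return out_img, out_mask
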