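"""Volume/mask handling: file I/O, isotropic resampling and gray-level discretization.

Images are kept as plain numpy arrays in (x, y, z) index order together with
their physical voxel spacing in millimetres.  Voxel centers follow the usual
half-voxel convention: voxel index i along an axis with spacing s sits at
physical coordinate origin + i * s, i.e. the origin is the center of voxel
(0, 0, 0), not its corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular grid.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values, axis order (x, y, z).
    spacing_mm : tuple of float
        Physical voxel size per axis, strictly positive.
    origin : tuple of float
        Physical coordinate of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_sitk(self) -> sitk.Image:
        # SimpleITK array layout is (z, y, x); transpose on the way out.
        data = self.data.astype(np.uint8) if self.data.dtype == bool else self.data
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
        img.SetSpacing(self.spacing_mm)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        data = sitk.GetArrayFromImage(img).T
        return cls(data=data, spacing_mm=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


@dataclass
class DiscretizedROI:
    """Gray levels of a masked region after fixed-bin-width discretization.

    ``levels`` is an integer array on the full image grid with 0 outside the
    mask and values in [1, n_levels] inside.
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float
    min_intensity: float
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.levels > 0
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("levels inside mask must lie in [1, n_levels]")


def read_volume(path: str) -> ImageVolume:
    """Read an NRRD or NIfTI volume (spacing/origin metadata preserved)."""
    return ImageVolume.from_sitk(sitk.ReadImage(str(path)))


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write to NRRD/NIfTI; the format follows the file extension."""
    sitk.WriteImage(volume.to_sitk(), str(path))


def resample_isotropic(
    volume: ImageVolume,
    mask: ImageVolume,
    target_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    interpolation: str = "linear",
    patient_id: str | None = None,
) -> tuple[ImageVolume, ImageVolume]:
    """Resample image and mask onto a ``target_mm`` grid.

    The image is interpolated (trilinear by default, ``interpolation`` may be
    ``"linear"``, ``"nearest"`` or ``"bspline"``); the mask is always
    nearest-neighbor so it stays binary.  Grids are aligned by physical
    coordinates; the output origin equals the input origin.

    Raises
    ------
    ValueError
        If the mask grid disagrees with the volume grid, or the resampled
        mask comes out empty.
    """
    if mask.shape != volume.shape or mask.spacing_mm != volume.spacing_mm:
        raise ValueError("mask must be aligned to the volume grid")
    target_mm = tuple(float(t) for t in target_mm)
    if any(t <= 0 for t in target_mm):
        raise ValueError("target spacing must be positive")

    interp = {
        "linear": sitk.sitkLinear,
        "nearest": sitk.sitkNearestNeighbor,
        "bspline": sitk.sitkBSpline,
    }[interpolation]

    src = volume.to_sitk()
    new_size = [
        max(2, int(round(n * s / t)))
        for n, s, t in zip(volume.shape, volume.spacing_mm, target_mm)
    ]

    def _resample(img: sitk.Image, how) -> sitk.Image:
        rs = sitk.ResampleImageFilter()
        rs.SetOutputSpacing(target_mm)
        rs.SetSize(new_size)
        rs.SetOutputOrigin(src.GetOrigin())
        rs.SetOutputDirection(src.GetDirection())
        rs.SetInterpolator(how)
        rs.SetDefaultPixelValue(0)
        return rs.Execute(img)

    out_vol = ImageVolume.from_sitk(_resample(src, interp))
    mask_img = sitk.Cast(mask.to_sitk(), sitk.sitkUInt8)
    out_mask = ImageVolume.from_sitk(_resample(mask_img, sitk.sitkNearestNeighbor))
    out_mask.data = out_mask.data > 0
    if not out_mask.data.any():
        who = f" for patient {patient_id}" if patient_id else ""
        raise ValueError(f"resampled mask is empty{who}")
    return out_vol, out_mask


def discretize(volume: np.ndarray | ImageVolume, mask: np.ndarray, bin_width: float = 25.0) -> DiscretizedROI:
    """Fixed-bin-width discretization referenced to the masked minimum.

    ``level(x) = floor((I(x) - min_masked) / bin_width) + 1`` inside the mask,
    0 outside; ``n_levels`` is the maximum assigned level (intermediate levels
    may be empty).  Invariant to adding a constant to all intensities.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    lo = float(data[mask].min())
    levels = np.zeros(data.shape, dtype=np.int32)
    levels[mask] = np.floor((data[mask] - lo) / bin_width).astype(np.int32) + 1
    return DiscretizedROI(
        levels=levels,
        n_levels=int(levels.max()),
        bin_width=float(bin_width),
        min_intensity=lo,
        mask=mask,
    )
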