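"""Intensity normalization and paired geometric augmentation.

Normalization rescales a slice by its own extrema to [0, 1]; augmentation
applies rotation, isotropic scaling and flips in that (inner-to-outer)
order, identically to the image and its mask.  Masks are re-binarized after
interpolation so they stay in {0, 1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError

__all__ = [
    "AugmentationSpec",
    "normalize_intensity",
    "augment_pair",
    "load_image",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Ranges for the random augmentation draw.

    Defaults: rotation uniform in +/- 15 degrees, scale uniform in
    [0.8, 1.2], horizontal and vertical flips each with probability 0.5.
    """

    rotation_degrees: float = 15.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    hflip: bool = True
    vflip: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.rotation_degrees < 0:
            raise ValidationError("rotation_degrees must be >= 0")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValidationError("scale_range must satisfy 0 < lo <= hi")

    def draw(self, rng: np.random.Generator) -> tuple[float, float, bool, bool]:
        r = rng.uniform(-self.rotation_degrees, self.rotation_degrees)
        s = rng.uniform(*self.scale_range)
        fh = bool(self.hflip and rng.random() < 0.5)
        fv = bool(self.vflip and rng.random() < 0.5)
        return r, s, fh, fv


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Min-max rescale an H x W grid to [0, 1].

    A constant image has no intensity range; by convention it maps to
    all-zeros with a warning rather than raising, so batch pipelines survive
    blank slices.
    """
    x = np.asarray(image, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValidationError("expected a non-empty H x W grid")
    if not np.all(np.isfinite(x)):
        raise ValidationError("image contains non-finite values")
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        warnings.warn("constant image: normalization returns all-zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(x)
    return (x - xmin) / (xmax - xmin)


def _rescale_about_center(arr: np.ndarray, scale: float, order: int) -> np.ndarray:
    """Zoom about the image center, then crop/pad back to the input shape."""
    if scale == 1.0:
        return arr
    h, w = arr.shape
    zoomed = ndimage.zoom(arr, scale, order=order, mode="constant", cval=0.0,
                          grid_mode=False, prefilter=order > 1)
    zh, zw = zoomed.shape
    out = np.zeros_like(arr)
    if zh >= h:
        top, left = (zh - h) // 2, (zw - w) // 2
        out[:, :] = zoomed[top : top + h, left : left + w]
    else:
        top, left = (h - zh) // 2, (w - zw) // 2
        out[top : top + zh, left : left + zw] = zoomed
    return out


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    spec: AugmentationSpec,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random (rotation, scale, flip) draw to an image-mask pair.

    Bilinear interpolation for the image, nearest-neighbour + 0.5 threshold
    for the mask; background fill is 0.  Output shape equals input shape.
    The draw is a pure function of the spec's seed unless an explicit ``rng``
    is passed.
    """
    spec.validate()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValidationError("image and mask must share shape")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    r, s, fh, fv = spec.draw(rng)

    img = image
    msk = mask.astype(float)
    if r != 0.0:
        img = ndimage.rotate(img, r, reshape=False, order=1, mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, r, reshape=False, order=0, mode="constant", cval=0.0)
    img = _rescale_about_center(img, s, order=1)
    msk = _rescale_about_center(msk, s, order=0)
    if fh:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if fv:
        img = img[::-1, :]
        msk = msk[::-1, :]

    img = np.clip(np.ascontiguousarray(img), 0.0, 1.0)
    msk = (np.ascontiguousarray(msk) > 0.5).astype(np.uint8)
    return img, msk


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale slice (PNG/JPEG, NIfTI .nii/.nii.gz, or single-frame
    DICOM) into an H x W float grid in native intensity units."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        if data.ndim != 2:
            raise ValidationError(f"{path.name}: expected a 2-D slice, got shape {data.shape}")
        return np.asarray(data, dtype=float)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.squeeze()
        if arr.ndim != 2:
            raise ValidationError(f"{path.name}: expected a single-frame DICOM")
        return np.asarray(arr, dtype=float)
    from PIL import Image

    return np.asarray(Image.open(path).convert("F"), dtype=float)
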