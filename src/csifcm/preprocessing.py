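"""Image loading, min–max normalization and Gaussian noise injection.

Images are plain 2-D float64 arrays.  Clustering operates on intensities
normalized to [0, 1]; the loaders keep whatever scale the file carries and
:func:`normalize_intensities` maps it.  Multi-channel inputs are reduced to
grayscale by the ITU-R 601 luminance weights before anything else.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import nibabel as nib
import numpy as np

_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an (H, W[, C]) array to 2-D by luminance; pass 2-D through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[:, :, :3] @ _LUMA
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    raise ValueError(f"cannot interpret shape {image.shape} as a grayscale image")


def load_image(path: str | os.PathLike, slice_index: int | None = None, axis: int = 2) -> np.ndarray:
    """Read a 2-D grayscale image from PNG/TIFF or a single NIfTI slice.

    For ``.nii``/``.nii.gz`` volumes ``slice_index`` selects a slice along
    ``axis`` (default: axial, the middle slice when unspecified).
    """
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(path).dataobj).astype(float)
        if data.ndim == 2:
            return data
        if slice_index is None:
            slice_index = data.shape[axis] // 2
        return np.take(data, slice_index, axis=axis)
    return to_grayscale(iio.imread(path))


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0,1] float image as 8-bit PNG/TIFF, or float NIfTI."""
    path = os.fspath(path)
    image = np.asarray(image, dtype=float)
    if path.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), path)
    else:
        iio.imwrite(path, np.clip(np.round(image * 255), 0, 255).astype(np.uint8))


def save_label_map(labels: np.ndarray, path: str | os.PathLike) -> None:
    """Write an integer label map as PNG (uint8) or NIfTI (int16)."""
    path = os.fspath(path)
    labels = np.asarray(labels)
    if path.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(labels.astype(np.int16), np.eye(4)), path)
    else:
        iio.imwrite(path, labels.astype(np.uint8))


def normalize_intensities(image: np.ndarray) -> np.ndarray:
    """Min–max map to [0, 1]: (x - min) / (max - min); constant images -> 0.

    Idempotent on already-normalized non-degenerate images.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def add_gaussian_noise(image: np.ndarray, variance: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given variance, then clip to [0, 1].

    Works on the normalized intensity scale: a variance of 0.01 is the
    conventional reading of "1% Gaussian noise" for [0, 1] images (the MATLAB
    ``imnoise`` convention).  Identical seeds give identical outputs.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    image = np.asarray(image, dtype=float)
    if variance == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image + rng.normal(0.0, np.sqrt(variance), size=image.shape)
    return np.clip(noisy, 0.0, 1.0)
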