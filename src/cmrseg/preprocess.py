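"""Reversible mapping of 2D slices onto the fixed network grid.

Every slice, whatever its acquisition matrix and pixel size, is
resampled to 1.37 mm x 1.37 mm pixels, center-cropped or zero-padded to
212 x 212, and z-scored per slice.  The :class:`ResampleRecord` returned
alongside carries everything needed to map a predicted label map back to
the original acquisition grid with nearest-neighbor interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

TARGET_SHAPE: tuple[int, int] = (212, 212)
TARGET_SPACING_MM: tuple[float, float] = (1.37, 1.37)

_ZERO_VAR_GUARD = 1e-6


@dataclass(frozen=True)
class ResampleRecord:
    """Spatial and intensity bookkeeping of one slice's preprocessing."""

    original_shape: tuple[int, int]
    original_spacing_mm: tuple[float, float]
    resampled_shape: tuple[int, int]
    target_shape: tuple[int, int]
    target_spacing_mm: tuple[float, float]
    intensity_shift: float  # slice mean subtracted
    intensity_scale: float  # slice sd divided by (1.0 if degenerate)


def zscore(img: np.ndarray) -> np.ndarray:
    """Per-slice z-score; constant slices map to all zeros."""
    img = np.asarray(img, dtype=np.float32)
    sd = float(img.std())
    if sd < _ZERO_VAR_GUARD:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def _crop_or_pad(img: np.ndarray, shape: tuple[int, int], fill: float = 0.0) -> np.ndarray:
    out = np.full(shape, fill, dtype=img.dtype)
    src_slices, dst_slices = [], []
    for ax in range(2):
        n, m = img.shape[ax], shape[ax]
        if n >= m:  # crop centrally
            off = (n - m) // 2
            src_slices.append(slice(off, off + m))
            dst_slices.append(slice(0, m))
        else:  # pad centrally
            off = (m - n) // 2
            src_slices.append(slice(0, n))
            dst_slices.append(slice(off, off + n))
    out[tuple(dst_slices)] = img[tuple(src_slices)]
    return out


def to_network_grid(
    slice2d: np.ndarray,
    spacing_mm: tuple[float, float],
    target_shape: tuple[int, int] = TARGET_SHAPE,
    target_spacing_mm: tuple[float, float] = TARGET_SPACING_MM,
) -> tuple[np.ndarray, ResampleRecord]:
    """Resample one slice to the network grid and z-score it.

    The physical field of view is resampled to the target pixel size
    (bilinear), then center-cropped / zero-padded to the target shape.
    Intensity is z-scored after resampling, with a zero-variance guard.
    """
    slice2d = np.asarray(slice2d, dtype=np.float32)
    if slice2d.ndim != 2 or slice2d.size == 0:
        raise ValueError("expected a non-empty 2D slice")
    if min(spacing_mm) <= 0:
        raise ValueError("non-positive spacing")
    res_shape = tuple(
        max(1, int(round(slice2d.shape[ax] * spacing_mm[ax] / target_spacing_mm[ax])))
        for ax in range(2)
    )
    if res_shape != slice2d.shape:
        resampled = resize(
            slice2d, res_shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
        ).astype(np.float32)
    else:
        resampled = slice2d
    # z-score on the content region, then pad with zeros (= the mean
    # after normalization), so padding never skews the statistics
    sd = float(resampled.std())
    mean = float(resampled.mean())
    if sd < _ZERO_VAR_GUARD:
        normed = np.zeros_like(resampled)
        shift, scale = mean, 1.0
    else:
        normed = (resampled - mean) / sd
        shift, scale = mean, sd
    out = _crop_or_pad(normed, target_shape)
    record = ResampleRecord(
        original_shape=slice2d.shape,
        original_spacing_mm=(float(spacing_mm[0]), float(spacing_mm[1])),
        resampled_shape=res_shape,
        target_shape=target_shape,
        target_spacing_mm=target_spacing_mm,
        intensity_shift=shift,
        intensity_scale=scale,
    )
    return out, record


def from_network_grid(mask2d: np.ndarray, record: ResampleRecord) -> np.ndarray:
    """Map a label map on the network grid back to the original grid.

    Inverts the center crop/pad, then nearest-neighbor resamples to the
    original shape.  Output labels are a subset of the input's labels.
    """
    mask2d = np.asarray(mask2d)
    if mask2d.shape != tuple(record.target_shape):
        raise ValueError(
            f"mask shape {mask2d.shape} does not match record {record.target_shape}"
        )
    # invert crop/pad back onto the resampled grid
    inter = _crop_or_pad(mask2d, record.resampled_shape)
    if record.resampled_shape == record.original_shape:
        return inter.astype(mask2d.dtype)
    out = resize(
        inter.astype(np.float32),
        record.original_shape,
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.rint(out).astype(mask2d.dtype)
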