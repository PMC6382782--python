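"""Binarization of denoised enface images and vessel-artifact removal.

Three stages turn a denoised OCT/OCTA pair into a clean fold mask:

1. :func:`adaptive_threshold` — local mean thresholding (window 35, offset 6
   by default), white where a pixel is strictly brighter (``polarity
   'bright'``, OCTA flow signal) or strictly darker (``polarity 'dark'``,
   hyporeflective folds and vessel shadows) than its local threshold.
2. :func:`subtract_vessels` — the binarized OCTA vessel tree (optionally
   dilated) is removed from the binarized OCT mask, deleting the shadow
   artifacts the vessels cast on the outer-retina slab.
3. :func:`remove_small_blobs` — connected components of fewer than 50 white
   pixels are discarded as noise (strict "less than").
"""

from __future__ import annotations

import numpy as np
from skimage import measure, morphology

__all__ = ["adaptive_threshold", "subtract_vessels", "remove_small_blobs"]


def _window_sums(img: np.ndarray, window: int) -> np.ndarray:
    """Exact sliding-window sums with replicate padding via integral image.

    Integer inputs are summed in int64 so the bright/dark comparison can be
    carried out exactly (no float rounding at the strict-inequality tie).
    """
    r = window // 2
    pad = np.pad(img, r, mode="edge")
    dtype = np.int64 if np.issubdtype(img.dtype, np.integer) else np.float64
    ii = np.zeros((pad.shape[0] + 1, pad.shape[1] + 1), dtype=dtype)
    np.cumsum(pad, axis=0, dtype=dtype, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    h, w = img.shape
    return (
        ii[window : window + h, window : window + w]
        - ii[:h, window : window + w]
        - ii[window : window + h, :w]
        + ii[:h, :w]
    )


def adaptive_threshold(
    img: np.ndarray,
    window: int = 35,
    offset: float = 6.0,
    polarity: str = "bright",
) -> np.ndarray:
    """Local-mean adaptive threshold.

    For every pixel p the threshold is ``T(p) = mean(window x window
    neighbourhood, replicate-padded, centre included) + offset``.  The pixel
    is white iff its intensity strictly exceeds T(p) (``polarity='bright'``)
    or strictly falls below it (``polarity='dark'``); a pixel exactly at the
    threshold is black.

    For integer images with an integer offset the comparison is performed in
    exact integer arithmetic (intensity * window^2 vs window sum + offset *
    window^2), so results are bit-reproducible and tie handling is exact.

    Returns a boolean mask of the same shape.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")

    area = window * window
    sums = _window_sums(img, window)
    exact = np.issubdtype(img.dtype, np.integer) and float(offset).is_integer()
    if exact:
        lhs = img.astype(np.int64) * area
        rhs = sums + int(offset) * area
    else:
        lhs = img.astype(np.float64)
        rhs = sums / area + offset
    return lhs > rhs if polarity == "bright" else lhs < rhs


def subtract_vessels(
    oct_mask: np.ndarray,
    octa_mask: np.ndarray,
    dilate_radius: int = 0,
) -> np.ndarray:
    """Remove vessel pixels from the OCT fold mask.

    The OCTA vessel mask is optionally dilated by a disk of
    ``dilate_radius`` pixels (shadow artifacts can be wider than the vessel
    core), then every vessel pixel is cleared from the OCT mask — the
    saturating binary equivalent of the image subtraction OCT − OCTA.
    """
    oct_mask = np.asarray(oct_mask, dtype=bool)
    octa_mask = np.asarray(octa_mask, dtype=bool)
    if oct_mask.shape != octa_mask.shape:
        raise ValueError(
            f"shape mismatch: oct {oct_mask.shape} vs octa {octa_mask.shape}"
        )
    if dilate_radius < 0:
        raise ValueError("dilate_radius must be >= 0")
    if dilate_radius > 0:
        octa_mask = morphology.dilation(
            octa_mask, footprint=morphology.disk(dilate_radius)
        ).astype(bool)
    return oct_mask & ~octa_mask


def remove_small_blobs(
    mask: np.ndarray,
    min_pixels: int = 50,
    connectivity: int = 8,
) -> np.ndarray:
    """Delete connected components with fewer than ``min_pixels`` pixels.

    Components of exactly ``min_pixels`` are kept (the rule is strictly
    "less than").  ``connectivity`` is 4 (edge neighbours) or 8 (edge +
    diagonal, the default).
    """
    mask = np.asarray(mask, dtype=bool)
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_pixels <= 1 or not mask.any():
        return mask.copy()
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_pixels  # strict: area < min_pixels is removed
    keep[0] = False
    return keep[labels]
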