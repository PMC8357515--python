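"""Region-of-interest extraction: iterative thresholding plus morphology.

The threshold follows the classic two-class-mean iteration: starting from
the global mean, the threshold is repeatedly reset to the midpoint of the
means of the two classes it induces, until it moves by less than the
tolerance. Binarization keeps pixels strictly above the threshold (body is
brighter than the air background on CT). The mask is then cleaned by the
fixed chain dilation, erosion, hole filling, opening, closing; the largest
8-connected component is kept and applied to the slice as a mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.morphology import disk

from .types import HU_AIR_FLOOR, BinaryMask, CTSlice, as_bool_mask, check_same_shape

__all__ = [
    "ThresholdResult",
    "ROIResult",
    "iterative_threshold",
    "morphology_chain",
    "apply_mask",
    "extract_roi",
    "largest_component",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdResult:
    threshold_hu: float
    n_iterations: int
    history: tuple[float, ...]
    converged: bool
    degenerate: bool = False  # one side of the split was empty at some point


@dataclass(frozen=True)
class ROIResult:
    roi_mask: BinaryMask
    masked_slice: CTSlice
    threshold: ThresholdResult


def iterative_threshold(
    ct: CTSlice, tolerance: float = 0.5, max_iter: int = 100
) -> ThresholdResult:
    """Two-class-mean threshold iteration to a fixed point.

    ``T0`` is the image mean; ``T_{k+1}`` is the midpoint of the means of
    the pixels at or below ``T_k`` and strictly above it. An empty class
    contributes ``T_k`` itself as its mean, which forces convergence on
    constant images.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    x = ct.pixels
    t = float(x.mean())
    history = [t]
    degenerate = False
    converged = False
    n_iter = 0
    for _ in range(max_iter):
        low = x[x <= t]
        high = x[x > t]
        m_low = float(low.mean()) if low.size else t
        m_high = float(high.mean()) if high.size else t
        if not (low.size and high.size):
            degenerate = True
        t_new = (m_low + m_high) / 2.0
        n_iter += 1
        history.append(t_new)
        if abs(t_new - t) < tolerance:
            t = t_new
            converged = True
            break
        t = t_new
    return ThresholdResult(
        threshold_hu=t,
        n_iterations=n_iter,
        history=tuple(history),
        converged=converged,
        degenerate=degenerate,
    )


def morphology_chain(mask: BinaryMask, se_radius_px: int = 2) -> BinaryMask:
    """Dilation, erosion, hole filling, opening, closing — in that order.

    The structuring element is a disk of ``se_radius_px``; pixels outside
    the image count as background. The sixth named step, masking, is
    :func:`apply_mask`.
    """
    if se_radius_px < 1:
        raise ValueError("se_radius_px must be >= 1")
    m = as_bool_mask(mask)
    se = disk(se_radius_px)
    m = ndimage.binary_dilation(m, se)
    m = ndimage.binary_erosion(m, se, border_value=0)
    m = ndimage.binary_fill_holes(m)
    m = ndimage.binary_opening(m, se)
    m = ndimage.binary_closing(m, se)
    return m


def apply_mask(ct: CTSlice, mask: BinaryMask, fill_hu: float = HU_AIR_FLOOR) -> CTSlice:
    """Keep slice values where the mask is true, fill elsewhere."""
    m = as_bool_mask(mask)
    check_same_shape(ct.pixels, m, "slice and mask")
    out = np.where(m, ct.pixels, fill_hu)
    return CTSlice(out, ct.spacing_mm)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """The largest 8-connected foreground component (empty in → empty out)."""
    m = as_bool_mask(mask)
    if not m.any():
        return m
    labels = label(m, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


@dataclass(frozen=True)
class ROIParams:
    tolerance_hu: float = 0.5
    max_iter: int = 100
    se_radius_px: int = 2
    fill_hu: float = HU_AIR_FLOOR


def extract_roi(ct: CTSlice, params: ROIParams | None = None) -> ROIResult:
    """Threshold, clean up, keep the largest component, mask the slice.

    The returned ROI mask is a single 8-connected component without
    interior holes (or empty, with a warning, when nothing exceeds the
    threshold).
    """
    params = params or ROIParams()
    thr = iterative_threshold(ct, params.tolerance_hu, params.max_iter)
    fg = ct.pixels > thr.threshold_hu
    if not fg.any():
        logger.warning(
            "no pixels above threshold %.1f HU: empty ROI", thr.threshold_hu
        )
        return ROIResult(
            roi_mask=fg,
            masked_slice=apply_mask(ct, fg, params.fill_hu),
            threshold=thr,
        )
    m = morphology_chain(fg, params.se_radius_px)
    m = largest_component(m)
    # guarantee the hole-free contract even if closing walled in background
    m = ndimage.binary_fill_holes(m)
    return ROIResult(
        roi_mask=m,
        masked_slice=apply_mask(ct, m, params.fill_hu),
        threshold=thr,
    )
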