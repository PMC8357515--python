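"""Core value types shared across the pipeline.

A :class:`CTSlice` is the unit of processing: a 2-D array of Hounsfield
units plus the physical pixel spacing. Binary masks are plain boolean
``numpy`` arrays aligned pixel-for-pixel with a slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Plausible Hounsfield range for 12-bit CT data.
HU_MIN = -1024
HU_MAX = 3071

#: Fill value used for pixels masked out of a slice (air floor).
HU_AIR_FLOOR = -1024.0

BinaryMask = np.ndarray  # boolean 2-D array


@dataclass
class CTSlice:
    """A single 2-D CT slice in Hounsfield units.

    Parameters
    ----------
    pixels:
        2-D float array of HU values.
    spacing_mm:
        ``(row, col)`` physical size of one pixel in millimetres.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"CTSlice.pixels must be 2-D, got {self.pixels.ndim}-D")
        if self.pixels.size == 0:
            raise ValueError("CTSlice.pixels must be non-empty")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTSlice.pixels must be finite")
        r, c = self.spacing_mm
        if r <= 0 or c <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        self.spacing_mm = (float(r), float(c))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_bool_mask(mask: np.ndarray) -> BinaryMask:
    """Coerce an array to a boolean mask (any nonzero value is foreground)."""
    return np.asarray(mask) != 0


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "arrays") -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch between {what}: {a.shape} vs {b.shape}")
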