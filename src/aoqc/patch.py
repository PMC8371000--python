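"""Core data containers: image patches and quality grade categories.

A *patch* is one 50 x 50 µm sampling window cut from an adaptive-optics
flood-illumination ophthalmoscopy (AO-FIO) mosaic — a small grayscale image
of the cone photoreceptor mosaic, about 65 x 65 px at the default pixel
scale of 50/65 ≈ 0.769 µm/px.

Quality grading uses three ordinal categories:

1. more than 5% of the patch is truncated (lies off the mosaic edge);
2. at most 5% truncation, but cones are unresolvable in at least one
   quadrant (poor quality);
3. at most 5% truncation with resolvable cones in all four quadrants
   (acceptable for quantitative analysis).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GradeCategory", "Provenance", "Patch"]


class GradeCategory(enum.IntEnum):
    """Ordinal image-quality category."""

    TRUNCATED = 1
    POOR = 2
    ACCEPTABLE = 3


#: Window position tags within one region of interest.
WINDOW_TAGS = ("Mid", "TL", "TR", "BL", "BR")

#: Quadrant tags, used for per-quadrant degradation.
QUADRANTS = ("TL", "TR", "BL", "BR")


@dataclass(frozen=True)
class Provenance:
    """Where a patch came from: subject, retinal location, window position."""

    subject_id: Optional[str] = None
    eccentricity_deg: Optional[float] = None
    meridian: Optional[str] = None
    window: Optional[str] = None

    def __post_init__(self) -> None:
        if self.window is not None and self.window not in WINDOW_TAGS:
            raise ValueError(f"window must be one of {WINDOW_TAGS}, got {self.window!r}")


@dataclass(frozen=True)
class Patch:
    """One 2-D grayscale sampling window.

    Parameters
    ----------
    intensities
        2-D array of finite, nonnegative intensities (row-major, top-left
        origin). Must be at least 3 x 3 px so the Laplacian kernel fits.
    pixel_scale
        Retinal sampling in µm per pixel.
    provenance
        Optional subject/location metadata.
    """

    intensities: np.ndarray
    pixel_scale: float
    provenance: Optional[Provenance] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"intensities must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValueError(f"patch must be at least 3x3 px, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_scale > 0:
            raise ValueError(f"pixel_scale must be > 0, got {self.pixel_scale}")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def side_um(self) -> float:
        """Physical side length (rows) in µm."""
        return self.shape[0] * self.pixel_scale
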